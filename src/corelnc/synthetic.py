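"""Synthetic multi-omics study with planted ground truth.

Every input layer of the pipeline is generated here with known
parameters, so each downstream stage can be tested for parameter
recovery without external data:

* a gene annotation (ids, biotype, chromosome, TSS, strand) on a spaced
  TSS grid so window arithmetic is unambiguous;
* activation expression datasets: negative-binomial counts with
  log-normally varying library sizes, where planted TF-induced target
  lncRNAs (and target mRNAs) have their mean shifted by ``effect_log2fc``
  in treated samples;
* ChIP peak sets: treated datasets place a peak uniformly within 900 bp
  upstream of each target TSS (strand-aware) with probability
  ``peak_prob_target``; every gene additionally receives background peaks
  near its locus with probability ``peak_prob_background``; control
  datasets use the background rate throughout;
* tumor cohorts: mRNA expression assembled from the linear model
  ``b0 + b_DM*DM + b_CNV*CNV + sum(b_lnc*lnc) + noise`` with methylation
  beta-values, GISTIC-style integer copy-number scores and independent
  lncRNA expression; p53-LOF samples have target-lncRNA expression
  attenuated; exponential survival with administrative censoring, hazard
  tied to designated lncRNAs;
* dependency screens: growth-promoting genes score around ``-dep_effect``,
  everything else around 0, with Gaussian noise, for each cell line and
  screen type.

All generators are pure functions of ``(config, seed)``; files written by
this module round-trip losslessly through its readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chip import PeakSet, read_bed, write_bed
from .config import SimulationConfig, derive_seed
from .depgsea import DependencyScreen
from .diffexpr import CountMatrix
from .exceptions import ConfigurationError, DataError
from .network import OmicsCohort

__all__ = [
    "TruthSet",
    "generate_annotation",
    "make_truth",
    "generate_activation_datasets",
    "generate_chip_datasets",
    "generate_cohort",
    "generate_cohorts",
    "generate_dependency_screens",
    "per_unit_multiplier_for_group_hr",
    "write_study",
    "read_study",
]

# Expected standardized-expression gap between median-split halves of a
# normal covariate: E[x | x > med] - E[x | x < med] = 2*sqrt(2/pi).
GROUP_SPLIT_GAP = 2.0 * np.sqrt(2.0 / np.pi)

TSS_SPACING = 100_000
N_CHROMS = 22


@dataclass
class TruthSet:
    """Planted ground truth for recovery tests.

    ``lnc_mrna_effects`` maps (lncRNA id, mRNA id) -> planted linear
    coefficient; ``survival_hazard_map`` maps lncRNA id -> hazard
    multiplier per standardized unit of expression (multiplier < 1 is
    protective).
    """

    target_lncrnas: set[str] = field(default_factory=set)
    target_mrnas: set[str] = field(default_factory=set)
    lnc_mrna_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    growth_promoting_genes: set[str] = field(default_factory=set)
    survival_hazard_map: dict[str, float] = field(default_factory=dict)

    def validate(self, annotation: pd.DataFrame) -> None:
        lncs = set(annotation.loc[annotation["biotype"] == "lncRNA", "gene_id"])
        all_genes = set(annotation["gene_id"])
        if not self.target_lncrnas <= lncs:
            raise DataError("target_lncrnas must be annotated lncRNAs")
        for lnc, mrna in self.lnc_mrna_effects:
            if lnc not in all_genes or mrna not in all_genes:
                raise DataError(f"lnc_mrna_effects references unannotated gene ({lnc}, {mrna})")


def per_unit_multiplier_for_group_hr(group_hr: float) -> float:
    """Per-standardized-unit hazard multiplier giving approximately
    ``group_hr`` between median-split expression halves."""
    return float(group_hr ** (1.0 / GROUP_SPLIT_GAP))


def generate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Gene annotation table with a deterministic spaced TSS layout.

    Returns ``n_genes`` rows (columns ``gene_id``, ``biotype``,
    ``chrom``, ``tss``, ``strand``), exactly ``n_lncrnas`` of biotype
    lncRNA, byte-identical for a fixed seed.  TSSs sit on a 100 kb grid
    with +-10 kb jitter so distinct genes never share a 10 kb window.
    """
    config.check()
    rng = np.random.default_rng(derive_seed(config.seed, "annotation"))
    n = config.n_genes
    ids = [f"LNC{i:05d}" for i in range(config.n_lncrnas)] + [
        f"PCG{i:05d}" for i in range(n - config.n_lncrnas)
    ]
    biotype = ["lncRNA"] * config.n_lncrnas + ["protein_coding"] * (n - config.n_lncrnas)
    order = rng.permutation(n)  # interleave biotypes along the genome
    chrom_idx = np.arange(n) % N_CHROMS
    slot = np.arange(n) // N_CHROMS
    tss = (slot + 1) * TSS_SPACING + rng.integers(-10_000, 10_001, size=n)
    strand = rng.choice(["+", "-"], size=n)
    ann = pd.DataFrame(
        {
            "gene_id": np.asarray(ids)[order],
            "biotype": np.asarray(biotype)[order],
            "chrom": [f"chr{c + 1}" for c in chrom_idx],
            "tss": tss.astype(np.int64),
            "strand": strand,
        }
    )
    return ann.sort_values("gene_id", ignore_index=True)


def make_truth(annotation: pd.DataFrame, config: SimulationConfig) -> TruthSet:
    """Plant the ground truth for a study.

    Target lncRNAs are TF-induced; each receives ``n_assoc_per_side``
    positively and negatively associated mRNAs (coefficients
    +-``beta_lnc_effect``) drawn from two disjoint pools so that the
    negatively associated genes can double as the growth-promoting set
    without contaminating the positive sets.  ``n_protective_lncrnas`` of
    the targets get a protective survival hazard multiplier tuned so the
    median-split hazard ratio is ``protective_group_hr``.
    """
    config.check()
    rng = np.random.default_rng(derive_seed(config.seed, "truth"))
    lncs = annotation.loc[annotation["biotype"] == "lncRNA", "gene_id"].to_numpy()
    pcgs = annotation.loc[annotation["biotype"] == "protein_coding", "gene_id"].to_numpy()
    targets = set(rng.choice(lncs, size=config.n_target_lncrnas, replace=False))
    n_tm = min(config.n_target_mrnas, len(pcgs))
    target_mrnas = set(rng.choice(pcgs, size=n_tm, replace=False))

    pool_size = min(config.assoc_pool_size, len(pcgs) // 2)
    shuffled = rng.permutation(pcgs)
    pool_neg = shuffled[:pool_size]
    pool_pos = shuffled[pool_size : 2 * pool_size]
    effects: dict[tuple[str, str], float] = {}
    growth: set[str] = set()
    k = min(config.n_assoc_per_side, pool_size)
    for lnc in sorted(targets):
        neg = rng.choice(pool_neg, size=k, replace=False)
        pos = rng.choice(pool_pos, size=k, replace=False)
        for g in neg:
            effects[(lnc, str(g))] = -config.beta_lnc_effect
        for g in pos:
            effects[(lnc, str(g))] = config.beta_lnc_effect
        growth.update(str(g) for g in neg)

    m = per_unit_multiplier_for_group_hr(1.0 / config.protective_group_hr)
    protective = sorted(targets)[: config.n_protective_lncrnas]
    hazard = {lnc: m for lnc in protective}
    truth = TruthSet(
        target_lncrnas=targets,
        target_mrnas=target_mrnas,
        lnc_mrna_effects=effects,
        growth_promoting_genes=growth,
        survival_hazard_map=hazard,
    )
    truth.validate(annotation)
    return truth


def generate_activation_datasets(
    annotation: pd.DataFrame, truth: TruthSet, config: SimulationConfig
) -> list[CountMatrix]:
    """Negative-binomial activation datasets with planted induction.

    Each of ``n_datasets`` matrices has ``n_treated`` treated and
    ``n_control`` control samples.  Per-gene baseline means are
    log-normal around ``base_mean``; library sizes vary log-normally
    (sd ``libsize_sd``); treated-sample means of planted targets
    (lncRNA and mRNA) are multiplied by ``2**effect_log2fc``; counts are
    NB with dispersion ``nb_dispersion`` (variance mu + phi*mu^2).
    """
    config.check()
    if not truth.target_lncrnas <= set(annotation["gene_id"]):
        raise DataError("truth targets must be annotated")
    if config.n_treated < 3 or config.n_control < 3:
        raise ConfigurationError("activation datasets need >= 3 samples per condition")
    rng = np.random.default_rng(derive_seed(config.seed, "activation"))
    genes = annotation["gene_id"].to_numpy()
    is_target = np.isin(genes, sorted(truth.target_lncrnas | truth.target_mrnas))
    phi = config.nb_dispersion
    out = []
    for d in range(config.n_datasets):
        base = np.exp(rng.normal(np.log(config.base_mean), 1.0, size=len(genes)))
        n_t, n_c = config.n_treated, config.n_control
        libs = np.exp(rng.normal(0.0, config.libsize_sd, size=n_t + n_c))
        cond = ["treated"] * n_t + ["control"] * n_c
        mu = np.outer(base, libs)
        mu[is_target, :n_t] *= 2.0**config.effect_log2fc
        counts = rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))
        samples = [f"D{d:02d}_S{i}_{c}" for i, c in enumerate(cond)]
        cm = CountMatrix(
            dataset_id=f"D{d:02d}",
            counts=pd.DataFrame(counts, index=genes, columns=samples),
            condition=pd.Series(cond, index=samples),
        )
        out.append(cm)
    return out


def _upstream_peak(rng, tss: int, strand: str, window: int) -> tuple[int, int]:
    """A random interval entirely within ``window`` bp upstream of a TSS,
    by the covered-base distance convention."""
    width = int(rng.integers(50, 151))
    width = min(width, window)
    if strand == "+":
        start = int(rng.integers(tss - window, tss - width + 1))
    else:
        start = int(rng.integers(tss + 1, tss + window - width + 2))
    return start, start + width


def generate_chip_datasets(
    annotation: pd.DataFrame, truth: TruthSet, config: SimulationConfig
) -> list[PeakSet]:
    """ChIP peak sets per treatment class with planted promoter binding.

    Treated datasets (Nutlin and non-Nutlin classes) place a peak within
    ``upstream_window`` (default 900) bp upstream of each target lncRNA's
    TSS with probability ``peak_prob_target``; every gene in every
    dataset additionally gets a background peak near its locus
    (uniform within +-50 kb of the TSS) with probability
    ``peak_prob_background``.  Control datasets use only the background
    process.
    """
    config.check()
    rng = np.random.default_rng(derive_seed(config.seed, "chip"))
    ann = annotation.set_index("gene_id")
    targets = sorted(truth.target_lncrnas)
    t_tss = ann.loc[targets, "tss"].to_numpy(dtype=np.int64)
    t_strand = ann.loc[targets, "strand"].to_numpy()
    t_chrom = ann.loc[targets, "chrom"].to_numpy()
    all_tss = ann["tss"].to_numpy(dtype=np.int64)
    all_chrom = ann["chrom"].to_numpy()
    win = config.upstream_window
    classes = (
        ["Nutlin"] * config.n_chip_nutlin
        + ["non-Nutlin"] * config.n_chip_nonnutlin
        + ["control"] * config.n_chip_control
    )
    out = []
    for d, cls in enumerate(classes):
        chroms, starts, ends = [], [], []
        if cls != "control":
            hit = rng.random(len(targets)) < config.peak_prob_target
            for i in np.flatnonzero(hit):
                s, e = _upstream_peak(rng, int(t_tss[i]), t_strand[i], win)
                chroms.append(t_chrom[i])
                starts.append(s)
                ends.append(e)
        bg = rng.random(len(ann)) < config.peak_prob_background
        for i in np.flatnonzero(bg):
            width = int(rng.integers(50, 151))
            lo = max(0, int(all_tss[i]) - 50_000)
            s = int(rng.integers(lo, int(all_tss[i]) + 50_000))
            chroms.append(all_chrom[i])
            starts.append(s)
            ends.append(s + width)
        iv = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends},
                          columns=["chrom", "start", "end"])
        iv = iv.sort_values(["chrom", "start", "end"], ignore_index=True)
        out.append(PeakSet(dataset_id=f"CHIP{d:02d}", treatment_class=cls, intervals=iv))
    return out


def generate_cohort(
    annotation: pd.DataFrame,
    truth: TruthSet,
    config: SimulationConfig,
    cancer_type: str = "CT0",
) -> OmicsCohort:
    """One tumor cohort assembled from the planted linear model.

    lncRNA expression is log-normal (attenuated by ``lof_attenuation``
    for target lncRNAs in p53-LOF samples, the LOF fraction being
    ``lof_fraction``); mRNA expression is
    ``b0 + b_DM*DM + b_CNV*CNV + sum_l beta_l*lnc_l + N(0, noise_sd)``
    with b0 = 8, b_DM = -2, b_CNV = 1.  Each mRNA promoter carries
    ``n_probes_per_promoter`` methylation probes of which exactly one
    (the first) is the informative, expression-anticorrelated one.
    Survival is exponential with administrative censoring at
    ``censor_horizon`` and hazard tied to the truth's hazard map through
    standardized lncRNA expression.
    """
    config.check()
    if config.cohort_n < 30:
        raise ConfigurationError("cohort_n must be >= 30")
    rng = np.random.default_rng(derive_seed(config.seed, f"cohort:{cancer_type}"))
    n = config.cohort_n
    samples = pd.Index([f"{cancer_type}_S{i:04d}" for i in range(n)], name="sample")
    lnc_ids = annotation.loc[annotation["biotype"] == "lncRNA", "gene_id"].tolist()
    mrna_ids = annotation.loc[annotation["biotype"] == "protein_coding", "gene_id"].tolist()

    status = np.where(rng.random(n) < config.lof_fraction, "LOF", "WT")
    lnc = np.exp(rng.normal(0.0, 0.5, size=(len(lnc_ids), n)))
    lnc_df = pd.DataFrame(lnc, index=lnc_ids, columns=samples)
    is_lof = status == "LOF"
    for g in sorted(truth.target_lncrnas):
        lnc_df.loc[g, is_lof] *= config.lof_attenuation

    cnv = rng.choice([-2, -1, 0, 1, 2], size=(len(mrna_ids), n), p=[0.05, 0.2, 0.5, 0.2, 0.05])
    dm_true = rng.uniform(0.1, 0.9, size=(len(mrna_ids), n))

    effects_by_mrna: dict[str, list[tuple[str, float]]] = {}
    for (l, m), beta in truth.lnc_mrna_effects.items():
        effects_by_mrna.setdefault(m, []).append((l, beta))

    # lncRNA contributions enter mean-centered: the per-sample slope is the
    # planted beta while the gene's baseline stays at b0 however many
    # lncRNAs hit it, keeping expression on the filter-passing scale.
    b0, b_dm, b_cnv = 8.0, -2.0, 1.0
    y = b0 + b_dm * dm_true + b_cnv * cnv + rng.normal(0.0, config.noise_sd, size=(len(mrna_ids), n))
    lnc_arr = lnc_df.to_numpy()
    lnc_centered = lnc_arr - lnc_arr.mean(axis=1, keepdims=True)
    lnc_pos = {g: i for i, g in enumerate(lnc_ids)}
    for i, m in enumerate(mrna_ids):
        for l, beta in effects_by_mrna.get(m, ()):  # noqa: E741
            y[i] += beta * lnc_centered[lnc_pos[l]]
    mrna_df = pd.DataFrame(y, index=mrna_ids, columns=samples)
    cnv_df = pd.DataFrame(cnv, index=mrna_ids, columns=samples)

    # probes: probe 0 tracks the true promoter methylation (informative,
    # anti-correlated with expression through b_dm < 0); the rest are noise
    k = config.n_probes_per_promoter
    probe_ids, probe_gene, rowsm = [], [], []
    for i, m in enumerate(mrna_ids):
        for j in range(k):
            probe_ids.append(f"{m}_p{j}")
            probe_gene.append(m)
            if j == 0:
                v = np.clip(dm_true[i] + rng.normal(0.0, 0.02, size=n), 0.0, 1.0)
            else:
                v = rng.uniform(0.0, 1.0, size=n)
            rowsm.append(v)
    meth_df = pd.DataFrame(np.vstack(rowsm), index=probe_ids, columns=samples)
    probe_map = pd.Series(probe_gene, index=probe_ids, name="mrna_id")

    log_h = np.full(n, np.log(config.base_hazard))
    for g, mult in truth.survival_hazard_map.items():
        x = lnc_df.loc[g].to_numpy()
        z = (x - x.mean()) / (x.std() or 1.0)
        log_h += np.log(mult) * z
    raw = rng.exponential(1.0 / np.exp(log_h))
    event = (raw <= config.censor_horizon).astype(int)
    time = np.minimum(raw, config.censor_horizon)
    time = np.maximum(time, 1e-6)
    survival = pd.DataFrame({"time": time, "event": event}, index=samples)

    return OmicsCohort(
        cancer_type=cancer_type,
        lnc_expr=lnc_df,
        mrna_expr=mrna_df,
        cnv=cnv_df,
        meth=meth_df,
        probe_map=probe_map,
        p53_status=pd.Series(status, index=samples),
        survival=survival,
    )


def generate_cohorts(
    annotation: pd.DataFrame, truth: TruthSet, config: SimulationConfig
) -> list[OmicsCohort]:
    """One cohort per cancer type (``CT0`` ... ``CT{k-1}``)."""
    return [
        generate_cohort(annotation, truth, config, cancer_type=f"CT{i}")
        for i in range(config.n_cancer_types)
    ]


def generate_dependency_screens(
    annotation: pd.DataFrame, truth: TruthSet, config: SimulationConfig
) -> list[DependencyScreen]:
    """RNAi-like and CRISPR-like dependency screens.

    Growth-promoting genes score ``N(-dep_effect, dep_noise_sd)``, all
    other protein-coding genes ``N(0, dep_noise_sd)``, independently per
    cell line; one matrix per screen type, no missing values.
    """
    config.check()
    if config.n_cell_lines < 1:
        raise ConfigurationError("n_cell_lines must be >= 1")
    rng = np.random.default_rng(derive_seed(config.seed, "dependency"))
    genes = annotation.loc[annotation["biotype"] == "protein_coding", "gene_id"].tolist()
    shift = np.where(np.isin(genes, sorted(truth.growth_promoting_genes)), -config.dep_effect, 0.0)
    out = []
    for stype in ("RNAi", "CRISPR"):
        cols = [f"{stype}_CL{i:02d}" for i in range(config.n_cell_lines)]
        scores = shift[:, None] + rng.normal(0.0, config.dep_noise_sd, size=(len(genes), len(cols)))
        out.append(DependencyScreen(screen_type=stype, scores=pd.DataFrame(scores, index=genes, columns=cols)))
    return out


# ---------------------------------------------------------------------------
# on-disk study bundle


def write_study(
    outdir,
    annotation: pd.DataFrame,
    truth: TruthSet,
    datasets: list[CountMatrix],
    peaks: list[PeakSet],
    cohorts: list[OmicsCohort],
    screens: list[DependencyScreen],
) -> None:
    """Write every layer as plain text under ``outdir`` with a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    manifest: dict = {"counts": [], "peaks": [], "cohorts": [], "screens": []}
    for cm in datasets:
        path = outdir / f"counts_{cm.dataset_id}.tsv"
        df = cm.counts.copy()
        df.columns = [f"{s}|{cm.condition[s]}" for s in df.columns]
        df.to_csv(path, sep="\t", index_label="gene_id")
        manifest["counts"].append({"dataset_id": cm.dataset_id, "path": path.name})
    for ps in peaks:
        path = outdir / f"peaks_{ps.dataset_id}.bed"
        write_bed(ps, path)
        manifest["peaks"].append(
            {"dataset_id": ps.dataset_id, "treatment_class": ps.treatment_class, "path": path.name}
        )
    for co in cohorts:
        cdir = outdir / f"cohort_{co.cancer_type}"
        cdir.mkdir(exist_ok=True)
        co.lnc_expr.to_csv(cdir / "lnc_expr.tsv", sep="\t", index_label="lncrna_id")
        co.mrna_expr.to_csv(cdir / "mrna_expr.tsv", sep="\t", index_label="mrna_id")
        co.cnv.to_csv(cdir / "cnv.tsv", sep="\t", index_label="mrna_id")
        co.meth.to_csv(cdir / "meth.tsv", sep="\t", index_label="probe_id")
        co.probe_map.rename("mrna_id").to_csv(cdir / "probe_map.tsv", sep="\t", index_label="probe_id")
        clin = pd.DataFrame(
            {"p53_status": co.p53_status, "time": co.survival["time"], "event": co.survival["event"]}
        )
        clin.to_csv(cdir / "clinical.tsv", sep="\t", index_label="sample")
        manifest["cohorts"].append({"cancer_type": co.cancer_type, "path": cdir.name})
    for sc in screens:
        path = outdir / f"screen_{sc.screen_type}.tsv"
        sc.scores.to_csv(path, sep="\t", index_label="gene_id")
        manifest["screens"].append({"screen_type": sc.screen_type, "path": path.name})
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "target_lncrnas": sorted(truth.target_lncrnas),
                "target_mrnas": sorted(truth.target_mrnas),
                "lnc_mrna_effects": [
                    {"lncrna_id": l, "mrna_id": m, "beta": b}  # noqa: E741
                    for (l, m), b in sorted(truth.lnc_mrna_effects.items())
                ],
                "growth_promoting_genes": sorted(truth.growth_promoting_genes),
                "survival_hazard_map": dict(sorted(truth.survival_hazard_map.items())),
            },
            fh,
            indent=1,
        )


def read_study(outdir):
    """Read a study bundle back; inverse of :func:`write_study`."""
    outdir = Path(outdir)
    with open(outdir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    annotation = pd.read_csv(outdir / "annotation.tsv", sep="\t")
    datasets = []
    for entry in manifest["counts"]:
        df = pd.read_csv(outdir / entry["path"], sep="\t", index_col="gene_id")
        df.index.name = None
        cond = pd.Series({c.split("|")[0]: c.split("|")[1] for c in df.columns})
        df.columns = [c.split("|")[0] for c in df.columns]
        datasets.append(CountMatrix(dataset_id=entry["dataset_id"], counts=df, condition=cond))
    peaks = [
        read_bed(outdir / e["path"], dataset_id=e["dataset_id"], treatment_class=e["treatment_class"])
        for e in manifest["peaks"]
    ]
    cohorts = []
    for entry in manifest["cohorts"]:
        cdir = outdir / entry["path"]
        clin = pd.read_csv(cdir / "clinical.tsv", sep="\t", index_col="sample")
        cohorts.append(
            OmicsCohort(
                cancer_type=entry["cancer_type"],
                lnc_expr=pd.read_csv(cdir / "lnc_expr.tsv", sep="\t", index_col="lncrna_id"),
                mrna_expr=pd.read_csv(cdir / "mrna_expr.tsv", sep="\t", index_col="mrna_id"),
                cnv=pd.read_csv(cdir / "cnv.tsv", sep="\t", index_col="mrna_id"),
                meth=pd.read_csv(cdir / "meth.tsv", sep="\t", index_col="probe_id"),
                probe_map=pd.read_csv(cdir / "probe_map.tsv", sep="\t", index_col="probe_id")["mrna_id"],
                p53_status=clin["p53_status"],
                survival=clin[["time", "event"]],
            )
        )
    screens = [
        DependencyScreen(
            screen_type=e["screen_type"],
            scores=pd.read_csv(outdir / e["path"], sep="\t", index_col="gene_id"),
        )
        for e in manifest["screens"]
    ]
    truth = None
    if (outdir / "truth.json").exists():
        with open(outdir / "truth.json") as fh:
            raw = json.load(fh)
        truth = TruthSet(
            target_lncrnas=set(raw["target_lncrnas"]),
            target_mrnas=set(raw["target_mrnas"]),
            lnc_mrna_effects={
                (e["lncrna_id"], e["mrna_id"]): e["beta"] for e in raw["lnc_mrna_effects"]
            },
            growth_promoting_genes=set(raw["growth_promoting_genes"]),
            survival_hazard_map=dict(raw["survival_hazard_map"]),
        )
    return annotation, truth, datasets, peaks, cohorts, screens
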