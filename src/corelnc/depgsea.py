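"""Pre-ranked GSEA of lncRNA-associated gene sets on dependency screens.

Dependency screens score every gene in a cell line; a lower score means
the line depends more strongly on the gene for survival/growth.  For the
enrichment analysis the genome is ordered by score descending (standard
pre-ranked convention), so the *bottom* of the list holds the strongest
dependencies and a gene set concentrated there receives a negative
enrichment score.

The running-sum statistic walks the ordered list: a hit increments by
|score|^p normalized by the set's total weight, a miss decrements by
1/(N - |set|); ES is the signed maximum deviation from zero.  The null is
random gene sets of matched size; NES divides ES by the mean |ES*| of the
same-sign permutations, p-values come from the same-sign permutation
tail, and the FDR follows the standard pooled-null pre-ranked procedure
across all sets scored in a batch.

A lncRNA is then classified per cell line: *suppressive* when only its
negatively associated set has a significantly negative NES (it induces
genes whose loss spares the cell, i.e. suppresses growth-promoting
genes), *oncogenic* when only the positive set does, *excluded* when both
do, *unclassified* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError
from .meta_rank import bh_adjust

__all__ = [
    "DependencyScreen",
    "EnrichmentResult",
    "rank_dependency",
    "gsea_preranked",
    "gsea_batch",
    "classify_lncrna",
    "summarize_across_lines",
    "ora_hypergeometric",
    "read_gmt",
    "write_gmt",
]

LABELS = ("suppressive", "oncogenic", "excluded", "unclassified")


@dataclass
class DependencyScreen:
    """Gene x cell-line viability/growth score matrix for one screen type."""

    screen_type: str  # "RNAi" or "CRISPR"
    scores: pd.DataFrame

    def __post_init__(self):
        if self.screen_type not in ("RNAi", "CRISPR"):
            raise DataError(f"screen_type must be 'RNAi' or 'CRISPR', got {self.screen_type!r}")
        if self.scores.shape[1] < 1:
            raise DataError("a dependency screen needs at least one cell line")
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise DataError("dependency scores must be finite")

    @property
    def cell_lines(self) -> pd.Index:
        return self.scores.columns


@dataclass
class EnrichmentResult:
    """One gene set's enrichment on one ranked list."""

    set_id: str
    es: float
    nes: float
    pvalue: float
    fdr: float
    size: int


def rank_dependency(screen: DependencyScreen, cell_line: str) -> pd.Series:
    """One cell line's genes ranked by dependency score ascending
    (most-depended first; rank 1 = strongest dependency), ties broken by
    gene id."""
    if cell_line not in screen.scores.columns:
        raise KeyError(f"cell line {cell_line!r} not in screen {screen.screen_type}")
    s = screen.scores[cell_line]
    order = sorted(s.index, key=lambda g: (s[g], g))
    return s.loc[order]


def _prepare_ranking(scores: pd.Series) -> tuple[np.ndarray, pd.Index]:
    """Order genes by score descending (ties by gene id) for the running sum."""
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return scores.loc[order].to_numpy(dtype=float), pd.Index(order)


def _es_from_positions(pos: np.ndarray, w: np.ndarray, n_genes: int) -> np.ndarray:
    """ES for hit-position matrices (rows = sets), avoiding full N-length sums.

    ``pos`` holds sorted 0-based hit positions per row, ``w`` the
    corresponding non-negative weights.  Between hits the running sum only
    decreases, so the extremes occur immediately after a hit (candidate
    maximum) or immediately before one (candidate minimum).  When the
    positive and negative extremes tie in magnitude, ES takes the
    positive value (stated convention).
    """
    pos = np.atleast_2d(pos)
    w = np.atleast_2d(w)
    n_sets, k = pos.shape
    if k >= n_genes:
        return np.ones(n_sets)
    wsum = w.sum(axis=1, keepdims=True)
    # uniform fallback when every member weight is zero
    wn = np.where(wsum > 0, w / np.where(wsum == 0, 1, wsum), 1.0 / k)
    cum_after = np.cumsum(wn, axis=1)
    cum_before = cum_after - wn
    miss = 1.0 / (n_genes - k)
    idx = np.arange(k)
    val_after = cum_after - (pos + 1 - (idx + 1)) * miss
    val_before = cum_before - (pos - idx) * miss
    hi = val_after.max(axis=1)
    lo = np.minimum(val_before.min(axis=1), 0.0)
    return np.where(hi >= -lo - 1e-12, hi, lo)


def _observed_es(
    ranked_scores: np.ndarray, ranked_genes: pd.Index, members: set[str], weight_p: float
) -> tuple[float, np.ndarray, np.ndarray]:
    hit = ranked_genes.isin(members)
    pos = np.flatnonzero(hit)
    if pos.size == 0:
        raise DataError("gene set is disjoint from the ranked universe")
    w = np.abs(ranked_scores) ** weight_p
    es = float(_es_from_positions(pos[None, :], w[pos][None, :], len(ranked_scores))[0])
    return es, pos, w


def gsea_batch(
    scores: pd.Series,
    gene_sets: dict[str, set[str] | list[str]],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """Score a collection of gene sets against one ranked profile.

    ``scores`` maps gene -> score; genes are internally ordered score
    descending so negative ES marks concentration among the lowest scores
    (the dependency end).  The permutation null draws ``n_perm`` random
    gene sets of matched size from the universe (shared across sets of
    equal size); NES, p and the batch FDR follow the standard pre-ranked
    procedure.  Reproducible for a fixed ``seed``.
    """
    if n_perm < 100:
        raise DataError("n_perm must be >= 100")
    ranked_scores, ranked_genes = _prepare_ranking(scores)
    n_genes = len(ranked_scores)
    w_all = np.abs(ranked_scores) ** weight_p
    rng = np.random.default_rng(seed)

    universe = set(ranked_genes)
    sets = {sid: set(m) & universe for sid, m in gene_sets.items()}
    for sid, m in sets.items():
        if len(m) < 2:
            raise DataError(f"gene set {sid!r} has < 2 members in the ranked universe")

    # One shared random-key pool serves every set size in the batch: the k
    # smallest keys of a row are a uniform size-k subset of the universe.
    kmax = min(max(len(m) for m in sets.values()), n_genes - 1)
    keys = rng.random((n_perm, n_genes), dtype=np.float32)
    part = np.argpartition(keys, kmax, axis=1)[:, :kmax]
    order = np.argsort(np.take_along_axis(keys, part, axis=1), axis=1)
    pool = np.take_along_axis(part, order, axis=1)  # positions, key-ascending
    del keys, part, order

    null_by_size: dict[int, np.ndarray] = {}

    def null_es(k: int) -> np.ndarray:
        if k not in null_by_size:
            if k >= n_genes:
                null_by_size[k] = np.ones(n_perm)
            else:
                draws = np.sort(pool[:, :k], axis=1)
                null_by_size[k] = _es_from_positions(draws, w_all[draws], n_genes)
        return null_by_size[k]

    observed: dict[str, tuple[float, int]] = {}
    nes_obs: dict[str, float] = {}
    pvals: dict[str, float] = {}
    null_nes_pool: list[np.ndarray] = []
    for sid in sorted(sets):
        es, _, _ = _observed_es(ranked_scores, ranked_genes, sets[sid], weight_p)
        k = len(sets[sid])
        null = null_es(k)
        same = null[null > 0] if es >= 0 else null[null < 0]
        if same.size == 0:
            p = 1.0 / (n_perm + 1)
            nes = np.sign(es) * 1.0 if es != 0 else 0.0
        else:
            # ties with the observed ES count as at-least-as-extreme
            p = (1 + np.sum(np.abs(same) >= abs(es) - 1e-12)) / (1 + same.size)
            nes = es / np.mean(np.abs(same))
        observed[sid] = (es, k)
        nes_obs[sid] = float(nes)
        pvals[sid] = float(p)
        # normalize the permutation ES the same way for the pooled FDR null
        pos_mean = np.mean(null[null > 0]) if (null > 0).any() else 1.0
        neg_mean = np.mean(np.abs(null[null < 0])) if (null < 0).any() else 1.0
        null_nes_pool.append(np.where(null >= 0, null / pos_mean, null / neg_mean))

    pool = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])
    obs_nes = np.array([nes_obs[sid] for sid in sorted(sets)])
    results = []
    for sid in sorted(sets):
        nes = nes_obs[sid]
        if nes >= 0:
            null_frac = np.mean(pool[pool >= 0] >= nes) if (pool >= 0).any() else 0.0
            obs_side = obs_nes[obs_nes >= 0]
            obs_frac = np.mean(obs_side >= nes) if obs_side.size else 1.0
        else:
            null_frac = np.mean(pool[pool < 0] <= nes) if (pool < 0).any() else 0.0
            obs_side = obs_nes[obs_nes < 0]
            obs_frac = np.mean(obs_side <= nes) if obs_side.size else 1.0
        fdr = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 0.0
        es, k = observed[sid]
        results.append(
            EnrichmentResult(set_id=sid, es=es, nes=nes, pvalue=pvals[sid], fdr=fdr, size=k)
        )
    return results


def gsea_preranked(
    scores: pd.Series,
    gene_set: set[str] | list[str],
    set_id: str = "set",
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> EnrichmentResult:
    """Enrichment of a single gene set on one ranked profile.

    Convenience wrapper around :func:`gsea_batch`; with a single set the
    batch FDR reduces to its permutation p-value scale.
    """
    return gsea_batch(scores, {set_id: gene_set}, weight_p=weight_p, n_perm=n_perm, seed=seed)[0]


def classify_lncrna(
    pos_result: EnrichmentResult,
    neg_result: EnrichmentResult,
    fdr_cut: float = 1e-3,
) -> str:
    """Label a lncRNA from its two association sets' enrichments.

    ``suppressive`` iff only the negatively associated set has nes < 0 at
    ``fdr <= fdr_cut`` (the lncRNA suppresses growth-promoting genes);
    ``oncogenic`` iff only the positive set does; ``excluded`` iff both;
    ``unclassified`` otherwise.  Exhaustive and mutually exclusive.
    """
    neg_hit = neg_result.nes < 0 and neg_result.fdr <= fdr_cut
    pos_hit = pos_result.nes < 0 and pos_result.fdr <= fdr_cut
    if neg_hit and pos_hit:
        return "excluded"
    if neg_hit:
        return "suppressive"
    if pos_hit:
        return "oncogenic"
    return "unclassified"


def summarize_across_lines(labels: pd.DataFrame) -> dict:
    """Summarize per-(lncRNA, cell line) labels across cell lines.

    ``labels`` needs columns ``lncrna_id``, ``cell_line``, ``label``.
    Returns per-lncRNA and per-cell-line counts of suppressive/oncogenic
    calls plus a two-sided Wilcoxon rank-sum comparison of the per-line
    suppressive vs oncogenic lncRNA counts (p = 1 by convention when both
    count vectors are all zero / identical).
    """
    for col in ("lncrna_id", "cell_line", "label"):
        if col not in labels.columns:
            raise DataError(f"labels table lacks column {col!r}")
    by_lnc = (
        labels.assign(
            suppressive=labels["label"] == "suppressive",
            oncogenic=labels["label"] == "oncogenic",
        )
        .groupby("lncrna_id")[["suppressive", "oncogenic"]]
        .sum()
    )
    by_line = (
        labels.assign(
            suppressive=labels["label"] == "suppressive",
            oncogenic=labels["label"] == "oncogenic",
        )
        .groupby("cell_line")[["suppressive", "oncogenic"]]
        .sum()
    )
    sup = by_line["suppressive"].to_numpy(dtype=float)
    onc = by_line["oncogenic"].to_numpy(dtype=float)
    if np.array_equal(sup, onc):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(sup, onc, alternative="two-sided").pvalue)
    return {"per_lncrna": by_lnc, "per_cell_line": by_line, "rank_sum_p": p}


def ora_hypergeometric(
    query: set[str], collection: dict[str, set[str] | list[str]], universe: set[str]
) -> pd.DataFrame:
    """Over-representation of a query gene set in each collection member.

    Upper-tail hypergeometric p-value P(X >= overlap) for each set
    (intersected with the universe), BH-corrected across the collection.
    Requires ``query`` to be a subset of a non-empty ``universe``.
    """
    if not universe:
        raise DataError("universe must be non-empty")
    if not set(query) <= set(universe):
        raise DataError("query must be a subset of the universe")
    M = len(universe)
    q = len(query)
    rows = []
    for sid in sorted(collection):
        members = set(collection[sid]) & set(universe)
        overlap = len(members & set(query))
        p = float(stats.hypergeom.sf(overlap - 1, M, len(members), q))
        rows.append({"set_id": sid, "set_size": len(members), "overlap": overlap, "pvalue": p})
    df = pd.DataFrame(rows).set_index("set_id")
    if len(df):
        df["fdr"] = bh_adjust(df["pvalue"].to_numpy())
    else:
        df["fdr"] = []
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection (set, description, members...)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            out[parts[0]] = {g for g in parts[2:] if g}
    return out


def write_gmt(collection: dict[str, set[str] | list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for sid in sorted(collection):
            members = "\t".join(sorted(collection[sid]))
            fh.write(f"{sid}\t{description}\t{members}\n")
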