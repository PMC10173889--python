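"""Configuration objects for the synthetic study and the pipeline.

``SimulationConfig`` fixes every free parameter of the synthetic multi-omics
study (sample sizes, effect sizes, noise levels, rates) in one place so that
all generators are pure functions of ``(config, seed)``.  ``PipelineConfig``
carries the analysis thresholds; its defaults are the published operating
points of the method (meta-analysis FDR 0.05 with a two-thirds consistency
rule, a 10 kb TSS window with >=5 supporting ChIP datasets, regression FDR
1e-3 with top-200 association sets, GSEA FDR 1e-3, survival |z| > 1.96).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields

from .exceptions import ConfigurationError

__all__ = ["SimulationConfig", "PipelineConfig", "derive_seed", "validate_config"]


def derive_seed(seed: int, label: str) -> int:
    """Derive a stage-specific seed from the master seed.

    Stable across processes (CRC32 of the label, not ``hash``) so that every
    stage is independently reproducible from the single configured seed.
    The result is always < 2**31.
    """
    return (int(seed) ^ zlib.crc32(label.encode("utf-8"))) % (2**31)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-layer study.

    Defaults are the study conditions exercised throughout the test suite:
    2,000 genes of which 200 are lncRNAs, 40 planted TF-induced target
    lncRNAs, 14 activation expression datasets, 17 ChIP peak sets
    (7 Nutlin-class + 7 non-Nutlin-class treated, 3 control), 3 tumor
    cohorts of n=300, and 20 cell lines per dependency-screen type.
    """

    seed: int = 0

    # gene universe
    n_genes: int = 2000
    n_lncrnas: int = 200

    # planted truth
    n_target_lncrnas: int = 40
    n_target_mrnas: int = 100
    n_assoc_per_side: int = 25
    assoc_pool_size: int = 400
    beta_lnc_effect: float = 1.5
    n_protective_lncrnas: int = 5
    protective_group_hr: float = 2.0

    # activation expression datasets
    n_datasets: int = 14
    n_treated: int = 4
    n_control: int = 4
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    base_mean: float = 100.0
    libsize_sd: float = 0.3

    # ChIP peak sets
    n_chip_nutlin: int = 7
    n_chip_nonnutlin: int = 7
    n_chip_control: int = 3
    peak_prob_target: float = 0.9
    peak_prob_background: float = 0.02
    upstream_window: int = 900

    # tumor cohorts
    cohort_n: int = 300
    n_cancer_types: int = 3
    lof_fraction: float = 0.3
    lof_attenuation: float = 0.5
    noise_sd: float = 1.0
    n_probes_per_promoter: int = 3
    base_hazard: float = 0.1
    censor_horizon: float = 15.0

    # dependency screens
    n_cell_lines: int = 20
    dep_effect: float = 3.0
    dep_noise_sd: float = 0.5

    def validate(self) -> list[str]:
        """Return a list of human-readable constraint violations (empty = ok)."""
        v: list[str] = []
        for name in (
            "n_genes", "n_lncrnas", "n_target_lncrnas", "n_datasets",
            "n_treated", "n_control", "cohort_n", "n_cancer_types",
            "n_cell_lines", "n_probes_per_promoter",
        ):
            if getattr(self, name) < 1:
                v.append(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_lncrnas > self.n_genes:
            v.append("n_lncrnas cannot exceed n_genes")
        if self.n_target_lncrnas > self.n_lncrnas:
            v.append("n_target_lncrnas cannot exceed n_lncrnas")
        for name in ("peak_prob_target", "peak_prob_background", "lof_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                v.append(f"{name} must lie in [0, 1], got {p}")
        for name in ("nb_dispersion", "base_mean", "noise_sd", "base_hazard",
                     "censor_horizon", "dep_noise_sd"):
            if getattr(self, name) <= 0:
                v.append(f"{name} must be positive, got {getattr(self, name)}")
        return v

    def check(self) -> "SimulationConfig":
        """Raise :class:`ConfigurationError` on the first violation."""
        v = self.validate()
        if v:
            raise ConfigurationError("; ".join(v))
        return self


@dataclass
class PipelineConfig:
    """Thresholds and orchestration parameters for a full pipeline run.

    All thresholds default to the method's published operating points and
    every one is overridable.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    output_dir: str = "corelnc_run"

    # meta-analysis stage
    meta_fdr: float = 0.05
    consistency_fraction: float = 2.0 / 3.0

    # ChIP stage
    tss_window_bp: int = 10_000
    chip_min_datasets: int = 5

    # regression network stage
    regression_fdr: float = 1e-3
    network_top_k: int = 200
    log_transform_expression: bool = False

    # dependency GSEA stage
    gsea_fdr: float = 1e-3
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0

    # cohort statistics stage
    survival_z_threshold: float = 1.96
    lof_meta_direction: str = "down"  # tail combined by the Fisher method

    def validate(self) -> list[str]:
        v = list(self.simulation.validate())
        for name in ("meta_fdr", "regression_fdr", "gsea_fdr"):
            val = getattr(self, name)
            if not 0 < val <= 1:
                v.append(f"{name} must lie in (0, 1], got {val}")
        if not 0 < self.consistency_fraction <= 1:
            v.append(f"consistency_fraction must lie in (0, 1], got {self.consistency_fraction}")
        if self.tss_window_bp <= 0:
            v.append(f"tss_window_bp must be positive, got {self.tss_window_bp}")
        if self.chip_min_datasets < 1:
            v.append(f"chip_min_datasets must be >= 1, got {self.chip_min_datasets}")
        if self.network_top_k < 1:
            v.append(f"network_top_k must be >= 1, got {self.network_top_k}")
        if self.gsea_n_perm < 100:
            v.append(f"gsea_n_perm must be >= 100, got {self.gsea_n_perm}")
        if self.survival_z_threshold <= 0:
            v.append(f"survival_z_threshold must be positive, got {self.survival_z_threshold}")
        if self.lof_meta_direction not in ("down", "up"):
            v.append(f"lof_meta_direction must be 'down' or 'up', got {self.lof_meta_direction}")
        return v

    def check(self) -> "PipelineConfig":
        v = self.validate()
        if v:
            raise ConfigurationError("; ".join(v))
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if not isinstance(sim, SimulationConfig):
            known = {f.name for f in fields(SimulationConfig)}
            bad = set(sim) - known
            if bad:
                raise ConfigurationError(f"unknown simulation fields: {sorted(bad)}")
            sim = SimulationConfig(**sim)
        known = {f.name for f in fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigurationError(f"unknown pipeline fields: {sorted(bad)}")
        return cls(simulation=sim, **d)


def validate_config(config: PipelineConfig) -> list[str]:
    """Check a pipeline configuration; returns the list of violations.

    Never mutates state; an empty list means the configuration is usable.
    """
    return config.validate()
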