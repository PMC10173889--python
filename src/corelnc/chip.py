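"""TF-binding annotation of gene TSSs across ChIP-seq peak sets.

Peaks are BED intervals (0-based, half-open).  A gene counts as bound in a
dataset when the nearest covered base of some peak lies within a symmetric
window (default 10 kb) of its TSS: distance 0 if the interval covers the
TSS, otherwise ``min(|start - tss|, |end - 1 - tss|)``, window boundary
inclusive.  The direct-target rule keeps genes bound in at least
``min_datasets`` peak sets including at least one Nutlin-class and one
non-Nutlin-class treated dataset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, ParseError

__all__ = [
    "PeakSet",
    "BindingProfile",
    "read_bed",
    "write_bed",
    "annotate_tss_binding",
    "direct_target_filter",
    "binding_enrichment_test",
]

logger = logging.getLogger(__name__)

TREATMENT_CLASSES = ("Nutlin", "non-Nutlin", "control")


@dataclass
class PeakSet:
    """One ChIP-seq dataset's peak intervals plus its treatment class."""

    dataset_id: str
    treatment_class: str
    intervals: pd.DataFrame  # columns chrom, start, end; record order preserved

    def __post_init__(self):
        if self.treatment_class not in TREATMENT_CLASSES:
            raise DataError(
                f"peak set {self.dataset_id!r}: treatment_class must be one of "
                f"{TREATMENT_CLASSES}, got {self.treatment_class!r}"
            )
        iv = self.intervals
        if len(iv):
            if (iv["start"] < 0).any():
                raise DataError(f"peak set {self.dataset_id!r}: negative coordinates")
            if (iv["start"] >= iv["end"]).any():
                raise DataError(f"peak set {self.dataset_id!r}: interval with start >= end")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class BindingProfile:
    """Per-gene binding summary across a collection of peak sets.

    ``bound`` is a genes x datasets boolean frame; ``summary`` is indexed
    by gene with columns ``n_datasets_bound``, ``n_nutlin_bound``,
    ``n_nonnutlin_bound``, ``n_control_bound`` and ``min_tss_distance``
    (the most proximal peak over all datasets, ``inf`` when no dataset has
    a peak on the gene's chromosome).
    """

    bound: pd.DataFrame
    summary: pd.DataFrame
    window_bp: int = 10_000
    classes: dict[str, str] = field(default_factory=dict)


def read_bed(path, dataset_id: str | None = None, treatment_class: str = "control") -> PeakSet:
    """Parse a BED3+ file into a :class:`PeakSet`.

    Extra columns beyond the first three are ignored; record order is
    preserved.  Malformed lines raise :class:`ParseError` with the line
    number; ``start >= end`` raises :class:`DataError`.
    """
    chroms, starts, ends = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"expected >= 3 tab-separated columns, got {len(parts)}", lineno)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", lineno) from None
            if start >= end:
                raise DataError(f"line {lineno}: interval start {start} >= end {end}")
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
    iv = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    if dataset_id is None:
        dataset_id = str(path)
    return PeakSet(dataset_id=dataset_id, treatment_class=treatment_class, intervals=iv)


def write_bed(ps: PeakSet, path) -> None:
    """Write a peak set as 6-column BED (name = dataset:index, score 0)."""
    with open(path, "w") as fh:
        for i, row in enumerate(ps.intervals.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{ps.dataset_id}:{i}\t0\t.\n")


def _nearest_distances(tss: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Distance from each TSS to the nearest interval on one chromosome.

    Intervals may overlap; for intervals entirely left of the TSS the
    closest is the one with the largest end, hence the prefix-max trick.
    """
    order = np.argsort(starts, kind="stable")
    starts = starts[order]
    ends = ends[order]
    prefix_max_end = np.maximum.accumulate(ends)
    dist = np.full(tss.shape, np.inf)
    idx = np.searchsorted(starts, tss, side="right") - 1
    has_left = idx >= 0
    left = np.where(has_left, tss - (prefix_max_end[np.clip(idx, 0, None)] - 1), np.inf)
    left = np.maximum(left, 0)  # covered => distance 0
    dist = np.where(has_left, left, dist)
    nxt = idx + 1
    has_right = nxt < len(starts)
    right = np.where(has_right, starts[np.clip(nxt, None, len(starts) - 1)] - tss, np.inf)
    return np.minimum(dist, right)


def annotate_tss_binding(
    peaks: list[PeakSet], annotation: pd.DataFrame, window_bp: int = 10_000
) -> BindingProfile:
    """Annotate TF binding near every gene's TSS across peak sets.

    ``annotation`` must carry columns ``gene_id``, ``chrom``, ``tss``.  A
    gene is bound in a dataset iff its nearest peak distance is <=
    ``window_bp`` (inclusive); the window is symmetric around the TSS.
    Peaks on chromosomes absent from the annotation are skipped with a
    logged warning.
    """
    ann = annotation.set_index("gene_id") if "gene_id" in annotation.columns else annotation
    genes = ann.index
    known_chroms = set(ann["chrom"].unique())
    bound = pd.DataFrame(False, index=genes, columns=[ps.dataset_id for ps in peaks])
    min_dist = pd.Series(np.inf, index=genes)
    classes: dict[str, str] = {}
    for ps in peaks:
        classes[ps.dataset_id] = ps.treatment_class
        stray = set(ps.intervals["chrom"].unique()) - known_chroms
        if stray:
            logger.warning(
                "peak set %s: skipping peaks on chromosome(s) %s absent from annotation",
                ps.dataset_id, sorted(stray),
            )
        for chrom, sub in ps.intervals.groupby("chrom", sort=False):
            if chrom not in known_chroms:
                continue
            mask = ann["chrom"] == chrom
            tss = ann.loc[mask, "tss"].to_numpy(dtype=np.int64)
            d = _nearest_distances(tss, sub["start"].to_numpy(), sub["end"].to_numpy())
            bound.loc[mask, ps.dataset_id] = d <= window_bp
            min_dist.loc[mask] = np.minimum(min_dist.loc[mask], d)

    by_class = {c: [ds for ds, cls in classes.items() if cls == c] for c in TREATMENT_CLASSES}
    summary = pd.DataFrame(
        {
            "n_datasets_bound": bound.sum(axis=1),
            "n_nutlin_bound": bound[by_class["Nutlin"]].sum(axis=1),
            "n_nonnutlin_bound": bound[by_class["non-Nutlin"]].sum(axis=1),
            "n_control_bound": bound[by_class["control"]].sum(axis=1),
            "min_tss_distance": min_dist,
        }
    )
    return BindingProfile(bound=bound, summary=summary, window_bp=window_bp, classes=classes)


def direct_target_filter(profile: BindingProfile, min_datasets: int = 5) -> set[str]:
    """Direct-target rule over a binding profile.

    Keeps genes bound in >= ``min_datasets`` peak sets overall AND bound
    in at least one Nutlin-class and at least one non-Nutlin-class
    treated dataset.
    """
    s = profile.summary
    keep = (
        (s["n_datasets_bound"] >= min_datasets)
        & (s["n_nutlin_bound"] >= 1)
        & (s["n_nonnutlin_bound"] >= 1)
    )
    return set(s.index[keep])


def binding_enrichment_test(
    profile: BindingProfile,
    foreground: set[str],
    background: set[str],
    metric: str = "n_datasets_bound",
    alternative: str = "greater",
) -> float:
    """One-sided Wilcoxon rank-sum comparison of a binding metric.

    Compares ``metric`` (``n_datasets_bound`` or ``min_tss_distance``)
    between disjoint non-empty foreground and background gene sets.  The
    exact null distribution is used for small tie-free samples (total
    <= 25); otherwise the normal approximation with tie correction.
    Returns the one-sided p-value with ``foreground <alternative>
    background``.
    """
    if metric not in ("n_datasets_bound", "min_tss_distance"):
        raise DataError(f"unknown metric {metric!r}")
    if not foreground or not background:
        raise DataError("foreground and background must both be non-empty")
    if foreground & background:
        raise DataError("foreground and background must be disjoint")
    s = profile.summary[metric]
    x = s.loc[sorted(foreground)].to_numpy(dtype=float)
    y = s.loc[sorted(background)].to_numpy(dtype=float)
    # infinite distances (never-bound genes) still rank correctly; map to a
    # finite value above all observed ones to keep scipy happy
    finite_max = np.nanmax(np.concatenate([x, y])[np.isfinite(np.concatenate([x, y]))], initial=0.0)
    x = np.where(np.isinf(x), finite_max + 1, x)
    y = np.where(np.isinf(y), finite_max + 1, y)
    total = len(x) + len(y)
    ties = len(np.unique(np.concatenate([x, y]))) < total
    method = "exact" if (total <= 25 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.pvalue)
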