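"""Robust rank aggregation across expression datasets.

Each activation dataset contributes an ordered list of up- (or down-)
regulated genes.  Under the null hypothesis that the lists are mutually
uncorrelated, a gene's normalized ranks ``r_1 <= ... <= r_n`` behave like
sorted uniforms, so the probability that the k-th smallest normalized rank
is as small as observed is the Beta(k, n-k+1) CDF at ``r_(k)``.  The
aggregation score is

    rho(g) = min_k  P( Beta(k, n-k+1) <= r_(k) )

and the per-gene p-value applies a Bonferroni factor of ``n`` over the
choice of k, following the published robust-rank-aggregation algorithm.
Genes missing from a list receive normalized rank 1 (they provide no
evidence).  Stability is assessed by repeating the aggregation on every
leave-one-out subset of the lists, averaging the corrected p-values, and
BH-adjusting the averages across genes; a consistency filter then keeps
genes significant at the chosen FDR that appear in the given direction in
at least a fixed fraction (default two-thirds) of the datasets in which
they were detected at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DataError

__all__ = [
    "RankedList",
    "rra_rho",
    "aggregate_ranks",
    "stability_aggregate",
    "select_consistent",
    "bh_adjust",
]


@dataclass
class RankedList:
    """One dataset's ordered gene list for a single direction.

    ``genes`` are ordered from strongest to weakest evidence (rank 1 first);
    ``universe_size`` is the number of genes detected in that dataset, used
    to normalize ranks, so ``len(genes) <= universe_size``.
    """

    dataset_id: str
    direction: str  # "up" or "down"
    genes: list[str] = field(default_factory=list)
    universe_size: int = 0

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ConfigurationError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if len(set(self.genes)) != len(self.genes):
            raise DataError(f"ranked list {self.dataset_id!r} contains duplicate genes")
        if self.universe_size < len(self.genes):
            raise DataError(
                f"ranked list {self.dataset_id!r}: universe_size {self.universe_size} "
                f"< list length {len(self.genes)}"
            )

    def normalized_ranks(self) -> dict[str, float]:
        """Map gene -> (1-based position) / universe_size."""
        n = self.universe_size
        return {g: (i + 1) / n for i, g in enumerate(self.genes)}


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns q-values in the input order: ``q_i = min_{j: p_(j) >= p_(i)}
    p_(j) * n / j`` capped at 1.  Raises :class:`DataError` on values
    outside [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise DataError("bh_adjust expects a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise DataError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def rra_rho(normalized_ranks: Sequence[float] | np.ndarray, n_lists: int) -> tuple[float, float]:
    """Beta order-statistic aggregation score for one gene.

    Parameters
    ----------
    normalized_ranks
        The gene's normalized ranks, each in (0, 1].  If fewer than
        ``n_lists`` values are supplied the gene is treated as absent from
        the remaining lists (normalized rank 1).
    n_lists
        Total number of lists aggregated.

    Returns
    -------
    (rho, pvalue)
        ``rho`` is the minimum Beta(k, n-k+1) CDF over k; ``pvalue`` is
        ``min(1, rho * n_lists)`` (Bonferroni over the choice of k).
    """
    r = np.asarray(normalized_ranks, dtype=float)
    if r.ndim != 1:
        raise DataError("normalized ranks must be a 1-D vector")
    if np.any(r <= 0) or np.any(r > 1) or np.any(np.isnan(r)):
        raise DataError("normalized ranks must lie in (0, 1]")
    if n_lists < 1:
        raise ConfigurationError("n_lists must be >= 1")
    if r.size > n_lists:
        raise DataError(f"got {r.size} ranks for {n_lists} lists")
    if r.size < n_lists:
        r = np.concatenate([r, np.ones(n_lists - r.size)])
    r = np.sort(r)
    k = np.arange(1, n_lists + 1)
    rho = float(np.min(stats.beta.cdf(r, k, n_lists - k + 1)))
    return rho, min(1.0, rho * n_lists)


def _rank_matrix(lists: Sequence[RankedList], genes: Sequence[str]) -> np.ndarray:
    """Genes x lists matrix of normalized ranks, 1.0 where absent."""
    gene_index = {g: i for i, g in enumerate(genes)}
    mat = np.ones((len(genes), len(lists)))
    for j, rl in enumerate(lists):
        if rl.universe_size == 0:
            continue
        for pos, g in enumerate(rl.genes):
            mat[gene_index[g], j] = (pos + 1) / rl.universe_size
    return mat


def _aggregate_matrix(mat: np.ndarray, score: str = "corrected") -> np.ndarray:
    """Per-row rho or corrected p for a genes x lists normalized-rank matrix."""
    n = mat.shape[1]
    srt = np.sort(mat, axis=1)
    k = np.arange(1, n + 1)
    rho = stats.beta.cdf(srt, k, n - k + 1).min(axis=1)
    if score == "rho":
        return rho
    return np.minimum(1.0, rho * n)


def aggregate_ranks(lists: Sequence[RankedList]) -> pd.DataFrame:
    """Single-pass aggregation over the union of genes in the lists.

    Returns a DataFrame indexed by gene with columns ``rho`` and ``pvalue``.
    """
    lists = list(lists)
    if not lists:
        raise ConfigurationError("at least one ranked list is required")
    genes = sorted(set().union(*(rl.genes for rl in lists)))
    mat = _rank_matrix(lists, genes)
    rho = _aggregate_matrix(mat, score="rho")
    p = np.minimum(1.0, rho * len(lists))
    return pd.DataFrame({"rho": rho, "pvalue": p}, index=pd.Index(genes, name="gene_id"))


def stability_aggregate(
    lists: Sequence[RankedList],
    detected: Mapping[str, Iterable[str]] | None = None,
    score: str = "corrected",
) -> pd.DataFrame:
    """Leave-one-out stabilized aggregation across >= 2 ranked lists.

    The aggregation is repeated once per leave-one-out subset of the lists;
    each repeat's per-gene p-value (Bonferroni-corrected by default,
    ``score="rho"`` to average raw scores instead) is averaged and the
    averages are BH-adjusted across genes.

    Parameters
    ----------
    lists
        Ranked lists, all for the same direction.
    detected
        Optional map ``dataset_id -> iterable of genes detected`` (i.e.
        expressed/tested) in that dataset.  A dataset counts toward a
        gene's ``n_detected`` only if the gene was detected there; when
        omitted every gene is assumed detected in every dataset.

    Returns
    -------
    DataFrame indexed by gene with columns ``rho``, ``pvalue``,
    ``stability_pvalue``, ``fdr``, ``n_detected``, ``n_consistent``.
    """
    lists = list(lists)
    if len(lists) < 2:
        raise ConfigurationError("stability aggregation requires at least 2 ranked lists")
    directions = {rl.direction for rl in lists}
    if len(directions) != 1:
        raise ConfigurationError(f"all lists must share one direction, got {sorted(directions)}")
    # Canonical list order: results must not depend on supply order.
    lists = sorted(lists, key=lambda rl: rl.dataset_id)
    genes = sorted(set().union(*(rl.genes for rl in lists)))
    mat = _rank_matrix(lists, genes)
    n = len(lists)

    full_rho = _aggregate_matrix(mat, score="rho")
    full_p = np.minimum(1.0, full_rho * n)

    loo = np.empty((len(genes), n))
    for j in range(n):
        sub = np.delete(mat, j, axis=1)
        loo[:, j] = _aggregate_matrix(sub, score=score)
    stability_p = loo.mean(axis=1)
    fdr = bh_adjust(np.clip(stability_p, 0.0, 1.0))

    membership = np.zeros(len(genes), dtype=int)
    gene_index = {g: i for i, g in enumerate(genes)}
    for rl in lists:
        for g in rl.genes:
            membership[gene_index[g]] += 1
    if detected is None:
        n_detected = np.full(len(genes), n, dtype=int)
    else:
        det_sets = {ds: set(gs) for ds, gs in detected.items()}
        n_detected = np.zeros(len(genes), dtype=int)
        for rl in lists:
            det = det_sets.get(rl.dataset_id, set())
            for g in genes:
                if g in det:
                    n_detected[gene_index[g]] += 1
    # A list membership implies detection; keep the invariant explicit.
    n_detected = np.maximum(n_detected, membership)

    return pd.DataFrame(
        {
            "rho": full_rho,
            "pvalue": full_p,
            "stability_pvalue": stability_p,
            "fdr": fdr,
            "n_detected": n_detected,
            "n_consistent": membership,
        },
        index=pd.Index(genes, name="gene_id"),
    )


def select_consistent(
    results: pd.DataFrame, fdr_cut: float = 0.05, frac: float = 2.0 / 3.0
) -> set[str]:
    """Apply the FDR + consistency filter to an aggregation table.

    Keeps genes with ``fdr <= fdr_cut`` whose direction-consistent
    detections reach at least ``frac`` of the datasets in which they were
    detected; the fractional boundary is inclusive.
    """
    if (results["n_detected"] < 1).any():
        raise DataError("every gene must be detected in at least one dataset")
    ratio = results["n_consistent"] / results["n_detected"]
    # nudge for binary representation of fractions like 2/3 at e.g. 8/12
    keep = (results["fdr"] <= fdr_cut) & (ratio + 1e-12 >= frac)
    return set(results.index[keep])


def write_ranked_list(rl: RankedList, path) -> None:
    """Write a ranked list as two-column TSV (rank, gene); the header
    carries the direction and universe size."""
    with open(path, "w") as fh:
        fh.write(f"# direction={rl.direction}\tuniverse_size={rl.universe_size}\n")
        fh.write("rank\tgene_id\n")
        for i, g in enumerate(rl.genes, start=1):
            fh.write(f"{i}\t{g}\n")


def read_ranked_list(path, dataset_id: str) -> RankedList:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(part.split("=", 1) for part in header.lstrip("# ").split("\t"))
        fh.readline()  # column header
        genes = [line.rstrip("\n").split("\t")[1] for line in fh if line.strip()]
    return RankedList(
        dataset_id=dataset_id,
        direction=meta["direction"],
        genes=genes,
        universe_size=int(meta["universe_size"]),
    )
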