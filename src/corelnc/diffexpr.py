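"""Per-dataset differential expression and fold-change ranking.

Counts are normalized to counts-per-million (CPM) on raw library sizes and
differential expression of treated vs control samples is assessed with a
Welch t-test on log2(CPM + 1), BH-corrected across genes.  The downstream
meta-analysis consumes only the fold-change *ranks*, which are robust to
the exact test; a precomputed differential-expression table may be supplied
in place of this module's output anywhere a ``DETable`` is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError
from .meta_rank import RankedList, bh_adjust

__all__ = ["CountMatrix", "normalize_counts", "differential_expression", "rank_split"]

TREATED = "treated"
CONTROL = "control"


@dataclass
class CountMatrix:
    """A genes x samples matrix of non-negative integer read counts.

    ``condition`` maps each sample (column) to ``"treated"`` or
    ``"control"``.
    """

    dataset_id: str
    counts: pd.DataFrame
    condition: pd.Series

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise DataError(f"dataset {self.dataset_id!r}: negative counts")
        if not self.counts.columns.equals(self.condition.index):
            self.condition = self.condition.reindex(self.counts.columns)
            if self.condition.isna().any():
                raise DataError(f"dataset {self.dataset_id!r}: samples lack condition labels")
        bad = set(self.condition.unique()) - {TREATED, CONTROL}
        if bad:
            raise DataError(f"dataset {self.dataset_id!r}: unknown condition labels {sorted(bad)}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


def normalize_counts(m: CountMatrix) -> pd.DataFrame:
    """Counts-per-million normalization on raw library sizes.

    Every normalized column sums to 1e6; gene and sample order are
    preserved.  A zero-depth sample is a :class:`DataError` naming the
    sample.
    """
    depths = m.counts.sum(axis=0)
    zero = depths.index[depths == 0]
    if len(zero):
        raise DataError(
            f"dataset {m.dataset_id!r}: zero total count in sample(s) {list(zero)}"
        )
    return m.counts / depths * 1e6


def differential_expression(m: CountMatrix) -> pd.DataFrame:
    """Treated-vs-control differential expression table.

    Welch t-test on log2(CPM + 1) per gene with BH correction across all
    genes in the matrix; ``log2fc`` is the difference of group means on the
    same log scale (the pseudocount keeps all-zero genes finite).  Genes
    with zero variance in both groups and equal means (e.g. all-zero
    genes) receive p = 1.

    Returns a DataFrame indexed by gene with columns ``log2fc``,
    ``pvalue``, ``fdr``, ``mean_expression``.
    """
    treated = m.condition.index[m.condition == TREATED]
    control = m.condition.index[m.condition == CONTROL]
    if len(treated) < 2 or len(control) < 2:
        raise DataError(
            f"dataset {m.dataset_id!r}: need >= 2 samples per condition "
            f"(treated={len(treated)}, control={len(control)})"
        )
    cpm = normalize_counts(m)
    log = np.log2(cpm + 1.0)
    a = log[treated].to_numpy()
    b = log[control].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvalue = np.asarray(res.pvalue, dtype=float)
    # degenerate genes (no within-group variance): identical means -> null
    nan = np.isnan(pvalue)
    pvalue[nan & (np.abs(log2fc) < 1e-12)] = 1.0
    pvalue[nan & (np.abs(log2fc) >= 1e-12)] = 0.0
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvalue,
            "fdr": bh_adjust(pvalue),
            "mean_expression": cpm.mean(axis=1).to_numpy(),
        },
        index=m.genes,
    )


def rank_split(table: pd.DataFrame, dataset_id: str = "") -> tuple[RankedList, RankedList]:
    """Split a differential-expression table into ranked up/down lists.

    Up list: genes with log2fc > 0 ordered by decreasing log2fc; down
    list: log2fc < 0 ordered by increasing log2fc (strongest change first
    in both).  Genes with log2fc exactly 0 appear in neither.  Ties are
    broken lexicographically by gene id so rankings are stable across
    runs.  ``universe_size`` of both lists is the number of genes tested.
    """
    if table.empty:
        raise DataError("cannot rank an empty differential-expression table")
    universe = len(table)
    fc = table["log2fc"]
    up = table.index[fc > 0]
    down = table.index[fc < 0]
    up_order = sorted(up, key=lambda g: (-fc[g], g))
    down_order = sorted(down, key=lambda g: (fc[g], g))
    return (
        RankedList(dataset_id=dataset_id, direction="up", genes=list(up_order), universe_size=universe),
        RankedList(dataset_id=dataset_id, direction="down", genes=list(down_order), universe_size=universe),
    )
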