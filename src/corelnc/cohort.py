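"""Cross-cancer meta-combination and median-split survival scans.

The log-rank test is the standard O-E tabulation: at each distinct event
time the observed events in the low-expression group are compared with
the expectation under the hypergeometric model given the pooled risk set,
and the variance accumulates the hypergeometric variances.  The Z-score
is ``(O_low - E_low)/sqrt(V)``, signed so z > 0 means the low group has
more events than expected (high expression favorable); z**2 is the usual
two-group log-rank chi-square.  The per-feature scan splits samples at
the median expression (ties to the low group) and flags |z| > 1.96,
the two-sided normal critical value at alpha = 0.05.

Evidence across cancer types is pooled by Fisher's combined probability:
``-2 * sum(ln p)`` over one-tailed p-values, chi-square with 2k degrees
of freedom under the null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError
from .meta_rank import bh_adjust

__all__ = [
    "SurvivalResult",
    "fisher_combine",
    "lof_meta_combine",
    "median_split",
    "logrank_test",
    "survival_scan",
    "km_curve",
]

logger = logging.getLogger(__name__)


@dataclass
class SurvivalResult:
    """Two-group log-rank outcome for one feature."""

    feature_id: str
    z: float
    p: float
    direction: str  # "favorable" or "unfavorable"
    n_low: int
    n_high: int

    @property
    def chi_square(self) -> float:
        return self.z**2


def fisher_combine(pvalues) -> dict:
    """Fisher's combined probability over one-tailed p-values.

    Returns ``{"fisher_stat", "df", "combined_p", "k"}`` with
    ``fisher_stat = -2 * sum(ln p)`` and the upper-tail chi-square p on
    ``2k`` degrees of freedom.  Zero p-values are clamped to the smallest
    positive float with a warning (BH-adjusted zeros occur in floating
    point); p > 1 or p < 0 is a data error.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 1:
        raise DataError("at least one p-value is required")
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise DataError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to the smallest positive float", RuntimeWarning)
        p = np.maximum(p, np.finfo(float).tiny)
    stat = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    return {
        "fisher_stat": stat,
        "df": df,
        "combined_p": float(stats.chi2.sf(stat, df)),
        "k": int(p.size),
    }


def lof_meta_combine(per_cancer_p: pd.DataFrame) -> pd.DataFrame:
    """Combine per-cancer one-tailed p-values feature-wise.

    ``per_cancer_p`` is features x cancer types; NaN marks a feature not
    tested in a cancer type and is dropped from that feature's
    combination.  Returns a DataFrame with ``fisher_stat``, ``df``,
    ``combined_p`` and BH ``fdr`` across features.
    """
    rows = []
    for feat, row in per_cancer_p.iterrows():
        vals = row.dropna().to_numpy(dtype=float)
        if vals.size == 0:
            rows.append({"feature_id": feat, "fisher_stat": np.nan, "df": 0, "combined_p": np.nan})
            continue
        res = fisher_combine(vals)
        rows.append(
            {
                "feature_id": feat,
                "fisher_stat": res["fisher_stat"],
                "df": res["df"],
                "combined_p": res["combined_p"],
            }
        )
    out = pd.DataFrame(rows).set_index("feature_id")
    tested = out["combined_p"].notna()
    fdr = np.full(len(out), np.nan)
    if tested.any():
        fdr[tested.to_numpy()] = bh_adjust(out.loc[tested, "combined_p"].to_numpy())
    out["fdr"] = fdr
    return out


def median_split(values: pd.Series) -> tuple[pd.Index, pd.Index]:
    """Split samples at the median of ``values``.

    Samples with value <= median go to the low group, the rest to high
    (ties deterministically to low).  All-identical values make the split
    impossible and raise :class:`DataError`.
    """
    v = values.astype(float)
    if len(v) < 2:
        raise DataError("median split needs at least 2 samples")
    med = float(np.median(v.to_numpy()))
    low = v.index[v <= med]
    high = v.index[v > med]
    if len(low) == 0 or len(high) == 0:
        raise DataError("median split impossible: no variation around the median")
    return low, high


def _logrank_oe(time: np.ndarray, event: np.ndarray, in_low: np.ndarray) -> tuple[float, float, float]:
    """O-E tabulation over distinct event times; returns (O_low, E_low, V)."""
    order = np.argsort(time, kind="stable")
    time, event, in_low = time[order], event[order], in_low[order]
    o = e = v = 0.0
    n = len(time)
    i = 0
    at_risk_total = n
    at_risk_low = int(in_low.sum())
    while i < n:
        t = time[i]
        j = i
        d = d_low = removed = removed_low = 0
        while j < n and time[j] == t:
            if event[j]:
                d += 1
                d_low += int(in_low[j])
            removed += 1
            removed_low += int(in_low[j])
            j += 1
        if d > 0:
            N, NL = at_risk_total, at_risk_low
            o += d_low
            e += d * NL / N
            if N > 1:
                v += d * (NL / N) * (1 - NL / N) * (N - d) / (N - 1)
        at_risk_total -= removed
        at_risk_low -= removed_low
        i = j
    return o, e, v


def logrank_test(
    time, event, group, feature_id: str = "", low_label=None
) -> SurvivalResult:
    """Two-group log-rank test with the stated sign convention.

    ``group`` labels each sample; ``low_label`` names the low-expression
    group (defaults to the lexicographically smaller label).  z > 0 means
    the low group has more events than expected, so the feature is
    ``favorable`` (high expression -> better survival) when z > 0.
    Requires events in at least one group; two groups with zero events in
    total are a data error.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise DataError(f"log-rank test requires exactly 2 groups, got {len(labels)}")
    if event.sum() == 0:
        raise DataError("no events in either group; log-rank test undefined")
    if low_label is None:
        low_label = labels[0]
    in_low = group == low_label
    o, e, v = _logrank_oe(time, event, in_low)
    if v <= 0:
        raise DataError("log-rank variance is zero (all events in one risk-set state)")
    z = (o - e) / np.sqrt(v)
    p = float(stats.chi2.sf(z**2, 1))
    return SurvivalResult(
        feature_id=feature_id,
        z=float(z),
        p=p,
        direction="favorable" if z > 0 else "unfavorable",
        n_low=int(in_low.sum()),
        n_high=int((~in_low).sum()),
    )


def survival_scan(
    survival: pd.DataFrame,
    expression: pd.DataFrame,
    z_threshold: float = 1.96,
) -> pd.DataFrame:
    """Median-split log-rank scan over expression features.

    ``survival`` (indexed by sample) needs ``time`` and ``event``
    columns; ``expression`` is features x samples on the same sample
    axis.  Features whose expression cannot be split (constant) are
    skipped with a logged reason.  Returns one row per tested feature
    with ``z``, ``p``, ``direction``, group sizes and a ``significant``
    flag at |z| > ``z_threshold``.
    """
    if not expression.columns.equals(survival.index):
        expression = expression[survival.index]
    rows = []
    for feat in expression.index:
        vals = expression.loc[feat]
        try:
            low, high = median_split(vals)
        except DataError as exc:
            logger.info("survival scan: skipping %s (%s)", feat, exc)
            continue
        grp = np.where(survival.index.isin(low), "low", "high")
        try:
            res = logrank_test(
                survival["time"].to_numpy(),
                survival["event"].to_numpy(),
                grp,
                feature_id=str(feat),
                low_label="low",
            )
        except DataError as exc:
            logger.info("survival scan: skipping %s (%s)", feat, exc)
            continue
        rows.append(
            {
                "feature_id": feat,
                "z": res.z,
                "p": res.p,
                "direction": res.direction,
                "n_low": res.n_low,
                "n_high": res.n_high,
                "significant": abs(res.z) > z_threshold,
            }
        )
    return pd.DataFrame(rows).set_index("feature_id") if rows else pd.DataFrame(
        columns=["z", "p", "direction", "n_low", "n_high", "significant"]
    )


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan-Meier step-function coordinates (time, survival) for plotting."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    at_risk = len(time)
    surv = 1.0
    rows = [{"time": 0.0, "survival": 1.0}]
    i = 0
    while i < len(time):
        t = time[i]
        d = removed = 0
        while i < len(time) and time[i] == t:
            d += event[i]
            removed += 1
            i += 1
        if d > 0:
            surv *= 1 - d / at_risk
            rows.append({"time": t, "survival": surv})
        at_risk -= removed
    return pd.DataFrame(rows)
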