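"""Per-cancer lncRNA-mRNA association networks by multivariate regression.

For each (lncRNA l, mRNA) pair in one tumor cohort the model

    y = b0 + b_DM * DM + b_CNV * CNV + b_lnc * lnc_l + e

is fit by ordinary least squares on the n samples, where DM is the
representative promoter-methylation beta-value, CNV the GISTIC-style copy
number score, and lnc_l the lncRNA's expression; b_lnc then quantifies the
expression association that is independent of copy number and methylation.
Pairs significant after BH correction (default FDR < 1e-3) are split by
the sign of b_lnc into each lncRNA's positive and negative association
sets, truncated to the top 200 a side.

Expression filters mirror the cohort-analysis conventions: an mRNA is kept
when >= 75% of samples have normalized expression >= 1; a lncRNA when its
median is > 0 and its 90th percentile is > 0.1 (linear-interpolation
percentiles).  When a promoter has several methylation probes, the one
whose beta-values have the most negative Spearman correlation with the
mRNA's expression represents it.

``p53lof_diffexp`` is the companion cohort test: per-lncRNA Welch t-test
of expression between p53 loss-of-function and wild-type samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import DataError, FitError
from .meta_rank import bh_adjust

__all__ = [
    "OmicsCohort",
    "RegressionFit",
    "AssociationNetwork",
    "filter_mrna",
    "filter_lncrna",
    "select_methyl_probe",
    "fit_lnc_mrna",
    "build_network",
    "p53lof_diffexp",
]

logger = logging.getLogger(__name__)


@dataclass
class OmicsCohort:
    """One cancer type's multi-omics sample bundle.

    All matrices share the sample axis (columns).  ``meth`` rows are
    probes; ``probe_map`` maps probe id -> the mRNA whose promoter it
    assays.  ``p53_status`` takes values ``"WT"``/``"LOF"``; ``survival``
    has columns ``time`` (> 0) and ``event`` (0/1).
    """

    cancer_type: str
    lnc_expr: pd.DataFrame
    mrna_expr: pd.DataFrame
    cnv: pd.DataFrame
    meth: pd.DataFrame
    probe_map: pd.Series  # probe id -> mRNA id
    p53_status: pd.Series
    survival: pd.DataFrame

    def __post_init__(self):
        samples = self.mrna_expr.columns
        for name in ("lnc_expr", "cnv", "meth"):
            if not getattr(self, name).columns.equals(samples):
                raise DataError(f"cohort {self.cancer_type!r}: {name} sample axis mismatch")
        for name in ("p53_status", "survival"):
            if not getattr(self, name).index.equals(samples):
                raise DataError(f"cohort {self.cancer_type!r}: {name} sample axis mismatch")
        mv = self.meth.to_numpy()
        if mv.size and ((mv < 0) | (mv > 1)).any():
            raise DataError(f"cohort {self.cancer_type!r}: methylation beta-values outside [0, 1]")
        if (self.survival["time"] <= 0).any():
            raise DataError(f"cohort {self.cancer_type!r}: non-positive survival times")
        if not set(self.survival["event"].unique()) <= {0, 1}:
            raise DataError(f"cohort {self.cancer_type!r}: event indicator must be 0/1")

    @property
    def n(self) -> int:
        return self.mrna_expr.shape[1]

    @property
    def samples(self) -> pd.Index:
        return self.mrna_expr.columns


@dataclass
class RegressionFit:
    """OLS fit of one lncRNA-mRNA pair with covariate control."""

    lncrna_id: str
    mrna_id: str
    beta0: float
    beta_dm: float | None
    beta_cnv: float
    beta_lnc: float
    p_lnc: float
    se_lnc: float
    fdr: float = np.nan


@dataclass
class AssociationNetwork:
    """Per-lncRNA signed association sets from one cohort.

    ``positive`` / ``negative`` map lncRNA id -> DataFrame indexed by mRNA
    with columns ``beta_lnc`` and ``fdr``, ordered by the top-k rule and
    truncated to ``top_k`` members.  ``pairs`` keeps the full table of
    tested pairs for reuse (GSEA, reporting).
    """

    cancer_type: str
    positive: dict[str, pd.DataFrame] = field(default_factory=dict)
    negative: dict[str, pd.DataFrame] = field(default_factory=dict)
    fdr_cut: float = 1e-3
    top_k: int = 200
    pairs: pd.DataFrame | None = None

    def gene_set(self, lncrna_id: str, sign: str) -> list[str]:
        side = self.positive if sign == "positive" else self.negative
        df = side.get(lncrna_id)
        return [] if df is None else list(df.index)


def filter_mrna(mrna_expr: pd.DataFrame, min_value: float = 1.0, min_fraction: float = 0.75) -> list[str]:
    """mRNAs whose expression is >= ``min_value`` in >= ``min_fraction``
    of samples (both boundaries inclusive)."""
    frac = (mrna_expr >= min_value).mean(axis=1)
    return list(mrna_expr.index[frac >= min_fraction])


def filter_lncrna(lnc_expr: pd.DataFrame, median_gt: float = 0.0, p90_gt: float = 0.1) -> list[str]:
    """lncRNAs with median > ``median_gt`` and 90th percentile >
    ``p90_gt`` (strict inequalities, linear-interpolation percentile)."""
    vals = lnc_expr.to_numpy(dtype=float)
    med = np.percentile(vals, 50, axis=1)
    p90 = np.percentile(vals, 90, axis=1)
    keep = (med > median_gt) & (p90 > p90_gt)
    return list(lnc_expr.index[keep])


def select_methyl_probe(probes: pd.DataFrame, expr: np.ndarray | pd.Series) -> str | None:
    """Representative promoter probe: strongest negative Spearman
    correlation with the mRNA's expression.

    ``probes`` is probe x sample beta-values for one promoter.  Constant
    probes (undefined correlation) are skipped; if every probe is
    constant, ``None`` is returned and the caller omits the methylation
    term.  Ties break on probe id.
    """
    if probes.shape[0] == 0:
        raise DataError("at least one probe is required")
    e = np.asarray(expr, dtype=float)
    if probes.shape[1] != e.size or e.size < 3:
        raise DataError("probe and expression vectors must share length >= 3")
    best: tuple[float, str] | None = None
    for probe_id in sorted(probes.index):
        v = probes.loc[probe_id].to_numpy(dtype=float)
        if np.all(v == v[0]) or np.all(e == e[0]):
            continue
        rho = stats.spearmanr(v, e).statistic
        if np.isnan(rho):
            continue
        cand = (rho, str(probe_id))
        if best is None or cand < best:
            best = cand
    if best is None:
        logger.info("all probes constant for a promoter; methylation term omitted")
        return None
    if best[0] >= 0:
        logger.info("representative probe %s has non-negative correlation %.3f", best[1], best[0])
    return best[1]


def fit_lnc_mrna(
    y: np.ndarray,
    dm: np.ndarray | None,
    cnv: np.ndarray,
    lnc: np.ndarray,
    lncrna_id: str = "",
    mrna_id: str = "",
) -> RegressionFit:
    """OLS of one mRNA on [1, DM, CNV, lncRNA] for one pair.

    ``p_lnc`` is the two-sided t-test p-value of the lncRNA coefficient
    with n - p degrees of freedom (p = 4 with the methylation term, 3
    without, when no usable probe exists).  Rank-deficient designs raise
    :class:`FitError` naming the offending covariate.
    """
    y = np.asarray(y, dtype=float)
    cnv = np.asarray(cnv, dtype=float)
    lnc = np.asarray(lnc, dtype=float)
    n = y.size
    if n < 10:
        raise DataError(f"need n >= 10 samples, got {n}")
    cols = [np.ones(n)]
    names = ["const"]
    if dm is not None:
        cols.append(np.asarray(dm, dtype=float))
        names.append("dm")
    cols.extend([cnv, lnc])
    names.extend(["cnv", "lnc"])
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the first covariate that adds no rank
        r = 1
        for j in range(1, X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                raise FitError(f"design is rank-deficient: covariate {names[j]!r} is collinear")
            r = rj
        raise FitError("design is rank-deficient")
    res = sm.OLS(y, X).fit()
    params = dict(zip(names, res.params))
    return RegressionFit(
        lncrna_id=lncrna_id,
        mrna_id=mrna_id,
        beta0=float(params["const"]),
        beta_dm=float(params["dm"]) if dm is not None else None,
        beta_cnv=float(params["cnv"]),
        beta_lnc=float(params["lnc"]),
        p_lnc=float(res.pvalues[names.index("lnc")]),
        se_lnc=float(res.bse[names.index("lnc")]),
    )


def _pair_scan(
    y_mat: np.ndarray, dm_mat: np.ndarray | None, cnv_mat: np.ndarray, lnc_mat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-pair b_lnc and p_lnc via Frisch-Waugh-Lovell.

    ``y_mat``/``cnv_mat`` are mRNA x sample, ``dm_mat`` mRNA x sample (the
    representative probe per mRNA, NaN rows meaning no probe), ``lnc_mat``
    lncRNA x sample.  For each mRNA, y and every lncRNA vector are
    residualized on [1, DM, CNV]; the pair coefficient and its t-test then
    follow from the residual regression, identically to the full OLS.
    Returns (beta, p) arrays of shape (n_mrna, n_lnc).
    """
    n_mrna, n = y_mat.shape
    n_lnc = lnc_mat.shape[0]
    beta = np.empty((n_mrna, n_lnc))
    pval = np.empty((n_mrna, n_lnc))
    L = lnc_mat.T  # n x K
    for i in range(n_mrna):
        cols = [np.ones(n)]
        if dm_mat is not None and not np.isnan(dm_mat[i]).any():
            cols.append(dm_mat[i])
        cols.append(cnv_mat[i])
        X0 = np.column_stack(cols)
        Q, _ = np.linalg.qr(X0)
        y = y_mat[i]
        ry = y - Q @ (Q.T @ y)
        RL = L - Q @ (Q.T @ L)  # n x K
        ss_l = np.einsum("ij,ij->j", RL, RL)
        ss_l = np.where(ss_l <= 0, np.nan, ss_l)
        b = (RL.T @ ry) / ss_l
        df = n - X0.shape[1] - 1
        sse = np.maximum(ry @ ry - b**2 * ss_l, 0.0)
        se = np.sqrt(sse / df / ss_l)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = b / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(np.isnan(t), 1.0, p)  # exact fit or degenerate lnc
        p = np.where(np.isinf(t), 0.0, p)
        beta[i] = np.where(np.isnan(b), 0.0, b)
        pval[i] = p
    return beta, pval


def build_network(
    cohort: OmicsCohort,
    fdr_cut: float = 1e-3,
    top_k: int = 200,
    log_transform: bool = False,
) -> AssociationNetwork:
    """Build the cohort's signed lncRNA-mRNA association network.

    Applies the expression filters and probe selection, fits every
    retained pair, BH-adjusts ``p_lnc`` across all tested pairs of the
    cancer type, and per lncRNA keeps the significant pairs split by the
    sign of ``beta_lnc``, each side ordered by (fdr ascending, |beta_lnc|
    descending, mRNA id) and truncated to ``top_k``.

    ``log_transform`` applies log2(x + 1) to both expression layers before
    regression; the default regresses normalized values as-is.
    """
    mrnas = filter_mrna(cohort.mrna_expr)
    lncs = filter_lncrna(cohort.lnc_expr)
    if not mrnas or not lncs:
        return AssociationNetwork(cohort.cancer_type, fdr_cut=fdr_cut, top_k=top_k,
                                  pairs=pd.DataFrame(columns=["lncrna_id", "mrna_id", "beta_lnc", "p_lnc", "fdr"]))
    y_df = cohort.mrna_expr.loc[mrnas]
    l_df = cohort.lnc_expr.loc[lncs]
    if log_transform:
        y_df = np.log2(y_df + 1.0)
        l_df = np.log2(l_df + 1.0)
    y_mat = y_df.to_numpy(dtype=float)
    lnc_mat = l_df.to_numpy(dtype=float)
    cnv_mat = cohort.cnv.reindex(mrnas).to_numpy(dtype=float)

    dm_mat = np.full_like(y_mat, np.nan)
    probes_by_gene = cohort.probe_map.groupby(cohort.probe_map).groups  # mRNA -> probe ids
    for i, g in enumerate(mrnas):
        probe_ids = probes_by_gene.get(g)
        if probe_ids is None:
            continue
        probes = cohort.meth.loc[list(probe_ids)]
        rep = select_methyl_probe(probes, y_mat[i])
        if rep is not None:
            dm_mat[i] = cohort.meth.loc[rep].to_numpy(dtype=float)

    beta, pval = _pair_scan(y_mat, dm_mat, cnv_mat, lnc_mat)
    fdr = bh_adjust(pval.ravel()).reshape(pval.shape)

    pairs = pd.DataFrame(
        {
            "lncrna_id": np.repeat(lncs, len(mrnas)),
            "mrna_id": np.tile(mrnas, len(lncs)),
            "beta_lnc": beta.T.ravel(),
            "p_lnc": pval.T.ravel(),
            "fdr": fdr.T.ravel(),
        }
    )
    net = AssociationNetwork(cohort.cancer_type, fdr_cut=fdr_cut, top_k=top_k, pairs=pairs)
    sig = pairs[pairs["fdr"] < fdr_cut]
    for lnc_id, sub in sig.groupby("lncrna_id", sort=True):
        for sign, side in (("positive", net.positive), ("negative", net.negative)):
            part = sub[sub["beta_lnc"] > 0] if sign == "positive" else sub[sub["beta_lnc"] < 0]
            if part.empty:
                continue
            part = part.assign(absbeta=part["beta_lnc"].abs())
            part = part.sort_values(
                ["fdr", "absbeta", "mrna_id"], ascending=[True, False, True]
            ).head(top_k)
            side[lnc_id] = part.set_index("mrna_id")[["beta_lnc", "fdr"]]
    return net


def p53lof_diffexp(lnc_expr: pd.DataFrame, p53_status: pd.Series) -> pd.DataFrame:
    """Per-lncRNA differential expression between p53-LOF and WT samples.

    Welch t-test on normalized expression, BH across lncRNAs.  Returns a
    DataFrame indexed by lncRNA with columns ``log2fc`` (LOF vs WT, small
    pseudocount), ``tstat``, ``pvalue`` (two-sided), ``p_down``
    (one-tailed, lower expression in LOF), ``fdr`` and ``constant`` (both
    groups constant -> p = 1 by convention, flagged).
    """
    lof = p53_status.index[p53_status == "LOF"]
    wt = p53_status.index[p53_status == "WT"]
    if len(lof) < 3 or len(wt) < 3:
        raise DataError(f"need >= 3 samples per p53 status group (LOF={len(lof)}, WT={len(wt)})")
    a = lnc_expr[lof].to_numpy(dtype=float)
    b = lnc_expr[wt].to_numpy(dtype=float)
    eps = 1e-9
    log2fc = np.log2((a.mean(axis=1) + eps) / (b.mean(axis=1) + eps))
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    const = np.isnan(t)
    t = np.where(const, 0.0, t)
    p = np.where(const, 1.0, p)
    # one-tailed "downregulated in LOF": lower tail of the t statistic
    df = np.asarray(res.df, dtype=float)
    df = np.where(np.isnan(df) | (df < 1), 1.0, df)
    p_down = np.where(const, 1.0, stats.t.cdf(t, df))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "tstat": t,
            "pvalue": p,
            "p_down": p_down,
            "fdr": bh_adjust(p),
            "constant": const,
        },
        index=lnc_expr.index,
    )
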