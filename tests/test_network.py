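"""Expression filters, probe selection, pair regression, network assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from corelnc.exceptions import DataError, FitError
from corelnc.network import (
    build_network,
    filter_lncrna,
    filter_mrna,
    fit_lnc_mrna,
    p53lof_diffexp,
    select_methyl_probe,
)


class TestExpressionFilters:
    def test_mrna_75pct_boundary_inclusive(self):
        df = pd.DataFrame([[1, 1, 1, 0.5]], index=["m"])
        assert filter_mrna(df) == ["m"]

    def test_mrna_below_value_dropped(self):
        df = pd.DataFrame([[0.9] * 4], index=["m"])
        assert filter_mrna(df) == []

    def test_mrna_all_high_kept(self):
        df = pd.DataFrame([[2.0] * 4], index=["m"])
        assert filter_mrna(df) == ["m"]

    def test_lncrna_all_zero_dropped(self):
        df = pd.DataFrame([[0.0] * 10], index=["l"])
        assert filter_lncrna(df) == []

    def test_lncrna_expressed_kept(self):
        df = pd.DataFrame([[0.5] * 9 + [0.9]], index=["l"])
        assert filter_lncrna(df) == ["l"]

    def test_lncrna_p90_boundary_strict(self):
        # 90th percentile exactly 0.1 fails the strict > rule
        vals = [0.05] * 8 + [0.1, 0.1]
        df = pd.DataFrame([vals], index=["l"])
        assert np.percentile(vals, 90) == pytest.approx(0.1)
        assert filter_lncrna(df) == []


class TestSelectMethylProbe:
    def _probes(self, rows, ids=None):
        ids = ids or [f"p{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=ids)

    def test_most_negative_correlation_wins(self, rng):
        expr = np.linspace(0, 1, 20)
        anti = 1 - expr + rng.normal(0, 0.05, 20)
        weak = rng.normal(0.5, 0.1, 20)
        probes = self._probes([np.clip(weak, 0, 1), np.clip(anti, 0, 1)], ["pA", "pB"])
        assert select_methyl_probe(probes, expr) == "pB"

    def test_single_probe_returned(self):
        probes = self._probes([[0.1, 0.5, 0.9, 0.2]])
        assert select_methyl_probe(probes, np.array([1.0, 2, 3, 4])) == "p0"

    def test_all_positive_minimum_chosen(self):
        expr = np.array([1.0, 2, 3, 4, 5])
        p_weak = np.array([0.1, 0.3, 0.2, 0.5, 0.4])  # positive, weaker
        p_strong = np.array([0.1, 0.2, 0.3, 0.4, 0.5])  # rho = +1
        probes = self._probes([p_strong, p_weak], ["pS", "pW"])
        assert select_methyl_probe(probes, expr) == "pW"

    def test_constant_probes_skipped(self):
        probes = self._probes([[0.5] * 5, [0.1, 0.2, 0.3, 0.4, 0.5]], ["pc", "pv"])
        assert select_methyl_probe(probes, np.arange(5.0)) == "pv"
        only_const = self._probes([[0.5] * 5])
        assert select_methyl_probe(only_const, np.arange(5.0)) is None


class TestFitLncMrna:
    def test_exact_linear_relation(self, rng):
        n = 50
        lnc = rng.normal(size=n)
        fit = fit_lnc_mrna(lnc.copy(), rng.random(n), rng.integers(-2, 3, n), lnc)
        assert fit.beta_lnc == pytest.approx(1.0, abs=1e-8)
        assert fit.p_lnc < 1e-20

    def test_null_type_one_error(self):
        """Independent y: p_lnc uniform, type-I at 0.05 within 0.05 +- 0.02."""
        rng = np.random.default_rng(17)
        n, reps = 100, 1000
        hits = 0
        for _ in range(reps):
            y = rng.normal(size=n)
            fit = fit_lnc_mrna(y, rng.random(n), rng.integers(-2, 3, n), rng.normal(size=n))
            hits += fit.p_lnc < 0.05
        assert abs(hits / reps - 0.05) <= 0.02

    def test_matches_normal_equations_oracle(self):
        """Coefficients match the closed-form normal-equations solution on
        random instances (tolerance 1e-8)."""
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(10, 40))
            X = np.column_stack(
                [np.ones(n), rng.random(n), rng.integers(-2, 3, n).astype(float), rng.normal(size=n)]
            )
            y = rng.normal(size=n)
            fit = fit_lnc_mrna(y, X[:, 1], X[:, 2], X[:, 3])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(
                [fit.beta0, fit.beta_dm, fit.beta_cnv, fit.beta_lnc], beta, atol=1e-8
            )
            # independent p-value oracle from the classical t formula
            resid = y - X @ beta
            s2 = resid @ resid / (n - 4)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[3, 3])
            p = 2 * stats.t.sf(abs(beta[3] / se), n - 4)
            assert fit.p_lnc == pytest.approx(p, abs=1e-10)

    def test_collinear_design_names_covariate(self, rng):
        n = 20
        cnv = rng.integers(-2, 3, n).astype(float)
        with pytest.raises(FitError, match="lnc"):
            fit_lnc_mrna(rng.normal(size=n), rng.random(n), cnv, 2 * cnv)

    def test_six_sample_minimum_rejected(self, rng):
        with pytest.raises(DataError):
            fit_lnc_mrna(np.ones(6), None, np.ones(6), np.ones(6))

    def test_confidence_calibration(self):
        """The 95% CI for beta_lnc covers the truth in ~95% of fits."""
        rng = np.random.default_rng(31)
        n, reps, beta_true = 60, 800, 0.7
        covered = 0
        for _ in range(reps):
            dm = rng.random(n)
            cnv = rng.integers(-2, 3, n).astype(float)
            lnc = rng.normal(size=n)
            y = 1.0 - 0.5 * dm + 0.3 * cnv + beta_true * lnc + rng.normal(size=n)
            fit = fit_lnc_mrna(y, dm, cnv, lnc)
            half = stats.t.ppf(0.975, n - 4) * fit.se_lnc
            covered += abs(fit.beta_lnc - beta_true) <= half
        assert abs(covered / reps - 0.95) <= 0.02


class TestBuildNetwork:
    def test_null_cohort_nearly_empty(self, annotation, small_config):
        """With no planted effects, essentially no pairs pass FDR < 1e-3."""
        from dataclasses import replace
        from corelnc import synthetic as syn
        from corelnc.synthetic import TruthSet

        cfg = replace(small_config, seed=99)
        truth = TruthSet()  # nothing planted
        co = syn.generate_cohort(annotation, truth, cfg)
        net = build_network(co)
        n_sig = sum(len(df) for df in net.positive.values()) + sum(
            len(df) for df in net.negative.values()
        )
        n_tested = len(net.pairs)
        assert n_sig / n_tested <= 0.002

    def test_planted_network_recovered(self, annotation, truth, cohort):
        """Planted positive/negative partners are recovered at >= 95%."""
        net = build_network(cohort)
        planted_pos = {}
        planted_neg = {}
        for (l, m), b in truth.lnc_mrna_effects.items():  # noqa: E741
            (planted_pos if b > 0 else planted_neg).setdefault(l, set()).add(m)
        recovered = total = 0
        for lnc, members in planted_pos.items():
            got = set(net.gene_set(lnc, "positive"))
            recovered += len(got & members)
            total += len(members)
        for lnc, members in planted_neg.items():
            got = set(net.gene_set(lnc, "negative"))
            recovered += len(got & members)
            total += len(members)
        assert recovered / total >= 0.95

    def test_sign_split_exact_and_truncated(self, cohort):
        net = build_network(cohort, top_k=5)
        for lnc, df in net.positive.items():
            assert (df["beta_lnc"] > 0).all()
            assert len(df) <= 5
        for lnc, df in net.negative.items():
            assert (df["beta_lnc"] < 0).all()
            assert len(df) <= 5
        for lnc in net.positive:
            overlap = set(net.gene_set(lnc, "positive")) & set(net.gene_set(lnc, "negative"))
            assert not overlap

    def test_pair_scan_matches_single_fits(self, cohort):
        """The vectorized scan reproduces the per-pair OLS surface."""
        net = build_network(cohort)
        sub = net.pairs.sample(20, random_state=0)
        probes_by_gene = cohort.probe_map.groupby(cohort.probe_map).groups
        for row in sub.itertuples(index=False):
            y = cohort.mrna_expr.loc[row.mrna_id].to_numpy()
            probes = cohort.meth.loc[list(probes_by_gene[row.mrna_id])]
            rep = select_methyl_probe(probes, y)
            dm = cohort.meth.loc[rep].to_numpy() if rep else None
            fit = fit_lnc_mrna(
                y, dm, cohort.cnv.loc[row.mrna_id].to_numpy(),
                cohort.lnc_expr.loc[row.lncrna_id].to_numpy(),
            )
            assert fit.beta_lnc == pytest.approx(row.beta_lnc, abs=1e-8)
            assert fit.p_lnc == pytest.approx(row.p_lnc, rel=1e-6, abs=1e-12)


class TestP53LofDiffexp:
    def test_null_distribution(self, rng):
        expr = pd.DataFrame(rng.normal(5, 1, size=(200, 60)),
                            columns=[f"s{i}" for i in range(60)])
        status = pd.Series(["LOF"] * 30 + ["WT"] * 30, index=expr.columns)
        res = p53lof_diffexp(expr, status)
        assert 0.3 < res["pvalue"].median() < 0.7
        assert (res["pvalue"] < 0.05).mean() < 0.12

    def test_attenuated_targets_recovered(self):
        """0.5x attenuation at n=150/150 flags planted targets at
        fdr < 0.05 with sensitivity >= 0.9."""
        from corelnc import synthetic as syn
        from corelnc.config import SimulationConfig

        cfg = SimulationConfig(seed=13, n_genes=600, n_lncrnas=150, n_target_lncrnas=25,
                               cohort_n=300, lof_fraction=0.5)
        ann = syn.generate_annotation(cfg)
        truth = syn.make_truth(ann, cfg)
        co = syn.generate_cohort(ann, truth, cfg)
        res = p53lof_diffexp(co.lnc_expr, co.p53_status)
        targets = sorted(truth.target_lncrnas)
        hit = ((res.loc[targets, "fdr"] < 0.05) & (res.loc[targets, "log2fc"] < 0)).mean()
        assert hit >= 0.9

    def test_constant_feature_flagged(self, rng):
        expr = pd.DataFrame(
            np.vstack([np.ones(12), rng.normal(size=12)]),
            index=["const", "var"], columns=[f"s{i}" for i in range(12)],
        )
        status = pd.Series(["LOF"] * 6 + ["WT"] * 6, index=expr.columns)
        res = p53lof_diffexp(expr, status)
        assert res.loc["const", "pvalue"] == 1.0
        assert bool(res.loc["const", "constant"])

    def test_small_group_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 5)), columns=[f"s{i}" for i in range(5)])
        status = pd.Series(["LOF", "LOF", "WT", "WT", "WT"], index=expr.columns)
        with pytest.raises(DataError):
            p53lof_diffexp(expr, status)
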