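"""Generator contracts: determinism, planted effect sizes, round-trips."""

import numpy as np
import pandas as pd
import pytest

from corelnc import synthetic as syn
from corelnc.config import SimulationConfig
from corelnc.diffexpr import differential_expression
from corelnc.exceptions import ConfigurationError
from corelnc.network import fit_lnc_mrna


class TestAnnotation:
    def test_counts_and_biotypes(self, small_config):
        ann = syn.generate_annotation(small_config)
        assert len(ann) == small_config.n_genes
        assert (ann["biotype"] == "lncRNA").sum() == small_config.n_lncrnas
        assert ann["gene_id"].is_unique
        assert (ann["tss"] >= 0).all()

    def test_deterministic_for_fixed_seed(self, small_config):
        a = syn.generate_annotation(small_config)
        b = syn.generate_annotation(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_lncrnas_rejected(self):
        with pytest.raises(ConfigurationError):
            syn.generate_annotation(SimulationConfig(n_lncrnas=0))

    def test_truth_references_annotation(self, annotation, truth):
        lncs = set(annotation.loc[annotation.biotype == "lncRNA", "gene_id"])
        genes = set(annotation["gene_id"])
        assert truth.target_lncrnas <= lncs
        for l, m in truth.lnc_mrna_effects:  # noqa: E741
            assert l in genes and m in genes
        assert truth.growth_promoting_genes <= genes


class TestActivationDatasets:
    def test_shapes_and_conditions(self, annotation, truth, small_config):
        ds = syn.generate_activation_datasets(annotation, truth, small_config)
        assert len(ds) == small_config.n_datasets
        for cm in ds:
            assert (cm.condition == "treated").sum() >= 3
            assert (cm.condition == "control").sum() >= 3
            assert (cm.counts.values >= 0).all()

    def test_deterministic(self, annotation, truth, small_config):
        a = syn.generate_activation_datasets(annotation, truth, small_config)
        b = syn.generate_activation_datasets(annotation, truth, small_config)
        pd.testing.assert_frame_equal(a[0].counts, b[0].counts)

    @pytest.mark.parametrize("effect,lo,hi", [(0.0, -0.1, 0.1), (2.0, 1.5, 2.5)])
    def test_planted_log2fc_recovered(self, effect, lo, hi):
        """Observed mean log2FC of planted targets matches the generator's
        own effect parameter (Monte-Carlo check, 14 datasets, 1000 genes)."""
        cfg = SimulationConfig(
            seed=11, n_genes=1000, n_lncrnas=100, n_target_lncrnas=20,
            n_target_mrnas=30, n_datasets=14, effect_log2fc=effect,
        )
        ann = syn.generate_annotation(cfg)
        truth = syn.make_truth(ann, cfg)
        fcs = []
        for cm in syn.generate_activation_datasets(ann, truth, cfg):
            table = differential_expression(cm)
            fcs.append(table.loc[sorted(truth.target_lncrnas), "log2fc"].mean())
        mean_fc = float(np.mean(fcs))
        assert lo < mean_fc < hi


class TestChipDatasets:
    def test_classes_and_valid_intervals(self, annotation, truth, small_config):
        peaks = syn.generate_chip_datasets(annotation, truth, small_config)
        classes = [p.treatment_class for p in peaks]
        assert classes.count("Nutlin") == small_config.n_chip_nutlin
        assert classes.count("control") == small_config.n_chip_control
        for p in peaks:
            assert (p.intervals["start"] < p.intervals["end"]).all()

    def test_extreme_probabilities(self, annotation, truth, small_config):
        from dataclasses import replace

        cfg = replace(small_config, peak_prob_target=1.0, peak_prob_background=0.0)
        peaks = syn.generate_chip_datasets(annotation, truth, cfg)
        n_targets = len(truth.target_lncrnas)
        for p in peaks:
            if p.treatment_class == "control":
                assert len(p) == 0
            else:
                assert len(p) == n_targets

    def test_target_peaks_within_upstream_window(self, annotation, truth, small_config):
        """Planted promoter peaks sit entirely within 900 bp upstream of the
        target TSS, strand-aware (post-hoc scan of the emitted intervals)."""
        from dataclasses import replace

        cfg = replace(small_config, peak_prob_target=1.0, peak_prob_background=0.0)
        ann = annotation.set_index("gene_id")
        for p in syn.generate_chip_datasets(annotation, truth, cfg):
            if p.treatment_class == "control":
                continue
            for row in p.intervals.itertuples(index=False):
                # find the target gene this peak belongs to
                near = ann[(ann.chrom == row.chrom) & (abs(ann.tss - row.start) <= 1000)]
                assert len(near) == 1
                tss, strand = int(near.iloc[0]["tss"]), near.iloc[0]["strand"]
                if strand == "+":
                    assert tss - 900 <= row.start and row.end - 1 < tss
                else:
                    assert tss < row.start and row.end - 1 <= tss + 900


class TestCohort:
    def test_dimensions_and_ranges(self, cohort, small_config):
        n = small_config.cohort_n
        assert cohort.n == n
        assert cohort.lnc_expr.shape[1] == n
        assert ((cohort.meth.values >= 0) & (cohort.meth.values <= 1)).all()
        assert set(cohort.survival["event"].unique()) <= {0, 1}
        assert (cohort.survival["time"] > 0).all()
        # >= 2 probes mapped per mRNA promoter
        assert cohort.probe_map.value_counts().min() >= 2

    def test_lof_fraction_zero(self, annotation, truth, small_config):
        from dataclasses import replace

        cfg = replace(small_config, lof_fraction=0.0)
        co = syn.generate_cohort(annotation, truth, cfg)
        assert (co.p53_status == "WT").all()

    def test_planted_beta_recovered_by_ols(self, annotation, small_config):
        """OLS on generated cohort data recovers the planted lncRNA
        coefficient with small bias (consistency check by simulation)."""
        cfg = SimulationConfig(
            seed=5, n_genes=500, n_lncrnas=60, n_target_lncrnas=10,
            n_assoc_per_side=10, assoc_pool_size=100, cohort_n=300,
            beta_lnc_effect=1.5, noise_sd=1.0,
        )
        ann = syn.generate_annotation(cfg)
        truth = syn.make_truth(ann, cfg)
        co = syn.generate_cohort(ann, truth, cfg)
        pairs = sorted(truth.lnc_mrna_effects.items())[:100]
        est = []
        for (lnc, mrna), beta in pairs:
            probes = co.meth.loc[co.probe_map[co.probe_map == mrna].index]
            fit = fit_lnc_mrna(
                co.mrna_expr.loc[mrna].to_numpy(),
                probes.iloc[0].to_numpy(),
                co.cnv.loc[mrna].to_numpy(),
                co.lnc_expr.loc[lnc].to_numpy(),
            )
            est.append(fit.beta_lnc - beta)
        assert abs(float(np.mean(est))) < 0.1


class TestDependencyScreens:
    def test_structure_and_determinism(self, annotation, truth, small_config):
        a = syn.generate_dependency_screens(annotation, truth, small_config)
        b = syn.generate_dependency_screens(annotation, truth, small_config)
        assert {s.screen_type for s in a} == {"RNAi", "CRISPR"}
        for sa, sb in zip(a, b):
            pd.testing.assert_frame_equal(sa.scores, sb.scores)
            assert sa.scores.notna().all().all()
            assert sa.scores.shape[1] == small_config.n_cell_lines

    def test_null_effect_leaves_ranks_uniform(self, annotation, truth, small_config):
        from dataclasses import replace

        cfg = replace(small_config, dep_effect=0.0)
        screen = syn.generate_dependency_screens(annotation, truth, cfg)[0]
        gp = sorted(truth.growth_promoting_genes)
        ranks = screen.scores.rank(axis=0)
        med_gp = ranks.loc[gp].median().median()
        med_all = ranks.median().median()
        assert abs(med_gp - med_all) / len(screen.scores) < 0.15

    def test_strong_effect_fills_bottom_quartile(self, annotation, truth, small_config):
        """dep_effect=3 with noise sd 0.5 puts essentially every
        growth-promoting gene in each line's bottom quartile."""
        screen = syn.generate_dependency_screens(annotation, truth, small_config)[0]
        gp = sorted(truth.growth_promoting_genes)
        for cl in screen.cell_lines:
            ranks = screen.scores[cl].rank()
            frac = (ranks.loc[gp] <= len(ranks) / 4).mean()
            assert frac >= 0.95


class TestRoundTrip:
    def test_study_bundle_round_trips(self, tmp_path, annotation, truth, small_config):
        ds = syn.generate_activation_datasets(annotation, truth, small_config)[:1]
        peaks = syn.generate_chip_datasets(annotation, truth, small_config)[:2]
        cohorts = [syn.generate_cohort(annotation, truth, small_config)]
        screens = syn.generate_dependency_screens(annotation, truth, small_config)
        syn.write_study(tmp_path / "study", annotation, truth, ds, peaks, cohorts, screens)
        ann2, truth2, ds2, peaks2, cohorts2, screens2 = syn.read_study(tmp_path / "study")
        pd.testing.assert_frame_equal(annotation, ann2)
        assert truth2.target_lncrnas == truth.target_lncrnas
        assert truth2.lnc_mrna_effects == truth.lnc_mrna_effects
        pd.testing.assert_frame_equal(ds[0].counts, ds2[0].counts, check_dtype=False)
        assert ds2[0].condition.tolist() == ds[0].condition.tolist()
        pd.testing.assert_frame_equal(peaks[0].intervals, peaks2[0].intervals)
        assert peaks2[1].treatment_class == peaks[1].treatment_class
        np.testing.assert_allclose(
            cohorts[0].mrna_expr.values, cohorts2[0].mrna_expr.values, rtol=0, atol=1e-9
        )
        np.testing.assert_allclose(screens[0].scores.values, screens2[0].scores.values, atol=1e-9)
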