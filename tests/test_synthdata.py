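"""Synthetic generators: determinism, noise calibration, truth recovery."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dsrt import synthdata as sd
from dsrt import biomarker as bm
from dsrt import screen
from dsrt.grfit import gr_transform

DOSES = list(sd.DEFAULT_CONCENTRATIONS_NM)


class TestPlates:
    def test_noise_free_step_response(self):
        truth = sd.ScreenTruth("L1", "D1", e_inf=0.0, ec50=100.0, hill=60.0)
        layout = sd.PlateLayout()
        wells = sd.gen_plate([truth], layout=layout, noise_cv=0.0, seed=0)
        drug = wells[wells.role == "drug"].set_index("concentration_nM")
        assert drug.loc[1.0, "signal"] == pytest.approx(layout.neg_level, rel=1e-6)
        assert drug.loc[10.0, "signal"] == pytest.approx(layout.neg_level, rel=1e-6)
        assert drug.loc[1000.0, "signal"] == pytest.approx(layout.pos_level, rel=1e-6)
        assert drug.loc[10000.0, "signal"] == pytest.approx(layout.pos_level, rel=1e-6)

    def test_determinism_byte_identical(self):
        truth = sd.ScreenTruth("L1", "D1", e_inf=0.1, ec50=30.0, hill=1.0)
        a = sd.gen_plate([truth], seed=42).to_csv()
        b = sd.gen_plate([truth], seed=42).to_csv()
        assert a == b

    def test_dmso_sample_cv_matches_generator(self):
        layout = sd.PlateLayout(n_neg=32, neg_level=1000.0)
        wells = sd.gen_plate([], layout=layout, noise_cv=0.05, seed=7)
        neg = wells.loc[wells.role == "neg_ctrl", "signal"]
        cv = neg.std(ddof=1) / neg.mean()
        assert 0.03 <= cv <= 0.07

    def test_layout_overflow(self):
        truths = [sd.ScreenTruth("L1", f"D{i}", e_inf=0.0, ec50=10.0, hill=1.0)
                  for i in range(80)]  # 80*5 + 32 controls > 384
        with pytest.raises(ValueError, match="overflow"):
            sd.gen_plate(truths)

    def test_screen_auc_recovers_truth_noise_free(self):
        scen = sd.default_scenario(seed=9, n_lines=4, n_compounds=3, n_hits=2)
        wells = sd.gen_screen(scen.screen_truths, seed=9, noise_cv=0.0)
        profiles = screen.build_profiles(screen.normalize_plate(wells))
        got = screen.auc_table(profiles)
        assert np.allclose(got.loc[scen.true_auc.index, scen.true_auc.columns],
                           scen.true_auc, atol=1e-9)


class TestGrowthCurves:
    def test_arrested_truth_flat_late_window(self):
        truth = sd.GrowthTruth("L1", baseline_rate=1 / 24,
                               drug_effect={10000.0: 0.0})
        s = sd.gen_growth_curves(truth, [10000.0], noise_sd=0.0, seed=0)[0]
        i96 = np.searchsorted(s.times, 96.0)
        i120 = np.searchsorted(s.times, 120.0)
        assert s.confluence[i120] - s.confluence[i96] == pytest.approx(0.0)

    def test_vehicle_strictly_increasing_until_capacity(self):
        truth = sd.GrowthTruth("L1", baseline_rate=1 / 24)
        s = sd.gen_growth_curves(truth, [0.0], noise_sd=0.0, seed=0)[0]
        below = s.confluence < truth.carrying_capacity - 1e-9
        assert np.all(np.diff(s.confluence[below]) > 0)

    def test_reversible_regrowth_exceeds_arrested_gain(self):
        effect = {100.0: 0.0}
        truth = sd.GrowthTruth("L1", baseline_rate=1 / 24, drug_effect=effect,
                               reversible=True)
        s = sd.gen_growth_curves(truth, [100.0], withdrawal_at=120.0,
                                 noise_sd=0.0, seed=0)[0]
        from dsrt.growth import window_delta
        pre = window_delta(s, 48.0, 120.0)
        post = window_delta(s, 120.0, 192.0)
        assert post > pre

    def test_non_monotone_grid_rejected(self):
        truth = sd.GrowthTruth("L1", baseline_rate=1 / 24)
        with pytest.raises(ValueError):
            sd.gen_growth_curves(truth, [0.0], t_grid=[0, 3, 2], seed=0)

    def test_multiplier_must_be_non_increasing(self):
        with pytest.raises(ValueError):
            sd.GrowthTruth("L1", baseline_rate=1 / 24,
                           drug_effect={1.0: 0.5, 10.0: 0.8})

    def test_determinism(self):
        truth = sd.GrowthTruth("L1", baseline_rate=1 / 24, drug_effect={1.0: 0.5})
        a = sd.gen_growth_curves(truth, [0.0, 1.0], seed=5)
        b = sd.gen_growth_curves(truth, [0.0, 1.0], seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.confluence, y.confluence)


class TestGRAssay:
    def test_transform_anchors_from_generated_counts(self):
        # gr_inf = 1 -> treated equals control -> GR 1 at every dose
        flat = sd.GRCurveTruth("L", "D", gr_inf=1.0, gec50=10.0, hill=1.0)
        df = sd.gen_gr_assay([flat])
        assert np.allclose(gr_transform(df.x0, df.x_ctrl, df.x_c), 1.0)
        # deep asymptote: at saturating dose treated stays near x0 -> GR ~ 0
        stat = sd.GRCurveTruth("L", "D", gr_inf=0.0, gec50=1.0, hill=3.0)
        df = sd.gen_gr_assay([stat])
        top = df[df.concentration_nM == df.concentration_nM.max()]
        assert gr_transform(top.x0, top.x_ctrl, top.x_c)[0] == \
            pytest.approx(0.0, abs=1e-6)

    def test_half_decay_example(self):
        # control doubles once while treated halves: GR = 2^(log2 0.5 / 1) - 1
        assert gr_transform(100.0, 200.0, 50.0) == pytest.approx(-0.5)

    def test_round_trip_matches_truth_curve(self):
        truth = sd.GRCurveTruth("L", "D", gr_inf=-0.6, gec50=55.0, hill=1.4)
        df = sd.gen_gr_assay([truth])
        gr = gr_transform(df.x0, df.x_ctrl, df.x_c)
        assert np.allclose(gr, truth.gr(df.concentration_nM.to_numpy()), atol=1e-12)


class TestExpression:
    def make_gr50(self, n_lines=13, seed=0):
        rng = np.random.default_rng(seed)
        lines = [f"LS{i:02d}" for i in range(n_lines)]
        return pd.DataFrame([rng.lognormal(3, 1, n_lines)], index=["D1"],
                            columns=lines)

    def test_maximal_effect_perfect_rank_correlation(self):
        gr50 = self.make_gr50()
        truth = sd.ExpressionTruth(
            planted_biomarkers=[("BM_S", "D1", "sensitizing", 1.0),
                                ("BM_R", "D1", "resistance", 1.0)],
            n_genes=50, n_lines=13, frac_below_floor=0.0)
        expr, info = sd.gen_expression(truth, gr50, seed=1)
        y = gr50.loc["D1"]
        rho_s = stats.spearmanr(expr.loc["BM_S"], y).statistic
        rho_r = stats.spearmanr(expr.loc["BM_R"], y).statistic
        assert rho_s == pytest.approx(-1.0)
        assert rho_r == pytest.approx(1.0)

    def test_floor_genes_all_removed_by_filter(self):
        gr50 = self.make_gr50()
        truth = sd.ExpressionTruth(planted_biomarkers=[], n_genes=100,
                                   n_lines=13, frac_below_floor=0.2)
        expr, info = sd.gen_expression(truth, gr50, seed=2)
        filtered = bm.filter_expressed(bm.ExpressionMatrix(expr))
        assert set(info["below_floor"]).isdisjoint(filtered.values.index)
        assert len(info["below_floor"]) == 20

    def test_null_pass_rate_consistent_with_binomial(self):
        """Background-only genes pass |rho|>=0.65 & p<0.05 at about the null rate."""
        gr50 = self.make_gr50(seed=3)
        truth = sd.ExpressionTruth(planted_biomarkers=[], n_genes=1000,
                                   n_lines=13, frac_below_floor=0.0)
        expr, _ = sd.gen_expression(truth, gr50, seed=3)
        proc = bm.preprocess_expression(bm.ExpressionMatrix(expr))
        assoc = bm.correlate_gene_drug(proc, gr50.loc["D1"])
        observed = int(assoc.passes_single.sum())
        # independent null estimate: permutation draws of Spearman rho at n=13
        rng = np.random.default_rng(0)
        y = np.arange(13, dtype=float)
        rhos = np.array([stats.spearmanr(rng.permutation(y), y).statistic
                         for _ in range(4000)])
        p0 = np.mean(np.abs(rhos) >= 0.65)
        n = len(assoc)
        bound = 4 * np.sqrt(n * p0 * (1 - p0))
        assert abs(observed - n * p0) <= max(bound, 5)

    def test_too_many_planted_rejected(self):
        with pytest.raises(ValueError):
            sd.ExpressionTruth(planted_biomarkers=[("G", "D", "sensitizing", 1.0)] * 5,
                               n_genes=3)

    def test_determinism(self):
        gr50 = self.make_gr50()
        truth = sd.ExpressionTruth(planted_biomarkers=[], n_genes=40, n_lines=13)
        a, _ = sd.gen_expression(truth, gr50, seed=8)
        b, _ = sd.gen_expression(truth, gr50, seed=8)
        assert a.equals(b)


class TestGeneSets:
    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            sd.gen_gene_sets([], n_sets=1)

    def test_zero_sets_empty_collection(self):
        assert sd.gen_gene_sets(list("abcdefghij"), n_sets=0,
                                set_size_range=(2, 3)) == {}

    def test_duplicate_planted_genes_deduplicated_with_warning(self):
        with pytest.warns(UserWarning, match="dedup"):
            sets = sd.gen_gene_sets(list("abcdefghij"), n_sets=0,
                                    set_size_range=(2, 3),
                                    planted_set=["a", "b", "a"])
        assert sets["PLANTED_SET"] == ["a", "b"]

    def test_sizes_within_range(self):
        sets = sd.gen_gene_sets([f"g{i}" for i in range(100)], n_sets=20,
                                set_size_range=(5, 9), seed=1)
        assert all(5 <= len(v) <= 9 for v in sets.values())
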