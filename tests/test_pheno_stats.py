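import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import ddct_direct, pearson_r_direct, welch_direct
from bequant.pheno_stats import (ataxia_composite, correlation_report,
                                 ddct_fold_change, fold_ratio, pearson,
                                 percent_change, round_half_away, welch_t)
from bequant.simulate import simulate_cohort, simulate_ct_table


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == 1.0
        assert res.ci_high == 1.0
        assert res.p == 0.0

    def test_perfect_anticorrelation(self):
        x = np.arange(5.0)
        assert pearson(x, -x).r == -1.0

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(101)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        res = pearson(x, y)
        r = pearson_r_direct(list(x), list(y))
        assert res.r == pytest.approx(r, abs=1e-12)
        t = r * math.sqrt(8 / (1 - r * r))
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), 8), abs=1e-12)
        z, se = math.atanh(r), 1 / math.sqrt(7)
        crit = stats.norm.ppf(0.975)
        assert res.ci_low == pytest.approx(math.tanh(z - crit * se), abs=1e-12)
        assert res.ci_high == pytest.approx(math.tanh(z + crit * se), abs=1e-12)
        assert res.ci_low <= res.r <= res.ci_high

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [3.0, 4.0])

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r = pearson(x, y).r
        assert pearson(y, x).r == pytest.approx(r, abs=1e-12)
        assert pearson(3.0 * x + 5.0, y).r == pytest.approx(r, abs=1e-12)
        assert pearson(-2.0 * x, y).r == pytest.approx(-r, abs=1e-12)


class TestChangeSummaries:
    def test_male_bodyweight_gain_rounds_to_published_value(self):
        # group means 25.0 g vs 24.0 g -> 4.2% gain at one decimal
        assert round_half_away(percent_change(25.0, 24.0)) == 4.2

    def test_no_change_is_zero(self):
        assert percent_change(17.3, 17.3) == 0.0

    def test_female_six_week_means_give_5_9_percent(self):
        # direct arithmetic on the printed 6-week means 16.2 g vs 15.3 g
        assert round_half_away(percent_change(16.2, 15.3)) == 5.9

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            percent_change(10.0, 0.0)

    def test_vector_dose_ratio_rounds_to_1_7(self):
        # 8.0e10 vs 4.8e10 vector genomes
        assert fold_ratio(8.0e10, 4.8e10) == pytest.approx(5 / 3)
        assert round_half_away(fold_ratio(8.0e10, 4.8e10)) == 1.7

    def test_equal_doses_give_unity(self):
        assert fold_ratio(3.0, 3.0) == 1.0

    def test_exact_1_25_renders_1_3(self):
        assert fold_ratio(6.0e10, 4.8e10) == pytest.approx(1.25)
        assert round_half_away(1.25) == 1.3
        assert round_half_away(-1.25) == -1.3


class TestWelch:
    def test_identical_groups_give_t_zero_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        t, df, p = welch_t(a, a)
        assert t == 0.0
        assert p == 1.0

    def test_matches_direct_formula_oracle(self):
        a = [19.8, 21.2, 20.6, 22.1, 20.9, 23.0]
        b = [17.4, 18.9, 18.1, 19.6, 17.9]
        t, df, p = welch_t(a, b)
        t0, df0 = welch_direct(a, b)
        assert t == pytest.approx(t0, abs=1e-12)
        assert df == pytest.approx(df0, abs=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(t0), df0), abs=1e-12)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [2.0, 3.0])


class TestDdct:
    def _table(self):
        # hand-built 4-sample plate: (sample, group, gene, ct)
        rows = [
            ("h1", "het", "Akt", 20.0), ("h1", "het", "Atf4", 24.0),
            ("h2", "het", "Akt", 20.4), ("h2", "het", "Atf4", 24.6),
            ("m1", "hom", "Akt", 19.8), ("m1", "hom", "Atf4", 22.6),
            ("m2", "hom", "Akt", 20.2), ("m2", "hom", "Atf4", 23.2),
        ]
        return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])

    def test_calibrator_against_itself_is_exactly_one(self):
        assert ddct_fold_change(self._table(), "Atf4", "het", "het") == 1.0

    def test_unit_negative_ddct_doubles(self):
        table = self._table()
        shifted = table.copy()
        mask = (shifted["group"] == "hom") & (shifted["gene"] == "Atf4")
        # set hom dCt exactly one cycle below het dCt
        shifted.loc[mask, "ct"] = [19.8 + 3.1, 20.2 + 3.1]
        assert ddct_fold_change(shifted, "Atf4", "hom", "het") == pytest.approx(2.0)

    def test_matches_hand_computed_oracle(self):
        got = ddct_fold_change(self._table(), "Atf4", "hom", "het")
        oracle = ddct_direct(
            {
                "h1": ("het", 24.0, 20.0), "h2": ("het", 24.6, 20.4),
                "m1": ("hom", 22.6, 19.8), "m2": ("hom", 23.2, 20.2),
            },
            "hom", "het",
        )
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_missing_reference_gene_rejected(self):
        table = self._table()
        with pytest.raises(ValueError, match="reference gene"):
            ddct_fold_change(table[table["gene"] != "Akt"], "Atf4", "hom", "het")

    def test_recovers_planted_fold_from_simulated_plate(self):
        ct = simulate_ct_table(fold=2.5, n_per_group=6, noise_sd=0.1, seed=11)
        folds = [
            ddct_fold_change(ct, g, "hom", "het")
            for g in ("Gadd34", "Atf4", "Ddit3", "Trib3")
        ]
        assert np.mean(folds) == pytest.approx(2.5, rel=0.15)


class TestAtaxiaComposite:
    def test_extremes_of_the_scale(self):
        assert ataxia_composite(3, 3, 3, 3, 1) == 13
        assert ataxia_composite(0, 0, 0, 0, 0) == 0

    def test_out_of_range_item_rejected(self):
        with pytest.raises(ValueError):
            ataxia_composite(4, 0, 0, 0, 0)
        with pytest.raises(ValueError):
            ataxia_composite(0, 0, 0, 0, 2)
        with pytest.raises(ValueError):
            ataxia_composite(-1, 0, 0, 0, 0)


class TestCorrelationReport:
    def test_planted_cohort_correlations_recovered_exactly(self):
        df = simulate_cohort(n=24, seed=3)
        rep = correlation_report(df, ["nonsyn_bystander_pct"])
        by_pheno = rep.set_index("phenotype")["r"]
        assert by_pheno["bodyweight_g"] == pytest.approx(0.54, abs=1e-9)
        assert by_pheno["grip_strength_n"] == pytest.approx(0.06, abs=1e-9)
        assert by_pheno["traverse_time_s"] == pytest.approx(0.34, abs=1e-9)
        assert (rep["n"] == 24).all()

    def test_duplicated_animal_ids_rejected(self):
        df = simulate_cohort(n=6, seed=1)
        df.loc[1, "animal_id"] = df.loc[0, "animal_id"]
        with pytest.raises(ValueError, match="duplicated"):
            correlation_report(df, ["nonsyn_bystander_pct"])

    def test_small_stratum_skipped(self):
        df = simulate_cohort(n=6, seed=1)
        df.loc[0, "genotype"] = "hom"  # a 1-animal stratum
        rep = correlation_report(df, ["nonsyn_bystander_pct"])
        assert set(rep["stratum"]) == {"het"}

    def test_missing_columns_yield_empty_report(self):
        df = simulate_cohort(n=6, seed=1).drop(
            columns=["bodyweight_g", "grip_strength_n", "traverse_time_s"]
        )
        df["bodyweight_g"] = np.nan
        df["grip_strength_n"] = np.nan
        df["traverse_time_s"] = np.nan
        rep = correlation_report(df, ["nonsyn_bystander_pct"])
        assert rep.empty
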