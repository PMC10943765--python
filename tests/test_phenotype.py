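import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ftirharvest.datasets import load_harvest_window_table
from ftirharvest.phenotype import (TraitFactorModel, cv, dmc, factor_analysis,
                                   monthly_cv_table, rank_harvest_months,
                                   spearman_env, water_content)


class TestScalars:
    def test_cv_of_constant_vector_is_zero(self):
        assert cv([3.0, 3.0, 3.0]) == 0.0

    def test_cv_hand_computed(self):
        # mean 3, sample SD sqrt(2): CV = sqrt(2)/3
        assert cv([2.0, 4.0]) == pytest.approx(np.sqrt(2) / 3, abs=1e-4)
        assert cv([2.0, 4.0]) == pytest.approx(0.4714, abs=1e-4)

    def test_cv_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(1, 5, size=20)
        assert cv(v) == pytest.approx(np.std(v, ddof=1) / np.mean(v))

    def test_cv_zero_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cv([-1.0, 1.0])

    def test_dmc_values(self):
        assert dmc(1.0, 1.0) == 100.0
        assert dmc(0.2, 1.0) == pytest.approx(20.0)

    def test_dmc_above_fresh_warns(self):
        with pytest.warns(UserWarning):
            assert dmc(2.0, 1.0) == pytest.approx(200.0)

    def test_dmc_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            dmc(0.5, 0.0)
        with pytest.raises(ValueError):
            dmc(-0.1, 1.0)

    def test_water_content_complements(self):
        assert water_content(0.0) == 100.0
        assert water_content(22.37) == pytest.approx(77.63)
        assert water_content(14.27) == pytest.approx(85.73)

    def test_dmc_water_exact_complement_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            fresh = rng.uniform(0.5, 5.0)
            dry = rng.uniform(0.0, fresh)
            d = dmc(dry, fresh)
            assert d + water_content(d) == pytest.approx(100.0, abs=1e-12)


class TestHarvestWindowTable:
    def test_stem_complements_within_printed_precision(self):
        t = load_harvest_window_table()
        np.testing.assert_allclose(100.0 - t["X6"], t["X8"], atol=0.1)

    def test_leaf_complements_within_printed_precision(self):
        t = load_harvest_window_table()
        np.testing.assert_allclose(100.0 - t["X7"], t["X9"], atol=0.1)

    def test_covers_harvest_window_months(self):
        assert sorted(load_harvest_window_table()["month"]) == [1, 2, 3, 4, 11, 12]


class TestMonthlyCv:
    def test_identical_plants_give_zero_cv_no_flags(self, linked_dataset):
        _, traits, _ = linked_dataset
        clones = pd.concat([traits.iloc[[0]]] * 3)
        out = monthly_cv_table(clones.assign(month=1))
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-12)
        assert not out.attrs["unstable"].to_numpy().any()

    def test_high_variance_month_flagged(self):
        rng = np.random.default_rng(2)
        rows = []
        for month in (1, 2):
            scale = 3.0 if month == 2 else 0.02
            for _ in range(10):
                x6 = 20 + rng.normal(0, scale * 2)
                x7 = 15 + rng.normal(0, scale)
                rows.append({"month": month,
                             "X1": 20 + rng.normal(0, scale * 10),
                             "X2": 5.0, "X3": 3.0, "X4": 1.0, "X5": 0.5,
                             "X6": x6, "X7": x7,
                             "X8": 100 - x6, "X9": 100 - x7})
        out = monthly_cv_table(pd.DataFrame(rows))
        flags = out.attrs["unstable"]
        assert flags.loc[2, "X1"] and not flags.loc[1, "X1"]

    def test_full_synthetic_table_is_twelve_by_nine(self, linked_dataset):
        _, traits, _ = linked_dataset
        out = monthly_cv_table(traits)
        assert out.shape == (12, 9)


class TestFactorAnalysis:
    def test_three_latent_factors_recovered(self, linked_dataset):
        _, traits, _ = linked_dataset
        fr = factor_analysis(traits)
        assert fr.n_factors == 3
        assert fr.cumulative_contribution >= 70.0
        assert np.all(np.diff(np.concatenate([[0], np.cumsum(fr.contributions)]))
                      >= 0)
        assert fr.cumulative_contribution <= 100.0 + 1e-9

    def test_single_trait_gives_one_full_factor(self):
        t = pd.DataFrame({"month": [1, 1, 2, 2, 3, 3],
                          "X1": [1.0, 2.0, 3.0, 2.5, 1.5, 2.2]})
        fr = TraitFactorModel(t).fit()
        assert fr.n_factors == 1
        assert fr.cumulative_contribution == pytest.approx(100.0)

    def test_scores_invariant_to_affine_trait_rescaling(self, linked_dataset):
        _, traits, _ = linked_dataset
        fr1 = factor_analysis(traits, n_factors=3)
        rescaled = traits.copy()
        rescaled["X1"] = rescaled["X1"] * 10.0 + 5.0
        fr2 = factor_analysis(rescaled, n_factors=3)
        np.testing.assert_allclose(fr1.composite_scores.to_numpy(),
                                   fr2.composite_scores.to_numpy(), atol=1e-8)

    def test_varimax_preserves_communalities(self, linked_dataset):
        _, traits, _ = linked_dataset
        fr = factor_analysis(traits, n_factors=3)
        x = traits[fr.loadings.index].to_numpy(float)
        r = np.corrcoef(x, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(r)
        order = np.argsort(eigvals)[::-1]
        unrotated = eigvecs[:, order[:3]] * np.sqrt(eigvals[order[:3]])
        np.testing.assert_allclose((fr.loadings.to_numpy() ** 2).sum(axis=1),
                                   (unrotated ** 2).sum(axis=1), atol=1e-8)

    def test_zero_variance_trait_named_in_error(self):
        t = pd.DataFrame({"month": [1, 1, 2, 2],
                          "X1": [1.0, 2.0, 3.0, 2.5],
                          "X2": [5.0, 5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="X2"):
            TraitFactorModel(t).fit()

    def test_planted_best_month_ranked_first(self):
        # three independent latents, one month made uniformly superior
        rng = np.random.default_rng(3)
        rows = []
        for month in range(1, 13):
            boost = 3.0 if month == 11 else 0.0
            for _ in range(10):
                size, st, lf = rng.normal(boost, 1), rng.normal(boost, 1), \
                    rng.normal(boost, 1)
                x6 = 18 + 2 * st
                x7 = 14 + 1.5 * lf
                rows.append({"month": month,
                             "X1": 20 + 5 * size + rng.normal(0, 0.5),
                             "X2": 5 + size + rng.normal(0, 0.2),
                             "X3": 3 + size + rng.normal(0, 0.2),
                             "X4": 1 + 0.2 * size + rng.normal(0, 0.05),
                             "X5": 0.5 + 0.1 * size + rng.normal(0, 0.02),
                             "X6": x6, "X7": x7,
                             "X8": 100 - x6, "X9": 100 - x7})
        fr = factor_analysis(pd.DataFrame(rows))
        assert fr.ranking[0] == 11


def brute_force_spearman(a, b):
    """Midrank-based rank correlation computed from first principles."""
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    ra_c = ra - ra.mean()
    rb_c = rb - rb.mean()
    return float(ra_c @ rb_c / np.sqrt((ra_c @ ra_c) * (rb_c @ rb_c)))


class TestSpearmanEnv:
    def _table(self, x2_by_month, months=(11, 12, 1, 2, 3, 4)):
        rows = []
        for month, x2 in zip(months, x2_by_month):
            for _ in range(2):
                rows.append({"month": month, "X1": 20.0, "X2": x2,
                             "X3": 3.0, "X4": 1.0, "X5": 0.5,
                             "X6": 18.0, "X7": 14.0, "X8": 82.0, "X9": 86.0})
        # tiny jitter so traits are not all constant
        t = pd.DataFrame(rows)
        rng = np.random.default_rng(0)
        for c in ("X1", "X3", "X4", "X5"):
            t[c] = t[c] + rng.normal(0, 1e-3, len(t))
        return t

    def _env(self, months=(11, 12, 1, 2, 3, 4)):
        return pd.DataFrame({"month": months,
                             "sard": [100, 200, 300, 400, 500, 600],
                             "pre": [60, 50, 40, 30, 20, 10]})

    def test_monotone_increase_gives_rho_one(self):
        t = self._table([1, 2, 3, 4, 5, 6])
        out = spearman_env(t, self._env())
        row = out[(out.trait == "X2") & (out.variable == "sard")].iloc[0]
        assert row.rho == pytest.approx(1.0)
        assert row.significant

    def test_reversed_ordering_gives_rho_minus_one(self):
        t = self._table([6, 5, 4, 3, 2, 1])
        out = spearman_env(t, self._env())
        row = out[(out.trait == "X2") & (out.variable == "sard")].iloc[0]
        assert row.rho == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        t = self._table([3, 3, 1, 5, 5, 2])
        env = self._env()
        out = spearman_env(t, env)
        row = out[(out.trait == "X2") & (out.variable == "sard")].iloc[0]
        monthly = t.groupby("month")["X2"].mean()
        merged = monthly.to_frame().join(env.set_index("month"))
        assert row.rho == pytest.approx(
            brute_force_spearman(merged["X2"].to_numpy(),
                                 merged["sard"].to_numpy()))

    def test_exact_permutation_p_for_small_n(self):
        t = self._table([1, 2, 3, 4, 5, 6])
        out = spearman_env(t, self._env())
        row = out[(out.trait == "X2") & (out.variable == "sard")].iloc[0]
        # perfectly monotone n=6: exact two-sided p = 2/6! = 1/360
        assert row.p == pytest.approx(2 / 720)

    def test_constant_trait_reported_missing(self):
        t = self._table([2, 2, 2, 2, 2, 2])
        out = spearman_env(t, self._env())
        row = out[(out.trait == "X2") & (out.variable == "sard")].iloc[0]
        assert np.isnan(row.rho) and not row.significant

    def test_planted_negative_link_recovered(self, linked_dataset):
        _, traits, env = linked_dataset
        harvest = traits[traits["month"].isin([11, 12, 1, 2, 3, 4])]
        out = spearman_env(harvest, env)
        row = out[(out.trait == "X2") & (out.variable == "sard")].iloc[0]
        assert row.rho < 0


class TestHarvestRanking:
    def test_planted_december_peak_is_optimal(self, linked_dataset):
        _, traits, _ = linked_dataset
        fr = factor_analysis(traits)
        report = rank_harvest_months(fr, traits)
        assert len(report) == 12
        assert report.loc[report["optimal"], "month"].iloc[0] == 12
        assert report["in_window"].any()

    def test_uniform_months_report_no_window(self):
        rng = np.random.default_rng(4)
        rows = []
        for month in range(1, 13):
            for _ in range(6):
                x6 = 18 + rng.normal(0, 1e-9)
                rows.append({"month": month, "X1": 20 + rng.normal(0, 1e-9),
                             "X2": 5.0 + rng.normal(0, 1e-9),
                             "X3": 3.0 + rng.normal(0, 1e-9),
                             "X4": 1.0 + rng.normal(0, 1e-9),
                             "X5": 0.5 + rng.normal(0, 1e-9),
                             "X6": x6, "X7": 14.0 + rng.normal(0, 1e-9),
                             "X8": 100 - x6, "X9": 86.0})
        t = pd.DataFrame(rows)
        t["X9"] = 100 - t["X7"]
        fr = factor_analysis(t)
        report = rank_harvest_months(fr, t)
        assert "no distinct window" in report.attrs["note"]

    def test_missing_months_rejected(self, linked_dataset):
        _, traits, _ = linked_dataset
        fr = factor_analysis(traits)
        with pytest.raises(ValueError, match="12 months"):
            rank_harvest_months(fr, traits[traits["month"] < 10])
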