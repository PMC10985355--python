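"""Genetic-parameter chain: ANOVA, variance components, CVs, h², GA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import droughtomics as dm
from droughtomics import quantgen as qg
from conftest import make_pheno


def brute_force_anova(pheno, trait, year, regime):
    """Sequential least-squares oracle for the genotype+replicate model."""
    sub = pheno[
        (pheno["trait"] == trait)
        & (pheno["year"] == year)
        & (pheno["regime"] == regime)
    ]
    y = sub["value"].to_numpy(dtype=float)
    n = len(y)
    sst = ((y - y.mean()) ** 2).sum()

    def rss(cols):
        X = np.ones((n, 1))
        for c in cols:
            X = np.column_stack([X, pd.get_dummies(sub[c].astype(str)).to_numpy()])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return ((y - X @ beta) ** 2).sum()

    ss_r = sst - rss(["rep"])
    ss_g = rss(["rep"]) - rss(["rep", "variety"])
    ss_e = rss(["rep", "variety"])
    return ss_g, ss_r, ss_e


class TestAnovaPerEnvironment:
    def test_all_equal_values_zero_mean_squares(self):
        ph = make_pheno({"g1": [5, 5], "g2": [5, 5], "g3": [5, 5]})
        an = qg.anova_per_environment(ph, "T", (2017, "WW"))
        assert an.ms("genotype") == 0
        assert an.ms("error") == 0

    def test_toy_table_against_least_squares_oracle(self):
        ph = make_pheno({"g1": [4, 6], "g2": [8, 10], "g3": [12, 14]})
        an = qg.anova_per_environment(ph, "T", (2017, "WW"))
        assert an.ms("genotype") == pytest.approx(32.0)
        ss_g, ss_r, ss_e = brute_force_anova(ph, "T", 2017, "WW")
        assert an.rows.set_index("source").loc["genotype", "ss"] == pytest.approx(ss_g)
        assert an.rows.set_index("source").loc["replicate", "ss"] == pytest.approx(ss_r)
        assert an.rows.set_index("source").loc["error", "ss"] == pytest.approx(
            ss_e, abs=1e-9
        )

    def test_unbalanced_layout_matches_oracle(self):
        ph = make_pheno({"g1": [4, 6, 5], "g2": [8, 10], "g3": [12, 14, 13]})
        an = qg.anova_per_environment(ph, "T", (2017, "WW"))
        ss_g, ss_r, ss_e = brute_force_anova(ph, "T", 2017, "WW")
        tab = an.rows.set_index("source")
        assert tab.loc["genotype", "ss"] == pytest.approx(ss_g)
        assert tab.loc["error", "ss"] == pytest.approx(ss_e)

    def test_single_replicate_errors(self):
        ph = make_pheno({"g1": [4], "g2": [8]})
        with pytest.raises(ValueError, match="replicate"):
            qg.anova_per_environment(ph, "T", (2017, "WW"))

    def test_null_f_pvalues_uniform(self):
        """Genotype-F p-values under the null are U(0,1) (KS test)."""
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(300):
            ph = make_pheno(
                {f"g{i}": list(rng.standard_normal(3)) for i in range(12)}
            )
            an = qg.anova_per_environment(ph, "T", (2017, "WW"))
            pvals.append(
                float(an.rows.set_index("source").loc["genotype", "p_value"])
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestCombinedAnova:
    @staticmethod
    def _multi_env(gen_effect=0.0, year_effect=0.0, gxe=0.0, seed=0, n_geno=30):
        rng = np.random.default_rng(seed)
        gvals = rng.standard_normal(n_geno) * gen_effect
        delta = rng.standard_normal(n_geno) * gxe  # regime-specific genotype effect
        rows = []
        for yi, year in enumerate((2017, 2018)):
            for regime in ("WW", "DS"):
                for g in range(n_geno):
                    for rep in (1, 2):
                        val = (
                            gvals[g]
                            + year_effect * yi
                            + delta[g] * (regime == "DS")
                            + rng.standard_normal()
                        )
                        rows.append((f"g{g}", "T", year, regime, rep, val))
        return pd.DataFrame(
            rows, columns=["variety", "trait", "year", "regime", "rep", "value"]
        )

    def test_identical_years_zero_year_mean_square(self):
        ph = self._multi_env(gen_effect=1.0, seed=1)
        # copy 2017 values into 2018 so years are identical
        a = ph[ph["year"] == 2017].copy()
        b = a.copy()
        b["year"] = 2018
        an = qg.combined_anova(pd.concat([a, b], ignore_index=True), "T")
        assert an.rows.set_index("source").loc["year", "mean_square"] == pytest.approx(
            0.0, abs=1e-18
        )

    def test_null_year_effect_rarely_significant(self):
        hits = 0
        n = 40
        for s in range(n):
            an = qg.combined_anova(self._multi_env(gen_effect=1.0, seed=s), "T")
            p = float(an.rows.set_index("source").loc["year", "p_value"])
            hits += p < 0.05
        assert hits / n <= 0.15

    def test_planted_gxe_detected(self):
        hits = 0
        n = 30
        for s in range(n):
            an = qg.combined_anova(
                self._multi_env(gen_effect=0.5, gxe=1.5, seed=1000 + s), "T"
            )
            p = float(
                an.rows.set_index("source").loc["genotype:regime", "p_value"]
            )
            hits += p < 0.05
        assert hits / n >= 0.8

    def test_single_year_raises(self):
        ph = make_pheno({"g1": [1, 2], "g2": [3, 4]})
        with pytest.raises(ValueError, match="2 years"):
            qg.combined_anova(ph, "T")


class TestVarianceComponents:
    def _anova(self, msg, mse, r):
        rows = pd.DataFrame(
            {
                "source": ["genotype", "error"],
                "df": [2, 4],
                "ss": [msg * 2, mse * 4],
                "mean_square": [msg, mse],
                "f_value": [np.nan, np.nan],
                "p_value": [np.nan, np.nan],
            }
        )
        return qg.AnovaTable(rows=rows, r=r)

    def test_direct_arithmetic(self):
        vc = qg.variance_components(self._anova(10, 4, 3))
        assert vc["sigma_g2"] == pytest.approx(2.0)
        assert vc["sigma_e2"] == pytest.approx(4.0)
        assert vc["sigma_p2"] == pytest.approx(6.0)
        assert not vc["negative_clamped"]

    def test_equal_mean_squares_zero_genetic_variance(self):
        assert qg.variance_components(self._anova(4, 4, 3))["sigma_g2"] == 0

    def test_negative_estimate_clamped_and_flagged(self):
        vc = qg.variance_components(self._anova(2, 4, 3))
        assert vc["sigma_g2"] == 0
        assert vc["negative_clamped"]

    def test_zero_replicates_error(self):
        with pytest.raises(ValueError):
            qg.variance_components(self._anova(10, 4, 0))


class TestCoefficientsOfVariation:
    def test_zero_genetic_variance(self):
        vc = {"sigma_g2": 0.0, "sigma_e2": 4.0, "sigma_p2": 4.0}
        cvs = qg.coefficients_of_variation(vc, mean=20.0, mse=4.0)
        assert cvs["ecv"] == pytest.approx(10.0)
        assert cvs["gcv"] == pytest.approx(0.0)
        assert cvs["pcv"] == pytest.approx(10.0)

    def test_worked_values(self):
        vc = {"sigma_g2": 2.0, "sigma_e2": 4.0, "sigma_p2": 6.0}
        cvs = qg.coefficients_of_variation(vc, mean=10.0, mse=4.0)
        assert cvs["gcv"] == pytest.approx(14.142, abs=1e-3)
        assert cvs["pcv"] == pytest.approx(24.495, abs=1e-3)

    def test_class_bounds(self):
        assert qg.cv_class(25.0) == "high"
        assert qg.cv_class(20.0) == "moderate"
        assert qg.cv_class(10.0) == "moderate"
        assert qg.cv_class(9.99) == "low"

    def test_nonpositive_mean_errors(self):
        with pytest.raises(ValueError):
            qg.coefficients_of_variation(
                {"sigma_g2": 1, "sigma_e2": 1, "sigma_p2": 2}, mean=0.0, mse=1.0
            )


class TestHeritabilityAndAdvance:
    def test_h2_extremes(self):
        assert qg.heritability(5.0, 5.0) == pytest.approx(100.0)
        assert qg.heritability(0.0, 5.0) == pytest.approx(0.0)
        assert np.isnan(qg.heritability(0.0, 0.0))

    def test_ga_worked_example(self):
        ga, gam = qg.genetic_advance(50.0, sigma_p=2.0, mean=10.0, k=1.76)
        assert ga == pytest.approx(1.76)
        assert gam == pytest.approx(17.6)

    def test_zero_h2_zero_advance(self):
        ga, gam = qg.genetic_advance(0.0, sigma_p=2.0, mean=10.0)
        assert ga == 0 and gam == 0

    @settings(max_examples=50, derandomize=True)
    @given(
        mean=st.floats(1.0, 1e3),
        pcv=st.floats(0.5, 80.0),
        ratio=st.floats(0.05, 1.0),
        k=st.floats(0.5, 3.0),
    )
    def test_equation_chain_consistency(self, mean, pcv, ratio, k):
        """h², GA, GAM from chained operations equal closed forms to 1e-10."""
        gcv = pcv * ratio
        sigma_p = pcv / 100 * mean
        sigma_g2 = (gcv / 100 * mean) ** 2
        sigma_p2 = sigma_p**2
        h2 = qg.heritability(sigma_g2, sigma_p2)
        ga, gam = qg.genetic_advance(h2, sigma_p, mean, k=k)
        h2_direct = 100 * ratio**2
        ga_direct = k * ratio**2 * sigma_p
        assert h2 == pytest.approx(h2_direct, rel=1e-10)
        assert ga == pytest.approx(ga_direct, rel=1e-10)
        assert gam == pytest.approx(100 * ga_direct / mean, rel=1e-10)


class TestGeneticParamsTable:
    @pytest.fixture()
    def table(self, small_geno):
        arch = [
            dm.TraitArchitecture(
                trait=t,
                h2_target=h,
                residual_sd=1.0,
                env_effects={"WW17": 20.0, "DS17": 15.0},
            )
            for t, h in (("T1", 0.6), ("T2", 0.3))
        ]
        ph, _ = dm.simulate_phenotypes(
            small_geno, arch, envs=[(2017, "WW"), (2017, "DS")], n_reps=3, seed=3
        )
        return qg.genetic_params_table(ph)

    def test_row_count(self, table):
        assert len(table) == 4

    def test_internal_invariants(self, table):
        assert np.allclose(
            table["sigma_p2"], table["sigma_g2"] + table["sigma_e2"]
        )
        assert (table["gcv"] <= table["pcv"] + 1e-12).all()
        assert np.allclose(table["gam"], table["ga"] / table["mean"] * 100)
        ratio_h2 = (table["gcv"] / table["pcv"]) ** 2 * 100
        assert np.allclose(table["h2"], ratio_h2, rtol=1e-9)
        assert ((table["h2"] >= 0) & (table["h2"] <= 100)).all()


class TestPercentReduction:
    def _table(self, ww_means, ds_means, trait="SY"):
        rows = []
        for year, m in zip((2017, 2018, 2020), ww_means):
            rows.append({"trait": trait, "regime": "WW", "year": year, "mean": m})
        for year, m in zip((2017, 2018, 2020), ds_means):
            rows.append({"trait": trait, "regime": "DS", "year": year, "mean": m})
        return pd.DataFrame(rows)

    def test_seed_yield_reduction(self):
        tab = self._table(
            [2594.18, 1352.23, 5125.42], [1918.77, 1088.11, 1200.34]
        )
        assert qg.percent_reduction(tab, "SY") == pytest.approx(53.62, abs=0.01)

    def test_plant_height_reduction(self):
        tab = self._table([108.20, 178.24, 142.31], [86.58, 170.60, 122.21], "PH")
        assert qg.percent_reduction(tab, "PH") == pytest.approx(11.51, abs=0.01)

    def test_identical_means_zero(self):
        tab = self._table([10, 10, 10], [10, 10, 10])
        assert qg.percent_reduction(tab, "SY") == pytest.approx(0.0)

    def test_missing_regime_errors(self):
        tab = self._table([10], [10]).query("regime == 'WW'")
        with pytest.raises(ValueError):
            qg.percent_reduction(tab, "SY")


class TestTraitCorrelations:
    def _pheno(self, traits: dict[str, list[float]]):
        rows = []
        for t, vals in traits.items():
            for i, v in enumerate(vals):
                rows.append((f"g{i}", t, 2017, "WW", 1, v))
        return pd.DataFrame(
            rows, columns=["variety", "trait", "year", "regime", "rep", "value"]
        )

    def test_collinear_traits(self):
        ph = self._pheno({"A": [1, 2, 3, 4], "B": [2, 4, 6, 8]})
        r, _ = qg.trait_correlations(ph, "WW")
        assert r.loc["A", "B"] == pytest.approx(1.0)

    def test_hand_computed_r(self):
        ph = self._pheno({"A": [1, 2, 3], "B": [2, 4, 7]})
        r, p = qg.trait_correlations(ph, "WW")
        assert r.loc["A", "B"] == pytest.approx(0.9934, abs=1e-4)

    def test_sign_flip_under_negation(self):
        ph = self._pheno({"A": [1, 2, 3, 5], "B": [4, 3, 5, 9]})
        r1, _ = qg.trait_correlations(ph, "WW")
        ph_neg = ph.copy()
        ph_neg.loc[ph_neg["trait"] == "B", "value"] *= -1
        r2, _ = qg.trait_correlations(ph_neg, "WW")
        assert r1.loc["A", "B"] == pytest.approx(-r2.loc["A", "B"])

    def test_constant_trait_flagged_nan(self):
        ph = self._pheno({"A": [1, 2, 3], "B": [5, 5, 5]})
        r, _ = qg.trait_correlations(ph, "WW")
        assert np.isnan(r.loc["A", "B"])


class TestContrastGroups:
    def test_identical_groups_t_zero(self):
        ph = make_pheno({f"g{i}": [float(i), float(i)] for i in range(8)})
        res = qg.contrast_groups(ph, ["g0", "g1", "g2", "g3"], ["g0", "g1", "g2", "g3"], "T")
        assert res["t"] == pytest.approx(0.0, abs=1e-12)

    def test_group_swap_flips_t(self):
        ph = make_pheno({f"g{i}": [float(i)] * 2 for i in range(8)})
        hi, lo = ["g4", "g5", "g6", "g7"], ["g0", "g1", "g2", "g3"]
        a = qg.contrast_groups(ph, hi, lo, "T")
        b = qg.contrast_groups(ph, lo, hi, "T")
        assert a["t"] == pytest.approx(-b["t"])

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        hits = 0
        for s in range(20):
            vals = {f"h{i}": [rng.normal(2.0), rng.normal(2.0)] for i in range(10)}
            vals.update(
                {f"l{i}": [rng.normal(0.0), rng.normal(0.0)] for i in range(10)}
            )
            ph = make_pheno(vals)
            res = qg.contrast_groups(
                ph, [f"h{i}" for i in range(10)], [f"l{i}" for i in range(10)], "T"
            )
            hits += res["p"] < 0.01
        assert hits >= 18

    def test_singleton_group_errors(self):
        ph = make_pheno({"g1": [1, 2], "g2": [3, 4], "g3": [5, 6]})
        with pytest.raises(ValueError):
            qg.contrast_groups(ph, ["g1"], ["g2", "g3"], "T")
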