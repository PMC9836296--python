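"""Linear screening, confounder selection, and BH-FDR against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cpglink import (
    CollinearDesignError,
    CpGUnit,
    InsufficientDataError,
    SimulationTruth,
    ValueDomainError,
    fdr_adjust,
    fit_linear,
    generate_cohort,
    r2_from_standardized_slope,
    screen_units,
    select_confounders,
)

from conftest import make_cohort


def ols_oracle(y: np.ndarray, X: np.ndarray) -> dict:
    """Brute-force normal equations: B, SE, t-test p, R2, F for each column."""
    n = len(y)
    D = np.column_stack([np.ones(n), X])
    p = D.shape[1]
    XtX_inv = np.linalg.inv(D.T @ D)
    beta = XtX_inv @ D.T @ y
    resid = y - D @ beta
    df_resid = n - p
    sigma2 = resid @ resid / df_resid
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1 - resid @ resid / ss_tot
    df_model = p - 1
    F = (r2 / df_model) / ((1 - r2) / df_resid)
    return {"beta": beta, "se": se, "p": pvals, "r2": r2, "F": F}


class TestFitLinear:
    def test_perfect_fit(self):
        x = np.arange(10, dtype=float)
        res = fit_linear(x, {"x": x}, focal="x")
        assert res.B == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)
        assert res.p < 1e-12

    def test_five_point_hand_computed_fixture(self):
        # x=[1..5], y=[2,1,4,3,5]: Sxx=10, Sxy=8 -> B=0.8; residual SS=3.6,
        # sigma^2=1.2, SE=sqrt(1.2/10); R^2 = 1 - 3.6/10 = 0.64
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        res = fit_linear(y, {"x": x}, focal="x")
        assert res.B == pytest.approx(0.8)
        assert res.SE == pytest.approx(np.sqrt(1.2 / 10))
        assert res.r2 == pytest.approx(0.64)
        assert res.n == 5 and res.df == (1, 3)

    def test_agrees_with_normal_equations_on_random_designs(self, rng):
        """100 random small designs, relative error < 1e-8 on B/SE/p/R2/F."""
        for i in range(100):
            n = int(rng.integers(8, 40))
            k = int(rng.integers(1, 4))
            X = rng.normal(size=(n, k))
            beta = rng.normal(size=k)
            y = X @ beta + rng.normal(size=n)
            names = [f"x{j}" for j in range(k)]
            focal = names[int(rng.integers(0, k))]
            res = fit_linear(y, dict(zip(names, X.T)), focal=focal)
            ora = ols_oracle(y, X)
            j = names.index(focal) + 1
            assert res.B == pytest.approx(ora["beta"][j], rel=1e-8)
            assert res.SE == pytest.approx(ora["se"][j], rel=1e-8)
            assert res.p == pytest.approx(ora["p"][j], rel=1e-8, abs=1e-300)
            assert res.r2 == pytest.approx(ora["r2"], rel=1e-8)
            assert res.F == pytest.approx(ora["F"], rel=1e-8)

    def test_complete_case_handling(self, rng):
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(size=30)
        y[3] = np.nan
        x2 = x.copy()
        x2[7] = np.nan
        res = fit_linear(y, {"x": x2}, focal="x")
        assert res.n == 28

    def test_constant_predictor_raises_named_error(self):
        with pytest.raises(CollinearDesignError, match="x2"):
            fit_linear(
                np.arange(10.0),
                {"x1": np.arange(10.0), "x2": np.ones(10)},
                focal="x1",
            )

    def test_duplicated_predictor_raises(self):
        x = np.arange(10.0)
        with pytest.raises(CollinearDesignError):
            fit_linear(x, {"x1": x, "x2": 2 * x}, focal="x1")

    def test_too_few_cases_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_linear([1.0, 2.0], {"x": [1.0, 2.0]}, focal="x")

    def test_standardized_slope_identity(self):
        # B=0.25 with SD_x=11.04, SD_y=8.79 implies R^2 ~ 0.10: a simple
        # regression generated to those moments reproduces it.
        assert r2_from_standardized_slope(0.25, 11.04, 8.79) == pytest.approx(
            0.0986, abs=1e-4
        )


class TestFdrAdjust:
    @staticmethod
    def bh_oracle(p: np.ndarray) -> np.ndarray:
        """Brute-force BH: sort, p*(m/rank), cumulative min from the top, clip."""
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        prev = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            val = min(prev, p[i] * m / rank_from_top)
            adj[i] = min(val, 1.0)
            prev = adj[i]
        return adj

    def test_textbook_example(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        assert fdr_adjust(p) == pytest.approx([0.05] * 5)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            np.testing.assert_allclose(fdr_adjust(p), self.bh_oracle(p), rtol=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    def test_adjusted_at_least_raw_and_permutation_equivariant(self, p):
        p = np.asarray(p)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(fdr_adjust(p[perm]), adj[perm], rtol=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueDomainError):
            fdr_adjust([0.5, 1.2])


def _screen_truth(n=500, a=0.08, n_null=5):
    units = [CpGUnit(f"G1_1_CpG_{i}", "G1", "chr1", (1000 + 100 * i,)) for i in range(n_null + 1)]
    return SimulationTruth(
        n_participants=n, units=units, a={"G1_1_CpG_0": a}, default_unit_sd=2.0
    )


class TestScreenUnits:
    def test_planted_unit_flagged_nulls_at_alpha_rate(self):
        cohort = generate_cohort(_screen_truth(), seed=31)
        table = screen_units(cohort, "exposure").set_index("unit_id")
        assert table.loc["G1_1_CpG_0", "significant_unadjusted"]
        assert table["fdr_p"].ge(table["p"]).all()

    def test_null_flag_rate_near_alpha(self):
        """~5% of null unit screens reach p<0.05 (binomial tolerance)."""
        hits = total = 0
        for s in range(40):
            cohort = generate_cohort(_screen_truth(n=156, a=0.0), seed=600 + s)
            t = screen_units(cohort, "exposure")
            hits += int(t["significant_unadjusted"].sum())
            total += len(t)
        rate = hits / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < 3 * se

    def test_zero_variance_unit_recorded_not_fatal(self):
        cohort = make_cohort(
            {"const": [50.0] * 12, "ok": list(np.linspace(10, 40, 12))},
            maltreatment=list(np.linspace(25, 80, 12)),
            depression=list(np.linspace(0, 22, 12)),
        )
        table = screen_units(cohort, "exposure").set_index("unit_id")
        assert table.loc["const", "error"] != ""
        assert np.isnan(table.loc["const", "p"])
        assert table.loc["ok", "error"] == ""

    def test_adjusted_models_include_covariates(self, rng):
        n = 200
        age = rng.normal(25, 4, n)
        x = rng.gamma(2, 6, n) + 25
        m = np.clip(50 + 0.5 * age + rng.normal(0, 2, n), 0, 100)
        cohort = make_cohort(
            {"u": list(m)},
            maltreatment=list(np.clip(x, 25, 125)),
            depression=list(rng.uniform(0, 30, n)),
            extra_phenotypes={"age": list(age)},
        )
        t = screen_units(cohort, "exposure", covariates=["age"]).iloc[0]
        assert not np.isnan(t["B_adj"])
        # adjusting for the age effect changes the model fit
        assert t["r2_adj"] > t["r2"]

    def test_regions_form_separate_family(self):
        from cpglink import group_regions

        truth = SimulationTruth(
            n_participants=120,
            units=[
                CpGUnit("G1_1_CpG_0", "G1", "chr1", (1000,)),
                CpGUnit("G1_1_CpG_1", "G1", "chr1", (1200,)),
            ],
            region_map={"r": (["G1_1_CpG_0", "G1_1_CpG_1"], 5.0)},
            default_unit_sd=1.0,
        )
        cohort = generate_cohort(truth, seed=77)
        g = group_regions(cohort.methylation)
        table = screen_units(cohort, "exposure", regions=g.regions)
        assert set(table["level"]) == {"unit", "region"}
        units_fdr = table[table["level"] == "unit"]["fdr_p"]
        assert units_fdr.notna().all()


class TestSelectConfounders:
    def _cohort_with_planted_confounding(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        age = rng.normal(25, 4, n)
        drug = rng.binomial(1, 0.3, n).astype(float)
        smoking = rng.binomial(1, 0.25, n).astype(float)
        alcohol = rng.poisson(2, n).astype(float)
        bmi = rng.normal(24, 3, n)
        x = np.clip(25 + rng.gamma(1.3, 9.5, n), 25, 125)
        m = np.clip(50 + 0.3 * (age - 25) + 2.0 * drug + rng.normal(0, 1, n), 0, 100)
        y = np.clip(10 + 0.2 * (x - x.mean()) - 0.3 * (age - 25) + 2.5 * drug
                    + rng.normal(0, 4, n), 0, 63)
        return make_cohort(
            {"u": list(m)},
            maltreatment=list(x),
            depression=list(y),
            extra_phenotypes={
                "age": list(age), "drug_use": list(drug), "smoking": list(smoking),
                "alcohol": list(alcohol), "bmi": list(bmi),
            },
        )

    def test_planted_age_and_drug_retained(self):
        cohort = self._cohort_with_planted_confounding(seed=0)
        retained, log = select_confounders(
            cohort, ["age", "smoking", "drug_use", "alcohol", "bmi"], alpha=0.10
        )
        assert retained == ["age", "drug_use"]
        assert set(log["candidate"]) == {"age", "drug_use"}
        # qualifying associations are logged with their p-values
        assert (log["p"] < 0.10).all()

    def test_null_candidate_excluded_at_analytic_rate(self):
        """A candidate independent of everything faces 3 tests at alpha=0.10
        here (exposure, outcome, one unit); exclusion rate over seeds should
        match 0.9^3 within binomial error."""
        excluded = 0
        n_seeds = 60
        for s in range(n_seeds):
            rng = np.random.default_rng(9000 + s)
            n = 200
            cohort = make_cohort(
                {"u": list(np.clip(rng.normal(50, 2, n), 0, 100))},
                maltreatment=list(np.clip(25 + rng.gamma(1.3, 9.5, n), 25, 125)),
                depression=list(np.clip(rng.normal(10, 8, n), 0, 63)),
                extra_phenotypes={"noise": list(rng.normal(size=n))},
            )
            retained, _ = select_confounders(cohort, ["noise"], alpha=0.10)
            excluded += "noise" not in retained
        expect = 0.9**3
        se = np.sqrt(expect * (1 - expect) / n_seeds)
        assert abs(excluded / n_seeds - expect) < 3 * se

    def test_single_level_candidate_warns_and_excluded(self):
        cohort = self._cohort_with_planted_confounding()
        cohort.phenotypes["flat"] = 1.0
        with pytest.warns(UserWarning, match="single level"):
            retained, _ = select_confounders(cohort, ["flat"], alpha=0.10)
        assert retained == []
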