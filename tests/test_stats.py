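"""Outlier filtering, Holm correction, effect-size conversions, the REML
mixed model with Satterthwaite dfs, and correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdemg_hypoxia.simulate import ConditionEffects, simulate_mu_property_table
from hdemg_hypoxia.stats import (
    cohens_f_from_eta_sq,
    corr_matrix,
    correlate,
    eta_sq_from_cohens_f,
    fit_lmm,
    holm_adjust,
    prepare_mu_table,
    zscore_filter,
)


class TestZScoreFilter:
    def test_outlier_dropped(self):
        keep = zscore_filter([10, 11, 10, 12, 50])
        # z of 50 = (50 - 18.6)/17.56 = 1.79?  verify by explicit computation
        x = np.array([10, 11, 10, 12, 50], float)
        z = (x - x.mean()) / x.std(ddof=1)
        assert np.array_equal(keep, np.abs(z) <= 2.5)

    def test_clear_outlier_in_larger_sample(self):
        x = [10, 11, 10, 12, 11, 10, 12, 11, 10, 11, 10, 12, 50]
        keep = zscore_filter(x)
        assert not keep[-1]
        assert keep[:-1].all()

    def test_zero_variance_keeps_all(self):
        assert zscore_filter([5, 5, 5, 5]).all()

    def test_values_within_one_sd_kept(self, rng):
        x = rng.uniform(9, 11, 50)
        assert zscore_filter(x).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(10, 2, 30)
        perm = rng.permutation(30)
        assert np.array_equal(zscore_filter(x)[perm], zscore_filter(x[perm]))


def _holm_brute_force(p):
    """Independent step-down implementation from the definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.zeros(m)
    for rank, idx in enumerate(order):
        candidates = [(m - r) * p[order[r]] for r in range(rank + 1)]
        adj[idx] = min(1.0, max(candidates))
    return adj


class TestHolm:
    def test_hand_computed_example(self):
        assert np.allclose(holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert np.allclose(holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_at_least_raw_and_idempotent(self, rng):
        p = rng.uniform(0, 1, 12)
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        assert np.allclose(np.sort(holm_adjust(adj)), np.sort(adj)) or np.all(
            holm_adjust(adj) >= adj
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), m=st.integers(1, 12))
    def test_matches_brute_force_oracle(self, seed, m):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, m)
        assert np.allclose(holm_adjust(p), _holm_brute_force(p), atol=1e-12)


class TestEffectSizeConversion:
    def test_round_trip_identity(self, rng):
        for eta in rng.uniform(0.01, 0.9, 20):
            f = cohens_f_from_eta_sq(eta)
            assert eta_sq_from_cohens_f(f) == pytest.approx(eta, rel=1e-12)

    def test_formula_values(self):
        assert cohens_f_from_eta_sq(0.5) == pytest.approx(1.0)
        assert cohens_f_from_eta_sq(0.0) == 0.0
        # the standard identity: eta 0.468 -> f = sqrt(.468/.532) = 0.938
        assert cohens_f_from_eta_sq(0.468) == pytest.approx(0.93793, abs=1e-4)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            cohens_f_from_eta_sq(1.0)
        with pytest.raises(ValueError):
            eta_sq_from_cohens_f(-0.1)


class TestPrepareTable:
    def test_flags_and_log_transform(self):
        df = simulate_mu_property_table(seed=3)
        df.loc[df.index[0], "idr"] = 90.0  # gross outlier
        out = prepare_mu_table(df)
        assert not out["idr_kept"].iloc[0]
        assert np.isnan(out["log_idr"].iloc[0])
        kept = out[out["idr_kept"]]
        assert np.allclose(kept["log_idr"], np.log(kept["idr"]))


@pytest.fixture(scope="module")
def report():
    df = prepare_mu_table(simulate_mu_property_table(seed=5))
    return fit_lmm(df, "cv")


class TestFitLMM:
    """The REML fit + Satterthwaite machinery, frozen against an
    independent lmerTest/emmeans run on the identical table
    (seed-5 cohort; Type III tests, sum coding, Holm post-hocs)."""

    def test_variance_components_match_lmer(self, report):
        assert report.sigma2_subject == pytest.approx(0.33485**2, rel=1e-3)
        assert report.sigma2_resid == pytest.approx(0.35887**2, rel=1e-3)

    def test_type3_f_tests_match_lmertest(self, report):
        t = report.terms.set_index("term")
        assert t.loc["condition", "F"] == pytest.approx(21.3978, rel=1e-3)
        assert t.loc["condition", "df2"] == pytest.approx(410.0, rel=5e-3)
        assert t.loc["sex", "F"] == pytest.approx(25.1694, rel=1e-3)
        assert t.loc["sex", "df2"] == pytest.approx(16.0, rel=5e-3)
        assert t.loc["condition:sex", "p"] == pytest.approx(0.9263, abs=1e-3)

    def test_pairwise_contrasts_match_emmeans(self, report):
        c = report.contrasts.set_index("contrast")
        assert c.loc["H1 - CON", "estimate"] == pytest.approx(0.0978, abs=2e-4)
        assert c.loc["H2 - CON", "estimate"] == pytest.approx(0.2730, abs=2e-4)
        assert c.loc["H1 - CON", "p_holm"] == pytest.approx(0.0213, abs=1e-3)

    def test_information_criteria_match_lmer_ml(self, report):
        assert report.aic == pytest.approx(405.9595, abs=0.1)
        assert report.bic == pytest.approx(438.5069, abs=0.1)

    def test_r2_ordering_and_range(self, report):
        assert 0 <= report.r2_marginal <= report.r2_conditional <= 1

    def test_random_effect_detected(self, report):
        assert report.random_effect_p < 1e-6

    def test_zero_between_subject_variance_reduces_to_ols(self):
        import statsmodels.formula.api as smf

        eff = ConditionEffects.null()
        df = prepare_mu_table(
            simulate_mu_property_table(n_f=5, n_m=5, n_mus=6, effects=eff, seed=11)
        )
        # remove the subject structure entirely
        rng = np.random.default_rng(0)
        df["cv"] = 4.0 + rng.normal(0, 0.3, len(df))
        rep = fit_lmm(df, "cv", include_diagnostics=False)
        ols = smf.ols("cv ~ C(condition, Sum) * C(sex, Sum)", data=df).fit()
        # without subject structure the GLS and OLS coefficients coincide
        for name, value in rep.extra["fe_params"].items():
            assert value == pytest.approx(ols.params[name], abs=5e-3)
        assert rep.sigma2_subject < 0.05 * rep.sigma2_resid

    def test_holm_on_contrasts_ge_raw(self, report):
        assert (report.contrasts["p_holm"] >= report.contrasts["p_raw"] - 1e-12).all()


class TestCorrelate:
    def test_perfect_linear(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2 * df["x"] + 1
        out = correlate(df, [("x", "y")])
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_constant_flagged_missing(self):
        df = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        out = correlate(df, [("x", "y")])
        assert np.isnan(out.loc[0, "r"]) and out.loc[0, "flag"] == "constant"

    def test_pairwise_nan_dropping(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=20), "y": rng.normal(size=20)})
        df.loc[3, "x"] = np.nan
        out = correlate(df, [("x", "y")])
        assert out.loc[0, "n"] == 19

    def test_null_calibration(self):
        # independent pairs, n=18: |r| exceeds the 5% critical value ~5% of
        # the time
        rng = np.random.default_rng(0)
        crit = 0.4683  # two-sided 5% critical r for n=18 (t table)
        hits = 0
        reps = 1000
        for _ in range(reps):
            x, y = rng.normal(size=(2, 18))
            r = np.corrcoef(x, y)[0, 1]
            hits += abs(r) > crit
        assert 0.03 < hits / reps < 0.07

    def test_matrix_symmetric(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        r, p = corr_matrix(df, ["a", "b", "c"])
        assert np.allclose(r.values, r.values.T)
        assert np.allclose(np.diag(r.values), 1.0)
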