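import numpy as np
import pandas as pd
import pytest

from betabef import (
    FitError,
    backward_select,
    beta_vs_assembly,
    cross_cruise_regression,
    fit_cruise_slopes,
    fit_mixed,
    fit_ols,
)
from betabef.bef_regression import fit_hypothesis1, prepare_pairs


def exact_pairs(slopes, intercept=1.0, n_pairs=15, noise_sd=0.0, seed=0):
    """Pair table obeying log(biomass) = intercept + slope_c*log(BC) exactly
    (plus optional Gaussian noise)."""
    rng = np.random.default_rng(seed)
    rows = []
    for c, slope in enumerate(slopes):
        bc = rng.uniform(0.2, 0.95, size=n_pairs)
        eps = rng.normal(0, noise_sd, size=n_pairs)
        for j in range(n_pairs):
            rows.append(
                {
                    "cruise": f"c{c + 1:02d}",
                    "site_a": f"s{j}", "site_b": f"s{j + 1}",
                    "bray_curtis": bc[j],
                    "summed_biomass": np.exp(intercept + slope * np.log(bc[j]) + eps[j]),
                }
            )
    return pd.DataFrame(rows)


class TestCruiseSlopes:
    def test_noise_free_fixture_recovers_slope(self):
        pairs = exact_pairs([0.17] * 3)
        eff = fit_cruise_slopes(pairs)
        np.testing.assert_allclose(eff["slope"], 0.17, atol=1e-8)
        assert (eff["n_pairs"] == 15).all()

    def test_constant_bray_curtis_is_fit_error(self):
        pairs = exact_pairs([0.2])
        pairs["bray_curtis"] = 0.5
        pairs["summed_biomass"] = np.exp(np.random.default_rng(0).normal(size=15))
        with pytest.raises(FitError, match="constant"):
            fit_cruise_slopes(pairs)

    def test_small_cruises_skipped(self, caplog):
        pairs = exact_pairs([0.2, 0.3], n_pairs=15)
        pairs = pairs[(pairs["cruise"] == "c01") | (pairs.index % 15 < 2)]
        eff = fit_cruise_slopes(pairs)
        assert list(eff["cruise"]) == ["c01"]

    def test_slope_rmse_within_monte_carlo_bound(self):
        """With noise, fitted slopes scatter around planted values with RMSE
        comparable to the reported standard errors."""
        rng = np.random.default_rng(0)
        slopes = rng.uniform(-0.2, 0.6, size=14)
        pairs = exact_pairs(slopes, noise_sd=0.1, seed=1)
        eff = fit_cruise_slopes(pairs)
        rmse = np.sqrt(np.mean((eff["slope"].to_numpy() - slopes) ** 2))
        assert rmse < 3 * eff["se"].mean()


class TestMixedModel:
    def test_zero_between_cruise_variance_matches_pooled_ols(self):
        pairs = exact_pairs([0.3] * 6, noise_sd=0.05, seed=2)
        data = prepare_pairs(pairs)
        mixed = fit_mixed(data, "log_summed_biomass", ["log_bray_curtis"])
        ols = fit_ols(data, "log_summed_biomass", ["log_bray_curtis"])
        np.testing.assert_allclose(
            mixed.terms["coef"], ols.terms["coef"], atol=1e-6
        )

    def test_random_intercepts_absorbed(self):
        """Cruise-specific intercepts should land in the random effect, not
        bias the common slope."""
        rng = np.random.default_rng(3)
        intercepts = rng.normal(1.0, 0.8, size=10)
        pairs = pd.concat(
            [exact_pairs([0.2], intercept=ic, noise_sd=0.05, seed=s)
             for s, ic in enumerate(intercepts)],
            ignore_index=True,
        )
        pairs["cruise"] = np.repeat([f"c{k:02d}" for k in range(10)], 15)
        data = prepare_pairs(pairs)
        res = fit_mixed(data, "log_summed_biomass", ["log_bray_curtis"])
        assert res.model_type == "mixed"
        assert res.random_effect_var > 0.1
        assert res.coef("log_bray_curtis") == pytest.approx(0.2, abs=0.05)

    def test_pure_noise_marginal_r2_small(self):
        """Against a noise-only response the fixed effects explain ~nothing."""
        r2 = []
        for rep in range(50):
            rng = np.random.default_rng(100 + rep)
            pairs = exact_pairs([0.0] * 6, noise_sd=1.0, seed=200 + rep)
            pairs["summed_biomass"] = np.exp(rng.normal(size=len(pairs)))
            data = prepare_pairs(pairs)
            res = fit_mixed(data, "log_summed_biomass", ["log_bray_curtis"])
            r2.append(res.marginal_r2)
        assert np.median(r2) < 0.05


class TestBackwardSelect:
    @staticmethod
    def _fitter(data, terms):
        return fit_ols(data, "y", terms)

    @staticmethod
    def _planted(seed, n=210, beta=2.0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        df["y"] = beta * df["a"] + rng.normal(size=n)
        return df

    def test_keeps_signal_drops_noise(self):
        df = self._planted(0)
        res = backward_select(self._fitter, df, list("abcd"))
        assert "a" in res.terms.index
        assert res.pvalue("a") < 0.05

    def test_protected_term_retained_despite_large_p(self):
        df = self._planted(1)
        res = backward_select(self._fitter, df, list("abcd"), protected=("b",))
        assert "b" in res.terms.index
        assert "b" not in res.selection_trace

    def test_alpha_one_returns_full_model(self):
        df = self._planted(2)
        res = backward_select(self._fitter, df, list("abcd"), alpha=1.0)
        assert set("abcd") <= set(res.terms.index)
        assert res.selection_trace == []

    def test_alpha_zero_returns_only_protected(self):
        df = self._planted(3)
        res = backward_select(self._fitter, df, list("abcd"), protected=("a",),
                              alpha=0.0)
        assert list(res.terms.index) == ["const", "a"]
        assert sorted(res.selection_trace) == ["b", "c", "d"]

    def test_all_significant_no_removals(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
        df["y"] = df["a"] + df["b"] + 0.1 * rng.normal(size=200)
        res = backward_select(self._fitter, df, ["a", "b"])
        assert res.selection_trace == []


class TestCrossCruise:
    def test_noise_free_fixture_recovers_coefficient(self):
        rng = np.random.default_rng(5)
        mpti = rng.uniform(-2.5, 0.5, size=14)
        eff = pd.DataFrame(
            {
                "cruise": [f"c{k:02d}" for k in range(14)],
                "slope": 0.3 + 0.79 * mpti,
                "mean_beta_mpti": mpti,
            }
        )
        res = cross_cruise_regression(eff)
        assert res.coef("mean_beta_mpti") == pytest.approx(0.79, abs=1e-8)

    def test_too_few_cruises_rejected(self):
        eff = pd.DataFrame(
            {"cruise": ["a", "b"], "slope": [0.1, 0.2],
             "mean_beta_mpti": [-1.0, -0.5]}
        )
        with pytest.raises(FitError, match="3 cruises"):
            cross_cruise_regression(eff)

    def test_covariates_pass_through_selection(self):
        rng = np.random.default_rng(6)
        mpti = rng.uniform(-2.0, 0.0, size=14)
        cov = pd.DataFrame(
            {"cruise": [f"c{k:02d}" for k in range(14)],
             "log_salinity": rng.normal(size=14)}
        )
        eff = pd.DataFrame(
            {"cruise": cov["cruise"], "slope": 0.3 + 0.79 * mpti
             + 0.001 * rng.normal(size=14), "mean_beta_mpti": mpti}
        )
        res = cross_cruise_regression(eff, cov)
        assert "log_salinity" in res.selection_trace
        assert res.coef("mean_beta_mpti") == pytest.approx(0.79, abs=0.05)


class TestHypothesisModels:
    def test_h1_protects_beta_diversity_term(self):
        pairs = exact_pairs([0.0] * 8, noise_sd=0.3, seed=7)
        for col in ("temperature", "salinity", "nitrogen",
                    "phosphate", "par", "chla"):
            pairs[col] = np.random.default_rng(8).uniform(1, 30, len(pairs))
        res = fit_hypothesis1(pairs)
        assert "log_bray_curtis" in res.terms.index
        assert "log_bray_curtis" not in res.selection_trace

    def test_beta_vs_assembly_constant_regressor_rejected(self):
        pairs = exact_pairs([0.2] * 4)
        pairs["beta_mpti"] = -1.0
        with pytest.raises(FitError, match="constant"):
            beta_vs_assembly(pairs)
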