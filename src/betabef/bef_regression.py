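"""Two-stage biodiversity-ecosystem-functioning hypothesis tests.

Stage I asks whether the summed biomass of a site pair rises with the
pair's beta diversity: a Gaussian linear mixed model of log summed biomass
on log Bray-Curtis with a random intercept per cruise, plus backward
elimination of non-significant environmental covariates (the beta-diversity
term is protected and never dropped).

Stage II asks whether the per-cruise beta-diversity effect — the OLS slope
of log summed biomass on log Bray-Curtis within each cruise — grows with
the determinism of community assembly, by regressing the cruise slopes on
each cruise's mean beta-MPTI across cruises.

All responses and positive covariates are natural-log transformed; tests
are two-sided Wald/t tests at alpha = 0.05 unless configured otherwise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitError
from .io import ENV_COLUMNS

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05

#: log-transformed environmental covariate column names
LOG_ENV_COLUMNS = [f"log_{c}" for c in ENV_COLUMNS]


@dataclass
class RegressionResult:
    """Coefficient table plus fit metadata for one (possibly mixed) model."""

    terms: pd.DataFrame  # index: term; columns: coef, se, p
    model_type: str  # "mixed" or "ols"
    nobs: int
    marginal_r2: float
    random_effect_var: float | None = None
    resid_var: float = np.nan
    selection_trace: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.terms.loc[term, "coef"])

    def pvalue(self, term: str) -> float:
        return float(self.terms.loc[term, "p"])


def _safe_log(v: pd.Series) -> pd.Series:
    v = v.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(v.to_numpy())
    out[~(v.to_numpy() > 0)] = np.nan
    return pd.Series(out, index=v.index)


def prepare_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Add log-scale columns used by the hypothesis tests.

    Pairs with zero Bray-Curtis (or non-positive covariates) get NaN in the
    corresponding log column and drop out of fits that use it.
    """
    out = pairs.copy()
    out["log_summed_biomass"] = _safe_log(pairs["summed_biomass"])
    out["log_bray_curtis"] = _safe_log(pairs["bray_curtis"])
    n_zero = int((pairs["bray_curtis"] <= 0).sum())
    if n_zero:
        logger.warning("%d pairs with Bray-Curtis <= 0 excluded from log fits", n_zero)
    for col in ENV_COLUMNS:
        if col in pairs:
            out[f"log_{col}"] = _safe_log(pairs[col])
    return out


def _model_frame(data: pd.DataFrame, response: str, terms: list[str], extra=()):
    cols = [response, *terms, *extra]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise FitError(f"columns not found: {missing}")
    frame = data[cols].dropna()
    if len(frame) <= len(terms) + 1:
        raise FitError(
            f"only {len(frame)} usable rows for {len(terms)} terms"
        )
    for t in terms:
        if np.ptp(frame[t].to_numpy()) == 0:
            raise FitError(f"regressor {t!r} is constant")
    return frame


def _result_from_params(params, bse, pvals, terms, **kw) -> RegressionResult:
    tab = pd.DataFrame(
        {"coef": params, "se": bse, "p": pvals}, index=["const", *terms]
    )
    return RegressionResult(terms=tab, **kw)


def fit_ols(data: pd.DataFrame, response: str, terms: list[str]) -> RegressionResult:
    """Ordinary least squares with an intercept; two-sided t-test p-values."""
    frame = _model_frame(data, response, terms)
    X = sm.add_constant(frame[terms], has_constant="add")
    fit = sm.OLS(frame[response], X).fit()
    fitted_var = float(np.var(fit.fittedvalues - fit.params["const"], ddof=0))
    resid_var = float(fit.scale)
    return _result_from_params(
        fit.params.to_numpy(), fit.bse.to_numpy(), fit.pvalues.to_numpy(), terms,
        model_type="ols", nobs=int(fit.nobs),
        marginal_r2=fitted_var / (fitted_var + resid_var),
        resid_var=resid_var,
    )


def fit_mixed(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
    group: str = "cruise",
    reml: bool = True,
) -> RegressionResult:
    """Gaussian linear mixed model with a random intercept per group.

    Fitted by REML. Reports the Nakagawa-Schielzeth marginal R-squared
    var(X beta) / (var(X beta) + var_group + var_resid). A singular or
    non-converged random-effect fit falls back to pooled OLS with a note.
    """
    frame = _model_frame(data, response, terms, extra=(group,))
    if frame[group].nunique() < 2:
        raise FitError("mixed model needs at least 2 groups")
    X = sm.add_constant(frame[terms], has_constant="add")
    notes = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(frame[response], X, groups=frame[group])
            fit = model.fit(reml=reml, method=["lbfgs", "powell"])
        converged = bool(getattr(fit, "converged", True))
        re_var = float(fit.cov_re.iloc[0, 0])
        if not converged or not np.isfinite(re_var):
            raise FitError("non-converged mixed fit")
    except (FitError, np.linalg.LinAlgError, ValueError) as exc:
        notes.append(f"mixed fit failed ({exc}); fell back to pooled OLS")
        logger.warning(notes[-1])
        res = fit_ols(data, response, terms)
        res.notes.extend(notes)
        return res

    fe = fit.fe_params
    k = len(fe)
    fitted = X.to_numpy() @ fe.to_numpy()
    var_f = float(np.var(fitted, ddof=0))
    resid_var = float(fit.scale)
    if re_var <= 1e-10:
        notes.append("random-intercept variance ~ 0 (singular fit)")
    return _result_from_params(
        fe.to_numpy(), fit.bse.to_numpy()[:k], fit.pvalues.to_numpy()[:k], terms,
        model_type="mixed", nobs=int(fit.nobs),
        marginal_r2=var_f / (var_f + re_var + resid_var),
        random_effect_var=re_var, resid_var=resid_var, notes=notes,
    )


def backward_select(
    fitter,
    data: pd.DataFrame,
    terms: list[str],
    protected=(),
    alpha: float = ALPHA_DEFAULT,
) -> RegressionResult:
    """Stepwise backward elimination on p-values.

    Repeatedly refits and drops the non-protected term with the largest
    p >= alpha until all remaining non-protected terms are significant.
    Protected terms are never candidates. ``fitter(data, terms)`` must
    return a :class:`RegressionResult`.
    """
    protected = set(protected)
    unknown = protected - set(terms)
    if unknown:
        raise FitError(f"protected terms not in model: {sorted(unknown)}")
    current = list(terms)
    trace: list[str] = []
    while True:
        res = fitter(data, current)
        candidates = [t for t in current if t not in protected]
        if not candidates:
            break
        pvals = {t: res.pvalue(t) for t in candidates}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] < alpha:
            break
        current.remove(worst)
        trace.append(worst)
    res.selection_trace = trace
    return res


def fit_cruise_slopes(
    pairs: pd.DataFrame, min_pairs: int = 3, alpha: float = ALPHA_DEFAULT
) -> pd.DataFrame:
    """Per-cruise OLS of log summed biomass on log Bray-Curtis.

    The slope is the cruise's beta-diversity effect. Cruises with fewer
    than ``min_pairs`` usable pairs are skipped with a warning; a cruise
    whose Bray-Curtis values are constant raises :class:`FitError`.
    """
    data = prepare_pairs(pairs)
    rows = []
    for cruise, sub in data.groupby("cruise", sort=True):
        frame = sub[["log_summed_biomass", "log_bray_curtis"]].dropna()
        if len(frame) < min_pairs:
            logger.warning(
                "cruise %s skipped: only %d usable pairs", cruise, len(frame)
            )
            continue
        if np.ptp(frame["log_bray_curtis"].to_numpy()) == 0:
            raise FitError(f"cruise {cruise}: Bray-Curtis constant across pairs")
        X = sm.add_constant(frame[["log_bray_curtis"]], has_constant="add")
        fit = sm.OLS(frame["log_summed_biomass"], X).fit()
        p = float(fit.pvalues["log_bray_curtis"])
        rows.append(
            {
                "cruise": cruise,
                "slope": float(fit.params["log_bray_curtis"]),
                "se": float(fit.bse["log_bray_curtis"]),
                "p_value": p,
                "significant": p < alpha,
                "n_pairs": int(fit.nobs),
            }
        )
    if not rows:
        raise FitError("no cruise had enough usable pairs")
    return pd.DataFrame(rows)


def fit_hypothesis1(
    pairs: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
    protect: tuple[str, ...] = ("log_bray_curtis",),
    include_alpha_diversity: bool = False,
    include_hnf: bool = False,
) -> RegressionResult:
    """Mixed-model test of the pair-level beta-diversity/biomass link.

    Starts from the full environmental covariate set and backward-eliminates
    at ``alpha``; the beta-diversity term (and pooled Shannon diversity, if
    ``include_alpha_diversity``) is always retained.
    """
    data = prepare_pairs(pairs)
    terms = ["log_bray_curtis"] + [c for c in LOG_ENV_COLUMNS if c in data]
    protect = list(protect)
    if include_alpha_diversity:
        terms.append("pooled_shannon")
        protect.append("pooled_shannon")
    if include_hnf and "hnf_biomass" in data:
        data["log_hnf_biomass"] = _safe_log(data["hnf_biomass"])
        terms.append("log_hnf_biomass")

    def fitter(d, t):
        return fit_mixed(d, "log_summed_biomass", t)

    return backward_select(fitter, data, terms, protected=protect, alpha=alpha)


def beta_vs_assembly(pairs: pd.DataFrame) -> RegressionResult:
    """Mixed model of log Bray-Curtis on beta-MPTI (cruise random intercept).

    Checks whether beta diversity itself rises as assembly turns from
    homogenizing toward diversifying selection.
    """
    data = prepare_pairs(pairs)
    return fit_mixed(data, "log_bray_curtis", ["beta_mpti"])


def cruise_covariates(pairs: pd.DataFrame) -> pd.DataFrame:
    """Cruise-level means of the pair-level log environmental covariates."""
    data = prepare_pairs(pairs)
    cols = [c for c in LOG_ENV_COLUMNS if c in data]
    return data.groupby("cruise", sort=True)[cols].mean().reset_index()


def cross_cruise_regression(
    effects: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    alpha: float = ALPHA_DEFAULT,
) -> RegressionResult:
    """OLS of per-cruise beta-diversity slopes on cruise mean beta-MPTI.

    ``effects`` must hold ``cruise``, ``slope`` and ``mean_beta_mpti``
    columns. Optional cruise-level covariates join on ``cruise`` and go
    through backward selection; the beta-MPTI term is protected. When there
    are too few cruises to fit the full covariate model, the covariates are
    dropped with a warning and only the beta-MPTI term is fitted.
    """
    needed = {"cruise", "slope", "mean_beta_mpti"}
    if not needed <= set(effects.columns):
        raise FitError(f"effects table needs columns {sorted(needed)}")
    data = effects.copy()
    terms = ["mean_beta_mpti"]
    if covariates is not None:
        n_params_full = len(covariates.columns) + 1  # + mpti + const
        if effects["cruise"].nunique() < n_params_full + 3:
            logger.warning(
                "too few cruises (%d) for backward selection over %d "
                "cruise-level covariates; fitting beta-MPTI alone",
                effects["cruise"].nunique(), len(covariates.columns) - 1,
            )
        else:
            data = data.merge(covariates, on="cruise", how="left")
            terms += [c for c in covariates.columns if c != "cruise"]
    data = data.dropna(subset=["slope", "mean_beta_mpti"])
    if data["cruise"].nunique() < 3:
        raise FitError("cross-cruise regression needs at least 3 cruises")

    def fitter(d, t):
        return fit_ols(d, "slope", t)

    return backward_select(
        fitter, data, terms, protected=("mean_beta_mpti",), alpha=alpha
    )
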