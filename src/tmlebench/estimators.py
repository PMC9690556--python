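"""Marginal-OR estimators: logistic regression, PS adjustment/matching/IPTW.

All estimators follow the scikit-learn convention: hyperparameters in the
constructor, ``fit(data)`` on a cohort DataFrame (columns w1..w6, z, y,
delta), fitted attributes with a trailing underscore (``or_``,
``se_log_or_``, ``ci_low_``, ``ci_high_``, ``n_used_``) and a ``result_``
``EstimateResult``.  Complete-case filtering (delta == 1) is applied before
any model fitting, mirroring the complete-case analysis pipeline.

These estimators use the *misspecified* working models of the simulation
study by default (outcome: Y ~ Z + W3 + W4; treatment: Z ~ W2 + W6).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .base import (EstimateResult, ModelSpec, OUTCOME_MISSPEC,
                   TREATMENT_MISSPEC)

__all__ = [
    "LogisticFit", "PropensityFit", "MatchResult",
    "fit_logistic", "match_nearest", "standardized_mean_differences",
    "lr_or", "ps_covariate_or", "ps_matching_or", "iptw_or",
    "LogisticOR", "PSCovariateOR", "PSMatchingOR", "IPTWOR",
]


@dataclass(frozen=True)
class LogisticFit:
    """Unpenalized ML logistic fit: coefficients, fitted probabilities."""

    params: pd.Series
    cov_params: pd.DataFrame
    fitted: np.ndarray
    model: ModelSpec
    n_iter: int


@dataclass(frozen=True)
class PropensityFit:
    """Per-subject treatment probabilities on probability and logit scales."""

    ps: np.ndarray
    logit_ps: np.ndarray
    model: ModelSpec
    coefficients: pd.Series


@dataclass(frozen=True)
class MatchResult:
    """1:1 greedy caliper matching output (positional row indices)."""

    pairs: tuple
    caliper_width: float
    n_matched: int


def _separating_column(X: pd.DataFrame, y: np.ndarray) -> str | None:
    """Best-effort identification of a perfectly separating covariate."""
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if v[y == 1].size and v[y == 0].size:
            if v[y == 1].min() > v[y == 0].max() or \
               v[y == 1].max() < v[y == 0].min():
                return col
    return None


def fit_logistic(frame: pd.DataFrame, spec: ModelSpec,
                 response: str) -> LogisticFit:
    """Maximum-likelihood logistic regression of ``response`` on the spec.

    Raises on missing values in used columns, perfect separation (naming the
    offending covariate where identifiable) and IRLS non-convergence.
    """
    X = spec.design_matrix(frame)
    y = frame[response].to_numpy(dtype=float)
    if np.isnan(y).any() or X.isna().any().any():
        raise ValueError(
            f"missing values in response {response!r} or covariates; "
            "filter to complete cases first")
    constant = [c for c in X.columns if X[c].std() == 0]
    if constant:
        # aliased with the intercept; keep the fit well-posed
        warnings.warn(f"dropping zero-variance covariates {constant}",
                      RuntimeWarning)
        X = X.drop(columns=constant)
    exog = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, exog, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=100)
        if not getattr(res, "converged", True):
            sep = _separating_column(X, y)
            if sep is not None:
                raise ValueError(
                    f"perfect separation detected; offending covariate: {sep}")
            res = model.fit(maxiter=1000)  # ill-conditioned but identifiable
    except PerfectSeparationError as exc:
        raise ValueError(
            "perfect separation detected; offending covariate: "
            f"{_separating_column(X, y) or '<combination of covariates>'}"
        ) from exc
    n_iter = len(res.fit_history["deviance"])
    if not getattr(res, "converged", True):
        raise RuntimeError(
            f"logistic fit did not converge in {n_iter} iterations")
    fitted = np.asarray(res.fittedvalues)
    if len(y) and np.abs(fitted - y).max() < 1e-6:
        # perfect prediction of a binary response = (quasi-)separation
        raise ValueError(
            "perfect separation detected; offending covariate: "
            f"{_separating_column(X, y) or '<combination of covariates>'}")
    return LogisticFit(params=res.params, cov_params=res.cov_params(),
                       fitted=np.asarray(res.fittedvalues), model=spec,
                       n_iter=n_iter)


def fit_propensity(frame: pd.DataFrame,
                   spec: ModelSpec = TREATMENT_MISSPEC) -> PropensityFit:
    """Logistic propensity-score model P(Z=1 | covariates)."""
    fit = fit_logistic(frame, spec, response="z")
    ps = np.clip(fit.fitted, 1e-12, 1 - 1e-12)
    return PropensityFit(ps=ps, logit_ps=np.log(ps / (1 - ps)),
                         model=spec, coefficients=fit.params)


def standardized_mean_differences(frame: pd.DataFrame, columns,
                                  z_col: str = "z") -> pd.Series:
    """Absolute standardized mean differences between treatment arms."""
    z = frame[z_col].to_numpy() == 1
    out = {}
    for c in columns:
        v = frame[c].to_numpy(dtype=float)
        m1, m0 = v[z].mean(), v[~z].mean()
        s = np.sqrt((v[z].var(ddof=1) + v[~z].var(ddof=1)) / 2.0)
        out[c] = abs(m1 - m0) / s if s > 0 else 0.0
    return pd.Series(out)


def match_nearest(ps_fit: PropensityFit, z: np.ndarray,
                  caliper_sd_mult: float = 0.15) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching on the logit PS, no replacement.

    The caliper is ``caliper_sd_mult`` times the pooled-sample SD of the
    logit PS.  Treated subjects are processed in descending PS order (ties by
    row index); each takes the nearest still-unmatched control within the
    caliper (ties by control row index).  Deterministic by construction.
    """
    z = np.asarray(z) == 1
    if z.all() or (~z).all():
        raise ValueError("both treatment groups must be non-empty")
    lp = np.asarray(ps_fit.logit_ps, dtype=float)
    sd = lp.std(ddof=1)
    if sd == 0:
        raise ValueError("zero SD of logit propensity scores")
    caliper = caliper_sd_mult * sd

    t_idx = np.flatnonzero(z)
    c_idx = np.flatnonzero(~z)
    order = t_idx[np.lexsort((t_idx, -lp[t_idx]))]  # descending ps, index ties
    c_lp = lp[c_idx]
    avail = np.ones(c_idx.size, dtype=bool)
    pairs = []
    for ti in order:
        d = np.abs(c_lp - lp[ti])
        d[~avail] = np.inf
        j = int(np.argmin(d))  # first minimum = lowest control index
        if d[j] <= caliper:
            pairs.append((int(ti), int(c_idx[j])))
            avail[j] = False
        if not avail.any():
            break
    return MatchResult(pairs=tuple(pairs), caliper_width=float(caliper),
                       n_matched=len(pairs))


def _z_coef_or(frame: pd.DataFrame, method: str,
               spec: ModelSpec | None = None,
               weights: np.ndarray | None = None,
               robust: bool = False, **diagnostics) -> EstimateResult:
    """exp(treatment coefficient) from a (possibly weighted) logistic fit."""
    y = frame["y"].to_numpy(dtype=float)
    X = spec.design_matrix(frame) if spec is not None \
        else frame[["z"]].astype(float)
    exog = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, exog, family=sm.families.Binomial(),
                   var_weights=weights)
    res = model.fit(cov_type="HC0") if robust else model.fit()
    se = float(np.sqrt(res.cov_params().loc["z", "z"]))
    return EstimateResult.from_log_or(method, float(res.params["z"]), se,
                                      n_used=len(frame), **diagnostics)


def lr_or(frame: pd.DataFrame,
          outcome_spec: ModelSpec = OUTCOME_MISSPEC) -> EstimateResult:
    """Covariate-adjusted logistic regression OR (conditional-OR surrogate
    for the marginal effect), exp of the treatment coefficient."""
    if "z" not in outcome_spec.covariates:
        raise ValueError("outcome model must include the treatment 'z'")
    cc = frame[frame["delta"] == 1]
    fit = fit_logistic(cc, outcome_spec, response="y")
    se = float(np.sqrt(fit.cov_params.loc["z", "z"]))
    return EstimateResult.from_log_or("LR", float(fit.params["z"]), se,
                                      n_used=len(cc))


def ps_covariate_or(frame: pd.DataFrame, ps_fit: PropensityFit,
                    outcome_spec: ModelSpec | None = None) -> EstimateResult:
    """Logistic regression of Y on treatment and the propensity score.

    With ``outcome_spec`` given, the outcome-model covariates are retained
    alongside the score (the form whose operating characteristics track the
    covariate-adjusted LR when the score is weakly informative).
    """
    cols = outcome_spec.covariates if outcome_spec is not None else ("z",)
    if "z" not in cols:
        raise ValueError("outcome model must include the treatment 'z'")
    aug = frame[list(dict.fromkeys(cols)) + ["y"]].copy()
    aug["ps"] = ps_fit.ps
    spec = ModelSpec("outcome", tuple(dict.fromkeys(cols)) + ("ps",))
    fit = fit_logistic(aug, spec, response="y")
    se = float(np.sqrt(fit.cov_params.loc["z", "z"]))
    return EstimateResult.from_log_or("PS Covariate", float(fit.params["z"]),
                                      se, n_used=len(aug))


def ps_matching_or(frame: pd.DataFrame, match: MatchResult,
                   outcome_spec: ModelSpec | None = None) -> EstimateResult:
    """Logistic OR of Y on Z within the matched sample.

    Unconditional (Y ~ Z) by default; with ``outcome_spec`` the outcome-model
    covariates are kept in the matched-sample regression.
    """
    if match.n_matched < 2:
        raise ValueError("need at least 2 matched pairs")
    rows = [i for pair in match.pairs for i in pair]
    sub = frame.iloc[rows]
    tab = pd.crosstab(sub["z"], sub["y"])
    if tab.shape != (2, 2) or (tab.to_numpy() == 0).any():
        raise ValueError("degenerate 2x2 outcome table in matched sample")
    return _z_coef_or(sub, "PS Matching", spec=outcome_spec,
                      n_pairs=match.n_matched, caliper=match.caliper_width)


def iptw_or(frame: pd.DataFrame, ps_fit: PropensityFit,
            truncation: tuple = (0.001, 0.999),
            outcome_spec: ModelSpec | None = None) -> EstimateResult:
    """Inverse-probability-of-treatment weighted OR with sandwich SE.

    Weighted Y ~ Z by default; with ``outcome_spec`` the weighted regression
    keeps the outcome-model covariates.
    """
    lo, hi = truncation
    ps = np.clip(ps_fit.ps, lo, hi)
    z = frame["z"].to_numpy(dtype=float)
    w = z / ps + (1 - z) / (1 - ps)
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite IPTW weight")
    return _z_coef_or(frame, "IPTW", spec=outcome_spec, weights=w,
                      robust=True)


class _BaseOR(BaseEstimator):
    """Shared fit plumbing: complete-case filter and fitted attributes."""

    method: str = "?"

    def _complete_cases(self, data: pd.DataFrame) -> pd.DataFrame:
        if "delta" not in data.columns:
            data = data.assign(delta=1)
        return data[data["delta"] == 1].reset_index(drop=True)

    def _store(self, result: EstimateResult) -> "EstimateResult":
        self.result_ = result
        self.or_ = result.or_hat
        self.se_log_or_ = result.se_log_or
        self.ci_low_ = result.ci_low
        self.ci_high_ = result.ci_high
        self.n_used_ = result.n_used
        return result


class LogisticOR(_BaseOR):
    """Misspecified-formula logistic regression estimator of the OR."""

    method = "LR"

    def __init__(self, outcome_spec: ModelSpec = OUTCOME_MISSPEC):
        self.outcome_spec = outcome_spec

    def fit(self, data: pd.DataFrame, y=None):
        self._store(lr_or(self._complete_cases(data), self.outcome_spec))
        return self


class PSCovariateOR(_BaseOR):
    """Propensity score entered as an additional covariate in the outcome
    model (Y ~ outcome covariates + PS); set ``outcome_spec=None`` for the
    score-only adjustment Y ~ Z + PS."""

    method = "PS Covariate"

    def __init__(self, treatment_spec: ModelSpec = TREATMENT_MISSPEC,
                 outcome_spec: ModelSpec | None = OUTCOME_MISSPEC):
        self.treatment_spec = treatment_spec
        self.outcome_spec = outcome_spec

    def fit(self, data: pd.DataFrame, y=None):
        cc = self._complete_cases(data)
        ps = fit_propensity(cc, self.treatment_spec)
        self.propensity_ = ps
        self._store(ps_covariate_or(cc, ps, self.outcome_spec))
        return self


class PSMatchingOR(_BaseOR):
    """1:1 greedy caliper matching on the logit PS, then a logistic fit of
    the outcome model in the matched sample (``outcome_spec=None`` gives the
    unadjusted matched-sample OR)."""

    method = "PS Matching"

    def __init__(self, treatment_spec: ModelSpec = TREATMENT_MISSPEC,
                 outcome_spec: ModelSpec | None = OUTCOME_MISSPEC,
                 caliper_sd_mult: float = 0.15):
        self.treatment_spec = treatment_spec
        self.outcome_spec = outcome_spec
        self.caliper_sd_mult = caliper_sd_mult

    def fit(self, data: pd.DataFrame, y=None):
        cc = self._complete_cases(data)
        ps = fit_propensity(cc, self.treatment_spec)
        self.propensity_ = ps
        self.match_ = match_nearest(ps, cc["z"].to_numpy(),
                                    self.caliper_sd_mult)
        self._store(ps_matching_or(cc, self.match_, self.outcome_spec))
        return self


class IPTWOR(_BaseOR):
    """Inverse-probability-of-treatment weighting: weighted logistic fit of
    the outcome model with sandwich SE (``outcome_spec=None`` fits the
    weighted Y ~ Z only)."""

    method = "IPTW"

    def __init__(self, treatment_spec: ModelSpec = TREATMENT_MISSPEC,
                 outcome_spec: ModelSpec | None = OUTCOME_MISSPEC,
                 truncation: tuple = (0.001, 0.999)):
        self.treatment_spec = treatment_spec
        self.outcome_spec = outcome_spec
        self.truncation = truncation

    def fit(self, data: pd.DataFrame, y=None):
        cc = self._complete_cases(data)
        ps = fit_propensity(cc, self.treatment_spec)
        self.propensity_ = ps
        self._store(iptw_or(cc, ps, self.truncation, self.outcome_spec))
        return self
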