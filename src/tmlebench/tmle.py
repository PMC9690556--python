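"""Targeted maximum likelihood estimation of the marginal odds ratio.

The estimator targets the counterfactual outcome probabilities
p1 = E[Y(1)], p0 = E[Y(0)] for a binary outcome Y that may be missing
(observation flag Delta), binary treatment Z and covariates W:

1. initial outcome regression Q0(Z, W) = E[Y | Z, W, Delta = 1], fit by a
   super learner on the observed-outcome rows;
2. treatment mechanism g(W) = P(Z = 1 | W), fit on all rows;
3. (IPW mode) missingness mechanism d(Z, W) = P(Delta = 1 | Z, W);
4. fluctuation: logistic regression of Y on the "clever covariate"
   H(Z, W) = [1 / d(Z, W)] * [Z / g(W) - (1 - Z) / (1 - g(W))]
   with offset logit Q0, which tilts the initial fit just enough to solve
   the efficient-influence-function estimating equation;
5. plug-in: p_a = mean over subjects of the updated Q*(a, W), a in {0, 1};
   mOR = odds(p1) / odds(p0); SE from the efficient influence function via
   the delta method, Wald 95% CI on the log-OR scale.

Missing outcomes are handled either by dropping unobserved rows entirely
(``missing_mode="cc"``) or by keeping all rows and inverse-weighting the
clever covariate by the fitted observation probability
(``missing_mode="ipw"``).

The default fluctuation uses one coefficient per treatment arm (two-epsilon
update, as in the reference TMLE software), which solves both arm-specific
score equations exactly; a single shared epsilon on the signed covariate is
available via ``fluctuation="combined"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .base import EstimateResult, ModelSpec, OUTCOME_MISSPEC, TREATMENT_MISSPEC
from .superlearner import SuperLearner

__all__ = ["TMLE", "TmleComponents", "clever_covariate", "tmle_estimate",
           "eif_se"]


@dataclass
class TmleComponents:
    """Nuisance fits and targeting quantities of one TMLE run.

    All arrays are aligned with the rows the estimator retained (all rows in
    IPW mode, observed-outcome rows in CC mode).
    """

    q0: np.ndarray        # initial Q at the observed treatment
    q0_1: np.ndarray      # initial Q at Z forced to 1
    q0_0: np.ndarray      # initial Q at Z forced to 0
    g1: np.ndarray        # P(Z=1 | W)
    d1: np.ndarray        # P(Delta=1 | Z=1, W)  (ones in CC mode)
    d0: np.ndarray        # P(Delta=1 | Z=0, W)
    h: np.ndarray         # signed clever covariate at the observed Z
    epsilon: np.ndarray   # fluctuation coefficient(s)
    q_star_1: np.ndarray  # targeted Q at Z=1
    q_star_0: np.ndarray  # targeted Q at Z=0


def clever_covariate(z, g1, d1, mode: str = "ipw"):
    """Signed clever covariate H(Z, W).

    H = [1/P(Delta=1|Z,W)] * [Z/g - (1-Z)/(1-g)]; in CC mode the leading
    missingness factor is 1.  Probabilities must already be bounded away
    from 0 and 1 (bounding happens upstream).
    """
    z = np.asarray(z, dtype=float)
    g1 = np.asarray(g1, dtype=float)
    d1 = np.asarray(d1, dtype=float)
    if np.any((g1 <= 0) | (g1 >= 1)):
        raise ValueError("treatment probabilities must lie strictly in (0,1)")
    if mode not in ("cc", "ipw"):
        raise ValueError("mode must be 'cc' or 'ipw'")
    h = z / g1 - (1 - z) / (1 - g1)
    if mode == "ipw":
        if np.any((d1 <= 0) | (d1 > 1)):
            raise ValueError("observation probabilities must lie in (0,1]")
        h = h / d1
    out = np.asarray(h, dtype=float)
    return float(out) if out.ndim == 0 else out


def eif_se(q_star_1, q_star_0, q_star_obs, y, z, delta, g1, d1, d0,
           p1: float, p0: float, mode: str = "ipw"):
    """SE of log mOR from the efficient influence function.

    Per-subject influence curves for (p1, p0):

        IC_a = 1{Z=a} * Delta * |H_a| * (Y - Q*(Z,W)) + Q*(a,W) - p_a

    with |H_1| = 1/(g*d(1,W)) and |H_0| = 1/((1-g)*d(0,W)).  The variance of
    log(OR) follows by the delta method with the empirical covariance of
    (IC_1, IC_0).  Returns (se_log_or, ic_matrix).
    """
    n = len(np.asarray(y))
    if n < 2:
        raise ValueError("need at least 2 subjects")
    z = np.asarray(z, dtype=float)
    delta = np.asarray(delta, dtype=float)
    yv = np.nan_to_num(np.asarray(y, dtype=float))
    resid = delta * (yv - np.asarray(q_star_obs))
    ic1 = (z / (np.asarray(g1) * np.asarray(d1))) * resid + q_star_1 - p1
    ic0 = (((1 - z) / ((1 - np.asarray(g1)) * np.asarray(d0))) * resid
           + q_star_0 - p0)
    ic = np.column_stack([ic1, ic0])
    cov = np.cov(ic, rowvar=False)
    grad = np.array([1.0 / (p1 * (1 - p1)), -1.0 / (p0 * (1 - p0))])
    var_log_or = float(grad @ cov @ grad) / n
    return float(np.sqrt(max(var_log_or, 0.0))), ic


class TMLE(BaseEstimator):
    """Missingness-aware TMLE of the marginal odds ratio.

    Parameters
    ----------
    q_spec, g_spec : ModelSpec
        Covariate sets of the outcome and treatment working models (the
        benchmark defaults are the deliberately misspecified sets
        {z, w3, w4} and {w2, w6}).
    d_covariates : tuple or None
        Covariates of the missingness model P(Delta=1 | Z, W); default is
        the treatment plus the outcome-model covariates.
    library : {"glm", "tmle1", "tmle2"} or explicit learner list
        Super-learner library used for all three nuisance fits.
    missing_mode : {"cc", "ipw"}
    g_bounds, q_bounds : (low, high)
        Truncation of the fitted treatment/missingness probabilities and of
        the initial outcome regression.
    fluctuation : {"per_arm", "combined", "none"}
        Two-epsilon update (default), single shared epsilon on the signed
        clever covariate, or no update (plug-in G-computation from Q0).
    folds, seed : super-learner controls.

    Fitted attributes: ``or_``, ``se_log_or_``, ``ci_low_``, ``ci_high_``,
    ``epsilon_``, ``components_``, ``p1_``, ``p0_``, ``n_used_``,
    ``result_``.
    """

    def __init__(self, q_spec: ModelSpec = OUTCOME_MISSPEC,
                 g_spec: ModelSpec = TREATMENT_MISSPEC,
                 d_covariates: tuple | None = None,
                 library="tmle1", missing_mode: str = "ipw",
                 g_bounds: tuple = (0.025, 0.975),
                 q_bounds: tuple = (0.0005, 0.9995),
                 fluctuation: str = "per_arm",
                 folds: int = 10, seed: int | None = None):
        self.q_spec = q_spec
        self.g_spec = g_spec
        self.d_covariates = d_covariates
        self.library = library
        self.missing_mode = missing_mode
        self.g_bounds = g_bounds
        self.q_bounds = q_bounds
        self.fluctuation = fluctuation
        self.folds = folds
        self.seed = seed

    @property
    def method(self) -> str:
        lib = self.library if isinstance(self.library, str) else "custom"
        name = {"tmle1": "TMLE1", "tmle2": "TMLE2", "glm": "TMLE-GLM"}.get(
            lib, f"TMLE[{lib}]")
        return f"{name} ({self.missing_mode.upper()})"

    # -- internals ---------------------------------------------------------
    def _check(self):
        for lo, hi in (self.g_bounds, self.q_bounds):
            if not 0 < lo < hi < 1:
                raise ValueError("bounds must satisfy 0 < lo < hi < 1")
        if self.missing_mode not in ("cc", "ipw"):
            raise ValueError("missing_mode must be 'cc' or 'ipw'")
        if self.fluctuation not in ("per_arm", "combined", "none"):
            raise ValueError("fluctuation must be per_arm/combined/none")

    def _sl(self, seed_offset: int) -> SuperLearner:
        seed = None if self.seed is None else \
            int(np.random.SeedSequence(self.seed, spawn_key=(seed_offset,))
                .generate_state(1)[0] & 0x7FFFFFFF)
        return SuperLearner(library=self.library, folds=self.folds, seed=seed)

    # -- estimator API -----------------------------------------------------
    def fit(self, data: pd.DataFrame, y=None):
        self._check()
        df = data.copy()
        if "delta" not in df.columns:
            df["delta"] = 1
        if self.missing_mode == "cc":
            df = df[df["delta"] == 1]
        df = df.reset_index(drop=True)
        obs = df["delta"].to_numpy() == 1
        if not obs.any():
            raise ValueError("no observed outcomes")
        n = len(df)
        z = df["z"].to_numpy(dtype=float)
        yv = df["y"].to_numpy(dtype=float)
        q_lo, q_hi = self.q_bounds
        g_lo, g_hi = self.g_bounds

        # (1) initial outcome regression on observed-outcome rows
        q_cols = list(self.q_spec.covariates)
        if "z" not in q_cols:
            q_cols = ["z"] + q_cols
        sl_q = self._sl(1).fit(df.loc[obs, q_cols], yv[obs])
        q0_1 = np.clip(sl_q.predict_proba1(df[q_cols].assign(z=1.0)), q_lo, q_hi)
        q0_0 = np.clip(sl_q.predict_proba1(df[q_cols].assign(z=0.0)), q_lo, q_hi)
        q0 = np.where(z == 1, q0_1, q0_0)

        # (2) treatment mechanism on all retained rows
        sl_g = self._sl(2).fit(df[list(self.g_spec.covariates)], z)
        g1 = np.clip(sl_g.predict_proba1(df[list(self.g_spec.covariates)]),
                     g_lo, g_hi)

        # (3) missingness mechanism (IPW mode only)
        if self.missing_mode == "ipw" and not obs.all():
            d_cols = list(self.d_covariates) if self.d_covariates is not None \
                else q_cols
            if "z" not in d_cols:
                d_cols = ["z"] + d_cols
            sl_d = self._sl(3).fit(df[d_cols], obs.astype(float))
            d1 = np.clip(sl_d.predict_proba1(df[d_cols].assign(z=1.0)),
                         g_lo, g_hi)
            d0 = np.clip(sl_d.predict_proba1(df[d_cols].assign(z=0.0)),
                         g_lo, g_hi)
        else:
            d1 = np.ones(n)
            d0 = np.ones(n)

        # (4) fluctuation among observed-outcome rows, offset logit Q0
        mode = "ipw" if self.missing_mode == "ipw" else "cc"
        d_obs = np.where(z == 1, d1, d0)
        h_obs = clever_covariate(z, g1, d_obs, mode=mode)
        h1 = 1.0 / (g1 * d1)            # |H| at z=1
        h0 = 1.0 / ((1 - g1) * d0)      # |H| at z=0
        offset = np.log(q0[obs] / (1 - q0[obs]))
        if self.fluctuation == "none":
            eps = np.zeros(1)
            qs1, qs0 = q0_1, q0_0
        elif self.fluctuation == "combined":
            eps = self._fluctuate(yv[obs], h_obs[obs][:, None], offset)
            qs1 = _expit_update(q0_1, eps[0] * h1)
            qs0 = _expit_update(q0_0, eps[0] * (-h0))
        else:  # per-arm
            C = np.column_stack([(z * h1)[obs], ((1 - z) * h0)[obs]])
            eps = self._fluctuate(yv[obs], C, offset)
            qs1 = _expit_update(q0_1, eps[0] * h1)
            qs0 = _expit_update(q0_0, eps[1] * h0)

        # (5) plug-in means and EIF-based inference
        p1, p0 = float(qs1.mean()), float(qs0.mean())
        if not (0 < p0 < 1 and 0 < p1 < 1):
            raise ValueError("degenerate counterfactual mean after targeting")
        log_or = np.log(p1 / (1 - p1)) - np.log(p0 / (1 - p0))
        q_star_obs = np.where(z == 1, qs1, qs0)
        se, ic = eif_se(qs1, qs0, q_star_obs, yv, z, obs.astype(float),
                        g1, d1, d0, p1, p0, mode=mode)

        self.components_ = TmleComponents(
            q0=q0, q0_1=q0_1, q0_0=q0_0, g1=g1, d1=d1, d0=d0, h=h_obs,
            epsilon=eps, q_star_1=qs1, q_star_0=qs0)
        self.influence_curves_ = ic
        self.epsilon_ = eps
        self.p1_, self.p0_ = p1, p0
        self.n_used_ = n
        self.result_ = EstimateResult.from_log_or(
            self.method, float(log_or), se, n_used=n,
            epsilon=[float(e) for e in eps], p1=p1, p0=p0,
            sl_weights_q=list(map(float, getattr(sl_q, "weights_", []))),
            sl_weights_g=list(map(float, getattr(sl_g, "weights_", []))))
        self.or_ = self.result_.or_hat
        self.se_log_or_ = se
        self.ci_low_ = self.result_.ci_low
        self.ci_high_ = self.result_.ci_high
        return self

    @staticmethod
    def _fluctuate(y_obs, C, offset) -> np.ndarray:
        """One-step logistic fluctuation: no intercept, fixed offset."""
        res = sm.GLM(y_obs, C, family=sm.families.Binomial(),
                     offset=offset).fit(maxiter=200)
        if not getattr(res, "converged", True):
            raise RuntimeError("fluctuation regression did not converge")
        return np.asarray(res.params, dtype=float)


def _expit_update(q, shift):
    return 1.0 / (1.0 + np.exp(-(np.log(q / (1 - q)) + shift)))


def tmle_estimate(frame: pd.DataFrame,
                  q_spec: ModelSpec = OUTCOME_MISSPEC,
                  g_spec: ModelSpec = TREATMENT_MISSPEC,
                  d_covariates: tuple | None = None,
                  **options) -> tuple[EstimateResult, TmleComponents]:
    """Functional wrapper: returns (EstimateResult, TmleComponents)."""
    est = TMLE(q_spec=q_spec, g_spec=g_spec, d_covariates=d_covariates,
               **options).fit(frame)
    return est.result_, est.components_
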