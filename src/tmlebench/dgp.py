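"""Synthetic cohort generator for the marginal-treatment-effect benchmark.

The generator draws subjects from a structural causal model with six baseline
covariates (sex, age, BMI, LDL cholesterol, insulin use, macroangiopathy
analogues), a binary treatment assigned by a covariate-dependent logistic
mechanism, and a binary outcome.  Both potential outcomes Y0 (treatment forced
to 0) and Y1 (treatment forced to 1) are drawn with a shared exogenous uniform
per subject, so consistency Y = Z*Y1 + (1-Z)*Y0 holds row by row and the
counterfactual coupling is monotone.

The true marginal odds ratio of the default configuration is obtained by
large-sample counterfactual Monte Carlo (`true_marginal_or`).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "DgpConfig",
    "TrueEffect",
    "COVARIATES",
    "COHORT_COLUMNS",
    "plogis",
    "generate_cohort",
    "true_marginal_or",
]

COVARIATES = ("w1", "w2", "w3", "w4", "w5", "w6")
COHORT_COLUMNS = COVARIATES + ("z", "y", "delta", "y0", "y1")

# fixed topological order of the child random streams; appending new variables
# at the end never perturbs earlier draws for a given root seed
_STREAMS = ("w1", "w2", "w3", "w4", "w5", "w6", "z", "y")


def plogis(x):
    """Inverse logit 1 / (1 + exp(-x)), elementwise.

    Raises ``ValueError`` on non-finite input.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("plogis requires finite input")
    out = expit(x)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DgpConfig:
    """Coefficients of the eight generating equations, sample size and seed.

    Defaults reproduce the benchmark data-generating process:

    - W1 ~ Bernoulli(0.6)
    - W2 ~ N(60, 8);  W3 ~ N(35, 6)
    - W4 ~ N(90 if W1=1 else 97, 30)
    - W5 ~ Bernoulli(plogis(-2 + 0.05 W2))
    - W6 ~ Bernoulli(plogis(-12 + 0.50 W3 - W1))
    - Z  ~ Bernoulli(plogis(-2 + 0.05 W3 - 0.20 W5 + 0.10 W6))
    - Y  ~ Bernoulli(plogis(-3 + Z - 0.05 W2 + 0.05 W4 - 0.80 W1 - 0.20 W1*W2))

    Every coefficient can be overridden (property tests rely on this).
    """

    w1_p: float = 0.6
    w2_mean: float = 60.0
    w2_sd: float = 8.0
    w3_mean: float = 35.0
    w3_sd: float = 6.0
    w4_mean_w1: float = 90.0
    w4_mean_w0: float = 97.0
    w4_sd: float = 30.0
    # (intercept, w2)
    w5_coef: tuple[float, float] = (-2.0, 0.05)
    # (intercept, w3, w1)
    w6_coef: tuple[float, float, float] = (-12.0, 0.50, -1.0)
    # (intercept, w3, w5, w6)
    z_coef: tuple[float, float, float, float] = (-2.0, 0.05, -0.20, 0.10)
    # (intercept, z, w2, w4, w1, w1*w2)
    y_coef: tuple[float, float, float, float, float, float] = (
        -3.0, 1.0, -0.05, 0.05, -0.80, -0.20)
    n: int = 1000
    seed: int = 0

    def replace(self, **changes) -> "DgpConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        """Config-file form: one key per generated variable."""
        return {
            "w1": [self.w1_p],
            "w2": [self.w2_mean, self.w2_sd],
            "w3": [self.w3_mean, self.w3_sd],
            "w4": [self.w4_mean_w1, self.w4_mean_w0, self.w4_sd],
            "w5": list(self.w5_coef),
            "w6": list(self.w6_coef),
            "z": list(self.z_coef),
            "y": list(self.y_coef),
            "n": self.n,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DgpConfig":
        kw = {}
        if "w1" in d:
            kw["w1_p"] = d["w1"][0]
        if "w2" in d:
            kw["w2_mean"], kw["w2_sd"] = d["w2"]
        if "w3" in d:
            kw["w3_mean"], kw["w3_sd"] = d["w3"]
        if "w4" in d:
            kw["w4_mean_w1"], kw["w4_mean_w0"], kw["w4_sd"] = d["w4"]
        for key, name in (("w5", "w5_coef"), ("w6", "w6_coef"),
                          ("z", "z_coef"), ("y", "y_coef")):
            if key in d:
                kw[name] = tuple(d[key])
        for key in ("n", "seed"):
            if key in d:
                kw[key] = int(d[key])
        return cls(**kw)


@dataclass(frozen=True)
class TrueEffect:
    """Counterfactual Monte-Carlo truth: mOR = odds(p1) / odds(p0)."""

    m_or: float
    p1: float
    p0: float
    n_mc: int


def _y_linpred(cfg: DgpConfig, z, w1, w2, w4):
    b0, bz, b2, b4, b1, b12 = cfg.y_coef
    return b0 + bz * z + b2 * w2 + b4 * w4 + b1 * w1 + b12 * w1 * w2


def generate_cohort(cfg: DgpConfig) -> pd.DataFrame:
    """Draw a cohort of ``cfg.n`` subjects from the structural model.

    Returns a DataFrame with columns w1..w6, z, y, delta, y0, y1.  ``delta``
    is initialised to 1 (outcome observed); the missingness module rewrites
    it.  Potential outcomes share one uniform exogenous draw per subject.
    """
    if cfg.n < 0:
        raise ValueError(f"n must be >= 0, got {cfg.n}")
    root = np.random.SeedSequence(cfg.seed)
    rngs = {name: np.random.default_rng(child)
            for name, child in zip(_STREAMS, root.spawn(len(_STREAMS)))}
    n = cfg.n

    w1 = (rngs["w1"].random(n) < cfg.w1_p).astype(np.int8)
    w2 = rngs["w2"].normal(cfg.w2_mean, cfg.w2_sd, n)
    w3 = rngs["w3"].normal(cfg.w3_mean, cfg.w3_sd, n)
    w4 = rngs["w4"].normal(np.where(w1 == 1, cfg.w4_mean_w1, cfg.w4_mean_w0),
                           cfg.w4_sd)
    a0, a2 = cfg.w5_coef
    w5 = (rngs["w5"].random(n) < plogis(a0 + a2 * w2)).astype(np.int8)
    b0, b3, b1 = cfg.w6_coef
    w6 = (rngs["w6"].random(n) < plogis(b0 + b3 * w3 + b1 * w1)).astype(np.int8)
    c0, c3, c5, c6 = cfg.z_coef
    z = (rngs["z"].random(n)
         < plogis(c0 + c3 * w3 + c5 * w5 + c6 * w6)).astype(np.int8)

    u = rngs["y"].random(n)  # shared exogenous noise for both arms
    p1 = plogis(_y_linpred(cfg, 1.0, w1, w2, w4)) if n else np.empty(0)
    p0 = plogis(_y_linpred(cfg, 0.0, w1, w2, w4)) if n else np.empty(0)
    y1 = (u < p1).astype(np.int8)
    y0 = (u < p0).astype(np.int8)
    y = np.where(z == 1, y1, y0).astype(np.int8)

    return pd.DataFrame({
        "w1": w1, "w2": w2, "w3": w3, "w4": w4, "w5": w5, "w6": w6,
        "z": z, "y": y.astype(float), "delta": np.ones(n, dtype=np.int8),
        "y0": y0, "y1": y1,
    })


def true_marginal_or(cfg: DgpConfig, n_mc: int = 5_000_000,
                     chunk: int = 1_000_000) -> TrueEffect:
    """True marginal OR by counterfactual Monte Carlo.

    Generates ``n_mc`` subjects in chunks, takes p1 = mean(Y1), p0 = mean(Y0)
    over the counterfactual pairs, and returns odds(p1)/odds(p0).
    """
    if n_mc < 10**5:
        raise ValueError("n_mc must be at least 1e5 for a stable truth")
    root = np.random.SeedSequence(cfg.seed, spawn_key=(907,))
    sum1 = sum0 = 0
    done = 0
    children = root.spawn((n_mc + chunk - 1) // chunk)
    for child in children:
        m = min(chunk, n_mc - done)
        sub = generate_cohort(cfg.replace(
            n=m, seed=int(child.generate_state(1)[0] & 0x7FFFFFFF)))
        sum1 += int(sub["y1"].sum())
        sum0 += int(sub["y0"].sum())
        done += m
    p1, p0 = sum1 / n_mc, sum0 / n_mc
    if p1 in (0.0, 1.0) or p0 in (0.0, 1.0):
        raise ValueError("degenerate counterfactual outcome probability")
    m_or = (p1 / (1 - p1)) / (p0 / (1 - p0))
    return TrueEffect(m_or=m_or, p1=p1, p0=p0, n_mc=n_mc)
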