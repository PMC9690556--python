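"""Outcome amputation: impose MNAR / MAR / MCAR missingness on the outcome.

MNAR: the probability that Y is missing depends on Y itself — P(miss | Y=1)
is fixed (default 0.70) and P(miss | Y=0) is solved so the overall rate hits
the target.  MAR: each subject gets an equal-weighted sum score of its
standardized covariates (outcome excluded) and the missingness probability is
a right-tailed logistic function of the score, location-shifted so the
expected overall rate matches the target.  MCAR is provided as a convenience.

Amputation masks ``y`` (set to NaN where delta=0); the potential-outcome
columns keep the simulation truth for the harness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .dgp import COVARIATES

__all__ = ["MissingnessSpec", "solve_p0", "ampute", "ampute_mnar",
           "ampute_mar", "ampute_mcar"]

_MECHANISMS = ("MNAR", "MAR", "MCAR")


@dataclass(frozen=True)
class MissingnessSpec:
    """Mechanism, overall target rate and mechanism-specific knobs."""

    mechanism: str = "MNAR"
    target_rate: float = 0.20
    p_miss_given_y1: float = 0.70          # MNAR only
    score_weights: tuple | None = None     # MAR only; None = equal weights
    seed: int = 0

    def __post_init__(self):
        if self.mechanism not in _MECHANISMS:
            raise ValueError(f"mechanism must be one of {_MECHANISMS}")
        if not 0.0 <= self.target_rate < 1.0:
            raise ValueError("target_rate must be in [0, 1)")
        if not 0.0 <= self.p_miss_given_y1 <= 1.0:
            raise ValueError("p_miss_given_y1 must be in [0, 1]")


def solve_p0(target_rate: float, p1_miss: float, p_y1: float) -> float:
    """P(miss | Y=0) from the overall-rate constraint.

    Solves ``p1_miss * p_y1 + p0 * (1 - p_y1) = target_rate`` for p0,
    clamping to [0, 1] with a warning when the constraint is infeasible.
    """
    if not 0.0 <= target_rate < 1.0:
        raise ValueError("target_rate must be in [0, 1)")
    if not 0.0 < p_y1 < 1.0:
        raise ValueError("p_y1 must be strictly between 0 and 1")
    p0 = (target_rate - p1_miss * p_y1) / (1.0 - p_y1)
    if p0 < 0.0 or p0 > 1.0:
        warnings.warn(
            f"overall missingness target {target_rate} infeasible with "
            f"P(miss|Y=1)={p1_miss} and P(Y=1)={p_y1:.3f}; clamping "
            f"P(miss|Y=0)={p0:.3f} to [0, 1]", RuntimeWarning)
        p0 = min(max(p0, 0.0), 1.0)
    return p0


def _check_frame(frame: pd.DataFrame) -> None:
    if len(frame) == 0:
        raise ValueError("cannot ampute an empty cohort")
    if frame["y"].isna().any():
        raise ValueError("cohort outcome must be fully observed before amputation")


def _apply_mask(frame: pd.DataFrame, missing: np.ndarray) -> pd.DataFrame:
    out = frame.copy()
    out["delta"] = (~missing).astype(np.int8)
    out.loc[missing, "y"] = np.nan
    return out


def ampute_mnar(frame: pd.DataFrame, spec: MissingnessSpec) -> pd.DataFrame:
    """Missing-not-at-random: P(delta=0) depends on the outcome value only."""
    _check_frame(frame)
    p_y1 = float(frame["y"].mean())
    p_miss_y0 = solve_p0(spec.target_rate, spec.p_miss_given_y1, p_y1)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
    p_miss = np.where(frame["y"].to_numpy() == 1.0,
                      spec.p_miss_given_y1, p_miss_y0)
    return _apply_mask(frame, rng.random(len(frame)) < p_miss)


def ampute_mar(frame: pd.DataFrame, spec: MissingnessSpec) -> pd.DataFrame:
    """Missing-at-random via an equal-weighted covariate sum score.

    Covariates (W1..W6 and Z, never the outcome) are standardized, combined
    with equal weights (or ``spec.score_weights``), and the standardized score
    enters a right-tailed logistic: P(delta=0) = expit(score - shift), with
    the shift solved so the expected overall rate equals the target.
    """
    _check_frame(frame)
    cols = list(COVARIATES) + ["z"]
    X = frame[cols].to_numpy(dtype=float)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        # constant covariates carry no ordering information; drop them
        keep = sd > 0
        X, sd = X[:, keep], sd[keep]
        if X.shape[1] == 0:
            raise ValueError("all covariates constant: MAR score undefined")
    Xs = (X - X.mean(axis=0)) / sd
    w = (np.ones(Xs.shape[1]) if spec.score_weights is None
         else np.asarray(spec.score_weights, dtype=float)[: Xs.shape[1]])
    score = Xs @ w
    if score.std() == 0:
        raise ValueError("zero-variance MAR score")
    score = (score - score.mean()) / score.std()

    if spec.target_rate == 0.0:
        missing = np.zeros(len(frame), dtype=bool)
        return _apply_mask(frame, missing)
    shift = brentq(lambda s: expit(score - s).mean() - spec.target_rate,
                   -50.0, 50.0)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2,)))
    return _apply_mask(frame, rng.random(len(frame)) < expit(score - shift))


def ampute_mcar(frame: pd.DataFrame, spec: MissingnessSpec) -> pd.DataFrame:
    """Missing completely at random at the target rate."""
    _check_frame(frame)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(3,)))
    return _apply_mask(frame, rng.random(len(frame)) < spec.target_rate)


def ampute(frame: pd.DataFrame, spec: MissingnessSpec) -> pd.DataFrame:
    """Dispatch on ``spec.mechanism``."""
    fn = {"MNAR": ampute_mnar, "MAR": ampute_mar, "MCAR": ampute_mcar}
    return fn[spec.mechanism](frame, spec)
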