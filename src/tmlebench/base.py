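"""Shared model-specification and result containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ModelSpec", "EstimateResult", "OUTCOME_MISSPEC",
           "TREATMENT_MISSPEC", "Z_CRIT"]

Z_CRIT = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ModelSpec:
    """A named working-model formula: role, covariate set, interaction pairs.

    ``design_matrix`` builds the matrix of main terms followed by the
    requested pairwise interaction columns (named ``"a:b"``), without an
    intercept (fitters add their own).
    """

    role: str = "outcome"
    covariates: tuple = ()
    interactions: tuple = ()

    def __post_init__(self):
        if self.role not in ("outcome", "treatment", "missingness"):
            raise ValueError("role must be outcome/treatment/missingness")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "interactions",
                           tuple(tuple(p) for p in self.interactions))

    @property
    def term_names(self) -> list:
        return list(self.covariates) + [f"{a}:{b}" for a, b in self.interactions]

    def design_matrix(self, frame: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.covariates if c not in frame.columns]
        if missing:
            raise KeyError(f"columns absent from frame: {missing}")
        X = frame[list(self.covariates)].astype(float).copy()
        for a, b in self.interactions:
            X[f"{a}:{b}"] = frame[a].astype(float) * frame[b].astype(float)
        return X


# misspecified working models of the simulation study: the outcome model
# swaps W3 in for the true drivers W1, W2, W1*W2; the treatment model swaps
# W2 in for the true drivers W3, W5
OUTCOME_MISSPEC = ModelSpec("outcome", ("z", "w3", "w4"))
TREATMENT_MISSPEC = ModelSpec("treatment", ("w2", "w6"))


@dataclass(frozen=True)
class EstimateResult:
    """One method's marginal-OR estimate with Wald 95% CI on the log scale."""

    method: str
    or_hat: float
    se_log_or: float
    ci_low: float
    ci_high: float
    n_used: int
    diagnostics: dict = field(default_factory=dict)

    @classmethod
    def from_log_or(cls, method: str, log_or: float, se_log_or: float,
                    n_used: int, **diagnostics) -> "EstimateResult":
        if not np.isfinite(log_or) or se_log_or < 0:
            raise ValueError("invalid log-OR or SE")
        half = Z_CRIT * se_log_or
        return cls(method=method, or_hat=float(np.exp(log_or)),
                   se_log_or=float(se_log_or),
                   ci_low=float(np.exp(log_or - half)),
                   ci_high=float(np.exp(log_or + half)),
                   n_used=int(n_used), diagnostics=diagnostics)
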