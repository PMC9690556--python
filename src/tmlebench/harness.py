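"""Monte-Carlo benchmarking harness: scenarios, summaries, pooling, tables.

A scenario fixes the cohort size, missingness mechanism and overall
missingness rate; ``run_scenario`` repeats generate -> ampute -> estimate for
every requested method, then reports the mean OR, bias (mean minus truth),
empirical SE (SD of the estimates across replicates) and 95% nominal
coverage per method.  Four presets mirror the benchmark grid: 20%/40% MNAR
outcome missingness crossed with n = 1000 / 5000.

``rubins_pool`` implements Rubin's rules (with Barnard-Rubin degrees of
freedom) for pooling estimates across multiply-imputed datasets; it is a
utility for analyses of real cohorts with imputed covariates and is not used
by the simulation itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dgp
from .base import EstimateResult
from .estimators import IPTWOR, LogisticOR, PSCovariateOR, PSMatchingOR
from .missingness import MissingnessSpec, ampute
from .tmle import TMLE

logger = logging.getLogger(__name__)

__all__ = ["Scenario", "ScenarioSummary", "SCENARIO_PRESETS", "METHOD_ORDER",
           "make_estimator", "run_scenario", "rubins_pool", "report_table",
           "summary_to_frame", "frame_to_summary"]

# column order of the benchmark's results table
METHOD_ORDER = ("LR", "PS Matching", "PS Covariate", "IPTW",
                "TMLE1 (CC)", "TMLE2 (CC)", "TMLE1 (IPW)", "TMLE2 (IPW)")


def make_estimator(name: str, folds: int = 10, seed: int | None = None):
    """Estimator factory for the benchmark method labels."""
    simple = {"LR": LogisticOR, "PS Matching": PSMatchingOR,
              "PS Covariate": PSCovariateOR, "IPTW": IPTWOR}
    if name in simple:
        return simple[name]()
    parts = name.replace(")", "").split(" (")
    if len(parts) == 2 and parts[0] in ("TMLE1", "TMLE2", "TMLE-GLM"):
        lib = {"TMLE1": "tmle1", "TMLE2": "tmle2", "TMLE-GLM": "glm"}[parts[0]]
        return TMLE(library=lib, missing_mode=parts[1].lower(),
                    folds=folds, seed=seed)
    raise ValueError(f"unknown method label {name!r}")


@dataclass(frozen=True)
class Scenario:
    """One simulation condition of the benchmark grid."""

    n: int = 1000
    mechanism: str = "MNAR"
    target_rate: float = 0.20
    reps: int = 1000
    methods: tuple = ("LR", "TMLE1 (IPW)")
    seed: int = 0
    sl_folds: int = 5   # desk-scale CV default for the TMLE super learner
    name: str = ""

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


SCENARIO_PRESETS = {
    1: Scenario(n=1000, target_rate=0.20, name="Scenario 1: 20% MNAR, n=1000"),
    2: Scenario(n=1000, target_rate=0.40, name="Scenario 2: 40% MNAR, n=1000"),
    3: Scenario(n=5000, target_rate=0.20, name="Scenario 3: 20% MNAR, n=5000"),
    4: Scenario(n=5000, target_rate=0.40, name="Scenario 4: 40% MNAR, n=5000"),
}


@dataclass
class ScenarioSummary:
    """Per-method Monte-Carlo operating characteristics."""

    scenario: Scenario
    true_or: float
    table: pd.DataFrame          # index: method; columns: mean_or, bias, ...
    replicates: pd.DataFrame     # one row per replicate x method
    n_failed: dict = field(default_factory=dict)


def _replicate_seeds(seed: int, rep: int) -> tuple[int, int]:
    s = np.random.SeedSequence(seed, spawn_key=(rep,)).generate_state(2)
    return int(s[0] & 0x7FFFFFFF), int(s[1] & 0x7FFFFFFF)


def run_scenario(sc: Scenario, dgp_config: dgp.DgpConfig | None = None,
                 true_or: float | None = None,
                 n_mc_truth: int = 2_000_000) -> ScenarioSummary:
    """Run the Monte-Carlo loop and summarise per-method performance.

    Per replicate: generate a cohort, ampute the outcome, run every method
    (complete-case methods see the masked frame; TMLE follows its own
    missing-outcome mode), and record the OR and CI.  Replicates where a
    method fails are excluded from that method's summary; more than 5%
    failures for any method aborts the run.
    """
    cfg = dgp_config if dgp_config is not None else dgp.DgpConfig()
    if true_or is None:
        true_or = dgp.true_marginal_or(cfg, n_mc=n_mc_truth).m_or

    rows = []
    failures = {m: 0 for m in sc.methods}
    for rep in range(sc.reps):
        seed_dgp, seed_miss = _replicate_seeds(sc.seed, rep)
        frame = dgp.generate_cohort(cfg.replace(n=sc.n, seed=seed_dgp))
        if sc.target_rate > 0:
            frame = ampute(frame, MissingnessSpec(
                mechanism=sc.mechanism, target_rate=sc.target_rate,
                seed=seed_miss))
        for m in sc.methods:
            est = make_estimator(m, folds=sc.sl_folds, seed=seed_miss)
            try:
                res: EstimateResult = est.fit(frame).result_
            except Exception as exc:
                failures[m] += 1
                logger.warning("replicate %d, method %s failed: %s",
                               rep, m, exc)
                continue
            rows.append({"rep": rep, "method": m, "or_hat": res.or_hat,
                         "se_log_or": res.se_log_or, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "n_used": res.n_used})
    for m, k in failures.items():
        if k > 0.05 * sc.reps:
            raise RuntimeError(
                f"method {m!r} failed in {k}/{sc.reps} replicates; "
                "configuration looks broken")

    reps_df = pd.DataFrame(rows)
    summary = {}
    for m in sc.methods:
        sub = reps_df[reps_df["method"] == m]
        ors = sub["or_hat"].to_numpy()
        mean_or = float(ors.mean())
        summary[m] = {
            "mean_or": mean_or,
            "bias": mean_or - true_or,
            "se_emp": float(ors.std(ddof=1)) if len(ors) > 1 else np.nan,
            "coverage_pct": float(100.0 * np.mean(
                (sub["ci_low"] <= true_or) & (true_or <= sub["ci_high"]))),
            "mean_se_model": float(sub["se_log_or"].mean()),
            "reps_completed": int(len(sub)),
        }
    table = pd.DataFrame(summary).T
    table.index.name = "method"
    return ScenarioSummary(scenario=sc, true_or=float(true_or), table=table,
                           replicates=reps_df, n_failed=failures)


# -- Rubin's rules ---------------------------------------------------------

@dataclass(frozen=True)
class PooledResult:
    estimate: float
    se: float
    df: float
    within: float
    between: float
    total_var: float


def rubins_pool(estimates, variances, df_complete: float = np.inf
                ) -> PooledResult:
    """Pool point estimates and variances across imputations (Rubin's rules).

    Total variance T = W + (1 + 1/m) B, where W is the mean within-imputation
    variance and B the between-imputation variance; degrees of freedom follow
    Barnard-Rubin when ``df_complete`` is finite, else the classical
    (m-1)(1 + W/((1+1/m)B))^2.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape:
        raise ValueError("estimates and variances must have equal length")
    m = q.size
    if m == 0:
        raise ValueError("nothing to pool")
    if m == 1:
        warnings.warn("single estimate: pooling is a passthrough",
                      RuntimeWarning)
        return PooledResult(float(q[0]), float(np.sqrt(u[0])), np.inf,
                            float(u[0]), 0.0, float(u[0]))
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t = w + (1 + 1 / m) * b
    if b == 0:
        nu = np.inf
    else:
        with np.errstate(divide="ignore", over="ignore"):
            r = np.divide((1 + 1 / m) * b, w) if w > 0 else np.inf
            nu_old = float((m - 1) * np.square(1.0 + np.divide(1.0, r))) \
                if np.isfinite(r) else float(m - 1)
        if np.isfinite(df_complete):
            lam = (1 + 1 / m) * b / t
            nu_obs = (df_complete + 1) / (df_complete + 3) * \
                df_complete * (1 - lam)
            nu = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
        else:
            nu = nu_old
    return PooledResult(qbar, float(np.sqrt(t)), float(nu), w, b, float(t))


# -- table rendering -------------------------------------------------------

_ROWS = (("OR", "mean_or"), ("Bias", "bias"), ("SE", "se_emp"),
         ("95% NCI", "coverage_pct"))


def _fmt(label: str, v: float) -> str:
    if np.isnan(v):
        return "NA"
    if label == "95% NCI":
        return f"{v:.1f}"
    if label == "Bias" and abs(v) < 0.01:
        return f"{v:.3f}"
    return f"{v:.2f}"


def report_table(summaries) -> str:
    """Human-readable results table (rows OR/Bias/SE/95% NCI per scenario)."""
    if not summaries:
        raise ValueError("need at least one summary")
    lines = []
    methods = [m for m in METHOD_ORDER
               if any(m in s.table.index for s in summaries)]
    methods += [m for s in summaries for m in s.table.index
                if m not in methods]
    header = "\t".join([""] + methods)
    lines.append(header)
    for s in summaries:
        name = s.scenario.name or (
            f"{s.scenario.target_rate:.0%} {s.scenario.mechanism}, "
            f"n = {s.scenario.n}")
        lines.append(name)
        for label, col in _ROWS:
            vals = [_fmt(label, float(s.table.loc[m, col]))
                    if m in s.table.index else ""
                    for m in methods]
            lines.append("\t".join([label] + vals))
    return "\n".join(lines)


def summary_to_frame(summary: ScenarioSummary) -> pd.DataFrame:
    """Full-precision delimited form of a summary (round-trippable)."""
    out = summary.table.copy()
    out.insert(0, "scenario", summary.scenario.name)
    out.insert(1, "true_or", summary.true_or)
    return out.reset_index()


def frame_to_summary(frame: pd.DataFrame, scenario: Scenario | None = None
                     ) -> ScenarioSummary:
    """Inverse of :func:`summary_to_frame` (replicate detail not recovered)."""
    table = frame.set_index("method").drop(columns=["scenario", "true_or"])
    return ScenarioSummary(
        scenario=scenario or Scenario(name=str(frame["scenario"].iloc[0])),
        true_or=float(frame["true_or"].iloc[0]),
        table=table, replicates=pd.DataFrame())
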