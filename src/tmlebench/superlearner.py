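"""Cross-validated stacking (super learner) for binary responses.

A configurable library of candidate learners is fit V-fold; out-of-fold
probability predictions enter a non-negative least-squares meta-regression
whose solution, normalized to the simplex, gives the ensemble weights.  The
canonical result is that the ensemble performs asymptotically as well as the
best single candidate (the oracle selector).

Candidate families
------------------
``glm_main``                main-terms logistic regression
``glm_step``                bidirectional AIC stepwise over main terms
``glm_interactions``        main terms + all pairwise products
``glm_step_interactions``   stepwise over main terms + pairwise products
``gam``                     logistic additive model, B-spline smooths on
                            continuous covariates (linear in binaries)
``random_forest``           random forest (100 trees, leaf size 5)
``tree``                    single CART tree with cost-complexity pruning

Two presets mirror the benchmark's TMLE variants: ``"tmle1"`` (the three GLM
learners) and ``"tmle2"`` (all seven families); ``"glm"`` is main-terms only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

__all__ = ["LearnerSpec", "SuperLearner", "sl_fit", "sl_predict",
           "TMLE1_LIBRARY", "TMLE2_LIBRARY", "GLM_LIBRARY"]

_FAMILIES = ("glm_main", "glm_step", "glm_interactions",
             "glm_step_interactions", "gam", "random_forest", "tree",
             "mean")  # "mean" = constant-rate baseline, not in any preset

_EPS = 1e-10


@dataclass(frozen=True)
class LearnerSpec:
    name: str
    family: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}")


TMLE1_LIBRARY = tuple(LearnerSpec(f, f) for f in _FAMILIES[:3])
TMLE2_LIBRARY = tuple(LearnerSpec(f, f) for f in _FAMILIES)
GLM_LIBRARY = (LearnerSpec("glm_main", "glm_main"),)

_PRESETS = {"tmle1": TMLE1_LIBRARY, "tmle2": TMLE2_LIBRARY, "glm": GLM_LIBRARY}


def _interaction_expand(X: np.ndarray) -> np.ndarray:
    cols = [X]
    for i, j in combinations(range(X.shape[1]), 2):
        cols.append((X[:, i] * X[:, j])[:, None])
    return np.hstack(cols) if len(cols) > 1 else X


def _loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


class _ConstantModel:
    def __init__(self, p):
        self.p = p

    def predict(self, X):
        return np.full(len(X), self.p)


class _GlmModel:
    """Unpenalized logistic regression on a column subset."""

    def __init__(self, columns, interactions):
        self.columns = list(columns)
        self.interactions = interactions

    def _design(self, X):
        Xe = _interaction_expand(X) if self.interactions else X
        return Xe[:, self.columns] if self.columns else np.empty((len(X), 0))

    def fit(self, X, y):
        D = self._design(X)
        if D.shape[1] == 0:
            self._model = _ConstantModel(float(np.mean(y)))
        else:
            self._model = None
            # newton-cholesky: IRLS-like, robust to unscaled interactions
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._lr = LogisticRegression(
                    C=np.inf, solver="newton-cholesky", max_iter=200,
                    tol=1e-8).fit(D, y)
        return self

    def predict(self, X):
        D = self._design(X)
        if self._model is not None:
            return self._model.predict(D)
        return self._lr.predict_proba(D)[:, 1]


def _fit_glm(X, y, columns, interactions):
    return _GlmModel(columns, interactions).fit(X, y)


def _stepwise_glm(X, y, interactions):
    """Bidirectional AIC stepwise from the intercept-only model."""
    Xe = _interaction_expand(X) if interactions else X
    n_terms = Xe.shape[1]
    n = len(y)

    def aic(cols):
        model = _GlmModel(cols, False).fit(Xe, y)
        return 2 * (len(cols) + 1) - 2 * _loglik(y, model.predict(Xe)), model

    current: list = []
    best_aic, best_model = aic(current)
    improved = True
    while improved:
        improved = False
        moves = [current + [j] for j in range(n_terms) if j not in current]
        moves += [[c for c in current if c != j] for j in current]
        for cols in moves:
            a, m = aic(cols)
            if a < best_aic - 1e-9:
                best_aic, best_model, current, improved = a, m, cols, True
        # accept the single best move per sweep (greedy bidirectional)
    model = _GlmModel(current, interactions)
    model._model = best_model._model
    if best_model._model is None:
        model._lr = best_model._lr
    return model


class _GamModel:
    """Logistic GAM: B-spline smooths on continuous columns, linear binaries."""

    def __init__(self, df=4, degree=3):
        self.df = df
        self.degree = degree

    def fit(self, X, y):
        import statsmodels.api as sm
        from statsmodels.gam.api import BSplines, GLMGam
        nuniq = np.array([len(np.unique(X[:, j])) for j in range(X.shape[1])])
        self.cont_ = np.flatnonzero(nuniq > 10)
        self.lin_ = np.flatnonzero(nuniq <= 10)
        if self.cont_.size == 0:
            self._fallback = _fit_glm(X, y, list(range(X.shape[1])), False)
            return self
        self._fallback = None
        Xc = X[:, self.cont_]
        self._lo = Xc.min(axis=0)
        self._hi = Xc.max(axis=0)
        self._bs = BSplines(Xc, df=[self.df] * Xc.shape[1],
                            degree=[self.degree] * Xc.shape[1])
        exog = sm.add_constant(X[:, self.lin_], has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._res = GLMGam(y, exog=exog, smoother=self._bs,
                               family=sm.families.Binomial()).fit()
        return self

    def predict(self, X):
        import statsmodels.api as sm
        if self._fallback is not None:
            return self._fallback.predict(X)
        exog = sm.add_constant(X[:, self.lin_], has_constant="add")
        # B-spline bases do not extrapolate; clamp to the training range
        Xc = np.clip(X[:, self.cont_], self._lo, self._hi)
        p = self._res.predict(exog=exog, exog_smooth=Xc)
        return np.clip(np.asarray(p), 0.0, 1.0)


class _ProbWrapper:
    """predict_proba -> single probability column, one-class safe."""

    def __init__(self, clf):
        self.clf = clf

    def fit(self, X, y):
        self.clf.fit(X, y)
        return self

    def predict(self, X):
        proba = self.clf.predict_proba(X)
        if proba.shape[1] == 1:
            return np.full(len(X), float(self.clf.classes_[0]))
        return proba[:, np.flatnonzero(self.clf.classes_ == 1)[0]]


def _build_learner(spec: LearnerSpec, X, y, seed: int):
    hp = spec.hyperparameters
    fam = spec.family
    p = X.shape[1]
    if fam == "mean":
        return _ConstantModel(float(np.mean(y)))
    if fam == "glm_main":
        return _fit_glm(X, y, list(range(p)), False)
    if fam == "glm_interactions":
        q = _interaction_expand(X).shape[1]
        return _fit_glm(X, y, list(range(q)), True)
    if fam == "glm_step":
        return _stepwise_glm(X, y, False)
    if fam == "glm_step_interactions":
        return _stepwise_glm(X, y, True)
    if fam == "gam":
        return _GamModel(df=hp.get("df", 4),
                         degree=hp.get("degree", 3)).fit(X, y)
    if fam == "random_forest":
        clf = RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 100),
            min_samples_leaf=hp.get("min_samples_leaf", 5),
            random_state=seed, n_jobs=1)
        return _ProbWrapper(clf).fit(X, y)
    if fam == "tree":
        pbar = float(np.mean(y))
        root_gini = 2 * pbar * (1 - pbar)
        # cost-complexity pruning at 1% of the root impurity (rpart-style cp)
        clf = DecisionTreeClassifier(
            min_samples_split=hp.get("min_samples_split", 20),
            ccp_alpha=hp.get("ccp_alpha", 0.01 * root_gini),
            random_state=seed)
        return _ProbWrapper(clf).fit(X, y)
    raise ValueError(fam)


def _resolve_library(library) -> tuple:
    if isinstance(library, str):
        if library not in _PRESETS:
            raise ValueError(f"unknown library preset {library!r}")
        return _PRESETS[library]
    out = []
    for item in library:
        out.append(item if isinstance(item, LearnerSpec)
                   else LearnerSpec(str(item), str(item)))
    return tuple(out)


class SuperLearner(BaseEstimator):
    """V-fold cross-validated stacking over a candidate-learner library.

    Parameters
    ----------
    library : str or sequence
        ``"tmle1"``, ``"tmle2"``, ``"glm"`` or an explicit sequence of
        family names / :class:`LearnerSpec`.
    folds : int
        Number of stratified CV folds (10 is the conventional default; 5 is
        a good fast setting at benchmark sample sizes).
    meta : {"nnls", "nll"}
        Meta-learning loss: squared error via non-negative least squares
        (default), or negative log-likelihood minimized on the simplex.
    seed : int or None
        Seeds the fold shuffle and all stochastic candidates.

    Fitted attributes: ``weights_`` (simplex), ``cv_risks_`` (per-candidate
    mean squared error of out-of-fold predictions), ``learners_`` (refit on
    the full data), ``library_``.
    """

    def __init__(self, library="tmle1", folds: int = 10, meta: str = "nnls",
                 seed: int | None = None):
        self.library = library
        self.folds = folds
        self.meta = meta
        self.seed = seed

    # -- helpers ----------------------------------------------------------
    def _coerce_X(self, X, fitting: bool):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(arr.shape[1])]
        if fitting:
            self.feature_names_in_ = names
            self.n_features_in_ = arr.shape[1]
        else:
            if names != self.feature_names_in_ and \
                    arr.shape[1] != self.n_features_in_:
                raise ValueError("prediction columns do not match training")
            if isinstance(X, pd.DataFrame) and names != self.feature_names_in_:
                raise ValueError(
                    f"prediction columns {names} do not match training "
                    f"columns {self.feature_names_in_}")
        return arr

    def _learner_seeds(self, k: int):
        root = np.random.SeedSequence(0 if self.seed is None else self.seed)
        return [int(s & 0x7FFFFFFF) for s in root.generate_state(k)]

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y):
        specs = _resolve_library(self.library)
        Xa = self._coerce_X(X, fitting=True)
        ya = np.asarray(y, dtype=float).ravel()
        if len(np.unique(ya)) < 2:
            raise ValueError("response is constant; nothing to learn")
        K = len(specs)
        seeds = self._learner_seeds(K + 1)
        self.library_ = specs

        if K == 1:
            # degenerate ensemble: skip CV, weight 1 on the only candidate
            self.learners_ = [_build_learner(specs[0], Xa, ya, seeds[0])]
            self.weights_ = np.array([1.0])
            self.cv_risks_ = np.array([np.nan])
            return self

        if len(ya) < 2 * self.folds:
            raise ValueError("need at least 2 rows per fold")
        skf = StratifiedKFold(n_splits=self.folds, shuffle=True,
                              random_state=seeds[K] % (2**32 - 1))
        oof = np.full((len(ya), K), np.nan)
        failed = np.zeros(K, dtype=bool)
        for tr, te in skf.split(Xa, ya):
            for k, spec in enumerate(specs):
                if failed[k]:
                    continue
                try:
                    model = _build_learner(spec, Xa[tr], ya[tr], seeds[k])
                    oof[te, k] = np.clip(model.predict(Xa[te]), 0.0, 1.0)
                except Exception as exc:  # graceful degradation
                    failed[k] = True
                    logger.warning("learner %s failed (%s); weight forced to 0",
                                   spec.name, exc)
        if failed.all():
            raise RuntimeError("every candidate learner failed")

        ok = ~failed
        risks = np.full(K, np.nan)
        risks[ok] = np.mean((oof[:, ok] - ya[:, None]) ** 2, axis=0)
        self.cv_risks_ = risks
        self.oof_predictions_ = oof

        w = np.zeros(K)
        w_ok, _ = nnls(oof[:, ok], ya)
        if w_ok.sum() <= 0:
            w_ok = np.zeros(ok.sum())
            w_ok[int(np.nanargmin(risks[ok]))] = 1.0
        else:
            w_ok = w_ok / w_ok.sum()
        if self.meta == "nll":
            w_ok = self._nll_weights(oof[:, ok], ya, w_ok)
        elif self.meta != "nnls":
            raise ValueError("meta must be 'nnls' or 'nll'")
        w[ok] = w_ok
        self.weights_ = w
        self.ensemble_cv_risk_ = float(np.mean((oof[:, ok] @ w_ok - ya) ** 2))

        self.learners_ = [
            _build_learner(spec, Xa, ya, seeds[k]) if ok[k] else None
            for k, spec in enumerate(specs)]
        return self

    @staticmethod
    def _nll_weights(P, y, w0):
        def nll(w):
            w = np.abs(w)
            s = w.sum()
            if s == 0:
                return np.inf
            return -_loglik(y, P @ (w / s)) / len(y)
        res = minimize(nll, w0, method="Nelder-Mead",
                       options={"maxiter": 500, "xatol": 1e-6})
        w = np.abs(res.x)
        return w / w.sum()

    def predict_proba1(self, X) -> np.ndarray:
        """Ensemble probability of the positive class."""
        Xa = self._coerce_X(X, fitting=False)
        out = np.zeros(len(Xa))
        for w, model in zip(self.weights_, self.learners_):
            if w > 0 and model is not None:
                out += w * np.clip(model.predict(Xa), 0.0, 1.0)
        return np.clip(out, 0.0, 1.0)

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.predict_proba1(X)
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba1(X) >= 0.5).astype(int)


def sl_fit(X, y, library="tmle1", folds: int = 10,
           seed: int | None = None) -> SuperLearner:
    """Functional wrapper over :class:`SuperLearner`."""
    return SuperLearner(library=library, folds=folds, seed=seed).fit(X, y)


def sl_predict(fit: SuperLearner, X_new) -> np.ndarray:
    """Ensemble probabilities for new data (columns must match training)."""
    return fit.predict_proba1(X_new)
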