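"""Cross-validated stacking ensemble used as the G-formula outcome model.

A library of candidate learners (GLM, random forest, neural network, a
piecewise-linear spline approximation of MARS, gradient boosting) is
cross-validated on shared V folds; out-of-fold predictions form the design
of a meta-regression of the outcome, solved as least squares over the
probability simplex (non-negative weights summing to one).  Solving the
constrained problem exactly — by enumerating active sets, which is cheap
for a handful of learners — guarantees the stacked cross-validated risk is
never worse than the best single learner's on the same folds.

Treatment enters the outcome model as an ordinary column of X; one library
member additionally expands treatment-by-covariate interaction features,
which lets the stack express effect modification without a separate
per-arm fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier, XGBRegressor

from .schema import TREATMENT_COL

log = logging.getLogger(__name__)

FAMILIES = (
    "glm",
    "random_forest",
    "neural_network",
    "mars",
    "gradient_boosting",
)
PROB_CLIP = 1e-6


@dataclass(frozen=True)
class LearnerSpec:
    name: str
    family: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}")


def default_library() -> list[LearnerSpec]:
    """Full candidate library (one member per family, plus an
    interaction-augmented GLM)."""
    return [
        LearnerSpec("glm", "glm"),
        LearnerSpec("glm_tx_interactions", "glm", {"treatment_interactions": True}),
        LearnerSpec("random_forest", "random_forest", {"n_estimators": 300, "min_samples_leaf": 10}),
        LearnerSpec("neural_network", "neural_network", {"hidden": 32, "max_iter": 400}),
        LearnerSpec("mars", "mars"),
        LearnerSpec("gradient_boosting", "gradient_boosting", {"n_estimators": 200, "max_depth": 3}),
    ]


def glm_library() -> list[LearnerSpec]:
    """Fast two-member library (plain GLM + treatment-interaction GLM) for
    large simulation batches."""
    return [
        LearnerSpec("glm", "glm"),
        LearnerSpec("glm_tx_interactions", "glm", {"treatment_interactions": True}),
    ]


# ---------------------------------------------------------------------------
# learner wrappers
# ---------------------------------------------------------------------------


class _SkLearner:
    """Uniform fit/predict facade over a sklearn-style estimator."""

    def __init__(self, est, binary: bool, tx_index: int | None = None):
        self.est = est
        self.binary = binary
        self.tx_index = tx_index  # if set, append treatment-by-covariate products

    def _features(self, X: np.ndarray) -> np.ndarray:
        if self.tx_index is None:
            return X
        a = X[:, self.tx_index : self.tx_index + 1]
        others = np.delete(X, self.tx_index, axis=1)
        return np.hstack([X, a * others])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SkLearner":
        self.est.fit(self._features(X), y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        F = self._features(X)
        if self.binary:
            return self.est.predict_proba(F)[:, 1]
        return np.asarray(self.est.predict(F), dtype=float)


class _HingeBasis:
    """Piecewise-linear (hinge) basis expansion at per-feature quantile knots;
    with a ridge-penalized GLM on top this approximates a MARS fit."""

    def __init__(self, quantiles=(0.25, 0.5, 0.75)):
        self.quantiles = quantiles
        self.knots_: list[tuple[int, float]] = []

    def fit(self, X: np.ndarray, y=None):
        self.knots_ = []
        for j in range(X.shape[1]):
            col = X[:, j]
            if len(np.unique(col)) > 4:
                for q in self.quantiles:
                    self.knots_.append((j, float(np.quantile(col, q))))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        parts = [X]
        for j, t in self.knots_:
            parts.append(np.maximum(X[:, j : j + 1] - t, 0.0))
            parts.append(np.maximum(t - X[:, j : j + 1], 0.0))
        return np.hstack(parts)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_params(self, deep=True):
        return {"quantiles": self.quantiles}

    def set_params(self, **kw):
        self.quantiles = kw.get("quantiles", self.quantiles)
        return self


def make_learner(
    spec: LearnerSpec, binary: bool, seed: int, feature_names: list[str]
) -> _SkLearner:
    hp = dict(spec.hyperparameters)
    tx_index = None
    if hp.pop("treatment_interactions", False):
        if TREATMENT_COL not in feature_names:
            raise ValueError("treatment_interactions learner needs a treatment column")
        tx_index = feature_names.index(TREATMENT_COL)
    if spec.family == "glm":
        C = hp.get("C", 1e4)
        est = (
            make_pipeline(StandardScaler(), LogisticRegression(C=C, max_iter=3000))
            if binary
            else make_pipeline(StandardScaler(), Ridge(alpha=1e-4))
        )
    elif spec.family == "random_forest":
        cls = RandomForestClassifier if binary else RandomForestRegressor
        est = cls(
            n_estimators=hp.get("n_estimators", 300),
            min_samples_leaf=hp.get("min_samples_leaf", 10),
            random_state=seed,
            n_jobs=1,
        )
    elif spec.family == "neural_network":
        cls = MLPClassifier if binary else MLPRegressor
        est = make_pipeline(
            StandardScaler(),
            cls(
                hidden_layer_sizes=(hp.get("hidden", 32),),
                max_iter=hp.get("max_iter", 400),
                random_state=seed,
            ),
        )
    elif spec.family == "mars":
        head = (
            LogisticRegression(C=hp.get("C", 1.0), max_iter=3000)
            if binary
            else Ridge(alpha=hp.get("alpha", 1.0))
        )
        est = make_pipeline(_HingeBasis(), StandardScaler(), head)
    elif spec.family == "gradient_boosting":
        cls = XGBClassifier if binary else XGBRegressor
        est = cls(
            n_estimators=hp.get("n_estimators", 200),
            max_depth=hp.get("max_depth", 3),
            learning_rate=hp.get("learning_rate", 0.1),
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            verbosity=0,
        )
    else:  # pragma: no cover - guarded by LearnerSpec
        raise ValueError(spec.family)
    return _SkLearner(est, binary, tx_index)


# ---------------------------------------------------------------------------
# meta-learning
# ---------------------------------------------------------------------------


def _simplex_lstsq(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact least squares over the probability simplex.

    Enumerates candidate active sets (feasible for library sizes used here)
    and solves each equality-constrained subproblem through its KKT system;
    the feasible candidate with the lowest objective is the global optimum.
    Collinear columns (duplicated learners) get a minimum-norm split, which
    leaves predictions unchanged.
    """
    n, K = Z.shape
    if K == 1:
        return np.array([1.0])
    ZtZ = Z.T @ Z
    Zty = Z.T @ y
    yty = float(y @ y)
    best_w, best_obj = None, np.inf
    for mask in range(1, 1 << K):
        idx = [i for i in range(K) if (mask >> i) & 1]
        k = len(idx)
        G = ZtZ[np.ix_(idx, idx)]
        KKT = np.zeros((k + 1, k + 1))
        KKT[:k, :k] = 2.0 * G
        KKT[:k, k] = 1.0
        KKT[k, :k] = 1.0
        rhs = np.concatenate([2.0 * Zty[idx], [1.0]])
        sol, *_ = np.linalg.lstsq(KKT, rhs, rcond=None)
        w = sol[:k]
        if np.any(w < -1e-9) or not np.isclose(w.sum(), 1.0, atol=1e-6):
            continue
        w = np.clip(w, 0.0, None)
        w = w / w.sum()
        obj = yty - 2.0 * w @ Zty[idx] + w @ G @ w
        if obj < best_obj - 1e-15:
            best_obj = obj
            best_w = np.zeros(K)
            best_w[idx] = w
    if best_w is None:  # numerically degenerate; fall back to best single learner
        risks = np.mean((y[:, None] - Z) ** 2, axis=0)
        best_w = np.zeros(K)
        best_w[int(np.argmin(risks))] = 1.0
    return best_w


@dataclass
class EnsembleModel:
    library: list[LearnerSpec]
    V: int
    fold_ids: np.ndarray
    cv_risks: np.ndarray  # per learner, inf for failed learners
    weights: np.ndarray  # simplex weights, 0 for failed learners
    refit_learners: list  # fitted on full data (None for failed learners)
    loss: str  # "binary" | "continuous"
    feature_names: list[str]
    oof_predictions: np.ndarray | None = None  # n x K, audit / risk recomputation

    @property
    def binary(self) -> bool:
        return self.loss == "binary"

    def stacked_cv_risk(self) -> float:
        """Cross-validated risk of the stacked predictor on the shared folds."""
        ok = np.isfinite(self.cv_risks)
        Z = self.oof_predictions[:, ok]
        w = self.weights[ok]
        return float(np.mean((self._y_oof - Z @ w) ** 2))


def cv_stack(
    X: pd.DataFrame,
    y: np.ndarray,
    library: list[LearnerSpec] | None = None,
    V: int = 10,
    seed: int = 0,
    loss: str | None = None,
) -> EnsembleModel:
    """Fit the cross-validated stacking ensemble.

    ``X`` must contain the treatment column and no missing values.  Folds
    are stratified by outcome for binary loss.  A learner that fails to fit
    on any fold is logged, assigned infinite cross-validated risk and zero
    weight; the stack proceeds on the survivors.
    """
    library = list(library) if library is not None else default_library()
    if not library:
        raise ValueError("empty learner library")
    y = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    if np.isnan(Xv).any() or np.isnan(y).any():
        raise ValueError("cv_stack requires complete data; impute first")
    n = len(y)
    if n < 2 * V:
        raise ValueError("need n >= 2V for V-fold stacking")
    if loss is None:
        loss = "binary" if set(np.unique(y)) <= {0.0, 1.0} else "continuous"
    binary = loss == "binary"
    feature_names = list(X.columns)

    splitter = (
        StratifiedKFold(n_splits=V, shuffle=True, random_state=seed)
        if binary
        else KFold(n_splits=V, shuffle=True, random_state=seed)
    )
    fold_ids = np.empty(n, dtype=int)
    folds = list(splitter.split(Xv, y if binary else None))
    for f, (_, test_idx) in enumerate(folds):
        fold_ids[test_idx] = f

    K = len(library)
    Z = np.full((n, K), np.nan)
    failed = np.zeros(K, dtype=bool)
    rng = np.random.default_rng(seed)
    learner_seeds = rng.integers(0, 2**31 - 1, size=K)
    for k, spec in enumerate(library):
        try:
            for train_idx, test_idx in folds:
                lrn = make_learner(spec, binary, int(learner_seeds[k]), feature_names)
                lrn.fit(Xv[train_idx], y[train_idx])
                Z[test_idx, k] = lrn.predict(Xv[test_idx])
        except Exception as exc:  # noqa: BLE001 - contract: survive learner failure
            log.warning("learner %s failed during cross-validation: %s", spec.name, exc)
            failed[k] = True
    if failed.all():
        raise RuntimeError("all learners failed to fit")
    if binary:
        Z = np.clip(Z, PROB_CLIP, 1.0 - PROB_CLIP)

    cv_risks = np.full(K, np.inf)
    ok = ~failed
    cv_risks[ok] = np.mean((y[:, None] - Z[:, ok]) ** 2, axis=0)

    weights = np.zeros(K)
    weights[ok] = _simplex_lstsq(Z[:, ok], y)

    refit = []
    for k, spec in enumerate(library):
        if failed[k]:
            refit.append(None)
            continue
        try:
            lrn = make_learner(spec, binary, int(learner_seeds[k]), feature_names)
            lrn.fit(Xv, y)
            refit.append(lrn)
        except Exception as exc:  # noqa: BLE001
            log.warning("learner %s failed on full-data refit: %s", spec.name, exc)
            refit.append(None)
            cv_risks[k] = np.inf
            weights[k] = 0.0
    if weights.sum() <= 0:
        raise RuntimeError("all learners failed to fit")
    weights = weights / weights.sum()

    model = EnsembleModel(
        library=library,
        V=V,
        fold_ids=fold_ids,
        cv_risks=cv_risks,
        weights=weights,
        refit_learners=refit,
        loss=loss,
        feature_names=feature_names,
        oof_predictions=Z,
    )
    model._y_oof = y  # kept for risk recomputation on the shared folds
    return model


def save_model(model: EnsembleModel, path) -> None:
    """Serialize the fitted stack (joblib) plus a JSON audit sidecar with
    the weights, cross-validated risks and fold/loss metadata."""
    import json
    from pathlib import Path

    import joblib

    from . import __version__

    path = Path(path)
    joblib.dump(model, path)
    sidecar = {
        "version": __version__,
        "loss": model.loss,
        "V": model.V,
        "library": [s.name for s in model.library],
        "weights": {s.name: float(w) for s, w in zip(model.library, model.weights)},
        "cv_risks": {
            s.name: (float(r) if np.isfinite(r) else None)
            for s, r in zip(model.library, model.cv_risks)
        },
        "feature_names": model.feature_names,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_model(path) -> EnsembleModel:
    import joblib

    return joblib.load(path)


def predict_ensemble(model: EnsembleModel, X: pd.DataFrame) -> np.ndarray:
    """Weighted prediction of the refit learners; probabilities are clipped
    away from 0/1 for binary loss."""
    if list(X.columns) != model.feature_names:
        missing = set(model.feature_names) - set(X.columns)
        extra = set(X.columns) - set(model.feature_names)
        raise ValueError(
            f"feature columns do not match training schema "
            f"(missing: {sorted(missing)}, unexpected: {sorted(extra)})"
        )
    Xv = X.to_numpy(dtype=float)
    out = np.zeros(len(X))
    for w, lrn in zip(model.weights, model.refit_learners):
        if w == 0.0 or lrn is None:
            continue
        out += w * lrn.predict(Xv)
    if model.binary:
        out = np.clip(out, PROB_CLIP, 1.0 - PROB_CLIP)
    return out
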