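"""Multi-algorithm suitability models and their TSS-weighted ensemble.

Ten algorithm ids are supported — GLM, GAM, MARS, GBM (regression flavours),
ANN, RF, MAXENT, SRE (machine-learning flavours), CTA and FDA (classification
flavours). Each is fitted behind a uniform contract: the fitted object maps a
predictor matrix to a score in [0, 1]. Most delegate to scikit-learn
estimators; SRE (the quantile surface range envelope) and the hinge-basis MARS
model are implemented here. The framework does not hard-require all ten — any
subset can be configured.

An ensemble keeps the runs whose true skill statistic clears a strict gate
(default TSS > 0.60) and averages their scores with weights proportional to
TSS. Variable importance follows the permutation-correlation convention:
``1 - cor(reference predictions, predictions with one layer shuffled)``,
averaged over permutations and normalised to sum 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .grid import RasterGrid
from .metrics import auc as _auc
from .metrics import tss as _tss
from .stack import PredictorStack

__all__ = [
    "ALGORITHMS",
    "ModelRun",
    "EnsembleModel",
    "SreEnvelope",
    "NoEnsembleError",
    "split",
    "fit",
    "evaluate",
    "build_ensemble",
    "predict_records",
    "predict_map",
    "choose_threshold",
    "binarise",
    "variable_importance",
]

ALGORITHMS = ("GLM", "GAM", "MARS", "GBM", "ANN", "RF", "MAXENT", "SRE", "CTA", "FDA")


class NoEnsembleError(RuntimeError):
    """No model run cleared the TSS gate."""


# ---------------------------------------------------------------------------
# learners


@dataclass
class SreEnvelope:
    """Surface range envelope: per-layer presence quantile bounds.

    Predicts 1 where every predictor lies inside its [q, 1-q] presence
    quantile interval (default q = 0.025), else 0 — the classic "bioclim"
    rectangular envelope.
    """

    q: float = 0.025
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, sample_weight=None) -> "SreEnvelope":
        pres = X[np.asarray(y) == 1]
        if pres.shape[0] == 0:
            raise ValueError("SRE needs presence records")
        self.lower = np.quantile(pres, self.q, axis=0)
        self.upper = np.quantile(pres, 1.0 - self.q, axis=0)
        return self

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        inside = (X >= self.lower) & (X <= self.upper)
        return inside.all(axis=1).astype(float)


class _SklearnModel:
    """Adapter giving scikit-learn classifiers the predict_scores contract."""

    def __init__(self, estimator, supports_weights: bool = True):
        self.estimator = estimator
        self.supports_weights = supports_weights

    def fit(self, X, y, sample_weight=None):
        if sample_weight is not None and self.supports_weights:
            self.estimator.fit(X, y, sample_weight=sample_weight)
        else:
            self.estimator.fit(X, y)
        return self

    def predict_scores(self, X) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        pos = list(self.estimator.classes_).index(1)
        return proba[:, pos]


class MarsModel:
    """Piecewise-linear (hinge-basis) logistic model.

    A light-weight multivariate-adaptive-regression-splines analogue: each
    predictor contributes hinge pairs max(x-k, 0) / max(k-x, 0) at its
    training-sample quartile knots, and an L2 logistic regression is fitted on
    that basis.
    """

    def __init__(self, knots=(0.25, 0.5, 0.75), seed: int = 0):
        self.knot_quantiles = knots
        self.seed = seed
        self.knots_: np.ndarray | None = None
        self.logit_: LogisticRegression | None = None

    def _basis(self, X: np.ndarray) -> np.ndarray:
        cols = [X]
        for j in range(X.shape[1]):
            for k in self.knots_[:, j]:
                cols.append(np.maximum(X[:, j:j + 1] - k, 0.0))
                cols.append(np.maximum(k - X[:, j:j + 1], 0.0))
        return np.hstack(cols)

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        self.knots_ = np.quantile(X, self.knot_quantiles, axis=0)
        self.logit_ = LogisticRegression(max_iter=2000, C=1.0)
        self.logit_.fit(self._basis(X), y, sample_weight=sample_weight)
        return self

    def predict_scores(self, X) -> np.ndarray:
        proba = self.logit_.predict_proba(self._basis(np.asarray(X, dtype=float)))
        pos = list(self.logit_.classes_).index(1)
        return proba[:, pos]


def _make_learner(algorithm_id: str, seed: int, hyper: dict | None):
    hyper = hyper or {}
    if algorithm_id == "GLM":
        return _SklearnModel(LogisticRegression(
            max_iter=2000, C=hyper.get("C", 1e6)))
    if algorithm_id == "GAM":
        return _SklearnModel(Pipeline([
            ("spline", SplineTransformer(
                n_knots=hyper.get("n_knots", 5), degree=3)),
            ("logit", LogisticRegression(max_iter=2000, C=hyper.get("C", 1.0))),
        ]), supports_weights=False)
    if algorithm_id == "MARS":
        return MarsModel(seed=seed)
    if algorithm_id == "GBM":
        return _SklearnModel(GradientBoostingClassifier(
            n_estimators=hyper.get("n_estimators", 80),
            max_depth=hyper.get("max_depth", 3),
            learning_rate=hyper.get("learning_rate", 0.1),
            random_state=seed))
    if algorithm_id == "ANN":
        return _SklearnModel(Pipeline([
            ("scale", StandardScaler()),
            ("mlp", MLPClassifier(
                hidden_layer_sizes=hyper.get("hidden_layer_sizes", (16,)),
                max_iter=hyper.get("max_iter", 300), tol=1e-3,
                random_state=seed)),
        ]), supports_weights=False)
    if algorithm_id == "RF":
        return _SklearnModel(RandomForestClassifier(
            n_estimators=hyper.get("n_estimators", 200),
            min_samples_leaf=hyper.get("min_samples_leaf", 2),
            random_state=seed, n_jobs=1))
    if algorithm_id == "MAXENT":
        # linear + quadratic + product features under an L1-ish logistic fit:
        # the standard maxent feature classes short of hinges
        return _SklearnModel(Pipeline([
            ("scale", StandardScaler()),
            ("poly", PolynomialFeatures(degree=2, include_bias=False)),
            ("logit", LogisticRegression(max_iter=3000, C=hyper.get("C", 1.0))),
        ]), supports_weights=False)
    if algorithm_id == "SRE":
        return SreEnvelope(q=hyper.get("q", 0.025))
    if algorithm_id == "CTA":
        return _SklearnModel(DecisionTreeClassifier(
            max_depth=hyper.get("max_depth", 8),
            min_samples_leaf=hyper.get("min_samples_leaf", 10),
            random_state=seed))
    if algorithm_id == "FDA":
        return _SklearnModel(LinearDiscriminantAnalysis(), supports_weights=False)
    raise ValueError(
        f"unsupported algorithm {algorithm_id!r}; supported: {ALGORITHMS}")


# ---------------------------------------------------------------------------
# runs and splits


@dataclass
class ModelRun:
    """One fitted learner plus (after :func:`evaluate`) its holdout metrics."""

    algorithm_id: str
    model: object
    features: list[str]
    pa_replicate: int | None = None
    cv_replicate: int | None = None
    eval: dict = field(default_factory=dict)

    @property
    def tss(self) -> float:
        return self.eval.get("tss", float("nan"))

    def predict_scores(self, X) -> np.ndarray:
        return self.model.predict_scores(np.asarray(X, dtype=float))


def split(data: pd.DataFrame, train_fraction: float = 0.70,
          cv_replicates: int = 3, seed: int = 0):
    """Stratified-by-label random train/test splits.

    Returns a list of ``cv_replicates`` (train, test) frame pairs; weights and
    all other columns are carried through. Raises if either class would be
    absent from train or test after 10 redraw attempts.
    """
    labels = data["label"].to_numpy()
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValueError("data must contain both classes")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(cv_replicates):
        for attempt in range(10):
            train_idx, test_idx = [], []
            for cls in (0, 1):
                idx = np.nonzero(labels == cls)[0]
                perm = rng.permutation(idx)
                k = int(round(train_fraction * len(idx)))
                train_idx.append(perm[:k])
                test_idx.append(perm[k:])
            train_idx = np.concatenate(train_idx)
            test_idx = np.concatenate(test_idx)
            tr_lab, te_lab = labels[train_idx], labels[test_idx]
            if all((lab == 1).any() and (lab == 0).any()
                   for lab in (tr_lab, te_lab)):
                break
        else:
            raise ValueError("could not produce a split with both classes "
                             "in train and test")
        splits.append((data.iloc[np.sort(train_idx)].reset_index(drop=True),
                       data.iloc[np.sort(test_idx)].reset_index(drop=True)))
    return splits


def fit(algorithm_id: str, train: pd.DataFrame, features,
        seed: int = 0, hyper: dict | None = None) -> ModelRun:
    """Fit one learner on a training frame (feature columns + label [+ weight])."""
    features = list(features)
    learner = _make_learner(algorithm_id, seed, hyper)
    X = train[features].to_numpy(dtype=float)
    y = train["label"].to_numpy()
    w = train["weight"].to_numpy(dtype=float) if "weight" in train.columns else None
    learner.fit(X, y, sample_weight=w)
    return ModelRun(algorithm_id, learner, features)


def evaluate(run: ModelRun, test: pd.DataFrame) -> ModelRun:
    """Score a run on held-out data: AUC plus max-TSS and its threshold."""
    scores = run.predict_scores(test[run.features].to_numpy(dtype=float))
    labels = test["label"].to_numpy()
    res = _tss(scores, labels)
    run.eval = {
        "auc": _auc(scores, labels),
        "tss": res.tss,
        "sensitivity": res.sensitivity,
        "specificity": res.specificity,
        "optimal_threshold": res.threshold,
    }
    return run


# ---------------------------------------------------------------------------
# the ensemble


@dataclass
class EnsembleModel:
    """TSS-weighted combination of the runs that cleared the gate."""

    members: list[ModelRun]
    weights: np.ndarray
    tss_cutoff: float

    @property
    def features(self) -> list[str]:
        out: list[str] = []
        for m in self.members:
            for f in m.features:
                if f not in out:
                    out.append(f)
        return out


def build_ensemble(runs, tss_cutoff: float = 0.60) -> EnsembleModel:
    """Keep runs with TSS strictly above the cutoff; weight by raw TSS.

    Weights are each member's TSS divided by the members' TSS total, so they
    sum to 1. Raises :class:`NoEnsembleError` when nothing passes — an
    ensemble of zero models is not silently substituted.
    """
    members = [r for r in runs if r.tss > tss_cutoff]
    if not members:
        raise NoEnsembleError(
            f"no run has TSS > {tss_cutoff}; cannot build an ensemble")
    tss_vals = np.array([m.tss for m in members], dtype=float)
    return EnsembleModel(members, tss_vals / tss_vals.sum(), tss_cutoff)


def predict_records(ensemble: EnsembleModel, X: pd.DataFrame) -> np.ndarray:
    """Weighted-mean ensemble score for a record table with feature columns."""
    out = np.zeros(len(X), dtype=float)
    for m, w in zip(ensemble.members, ensemble.weights):
        out += w * m.predict_scores(X[m.features].to_numpy(dtype=float))
    return out


def predict_map(ensemble: EnsembleModel, stack: PredictorStack) -> RasterGrid:
    """Cell-wise ensemble suitability over a predictor stack."""
    missing = [f for f in ensemble.features if f not in stack]
    if missing:
        raise KeyError(f"stack lacks layer(s) required by the ensemble: {missing}")
    mask = stack.mask
    rows, cols = np.nonzero(mask)
    out = np.full(stack.template.shape, np.nan)
    acc = np.zeros(rows.size, dtype=float)
    for m, w in zip(ensemble.members, ensemble.weights):
        X = np.column_stack([stack[f].values[rows, cols] for f in m.features])
        acc += w * m.predict_scores(X)
    out[rows, cols] = acc
    return stack.template.with_values(out)


def choose_threshold(ensemble: EnsembleModel, validation: pd.DataFrame) -> float:
    """Binarisation threshold maximising ensemble TSS on pooled validation data."""
    scores = predict_records(ensemble, validation)
    return _tss(scores, validation["label"].to_numpy()).threshold


def binarise(suitability: RasterGrid, threshold: float) -> RasterGrid:
    """Binary map: 1 where suitability >= threshold, 0 below, nodata kept."""
    v = np.where(suitability.values >= threshold, 1.0, 0.0)
    v = np.where(suitability.mask, v, np.nan)
    return suitability.with_values(v)


def variable_importance(ensemble: EnsembleModel, data: pd.DataFrame,
                        n_permutations: int = 3, seed: int = 0) -> pd.Series:
    """Permutation importance per predictor, normalised to sum 100%.

    For each feature, its column is shuffled across records and the drop in
    correlation with the reference predictions, ``1 - r``, is averaged over
    permutations. A constant reference prediction yields a zero vector with a
    warning rather than an error.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    features = ensemble.features
    ref = predict_records(ensemble, data)
    if np.std(ref) == 0:
        warnings.warn("ensemble predictions are constant; importances are zero",
                      stacklevel=2)
        return pd.Series(0.0, index=features)
    raw = {}
    for f in features:
        drops = []
        for _ in range(n_permutations):
            shuffled = data.copy()
            shuffled[f] = rng.permutation(shuffled[f].to_numpy())
            perm = predict_records(ensemble, shuffled)
            r = np.corrcoef(ref, perm)[0, 1] if np.std(perm) > 0 else 0.0
            drops.append(1.0 - r)
        raw[f] = float(np.mean(drops))
    s = pd.Series(raw)
    total = s.sum()
    return s * (100.0 / total) if total > 0 else s
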