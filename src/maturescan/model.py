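"""RBF-kernel SVM over duplex-window features.

The classifier realizes the standard soft-margin SVC decision function

    g(x) = sum_i  z_i alpha_i k(x, x_i) + w0,     0 <= alpha_i <= c,
    k(x_i, x_j) = exp(-gamma * ||x_i - x_j||^2),

with the penalty ``c`` and kernel width ``gamma`` chosen by grid search.
Because training data carry ~one positive per precursor against every other
putative start as a negative (heavily imbalanced), model selection uses the
quantity that actually matters — the per-precursor *exact-hit rate* (the
top-ranked candidate of a held-out precursor equals its true start) under
grouped cross-validation, with whole precursors held out so a precursor's
positive never informs the scoring of its own negatives.

Probabilities come from a Platt sigmoid fit on out-of-fold decision values
(the usual libSVM ``-b 1`` convention), so the serialized model is a
self-contained set of arrays that round-trips exactly through JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .features import FEATURE_LAYOUT_VERSION, N_FEATURES
from .hairpin import ENGINE_VERSION

MODEL_FORMAT = "maturescan-model-v1"


class ModelError(ValueError):
    pass


def _default_c_grid() -> np.ndarray:
    return 2.0 ** np.arange(-5, 16, 4)  # 2^-5, 2^-1, ..., 2^15


def _default_gamma_grid() -> np.ndarray:
    return 2.0 ** np.arange(-15, 4, 4)  # 2^-15, 2^-11, ..., 2^1


@dataclass
class ModelConfig:
    """Grid-search and CV settings.

    Grids follow common libSVM practice: ``c`` in 2^-5..2^15 and ``gamma``
    in 2^-15..2^3, both on a x2^4 ladder; 5 grouped folds.
    """

    c_grid: np.ndarray = field(default_factory=_default_c_grid)
    gamma_grid: np.ndarray = field(default_factory=_default_gamma_grid)
    cv_folds: int = 5
    class_weight: str | None = "balanced"
    seed: int = 0

    def validate(self) -> None:
        if len(self.c_grid) == 0 or len(self.gamma_grid) == 0:
            raise ModelError("empty parameter grid")
        if np.any(np.asarray(self.c_grid) <= 0) or np.any(
            np.asarray(self.gamma_grid) <= 0
        ):
            raise ModelError("c and gamma must be positive")


@dataclass
class TrainingSet:
    """Feature matrix with labels and per-row precursor grouping.

    ``y`` uses {+1, -1}; ``groups`` holds one precursor id per row so CV
    folds never split a precursor.
    """

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.groups = np.asarray(self.groups)
        if self.X.ndim != 2 or self.X.shape[1] != N_FEATURES:
            raise ModelError(f"X must be (n, {N_FEATURES})")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ModelError("labels must be +1/-1")
        if len(self.y) != len(self.X) or len(self.groups) != len(self.X):
            raise ModelError("X, y, groups must align")
        if np.isnan(self.X).any():
            raise ModelError("NaN in feature matrix")


def _grouped_folds(
    groups: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Seed-shuffled assignment of whole groups to folds (round-robin)."""
    uniq = np.unique(groups)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    fold_of_group = {uniq[g]: k % n_folds for k, g in enumerate(order)}
    fold_ids = np.array([fold_of_group[g] for g in groups])
    return [np.flatnonzero(fold_ids == k) for k in range(n_folds)]


def _exact_hit_rate(
    scores: np.ndarray, y: np.ndarray, groups: np.ndarray
) -> float:
    """Fraction of precursors whose top-scoring row is the true positive."""
    hits, total = 0, 0
    for g in np.unique(groups):
        mask = groups == g
        if not (y[mask] == 1).any():
            continue
        total += 1
        hits += y[mask][np.argmax(scores[mask])] == 1
    return hits / total if total else 0.0


def _fit_platt(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt scaling: p(+1 | f) = sigmoid(a*f + b), fit by regularized NLL.

    Uses Platt's target smoothing so the sigmoid stays finite on separable
    data.
    """
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params: np.ndarray) -> float:
        z = params[0] * decision + params[1]
        # log(1 + e^-z) and log(1 + e^z), stably
        return float(
            np.sum(t * np.logaddexp(0.0, -z) + (1 - t) * np.logaddexp(0.0, z))
        )

    res = minimize(nll, x0=np.array([1.0, 0.0]), method="Nelder-Mead")
    return float(res.x[0]), float(res.x[1])


@dataclass
class TrainedModel:
    """Fitted classifier: support vectors, kernel, scaling, calibration."""

    support_vectors: np.ndarray  # scaled, (m, 94)
    dual_coef: np.ndarray        # z_i * alpha_i, (m,)
    intercept: float             # w0
    c: float
    gamma: float
    calib_a: float
    calib_b: float
    scale_min: np.ndarray        # per-feature min (94,)
    scale_range: np.ndarray      # per-feature max - min, zeros mapped to 1
    feature_layout: str = FEATURE_LAYOUT_VERSION
    engine_version: str = ENGINE_VERSION
    seed: int = 0
    cv_report: pd.DataFrame | None = None

    def scale(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise ModelError(f"X must be (n, {N_FEATURES})")
        return (X - self.scale_min) / self.scale_range

    def decision_function(self, X: np.ndarray, scaled: bool = False) -> np.ndarray:
        """g(x) evaluated from the stored support expansion."""
        Xs = X if scaled else self.scale(X)
        k = np.exp(-self.gamma * cdist(Xs, self.support_vectors, "sqeuclidean"))
        return k @ self.dual_coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-row (p_positive, p_negative); rows sum to 1 exactly."""
        z = self.calib_a * self.decision_function(X) + self.calib_b
        p_pos = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([p_pos, 1.0 - p_pos])

    # --- serialization -------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "format": MODEL_FORMAT,
            "feature_layout": self.feature_layout,
            "engine_version": self.engine_version,
            "seed": self.seed,
            "c": self.c,
            "gamma": self.gamma,
            "intercept": self.intercept,
            "calib_a": self.calib_a,
            "calib_b": self.calib_b,
            "scale_min": self.scale_min.tolist(),
            "scale_range": self.scale_range.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "cv_report": None
            if self.cv_report is None
            else self.cv_report.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != MODEL_FORMAT:
            raise ModelError(
                f"model format {payload.get('format')!r} does not match "
                f"this code ({MODEL_FORMAT}); refusing to load"
            )
        if payload["feature_layout"] != FEATURE_LAYOUT_VERSION:
            raise ModelError(
                f"feature layout {payload['feature_layout']!r} does not "
                f"match this code ({FEATURE_LAYOUT_VERSION})"
            )
        return cls(
            support_vectors=np.array(payload["support_vectors"], dtype=float),
            dual_coef=np.array(payload["dual_coef"], dtype=float),
            intercept=float(payload["intercept"]),
            c=float(payload["c"]),
            gamma=float(payload["gamma"]),
            calib_a=float(payload["calib_a"]),
            calib_b=float(payload["calib_b"]),
            scale_min=np.array(payload["scale_min"], dtype=float),
            scale_range=np.array(payload["scale_range"], dtype=float),
            feature_layout=payload["feature_layout"],
            engine_version=payload["engine_version"],
            seed=int(payload["seed"]),
            cv_report=None
            if payload["cv_report"] is None
            else pd.DataFrame(payload["cv_report"]),
        )


def _svc(c: float, gamma: float, config: ModelConfig) -> SVC:
    return SVC(
        C=c,
        gamma=gamma,
        kernel="rbf",
        class_weight=config.class_weight,
        cache_size=500,
        random_state=config.seed,
    )


def fit(train: TrainingSet, config: ModelConfig | None = None) -> TrainedModel:
    """Grid search (c, gamma) by grouped CV exact-hit rate, then refit on all.

    Deterministic given ``config.seed``: fold assignment is the only random
    element and is seed-controlled; libSVM optimization itself is
    deterministic for a fixed row order.
    """
    config = config or ModelConfig()
    config.validate()
    if not ((train.y == 1).any() and (train.y == -1).any()):
        raise ModelError("training data must contain both classes")

    scale_min = train.X.min(axis=0)
    scale_range = train.X.max(axis=0) - scale_min
    scale_range[scale_range == 0] = 1.0
    Xs = (train.X - scale_min) / scale_range

    n_folds = min(config.cv_folds, len(np.unique(train.groups)))
    folds = _grouped_folds(train.groups, n_folds, config.seed)

    rows = []
    best = None
    oof_decision_best: np.ndarray | None = None
    for c in np.asarray(config.c_grid, dtype=float):
        for gamma in np.asarray(config.gamma_grid, dtype=float):
            oof = np.zeros(len(train.y))
            scores = []
            for k, val_idx in enumerate(folds):
                tr_idx = np.setdiff1d(np.arange(len(train.y)), val_idx)
                if not (
                    (train.y[tr_idx] == 1).any() and (train.y[tr_idx] == -1).any()
                ):
                    continue
                svc = _svc(c, gamma, config).fit(Xs[tr_idx], train.y[tr_idx])
                dec = svc.decision_function(Xs[val_idx])
                oof[val_idx] = dec
                scores.append(
                    _exact_hit_rate(dec, train.y[val_idx], train.groups[val_idx])
                )
            mean_score = float(np.mean(scores)) if scores else 0.0
            rows.append({"c": c, "gamma": gamma, "exact_hit": mean_score})
            if best is None or mean_score > best[0]:
                best = (mean_score, c, gamma)
                oof_decision_best = oof.copy()

    assert best is not None and oof_decision_best is not None
    _, c_star, gamma_star = best
    calib_a, calib_b = _fit_platt(oof_decision_best, train.y)

    final = _svc(c_star, gamma_star, config).fit(Xs, train.y)
    # sklearn stores dual_coef_ oriented so that positive decision values
    # favour classes_[1]; with labels {-1, +1}, classes_[1] == +1
    assert list(final.classes_) == [-1, 1]

    return TrainedModel(
        support_vectors=final.support_vectors_.copy(),
        dual_coef=final.dual_coef_.ravel().copy(),
        intercept=float(final.intercept_[0]),
        c=float(c_star),
        gamma=float(gamma_star),
        calib_a=calib_a,
        calib_b=calib_b,
        scale_min=scale_min,
        scale_range=scale_range,
        seed=config.seed,
        cv_report=pd.DataFrame(rows),
    )
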