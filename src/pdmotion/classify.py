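"""Classifier families for movement-category recognition.

Two families are provided, matching the study design:

* a one-hidden-layer neural network trained by error back-propagation, with
  the hidden-layer size rule ``n_hidden = ceil(n_in/2 + n_out)`` and a
  bipolar sigmoid activation, two outputs for the gait task ([1, 0]
  expected for gait) and four for hand movement;
* a soft-margin C-SVC with Gaussian kernel (defaults C = 62.5, gamma = 0.5
  in the ``exp(-||u-v||^2 / (2 gamma^2))`` parameterization), optionally
  tuned by exhaustive grid search, extended to multi-class by one-vs-all
  with calibrated-probability arbitration.

The hand classifier runs in cascade after the gait detector: only frames
not flagged as gait are analyzed for hand movement.

The printed activation ``beta (1 - e^{alpha x}) / (1 + e^{alpha x})`` is a
*decreasing* sigmoid (equal to ``-beta tanh(alpha x / 2)``); the default
uses the increasing ``tanh(alpha x / 2)`` form, functionally equivalent up
to weight signs, with the printed form behind ``mode="as_printed"``.
Likewise the printed Gaussian kernel omits the square on the distance; the
default ``standard`` mode computes ``exp(-gamma ||u - v||^2)`` — the
convention of the C-SVC implementations the study used (libSVM / OpenCV),
so that the published C and gamma values mean what they meant there — and
the literal printed form is behind ``kernel_mode="as_printed"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .preprocess import WindowedSession
from .recordings import GAIT_CLASS

__all__ = [
    "AnnConfig",
    "SvmConfig",
    "ClassifierModel",
    "hidden_layer_size",
    "activation",
    "train_ann",
    "rbf_kernel",
    "train_svm",
    "grid_search",
    "train_one_vs_all",
    "cascade_filter",
]


def hidden_layer_size(n_in: int, n_out: int) -> int:
    """``ceil(n_in / 2 + n_out)`` hidden neurons (rounded up for odd n_in)."""
    if n_in < 1 or n_out < 1:
        raise ValueError("layer sizes must be positive")
    return math.ceil(n_in / 2 + n_out)


def activation(x, mode: str = "default", alpha: float = 1.0, beta: float = 1.0):
    """Bipolar sigmoid; ``as_printed`` is its decreasing mirror image."""
    t = beta * np.tanh(alpha * np.asarray(x, dtype=float) / 2.0)
    return -t if mode == "as_printed" else t


@dataclass(frozen=True)
class AnnConfig:
    """One-hidden-layer back-propagation network settings."""

    n_out: int = 2
    alpha: float = 1.0
    beta: float = 1.0
    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 500
    seed: int = 0
    activation_mode: str = "default"  # "default" | "as_printed"


@dataclass(frozen=True)
class SvmConfig:
    """Soft-margin Gaussian-kernel C-SVC settings (defaults C=62.5, gamma=0.5)."""

    C: float = 62.5
    gamma: float = 0.5
    kernel_mode: str = "standard"  # "standard" | "as_printed"
    probability: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


def rbf_kernel(u, v, gamma: float, mode: str = "standard") -> float:
    """Gaussian kernel between two vectors.

    ``standard``: ``exp(-gamma ||u - v||^2)``, the libSVM/OpenCV convention
    under which the study's gamma = 0.5 was selected.  ``as_printed``: the
    literal published formula ``exp(-||u - v|| / (2 gamma^2))`` with the
    unsquared distance.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    d2 = float(np.sum((u - v) ** 2))
    if mode == "as_printed":
        return math.exp(-math.sqrt(d2) / (2.0 * gamma**2))
    return math.exp(-gamma * d2)


def _printed_kernel(gamma: float):
    def k(X, Y):
        return np.exp(-cdist(X, Y, metric="euclidean") / (2.0 * gamma**2))

    return k


def _make_svc(cfg: SvmConfig, probability: bool | None = None) -> SVC:
    prob = cfg.probability if probability is None else probability
    if cfg.kernel_mode == "as_printed":
        kernel = _printed_kernel(cfg.gamma)
        return SVC(C=cfg.C, kernel=kernel, probability=prob, random_state=cfg.seed)
    # sklearn's rbf kernel is exp(-gamma ||u-v||^2): gamma maps through as is
    return SVC(
        C=cfg.C,
        kernel="rbf",
        gamma=cfg.gamma,
        probability=prob,
        random_state=cfg.seed,
    )


def _fit_quietly(est: SVC, X, y) -> SVC:
    # SVC(probability=True) is deprecated in sklearn 1.9 but remains the
    # Platt-calibration mechanism libSVM exposes; keep it, silence the notice
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning)
        est.fit(X, y)
    return est


@dataclass
class ClassifierModel:
    """A trained classifier: predict() is total over layout-matching vectors."""

    kind: str  # "ann" | "svm" | "svm_ova"
    classes: list
    _predict_fn: object
    _proba_fn: object = None
    config: object = None
    normalizer: object = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.normalizer is not None:
            X = self.normalizer.transform(X)
        return self._predict_fn(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self._proba_fn is None:
            raise ValueError(f"{self.kind} model has no probability estimates")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.normalizer is not None:
            X = self.normalizer.transform(X)
        return self._proba_fn(X)


# ---------------------------------------------------------------------------
# neural network


def _check_training_set(X: np.ndarray, y: np.ndarray) -> None:
    if np.any(~np.isfinite(X)):
        raise ValueError("NaN or infinite values in training inputs")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: only one class present")


def train_ann(
    X: np.ndarray,
    y,
    cfg: AnnConfig | None = None,
    classes: list | None = None,
    normalizer=None,
) -> ClassifierModel:
    """Back-propagation training of the one-hidden-layer network.

    Targets are one-hot in {-1, +1} (the bipolar analogue of the [1, 0] /
    [0, 1] coding); the predicted class is the output neuron with the
    highest value.  Full-batch gradient descent with momentum, seeded
    uniform(-0.5, 0.5) weight initialization; bit-reproducible for a fixed
    (data, config, seed).
    """
    cfg = cfg or AnnConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_training_set(X, y)
    if classes is None:
        classes = sorted(np.unique(y).tolist())
    k = len(classes)
    if cfg.n_out != k:
        cfg = AnnConfig(
            n_out=k,
            alpha=cfg.alpha,
            beta=cfg.beta,
            learning_rate=cfg.learning_rate,
            momentum=cfg.momentum,
            epochs=cfg.epochs,
            seed=cfg.seed,
            activation_mode=cfg.activation_mode,
        )
    n, n_in = X.shape
    n_hid = hidden_layer_size(n_in, k)
    cls_index = {c: i for i, c in enumerate(classes)}
    T = -np.ones((n, k))
    for i, lab in enumerate(y):
        T[i, cls_index[lab]] = 1.0

    rng = np.random.default_rng(cfg.seed)
    W1 = rng.uniform(-0.5, 0.5, size=(n_in + 1, n_hid))
    W2 = rng.uniform(-0.5, 0.5, size=(n_hid + 1, k))
    V1 = np.zeros_like(W1)
    V2 = np.zeros_like(W2)
    sign = -1.0 if cfg.activation_mode == "as_printed" else 1.0
    a, b = cfg.alpha, cfg.beta

    Xb = np.hstack([X, np.ones((n, 1))])
    for _ in range(cfg.epochs):
        H = sign * b * np.tanh(a * (Xb @ W1) / 2.0)
        Hb = np.hstack([H, np.ones((n, 1))])
        O = sign * b * np.tanh(a * (Hb @ W2) / 2.0)
        err = O - T  # dMSE/dO (x2 folded into the rate)
        # f(z) = s*b*tanh(a z/2) => f'(z) = (a/(2 b)) * (b^2 - (O/s)^2) * s
        dO = err * (a / (2.0 * b)) * (b**2 - (O / sign) ** 2) * sign
        gW2 = Hb.T @ dO / n
        dH = (dO @ W2[:-1].T) * (a / (2.0 * b)) * (b**2 - (H / sign) ** 2) * sign
        gW1 = Xb.T @ dH / n
        V2 = cfg.momentum * V2 - cfg.learning_rate * gW2
        V1 = cfg.momentum * V1 - cfg.learning_rate * gW1
        W2 = W2 + V2
        W1 = W1 + V1

    classes_arr = np.asarray(classes, dtype=object)

    def forward(Xq: np.ndarray) -> np.ndarray:
        Xq = np.hstack([Xq, np.ones((len(Xq), 1))])
        H = sign * b * np.tanh(a * (Xq @ W1) / 2.0)
        Hb = np.hstack([H, np.ones((len(H), 1))])
        return sign * b * np.tanh(a * (Hb @ W2) / 2.0)

    def predict(Xq: np.ndarray) -> np.ndarray:
        return classes_arr[np.argmax(forward(Xq), axis=1)]

    model = ClassifierModel(
        kind="ann",
        classes=list(classes),
        _predict_fn=predict,
        _proba_fn=None,
        config=cfg,
        normalizer=normalizer,
    )
    model.weights = (W1, W2)  # exposed for reproducibility checks
    model.n_hidden = n_hid
    return model


# ---------------------------------------------------------------------------
# support vector machines


def train_svm(
    X: np.ndarray, y, cfg: SvmConfig | None = None, normalizer=None
) -> ClassifierModel:
    """Train a binary (or multiclass-by-libSVM) soft-margin kernel C-SVC."""
    cfg = cfg or SvmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_training_set(X, y)
    est = _fit_quietly(_make_svc(cfg), X, y)
    model = ClassifierModel(
        kind="svm",
        classes=est.classes_.tolist(),
        _predict_fn=est.predict,
        _proba_fn=est.predict_proba if cfg.probability else None,
        config=cfg,
        normalizer=normalizer,
    )
    model.estimator = est
    return model


def grid_search(
    X: np.ndarray,
    y,
    C_grid=None,
    gamma_grid=None,
    folds: int = 5,
    seed: int = 0,
    kernel_mode: str = "standard",
) -> tuple[float, float]:
    """Exhaustive (C, gamma) search by internal cross-validated accuracy.

    Default net: C in 2^-5..2^15, gamma in 2^-15..2^3 (odd powers of two),
    the customary grid for this algorithm family.  Ties break toward
    smaller C, then smaller gamma; the result is independent of the order
    the grids are supplied in.
    """
    if C_grid is None:
        C_grid = [2.0**p for p in range(-5, 16, 2)]
    if gamma_grid is None:
        gamma_grid = [2.0**p for p in range(-15, 4, 2)]
    C_grid = sorted(C_grid)
    gamma_grid = sorted(gamma_grid)
    if not C_grid or not gamma_grid:
        raise ValueError("grids must be non-empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_training_set(X, y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = None
    best_acc = -1.0
    for C in C_grid:
        for gamma in gamma_grid:
            cfg = SvmConfig(C=C, gamma=gamma, kernel_mode=kernel_mode, seed=seed)
            accs = []
            for tr, te in splits:
                est = _fit_quietly(_make_svc(cfg, probability=False), X[tr], y[tr])
                accs.append(float(np.mean(est.predict(X[te]) == y[te])))
            acc = float(np.mean(accs))
            if acc > best_acc:  # strict: earliest (smallest C, gamma) wins ties
                best_acc = acc
                best = (C, gamma)
    return best


def train_one_vs_all(
    X: np.ndarray,
    y,
    cfg: SvmConfig | None = None,
    classes: list | None = None,
    normalizer=None,
) -> ClassifierModel:
    """One binary machine per class; argmax of calibrated class probability.

    Each machine separates one class from the rest; at prediction time the
    class whose machine reports the highest probability wins (first class in
    the vocabulary order on exact ties).
    """
    cfg = cfg or SvmConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_training_set(X, y)
    if classes is None:
        classes = sorted(np.unique(y).tolist())
    machines = []
    for cls in classes:
        mask = y == cls
        if int(mask.sum()) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 training examples")
        est = _fit_quietly(_make_svc(cfg, probability=True), X, np.where(mask, 1, -1))
        pos_col = int(np.where(est.classes_ == 1)[0][0])
        machines.append((est, pos_col))

    classes_arr = np.asarray(classes, dtype=object)

    def proba(Xq: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [est.predict_proba(Xq)[:, col] for est, col in machines]
        )

    def predict(Xq: np.ndarray) -> np.ndarray:
        return classes_arr[np.argmax(proba(Xq), axis=1)]

    model = ClassifierModel(
        kind="svm_ova",
        classes=list(classes),
        _predict_fn=predict,
        _proba_fn=proba,
        config=cfg,
        normalizer=normalizer,
    )
    model.machines = machines
    return model


# ---------------------------------------------------------------------------
# gait -> hand cascade


def cascade_filter(
    gait_windowed: WindowedSession,
    gait_predictions,
    hand_windowed: WindowedSession,
) -> np.ndarray:
    """Boolean mask of hand frames eligible for hand-movement analysis.

    A hand frame is excluded when its half-open time span overlaps any
    gait-task frame that the gait detector labeled as gait.
    """
    preds = np.asarray(gait_predictions)
    if len(preds) != gait_windowed.n_frames:
        raise ValueError("one gait prediction per gait frame required")
    gait_spans = gait_windowed.frame_spans()[preds == GAIT_CLASS]
    hand_spans = hand_windowed.frame_spans()
    if len(gait_spans) == 0:
        return np.ones(len(hand_spans), dtype=bool)
    # overlap of half-open intervals: h_start < g_end and g_start < h_end
    overlaps = (hand_spans[:, None, 0] < gait_spans[None, :, 1]) & (
        gait_spans[None, :, 0] < hand_spans[:, None, 1]
    )
    return ~overlaps.any(axis=1)
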