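"""Glucose-class prediction from raw acoustic spectra.

Builds the observations x features matrix (one row per sweep, one column
per frequency bin, raw amplitudes with no scaling or preprocessing) and
evaluates two classifiers with seeded 10-fold cross-validation and a
holdout protocol:

* a k-nearest-neighbour classifier (default k = 1, Euclidean distance), and
* a "wide" neural network: a single fully connected hidden layer of 100
  rectified-linear units with a softmax/cross-entropy readout.

With 6 observations per class and 10 folds, exact stratification is
impossible; folds are filled round-robin per class after a seeded shuffle,
so fold sizes differ by at most one and every class is spread as evenly as
the counts allow.  Fold assignments are kept in the report for audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .synth import SpectrumDataset

__all__ = [
    "FeatureMatrix",
    "ClassificationReport",
    "KNNConfig",
    "WideNetConfig",
    "build_feature_matrix",
    "knn_predict",
    "wide_net_fit_predict",
    "stratified_folds",
    "cross_validate",
    "holdout_evaluate",
    "macro_f1",
    "make_classifier",
]


@dataclass
class FeatureMatrix:
    """Raw spectral feature matrix: rows are sweeps, columns frequency bins."""

    X: np.ndarray
    y: np.ndarray
    row_meta: list[tuple[int, int]]  # (day, round) per row

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X rows and y length must agree")

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)


def build_feature_matrix(dataset: SpectrumDataset) -> FeatureMatrix:
    """Stack phantom sweeps into the raw feature matrix.

    Row order follows the acquisition plan (day-major, then class, then
    round); amplitudes enter unscaled and unrectified.
    """
    phantoms = dataset.phantoms()
    if not phantoms:
        raise ValueError("dataset contains no phantom spectra")
    grid = phantoms[0].grid
    if any(sp.grid != grid for sp in phantoms):
        raise ValueError("all spectra must share one frequency grid")
    X = np.vstack([sp.amplitudes_uv for sp in phantoms])
    y = np.array([sp.glucose_mgdl for sp in phantoms])
    meta = [(sp.day, sp.round_idx) for sp in phantoms]
    return FeatureMatrix(X=X, y=y, row_meta=meta)


# ---------------------------------------------------------------------------
# classifiers


@dataclass(frozen=True)
class KNNConfig:
    """k-nearest-neighbour settings (k = 1, Euclidean, as used here)."""

    k: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class WideNetConfig:
    """Wide-network settings.

    One hidden layer of ``hidden_units`` rectified-linear neurons trained by
    L-BFGS on the cross-entropy objective with L2 penalty ``alpha`` and a
    cap of ``max_epochs`` iterations (the optimiser stops earlier on a
    training-loss plateau).  The net consumes the raw amplitude features
    (``standardize = False``): on lock-in spectra the informative variation
    lives in the high-amplitude resonance bins, and per-feature z-scoring
    would inflate the noise-floor bins to equal weight.  ``seed`` fixes the
    initialisation.
    """

    hidden_units: int = 100
    activation: str = "relu"
    alpha: float = 1e-4
    max_epochs: int = 1000
    standardize: bool = False
    seed: int = 0


def knn_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    query_X: np.ndarray,
    k: int = 1,
) -> np.ndarray:
    """Label queries by majority vote among the k nearest training rows.

    Euclidean distance; distance ties resolve to the lowest training-row
    index (stable sort), and vote ties to the smallest label.  ``k = 1``
    reduces to the nearest row's label.
    """
    train_X = np.asarray(train_X, dtype=float)
    train_y = np.asarray(train_y)
    query_X = np.atleast_2d(np.asarray(query_X, dtype=float))
    if train_X.size == 0:
        raise ValueError("empty training set")
    if k < 1:
        raise ValueError("k must be >= 1")
    d = cdist(query_X, train_X)
    if k == 1:
        return train_y[np.argmin(d, axis=1)]
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    out = []
    for row in order:
        labels, counts = np.unique(train_y[row], return_counts=True)
        out.append(labels[np.argmax(counts)])  # ties -> smallest label
    return np.array(out)


def wide_net_fit_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    query_X: np.ndarray,
    config: WideNetConfig | None = None,
) -> np.ndarray:
    """Train the wide network on the training rows and label the queries."""
    cfg = config or WideNetConfig()
    train_X = np.asarray(train_X, dtype=float)
    query_X = np.atleast_2d(np.asarray(query_X, dtype=float))
    if not (np.all(np.isfinite(train_X)) and np.all(np.isfinite(query_X))):
        raise ValueError("non-finite values in input matrices")
    if cfg.standardize:
        mu = train_X.mean(axis=0)
        sd = train_X.std(axis=0)
        sd[sd == 0] = 1.0
        train_X = (train_X - mu) / sd
        query_X = (query_X - mu) / sd
    net = MLPClassifier(
        hidden_layer_sizes=(cfg.hidden_units,),
        activation=cfg.activation,
        solver="lbfgs",
        alpha=cfg.alpha,
        max_iter=cfg.max_epochs,
        random_state=cfg.seed % (2**31),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(train_X, np.asarray(train_y))
    return net.predict(query_X)


def make_classifier(classifier_config: KNNConfig | WideNetConfig):
    """Return a ``fit_predict(train_X, train_y, query_X)`` callable."""
    if isinstance(classifier_config, KNNConfig):
        return lambda tx, ty, qx: knn_predict(tx, ty, qx, k=classifier_config.k)
    if isinstance(classifier_config, WideNetConfig):
        return lambda tx, ty, qx: wide_net_fit_predict(tx, ty, qx, classifier_config)
    if callable(classifier_config):  # e.g. an oracle in tests
        return classifier_config
    raise TypeError(f"unsupported classifier config {classifier_config!r}")


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ClassificationReport:
    """Pooled evaluation of a classifier: confusion matrix and metrics."""

    confusion: np.ndarray
    classes: np.ndarray
    accuracy: float  # percent
    f1_macro: float  # percent
    fold_assignments: np.ndarray | None
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def n_evaluated(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.astype(int).tolist(),
            "classes": [float(c) for c in self.classes],
            "accuracy": self.accuracy,
            "f1_macro": self.f1_macro,
            "fold_assignments": (
                None
                if self.fold_assignments is None
                else self.fold_assignments.astype(int).tolist()
            ),
            "seed": self.seed,
            "config": self.config,
        }

    def summary(self) -> str:
        lines = [
            "Classification report",
            "=" * 48,
            f"  observations evaluated: {self.n_evaluated}",
            f"  accuracy:               {self.accuracy:.1f} %",
            f"  macro F1:               {self.f1_macro:.1f} %",
            f"  seed:                   {self.seed}",
            "=" * 48,
        ]
        return "\n".join(lines)


def macro_f1(confusion: np.ndarray) -> float:
    """Unweighted mean per-class F1 from a confusion matrix, in percent.

    Classes with neither true nor predicted instances are excluded; a class
    with instances but no true positives scores 0.
    """
    conf = np.asarray(confusion, dtype=float)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    if conf.sum() == 0:
        raise ValueError("confusion matrix has no counts")
    tp = np.diag(conf)
    true_tot = conf.sum(axis=1)
    pred_tot = conf.sum(axis=0)
    f1s = []
    for i in range(conf.shape[0]):
        if true_tot[i] == 0 and pred_tot[i] == 0:
            continue
        denom = true_tot[i] + pred_tot[i]
        f1s.append(2.0 * tp[i] / denom if denom > 0 else 0.0)
    return 100.0 * float(np.mean(f1s))


def _confusion(classes: np.ndarray, true: np.ndarray, pred: np.ndarray) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((classes.size, classes.size), dtype=int)
    for t, p in zip(true, pred):
        conf[index[t], index[p]] += 1
    return conf


def stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Per-class round-robin fold assignment after a seeded shuffle.

    A running pointer deals each class's shuffled observations into
    consecutive folds, so fold sizes differ by at most one and classes are
    spread as evenly as their counts allow.
    """
    y = np.asarray(y)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > y.size:
        raise ValueError(f"n_folds ({n_folds}) exceeds observations ({y.size})")
    rng = np.random.default_rng(seed)
    fold = np.empty(y.size, dtype=int)
    pointer = 0
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        for i in idx:
            fold[i] = pointer % n_folds
            pointer += 1
    return fold


def cross_validate(
    matrix: FeatureMatrix,
    classifier_config,
    n_folds: int = 10,
    seed: int = 0,
) -> ClassificationReport:
    """Seeded k-fold cross-validation with pooled out-of-fold predictions."""
    classes = matrix.classes
    counts = np.array([(matrix.y == c).sum() for c in classes])
    if np.any(counts < 1):
        raise ValueError("every class needs at least one observation")
    fold = stratified_folds(matrix.y, n_folds, seed)
    fit_predict = make_classifier(classifier_config)
    pred = np.empty_like(matrix.y)
    for f in range(n_folds):
        test = fold == f
        if not np.any(test):
            continue
        pred[test] = fit_predict(matrix.X[~test], matrix.y[~test], matrix.X[test])
    conf = _confusion(classes, matrix.y, pred)
    return ClassificationReport(
        confusion=conf,
        classes=classes,
        accuracy=100.0 * np.trace(conf) / conf.sum(),
        f1_macro=macro_f1(conf),
        fold_assignments=fold,
        seed=seed,
        config=_config_dict(classifier_config, n_folds=n_folds),
    )


def holdout_evaluate(
    matrix: FeatureMatrix,
    classifier_config,
    holdout: str | float = "one-per-class",
    seed: int = 0,
) -> ClassificationReport:
    """Train on the retained rows, report on the held-out rows only.

    ``holdout`` is either ``"one-per-class"`` (one seeded pick per class) or
    a fraction in (0, 1).  The holdout is removed before any training.
    """
    rng = np.random.default_rng(seed)
    n = matrix.n_obs
    if holdout == "one-per-class":
        held = np.array(
            [rng.choice(np.where(matrix.y == c)[0]) for c in matrix.classes]
        )
    else:
        frac = float(holdout)
        if not 0 < frac < 1:
            raise ValueError("holdout fraction must be in (0, 1)")
        n_held = max(1, int(round(frac * n)))
        held = rng.choice(n, size=n_held, replace=False)
    mask = np.zeros(n, dtype=bool)
    mask[held] = True
    train_classes = np.unique(matrix.y[~mask])
    if train_classes.size < matrix.classes.size:
        raise ValueError("holdout would leave a class with no training data")
    fit_predict = make_classifier(classifier_config)
    pred = fit_predict(matrix.X[~mask], matrix.y[~mask], matrix.X[mask])
    conf = _confusion(matrix.classes, matrix.y[mask], pred)
    return ClassificationReport(
        confusion=conf,
        classes=matrix.classes,
        accuracy=100.0 * np.trace(conf) / conf.sum(),
        f1_macro=macro_f1(conf),
        fold_assignments=None,
        seed=seed,
        config=_config_dict(classifier_config, holdout=str(holdout)),
    )


def _config_dict(classifier_config, **extra) -> dict:
    if isinstance(classifier_config, (KNNConfig, WideNetConfig)):
        d = {"classifier": type(classifier_config).__name__, **asdict(classifier_config)}
    else:
        d = {"classifier": getattr(classifier_config, "__name__", "custom")}
    d.update(extra)
    return d
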