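"""Classifiers on raw or encoded trials, baselines, and significance tests.

Three classifier families operate on single-trial features:

* a linear max-margin classifier (SVC) with the trade-off parameter ``C``
  selected by validation accuracy over a grid,
* a bias-free temporal neural-network classifier: one weight pattern per
  class applied to the encoded waveform, trained with a multi-class hinge
  loss (softmax is applied only when reporting activations — prediction is
  the argmax of the linear scores either way, and hinge on softmax outputs
  is ill-conditioned),
* a dummy classifier that derives group or meter labels from predicted
  stimulus labels via the stimulus table.

Statistical machinery: the exact-binomial chance threshold (the lowest
accuracy that is unlikely at level alpha under guessing) and the mid-p
variant of McNemar's test for comparing paired classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.svm import LinearSVC

from .core import StimulusMeta

__all__ = [
    "MarginClassifier",
    "TemporalClassifier",
    "NnHyper",
    "ConfusionMatrix",
    "fit_margin_classifier",
    "fit_temporal_nn",
    "average_temporal_classifiers",
    "baseline_channel_mean",
    "dummy_group_from_stimulus",
    "binomial_chance_threshold",
    "mcnemar_midp",
    "evaluate",
]

DEFAULT_C_GRID = tuple(10.0**k for k in range(-3, 4))


@dataclass
class ConfusionMatrix:
    labels: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square with one row per label")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


@dataclass
class MarginClassifier:
    """Fitted linear SVC plus the C value selected on validation data."""

    model: LinearSVC
    c_value: float
    c_scores: dict[float, float]

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(features))


def fit_margin_classifier(
    features: np.ndarray,
    labels: Sequence,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    validation: tuple[np.ndarray, Sequence] | None = None,
) -> MarginClassifier:
    """Linear max-margin classifier with grid-searched C.

    ``validation=(X_val, y_val)`` supplies the held-out data whose accuracy
    drives the C selection (ties break toward the smaller, i.e. more
    regularized, C).  Without validation data, training accuracy is used.
    Deterministic given the data and grid.
    """
    features = np.asarray(features)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two classes")
    if validation is None:
        x_val, y_val = features, labels
    else:
        x_val, y_val = np.asarray(validation[0]), np.asarray(validation[1])
    best = None
    scores: dict[float, float] = {}
    for c in c_grid:
        model = LinearSVC(C=c, dual=False)
        model.fit(features, labels)
        acc = float(np.mean(model.predict(x_val) == y_val))
        scores[float(c)] = acc
        if best is None or acc > best[0]:
            best = (acc, float(c), model)
    _, c_value, model = best
    return MarginClassifier(model=model, c_value=c_value, c_scores=scores)


@dataclass
class TemporalClassifier:
    """One temporal weight pattern per class, applied to encoded waveforms."""

    class_labels: list
    weights: np.ndarray  # (n_classes, n_samples)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != len(self.class_labels):
            raise ValueError("one weight row per class required")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    def scores(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features))
        if features.shape[1] != self.weights.shape[1]:
            raise ValueError("feature length does not match classifier patterns")
        return features @ self.weights.T

    def softmax(self, features: np.ndarray) -> np.ndarray:
        """Class activations for reporting; does not change the argmax."""
        s = self.scores(features)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, features: np.ndarray) -> np.ndarray:
        idx = np.argmax(self.scores(features), axis=1)
        return np.asarray(self.class_labels)[idx]


@dataclass
class NnHyper:
    """Protocol hyperparameters for the temporal classifier: 100 epochs of
    SGD with batch size 120, Adam step rule, hinge loss."""

    epochs: int = 100
    batch_size: int = 120
    learning_rate: float = 1e-3
    margin: float = 1.0
    init_scale: float = 0.01
    seed: int = 0


def fit_temporal_nn(
    features: np.ndarray,
    labels: Sequence,
    hyper: NnHyper | None = None,
    validation: tuple[np.ndarray, Sequence] | None = None,
) -> TemporalClassifier:
    """Train the bias-free temporal classifier with a multi-class hinge loss.

    ``features`` is an (n, samples) array of encoded waveforms.  The loss per
    sample is ``max(0, margin + max_{j != y} s_j - s_y)`` on the linear class
    scores.  If validation data are given, the epoch snapshot with the best
    validation accuracy is returned; otherwise the final weights.  With
    ``epochs=0`` the initialization is returned unchanged.
    """
    hyper = hyper or NnHyper()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    class_idx = np.searchsorted(np.asarray(classes), labels)
    n, t = features.shape
    k = len(classes)
    rng = np.random.default_rng(hyper.seed)
    w = rng.uniform(-hyper.init_scale, hyper.init_scale, size=(k, t))
    m = np.zeros_like(w)
    v = np.zeros_like(w)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_w = w.copy()
    best_acc = -np.inf
    for _epoch in range(hyper.epochs):
        order = rng.permutation(n)
        for start in range(0, n, hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            x = features[idx]
            y = class_idx[idx]
            s = x @ w.T  # (b, k)
            s_true = s[np.arange(len(idx)), y]
            s_rival = s.copy()
            s_rival[np.arange(len(idx)), y] = -np.inf
            rival = np.argmax(s_rival, axis=1)
            viol = hyper.margin + s_rival[np.arange(len(idx)), rival] - s_true > 0
            grad = np.zeros_like(w)
            if viol.any():
                xv = x[viol]
                np.add.at(grad, rival[viol], xv)
                np.add.at(grad, y[viol], -xv)
                grad /= len(idx)
            step += 1
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad**2
            w = w - hyper.learning_rate * (m / (1 - beta1**step)) / (
                np.sqrt(v / (1 - beta2**step)) + eps
            )
        if validation is not None:
            clf = TemporalClassifier(classes, w)
            acc = float(np.mean(clf.predict(validation[0]) == np.asarray(validation[1])))
            if acc > best_acc:
                best_acc = acc
                best_w = w.copy()
    if validation is None or hyper.epochs == 0:
        best_w = w
    return TemporalClassifier(classes, best_w)


def average_temporal_classifiers(models: Sequence[TemporalClassifier]) -> TemporalClassifier:
    """Element-wise mean of fold models (labels must agree)."""
    models = list(models)
    if not models:
        raise ValueError("need at least one model")
    labels = models[0].class_labels
    for mdl in models[1:]:
        if mdl.class_labels != labels:
            raise ValueError("fold models must share class labels")
    return TemporalClassifier(labels, np.mean([mdl.weights for mdl in models], axis=0))


def baseline_channel_mean(trial) -> np.ndarray:
    """Naive spatial filter: arithmetic mean over channels per sample."""
    from .core import Trial

    data = trial.data if isinstance(trial, Trial) else np.asarray(trial)
    return data.mean(axis=0)


def dummy_group_from_stimulus(
    stim_predictions: Sequence[int],
    stimuli_table: Mapping[int, StimulusMeta],
    task: str,
) -> np.ndarray:
    """Map predicted stimulus ids to group or meter labels."""
    if task not in ("group", "meter"):
        raise ValueError("task must be 'group' or 'meter'")
    out = []
    for sid in stim_predictions:
        meta = stimuli_table[int(sid)]
        out.append(meta.group if task == "group" else meta.meter)
    return np.asarray(out)


def binomial_chance_threshold(n_trials: int, p0: float, alpha: float) -> float:
    """Smallest accuracy (in percent) unlikely under chance guessing.

    Returns ``100 * k / n`` for the smallest correct count ``k`` whose exact
    binomial CDF satisfies ``CDF(k; n, p0) >= 1 - alpha``: an observed
    accuracy at or above this value has probability < alpha under the
    chance rate ``p0``.
    """
    if not (0 < p0 < 1 and 0 < alpha < 1 and n_trials >= 1):
        raise ValueError("require 0<p0<1, 0<alpha<1, n>=1")
    k = int(binom.ppf(1 - alpha, n_trials, p0))
    while binom.cdf(k, n_trials, p0) < 1 - alpha:
        k += 1
    while k > 0 and binom.cdf(k - 1, n_trials, p0) >= 1 - alpha:
        k -= 1
    return 100.0 * k / n_trials


def mcnemar_midp(b: int, c: int) -> float:
    """Mid-p McNemar test on the discordant-pair counts of two classifiers.

    ``b`` and ``c`` count trials where exactly one of the two classifiers is
    correct.  Under the null both directions are equally likely, so the
    larger count is referred to Binomial(b + c, 1/2):
    ``midp = 2 * P(X >= max(b, c)) - P(X = max(b, c))``, capped at 1.
    Returns 1.0 when there are no discordant pairs.
    """
    if b < 0 or c < 0:
        raise ValueError("counts must be nonnegative")
    n = b + c
    if n == 0:
        return 1.0
    k = max(b, c)
    p = 2.0 * binom.sf(k - 1, n, 0.5) - binom.pmf(k, n, 0.5)
    return float(min(1.0, p))


def evaluate(predictions: Sequence, truth: Sequence, labels: Sequence | None = None):
    """Accuracy and confusion matrix (rows: truth, columns: prediction)."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    if labels is None:
        labels = sorted(set(truth.tolist()) | set(predictions.tolist()))
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(truth, predictions):
        counts[index[t], index[p]] += 1
    accuracy = float(np.trace(counts) / counts.sum()) if counts.sum() else 0.0
    return accuracy, ConfusionMatrix(labels, counts)
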