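"""Similarity-constraint encoding: learning a spatial EEG filter from triplets.

The encoder is a single spatial filter ``w`` (one weight per channel, no
bias) followed by a tanh nonlinearity: a trial ``X`` (channels x samples)
is aggregated into the waveform ``y_t = tanh(w . x_t)``.  Similarity
between two encoded trials is their dot product over time.  Training
minimizes the triplet hinge loss

    L(a, b, c) = max(0, margin - (s(a, b) - s(a, c)))

over mini-batches of relative-similarity triplets with the Adam step rule;
a triplet is counted correct iff ``s(a, b) > s(a, c)`` (ties count as
incorrect).  After the fixed number of epochs, the epoch snapshot with the
lowest binary error on the validation triplets is returned.

The model is tiny (64 parameters), so gradients are computed analytically;
no autodiff framework is involved.  For an active triplet the gradient of
the loss with respect to ``w`` is

    dL/dw = -[ X_a ((1 - y_a^2) * (y_b - y_c))
             + X_b ((1 - y_b^2) * y_a)
             - X_c ((1 - y_c^2) * y_a) ].

Because learned filters are sign-ambiguous (flipping ``w`` flips the encoded
waveform but leaves every similarity comparison unchanged), filters are
polarity-normalized on channel T7 — which empirically carries a large
weight — before averaging across folds, so that averaging does not cancel
equivalent solutions of opposite sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import ChannelMontage, Trial, TrialSet

__all__ = [
    "SpatialFilter",
    "SceHyper",
    "ForwardModel",
    "encode",
    "similarity",
    "triplet_hinge_loss",
    "pretrain_sce",
    "triplet_error",
    "normalize_polarity",
    "average_filters",
    "fit_forward_model",
    "save_filter",
    "load_filter",
]


@dataclass(frozen=True)
class SpatialFilter:
    """Per-channel weights of the learned encoder (no bias term)."""

    weights: np.ndarray
    montage: ChannelMontage | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float).ravel()
        object.__setattr__(self, "weights", w)
        if not np.all(np.isfinite(w)):
            raise ValueError("filter weights must be finite")
        if self.montage is not None and self.montage.size != w.size:
            raise ValueError("filter size does not match montage")


@dataclass(frozen=True)
class ForwardModel:
    """Channel-space pattern explaining how the encoded component appears
    in the measured EEG (one coefficient per channel)."""

    pattern: np.ndarray
    montage: ChannelMontage | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pattern, dtype=float).ravel()
        object.__setattr__(self, "pattern", p)
        if not np.all(np.isfinite(p)):
            raise ValueError("pattern must be finite")


@dataclass
class SceHyper:
    """Training hyperparameters for similarity-constraint encoding.

    The batch size (1000 triplets), step rule (Adam) and epoch budget (10)
    are fixed protocol choices; learning rate, hinge margin, and the
    initialization scale are open parameters with conventional defaults.
    """

    margin: float = 1.0
    batch_size: int = 1000
    max_epochs: int = 10
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    init_scale: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 0 or self.batch_size <= 0 or self.max_epochs < 0:
            raise ValueError("hyperparameters must be positive")
        if self.learning_rate < 0 or self.init_scale < 0 or self.weight_decay < 0:
            raise ValueError("learning_rate, init_scale, weight_decay must be >= 0")


def _as_stack(trials) -> np.ndarray:
    """TrialSet / list of Trial / ndarray -> (n, channels, samples) array."""
    if isinstance(trials, TrialSet):
        return trials.data_stack()
    if isinstance(trials, np.ndarray):
        if trials.ndim != 3:
            raise ValueError("trial stack must be (n, channels, samples)")
        return trials
    return np.stack([t.data if isinstance(t, Trial) else np.asarray(t) for t in trials])


def encode(trial, f: SpatialFilter) -> np.ndarray:
    """Encode a trial into a single waveform: ``y_t = tanh(w . x_t)``."""
    x = trial.data if isinstance(trial, Trial) else np.asarray(trial, dtype=float)
    if x.shape[0] != f.weights.size:
        raise ValueError(f"trial has {x.shape[0]} channels, filter has {f.weights.size}")
    return np.tanh(f.weights @ x)


def similarity(p: np.ndarray, q: np.ndarray) -> float:
    """Dot-product similarity of two encoded waveforms."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("encoded series must have equal length")
    return float(p @ q)


def triplet_hinge_loss(s_ab: float, s_ac: float, margin: float = 1.0):
    """Hinge loss ``max(0, margin - (s_ab - s_ac))``; broadcasts."""
    return np.maximum(0.0, margin - (np.asarray(s_ab) - np.asarray(s_ac)))


def _encode_all(w: np.ndarray, stack: np.ndarray) -> np.ndarray:
    return np.tanh(np.einsum("c,ncs->ns", w, stack))


def triplet_error(w_or_filter, trials, triplets: np.ndarray) -> float:
    """Fraction of triplets with ``s(a,b) <= s(a,c)`` (ties incorrect)."""
    w = w_or_filter.weights if isinstance(w_or_filter, SpatialFilter) else np.asarray(w_or_filter)
    stack = _as_stack(trials)
    y = _encode_all(w, stack)
    s_ab = np.einsum("nt,nt->n", y[triplets[:, 0]], y[triplets[:, 1]])
    s_ac = np.einsum("nt,nt->n", y[triplets[:, 0]], y[triplets[:, 2]])
    return float(np.mean(s_ab <= s_ac))


def _batch_grad(
    w: np.ndarray, stack: np.ndarray, batch: np.ndarray, margin: float
) -> tuple[float, np.ndarray]:
    """Mean hinge loss and its gradient for one triplet mini-batch."""
    y = _encode_all(w, stack)
    a, b, c = batch[:, 0], batch[:, 1], batch[:, 2]
    s_ab = np.einsum("nt,nt->n", y[a], y[b])
    s_ac = np.einsum("nt,nt->n", y[a], y[c])
    losses = np.maximum(0.0, margin - (s_ab - s_ac))
    active = losses > 0
    n_batch = batch.shape[0]
    if not np.any(active):
        return float(losses.mean()), np.zeros_like(w)
    a, b, c = a[active], b[active], c[active]
    dtanh = 1.0 - y**2
    # accumulate per-trial "output side" vectors v_i with dL/dw = sum_i X_i v_i
    v = np.zeros_like(y)
    np.add.at(v, a, -dtanh[a] * (y[b] - y[c]))
    np.add.at(v, b, -dtanh[b] * y[a])
    np.add.at(v, c, dtanh[c] * y[a])
    grad = np.einsum("ics,is->c", stack, v) / n_batch
    return float(losses.mean()), grad


def pretrain_sce(
    train_triplets: np.ndarray,
    val_triplets: np.ndarray,
    trials,
    hyper: SceHyper | None = None,
    montage: ChannelMontage | None = None,
    init: np.ndarray | None = None,
) -> tuple[SpatialFilter, dict]:
    """Train the spatial-filter encoder on relative-similarity triplets.

    ``trials`` is a TrialSet or an (n, channels, samples) stack; triplet
    entries index into it.  Training runs ``max_epochs`` epochs of shuffled
    mini-batches with Adam; after each epoch the binary error on the
    validation triplets is evaluated and the best epoch snapshot is
    returned.  Deterministic under a fixed ``hyper.seed``.

    Returns the selected filter and a history dict with per-epoch training
    loss and validation error.
    """
    hyper = hyper or SceHyper()
    if train_triplets.size == 0 or val_triplets.size == 0:
        raise ValueError("triplet sets must be non-empty")
    stack = _as_stack(trials)
    if isinstance(trials, TrialSet) and montage is None:
        montage = trials.montage
    n_ch = stack.shape[1]
    rng = np.random.default_rng(hyper.seed)
    w = (
        np.array(init, dtype=float).ravel().copy()
        if init is not None
        else rng.uniform(-hyper.init_scale, hyper.init_scale, size=n_ch)
    )
    # Adam state
    m = np.zeros_like(w)
    v = np.zeros_like(w)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_w = w.copy()
    best_err = np.inf
    history = {"train_loss": [], "val_error": []}
    for _epoch in range(hyper.max_epochs):
        order = rng.permutation(train_triplets.shape[0])
        epoch_losses = []
        for start in range(0, order.size, hyper.batch_size):
            batch = train_triplets[order[start : start + hyper.batch_size]]
            loss, grad = _batch_grad(w, stack, batch, hyper.margin)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss; reduce the learning rate")
            epoch_losses.append(loss)
            if hyper.weight_decay > 0:
                # L2 penalty keeps the stationary filter proportional to the
                # data-driven gradient; without it, adaptive per-coordinate
                # steps converge to a sign-like geometry that discards the
                # relative weight magnitudes
                grad = grad + hyper.weight_decay * w
            step += 1
            m = beta1 * m + (1 - beta1) * grad
            v = beta2 * v + (1 - beta2) * grad**2
            m_hat = m / (1 - beta1**step)
            v_hat = v / (1 - beta2**step)
            w = w - hyper.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        err = triplet_error(w, stack, val_triplets)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_error"].append(err)
        # ties prefer the later snapshot: at equal validation error the
        # longer-trained filter is kept
        if err <= best_err:
            best_err = err
            best_w = w.copy()
    if hyper.max_epochs == 0:
        best_w = w.copy()
    return SpatialFilter(best_w, montage), history


def normalize_polarity(f: SpatialFilter, montage: ChannelMontage | None = None) -> SpatialFilter:
    """Flip the filter sign iff the weight of channel T7 is negative.

    The encoder is sign-ambiguous; anchoring the polarity on T7 (which
    carries a consistently large weight) prevents cancellation when
    averaging filters across folds.  A zero T7 weight leaves the filter
    unchanged.
    """
    montage = montage or f.montage
    if montage is None:
        raise ValueError("a montage is required to locate channel T7")
    idx = montage.index_of("T7")
    if f.weights[idx] < 0:
        return SpatialFilter(-f.weights, montage)
    return SpatialFilter(f.weights.copy(), montage)


def average_filters(filters: Sequence[SpatialFilter]) -> SpatialFilter:
    """Element-wise mean of (polarity-normalized) filters."""
    filters = list(filters)
    if not filters:
        raise ValueError("need at least one filter to average")
    w = np.mean([f.weights for f in filters], axis=0)
    return SpatialFilter(w, filters[0].montage)


def fit_forward_model(trials, f: SpatialFilter) -> ForwardModel:
    """Recover the forward (generative) pattern of the encoded component.

    For each channel, the least-squares coefficient of the channel signal on
    the encoder output, pooled over all trials' samples:
    ``pattern_ch = cov(x_ch, y) / var(y)``.  Unlike the backward filter
    weights, this pattern is interpretable in terms of how the extracted
    component projects to the scalp.
    """
    stack = _as_stack(trials)
    y = _encode_all(f.weights, stack)  # (n, t)
    y_flat = y.ravel()
    y_c = y_flat - y_flat.mean()
    var = float(y_c @ y_c)
    if var <= 0:
        raise ValueError("encoder output is constant; forward model undefined")
    x_flat = np.swapaxes(stack, 0, 1).reshape(stack.shape[1], -1)
    x_c = x_flat - x_flat.mean(axis=1, keepdims=True)
    pattern = (x_c @ y_c) / var
    montage = trials.montage if isinstance(trials, TrialSet) else f.montage
    return ForwardModel(pattern, montage)


def save_filter(f: SpatialFilter, path: str | Path) -> None:
    """Two-column text file: channel name (or index), weight."""
    names = f.montage.names if f.montage is not None else [str(i) for i in range(f.weights.size)]
    with open(path, "w") as fh:
        for name, w in zip(names, f.weights):
            fh.write(f"{name}\t{float(w)!r}\n")


def load_filter(path: str | Path, montage: ChannelMontage | None = None) -> SpatialFilter:
    names = []
    weights = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, w = line.split("\t")
        names.append(name)
        weights.append(float(w))
    if montage is None and not all(n.isdigit() for n in names):
        montage = ChannelMontage(tuple(names))
    return SpatialFilter(np.array(weights), montage)
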