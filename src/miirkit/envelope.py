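"""Stimulus-envelope extraction and lagged linear EEG-to-envelope decoding.

The decoder is a backward model in the style of auditory attention
decoding: a weight for every (channel, time-lag) pair maps multichannel
EEG onto the stimulus amplitude envelope.  Because cortex responds tens of
milliseconds *after* the sound, the reconstruction at time ``t`` uses the
EEG samples at ``t .. t + max_lag`` (lags 0..L, EEG trailing the
stimulus); the default lag window of 375 ms comfortably covers reported
auditory response lags of 70-100 ms.

The plain least-squares fit of this model is notoriously unstable on short
trials (small lag-window changes can produce very different weights), so
the fit is ridge-regularized with the penalty chosen by generalized
cross-validation by default, and the channel dimension can optionally be
reduced by projection onto a principal subspace of the training EEG.
Per-trial decoders are averaged in a leave-one-out scheme; the
reconstruction quality measure — and the stimulus-identification rule — is
the Pearson correlation with candidate envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .core import BeatAnnotation, Trial, samples_for_duration

__all__ = [
    "LagDecoder",
    "audio_envelope",
    "beat_envelope",
    "fit_lag_decoder",
    "reconstruct",
    "loo_average_decoders",
    "classify_by_correlation",
]


@dataclass
class LagDecoder:
    """Channels x (lags + 1) weight matrix mapping EEG to an envelope.

    If ``projection`` is set (channels x dims), the EEG is first projected
    onto that channel subspace and ``weights`` lives in the reduced space.
    """

    weights: np.ndarray
    max_lag_s: float
    rate_hz: float
    projection: np.ndarray | None = None
    ridge: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("decoder weights must be finite")
        if self.weights.shape[1] != self.n_lags:
            raise ValueError("weight columns must equal floor(max_lag_s * rate) + 1")

    @property
    def n_lags(self) -> int:
        return int(np.floor(self.max_lag_s * self.rate_hz)) + 1

    @property
    def channel_weights(self) -> np.ndarray:
        """Weights expressed in channel space (undoing any projection)."""
        if self.projection is None:
            return self.weights
        return self.projection @ self.weights


# ---------------------------------------------------------------------------
# Envelope extraction
# ---------------------------------------------------------------------------


def audio_envelope(
    audio: np.ndarray,
    audio_rate: float,
    target_rate: float = 64.0,
    lp_hz: float = 8.0,
) -> np.ndarray:
    """Amplitude envelope of a mono audio signal.

    Magnitude of the analytic (Hilbert) signal, resampled to the EEG
    working rate, low-pass filtered, and clipped at zero (the filtering can
    produce small negative excursions).
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be mono (1-D)")
    env = np.abs(sps.hilbert(audio))
    if target_rate < audio_rate:
        from fractions import Fraction

        ratio = Fraction(target_rate / audio_rate).limit_denominator(10000)
        env = sps.resample_poly(env, ratio.numerator, ratio.denominator)
    if lp_hz < target_rate / 2:
        sos = sps.butter(4, lp_hz, fs=target_rate, output="sos")
        env = sps.sosfiltfilt(sos, env)
    return np.clip(env, 0.0, None)


def beat_envelope(
    annotation: BeatAnnotation,
    rate_hz: float,
    length_s: float,
    beat_weight: float = 1.0,
    downbeat_weight: float = 2.0,
    kernel_s: float = 0.06,
) -> np.ndarray:
    """Artificial envelope from beat annotations: a smoothed impulse train
    with downbeats weighted heavier than plain beats."""
    n = samples_for_duration(length_s, rate_hz)
    env = np.zeros(n)
    kernel = np.hanning(max(3, int(round(kernel_s * rate_hz)) | 1))
    half = kernel.size // 2
    downs = set(np.round(annotation.downbeat_times_s, 9))
    for t in annotation.beat_times_s:
        if t > length_s:
            continue
        amp = downbeat_weight if round(float(t), 9) in downs else beat_weight
        center = int(round(t * rate_hz))
        lo, hi = center - half, center + half + 1
        klo, khi = max(0, -lo), kernel.size - max(0, hi - n)
        lo, hi = max(0, lo), min(n, hi)
        if lo < hi:
            env[lo:hi] += amp * kernel[klo:khi]
    return env


# ---------------------------------------------------------------------------
# Lagged linear decoder
# ---------------------------------------------------------------------------


def _lagged_design(x: np.ndarray, n_lags: int) -> np.ndarray:
    """(channels, T) -> (T - n_lags + 1, channels * n_lags) design matrix.

    Row ``t`` holds ``x[ch, t + lag]`` for all channels and lags 0..L.
    """
    windows = sliding_window_view(x, n_lags, axis=1)  # (ch, T-L, n_lags)
    return np.swapaxes(windows, 0, 1).reshape(windows.shape[1], -1)


def _gcv_ridge(u_ty: np.ndarray, d2: np.ndarray, y: np.ndarray) -> float:
    """Ridge penalty minimizing the generalized cross-validation score."""
    n = y.size
    yty = float(y @ y)
    best = (np.inf, 1.0)
    for lam in 10.0 ** np.arange(-8.0, 6.0):
        shrink = d2 / (d2 + lam)
        df = float(np.sum(shrink))
        rss = yty - float((2 * shrink - shrink**2) @ u_ty**2)
        gcv = (rss / n) / (1.0 - df / n) ** 2 if df < n else np.inf
        if gcv < best[0]:
            best = (gcv, lam)
    return best[1]


def fit_lag_decoder(
    eeg,
    env: np.ndarray,
    max_lag_s: float = 0.375,
    ridge: float | str = "gcv",
    subspace_dims: int | None = None,
) -> LagDecoder:
    """Fit the lagged linear EEG-to-envelope decoder by regularized least
    squares.

    ``eeg`` is a Trial or a (channels, T) array at the same rate as ``env``
    (whose length must equal T).  ``ridge`` is a nonnegative penalty or
    ``"gcv"`` to select it by generalized cross-validation on the training
    trial.  ``ridge=0`` on a rank-deficient system raises, advising a
    positive ridge.  ``subspace_dims`` projects the channels onto the top
    principal subspace of the training EEG first, shrinking the parameter
    count from ``64 x lags`` to ``dims x lags``.
    """
    if isinstance(eeg, Trial):
        rate = eeg.rate_hz
        x = eeg.data
    else:
        raise_if = np.asarray(eeg)
        if raise_if.ndim != 2:
            raise ValueError("eeg must be a Trial or (channels, T) array")
        x = raise_if
        rate = 64.0
    env = np.asarray(env, dtype=float)
    if env.size != x.shape[1]:
        raise ValueError("envelope length must equal the trial sample count")

    projection = None
    if subspace_dims is not None:
        xc = x - x.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(xc.T, full_matrices=False)
        projection = vt[:subspace_dims].T  # (channels, dims)
        x = projection.T @ x

    n_lags = int(np.floor(max_lag_s * rate)) + 1
    a = _lagged_design(x, n_lags)
    y = env[: a.shape[0]]
    a = a - a.mean(axis=0, keepdims=True)
    y = y - y.mean()

    u, d, vt = np.linalg.svd(a, full_matrices=False)
    d2 = d**2
    u_ty = u.T @ y
    if ridge == "gcv":
        lam = _gcv_ridge(u_ty, d2, y)
    else:
        lam = float(ridge)
        if lam < 0:
            raise ValueError("ridge must be nonnegative")
        if lam == 0 and (d2 < d2.max() * 1e-10).any():
            raise np.linalg.LinAlgError(
                "lagged design is rank-deficient; refit with ridge > 0"
            )
    coef = vt.T @ (d / (d2 + lam) * u_ty)
    weights = coef.reshape(x.shape[0], n_lags)
    return LagDecoder(
        weights=weights,
        max_lag_s=max_lag_s,
        rate_hz=rate,
        projection=projection,
        ridge=lam,
    )


def reconstruct(eeg, d: LagDecoder) -> np.ndarray:
    """Apply a decoder: ``rec[t] = sum_ch sum_lag w[ch, lag] x[ch, t + lag]``.

    Only fully covered time points are produced ("valid" convention), so the
    output has ``T - n_lags + 1`` samples.
    """
    x = eeg.data if isinstance(eeg, Trial) else np.asarray(eeg, dtype=float)
    w = d.channel_weights
    if x.shape[0] != w.shape[0]:
        raise ValueError("channel count does not match the decoder")
    windows = sliding_window_view(x, d.n_lags, axis=1)  # (ch, T-L, lags)
    return np.einsum("cl,ctl->t", w, windows)


def loo_average_decoders(decoders: Sequence[LagDecoder], held_out_index: int) -> LagDecoder:
    """Mean decoder excluding the held-out trial's decoder.

    Averaging happens in channel space so that decoders with different
    (per-trial) subspace projections can be combined.
    """
    decoders = list(decoders)
    if len(decoders) < 2:
        raise ValueError("need at least two decoders")
    if not 0 <= held_out_index < len(decoders):
        raise IndexError("held_out_index out of range")
    rest = [d for i, d in enumerate(decoders) if i != held_out_index]
    w = np.mean([d.channel_weights for d in rest], axis=0)
    first = decoders[0]
    return LagDecoder(weights=w, max_lag_s=first.max_lag_s, rate_hz=first.rate_hz)


def classify_by_correlation(
    reconstruction: np.ndarray, candidate_envelopes: Mapping[int, np.ndarray]
):
    """Identify the stimulus whose envelope best matches a reconstruction.

    Candidates are truncated (never zero-padded — padding would give away
    the shorter stimuli by their silent tails) to the reconstruction length;
    the winner is the argmax of the Pearson correlation, even if all
    correlations are negative.  Returns ``(best_id, {id: r})``.
    """
    rec = np.asarray(reconstruction, dtype=float)
    scores: dict = {}
    for key, env in candidate_envelopes.items():
        env = np.asarray(env, dtype=float)
        n = min(rec.size, env.size)
        r = np.corrcoef(rec[:n], env[:n])[0, 1]
        scores[key] = float(r)
    best = max(scores, key=lambda k: (scores[k], -_sort_key(k)))
    return best, scores


def _sort_key(k):
    try:
        return float(k)
    except (TypeError, ValueError):
        return 0.0
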