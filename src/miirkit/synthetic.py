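"""Synthetic music-perception EEG with known ground truth.

The generator emulates the structure of a music-perception EEG study:
``n_subjects x n_blocks x n_stimuli`` trials, each a 64-channel recording of
stimulus-locked cortical sources mixed through a per-subject spatial forward
matrix plus 1/f background noise.  Three sources are simulated per trial:

* a *bar-pattern* source — a smooth waveform, unique per stimulus, that
  repeats every bar (anchored at the downbeats).  This models the
  stimulus-specific periodic response observed in bar-aligned ERPs and is
  the class-discriminative component that spatial-filter learning should
  recover;
* a *downbeat transient* — a damped oscillation emitted at every downbeat,
  with per-trial gain and latency jitter;
* an *envelope follower* — the stimulus amplitude envelope delayed by a
  fixed response lag (default 100 ms, in the range of reported
  auditory-response lags), with per-trial gain jitter.

Background noise is pink (1/f spectral shaping), scaled per trial so the
ratio of clean-signal power to noise power equals the requested linear SNR.

All randomness flows from ``SyntheticConfig.seed`` through
``numpy.random.SeedSequence`` spawning (PCG64 streams), so a fixed seed
reproduces the dataset bit-for-bit across platforms, and per-trial streams
are independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (
    BeatAnnotation,
    ChannelMontage,
    StimulusMeta,
    Trial,
    TrialSet,
    biosemi64_montage,
    default_stimuli,
    normalize_trial,
    samples_for_duration,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "make_stimulus_track",
    "simulate_trial",
    "simulate_dataset",
    "design_metadata",
]

SOURCE_NAMES = ("bar_pattern", "downbeat_transient", "envelope_follower")


@dataclass
class SyntheticConfig:
    """Study-design and signal parameters of the synthetic dataset.

    Defaults mirror the full perception-condition design: 9 subjects,
    5 blocks, the standard 12-stimulus table, 64 channels at 64 Hz.
    ``snr`` is the linear ratio of clean-signal power to noise power;
    the default of 1.0 is a realistically noisy single-trial EEG regime,
    while values of ~20 give a clearly separable "high SNR" regime used
    for method-validation runs.  ``np.inf`` disables noise entirely.
    """

    n_subjects: int = 9
    n_blocks: int = 5
    stimuli: tuple[StimulusMeta, ...] = field(default_factory=default_stimuli)
    n_sources: int = 3
    snr: float = 1.0
    seed: int = 0
    rate_hz: float = 64.0
    #: latency of the envelope-following source, seconds
    response_lag_s: float = 0.1
    #: relative source amplitudes (bar pattern, downbeat transient, envelope)
    source_amps: tuple[float, ...] = (1.0, 0.5, 0.5)
    #: std of the multiplicative per-trial gain jitter on sources 2 and 3
    gain_jitter: float = 0.3
    #: max per-trial latency jitter of the downbeat transient, seconds
    time_jitter_s: float = 0.05
    #: relative magnitude of per-subject forward-matrix perturbation
    subject_variability: float = 0.2
    condition: int = 1

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_blocks < 1 or not self.stimuli:
            raise ValueError("design must have >=1 subject, block, and stimulus")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if not 1 <= self.n_sources <= len(SOURCE_NAMES):
            raise ValueError(f"n_sources must be in 1..{len(SOURCE_NAMES)}")

    @property
    def subjects(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that an analysis must recover."""

    #: per-subject forward (mixing) matrix, channels x sources, unit-norm columns
    mixing: dict[str, np.ndarray]
    #: per-trial source time courses, (n_sources, n_samples), trial order
    sources: list[np.ndarray]
    #: per-trial metadata (same order as the TrialSet)
    labels: pd.DataFrame
    #: bar tempo (downbeats per minute) per stimulus id
    bar_tempo: dict[int, float]
    #: beat/downbeat annotations per stimulus id
    annotations: dict[int, BeatAnnotation]
    #: stimulus envelopes at the working rate, per stimulus id
    envelopes: dict[int, np.ndarray]
    source_names: tuple[str, ...] = SOURCE_NAMES

    def lsq_unmixing(
        self, ts: TrialSet, source: int = 0, trial_ids: Sequence[int] | None = None
    ) -> np.ndarray:
        """Least-squares unmixing vector for one source.

        Regresses the known source time course on the observed channel data,
        pooled over the selected trials: the returned 64-vector ``w``
        minimizes ``sum_t (w . x_t - s_t)^2``.  This is the ground-truth
        reference a learned spatial filter should align with.
        """
        ids = range(len(ts)) if trial_ids is None else trial_ids
        xtx = 0.0
        xty = 0.0
        for i in ids:
            x = ts[i].data
            s = self.sources[i][source]
            n = min(x.shape[1], s.shape[0])
            xtx = xtx + x[:, :n] @ x[:, :n].T
            xty = xty + x[:, :n] @ s[:n]
        return np.linalg.solve(xtx + 1e-12 * np.eye(xtx.shape[0]), xty)


# ---------------------------------------------------------------------------
# Stimulus tracks
# ---------------------------------------------------------------------------


def _beat_grid(meta: StimulusMeta) -> tuple[np.ndarray, np.ndarray]:
    period = 60.0 / meta.tempo_bpm
    beats = np.arange(0.0, meta.length_s - 1e-9, period)
    downbeats = beats[:: meta.meter]
    return beats, downbeats


def _accent_profile(meta: StimulusMeta, n_beats: int) -> np.ndarray:
    """Per-beat accent factors, deterministic per stimulus id.

    Models the loudness/articulation pattern that distinguishes two pieces
    sharing the same tempo and meter; without it, tempo-matched stimulus
    pairs would have identical click envelopes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([10_000, meta.id]))
    return rng.uniform(0.7, 1.3, size=n_beats)


def make_stimulus_track(
    meta: StimulusMeta, rate_hz: float, downbeat_weight: float = 1.8, click_s: float = 0.06
) -> tuple[np.ndarray, BeatAnnotation]:
    """Click-train stimulus envelope plus its beat annotation.

    Beats are spaced ``60/tempo_bpm`` s apart starting at 0; every
    ``meter``-th beat is a downbeat and is accented by ``downbeat_weight``.
    Each click is a Hann bump of ``click_s`` seconds, scaled by the
    stimulus-specific accent profile.
    """
    beats, downbeats = _beat_grid(meta)
    n = samples_for_duration(meta.length_s, rate_hz)
    env = np.zeros(n)
    kernel = np.hanning(max(3, int(round(click_s * rate_hz)) | 1))
    accents = _accent_profile(meta, beats.size)
    down_set = set(np.round(downbeats, 9))
    half = kernel.size // 2
    for t, acc in zip(beats, accents):
        amp = acc * (downbeat_weight if round(t, 9) in down_set else 1.0)
        center = int(round(t * rate_hz))
        lo, hi = center - half, center + half + 1
        klo, khi = max(0, -lo), kernel.size - max(0, hi - n)
        lo, hi = max(0, lo), min(n, hi)
        if lo < hi:
            env[lo:hi] += amp * kernel[klo:khi]
    return env, BeatAnnotation(beats, downbeats)


# ---------------------------------------------------------------------------
# Source waveforms
# ---------------------------------------------------------------------------


def _smooth_unit_noise(rng: np.random.Generator, n: int, rate_hz: float, lp_hz: float = 8.0) -> np.ndarray:
    """Low-passed white noise, normalized to unit RMS."""
    x = rng.standard_normal(max(n, 8))
    if lp_hz < rate_hz / 2:
        sos = sps.butter(4, lp_hz, fs=rate_hz, output="sos")
        x = sps.sosfiltfilt(sos, x)
    x = x[:n]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _bar_pattern_source(meta: StimulusMeta, rate_hz: float, n: int) -> np.ndarray:
    """Stimulus-specific smooth pattern tiled at the bar period.

    One bar worth of low-passed noise (seeded by the stimulus id) is
    repeated downbeat-to-downbeat, producing a waveform that is periodic at
    the bar tempo and unique to the stimulus.
    """
    bar_samples = max(4, int(round(meta.meter * 60.0 / meta.tempo_bpm * rate_hz)))
    rng = np.random.default_rng(np.random.SeedSequence([20_000, meta.id]))
    pattern = _smooth_unit_noise(rng, bar_samples, rate_hz)
    # taper ends so the tiled signal has no jump discontinuities
    edge = max(2, bar_samples // 8)
    ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(edge) / edge)
    pattern = pattern.copy()
    pattern[:edge] *= ramp
    pattern[-edge:] *= ramp[::-1]
    reps = int(np.ceil(n / bar_samples))
    return np.tile(pattern, reps)[:n]


def _downbeat_kernel(rate_hz: float, f_hz: float = 4.0, decay_s: float = 0.12, dur_s: float = 0.5) -> np.ndarray:
    """Damped oscillation modeling an evoked transient response."""
    t = np.arange(int(round(dur_s * rate_hz))) / rate_hz
    return np.exp(-t / decay_s) * np.sin(2 * np.pi * f_hz * t)


def _downbeat_source(
    annotation: BeatAnnotation,
    rate_hz: float,
    n: int,
    rng: np.random.Generator,
    time_jitter_s: float,
) -> np.ndarray:
    kernel = _downbeat_kernel(rate_hz)
    out = np.zeros(n)
    max_jit = int(round(time_jitter_s * rate_hz))
    for t in annotation.downbeat_times_s:
        jit = rng.integers(-max_jit, max_jit + 1) if max_jit > 0 else 0
        start = int(round(t * rate_hz)) + jit
        if start < 0:
            continue
        stop = min(n, start + kernel.size)
        if stop > start:
            out[start:stop] += kernel[: stop - start]
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def _envelope_source(envelope: np.ndarray, rate_hz: float, n: int, lag_s: float) -> np.ndarray:
    lag = int(round(lag_s * rate_hz))
    out = np.zeros(n)
    m = min(n - lag, envelope.size)
    if m > 0:
        out[lag : lag + m] = envelope[:m]
    out = out - out.mean()
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Independent pink (1/f amplitude) noise per channel, ~unit power."""
    n_ch, n = shape
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= scale
    pink = np.fft.irfft(spec, n=n, axis=1)
    rms = np.sqrt(np.mean(pink**2))
    return pink / rms if rms > 0 else pink


# ---------------------------------------------------------------------------
# Trial and dataset simulation
# ---------------------------------------------------------------------------


def _trial_sources(
    meta: StimulusMeta,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    envelope: np.ndarray,
    annotation: BeatAnnotation,
    n: int,
) -> np.ndarray:
    """Source time courses for one trial, (n_sources, n)."""
    amps = cfg.source_amps
    sources = []
    if cfg.n_sources >= 1:
        sources.append(amps[0] * _bar_pattern_source(meta, cfg.rate_hz, n))
    if cfg.n_sources >= 2:
        gain = max(0.1, 1.0 + cfg.gain_jitter * rng.standard_normal())
        sources.append(
            amps[1] * gain * _downbeat_source(annotation, cfg.rate_hz, n, rng, cfg.time_jitter_s)
        )
    if cfg.n_sources >= 3:
        gain = max(0.1, 1.0 + cfg.gain_jitter * rng.standard_normal())
        sources.append(amps[2] * gain * _envelope_source(envelope, cfg.rate_hz, n, cfg.response_lag_s))
    return np.asarray(sources)


def simulate_trial(
    meta: StimulusMeta,
    mixing: np.ndarray,
    snr: float,
    seed: int | np.random.SeedSequence,
    cfg: SyntheticConfig | None = None,
) -> tuple[Trial, np.ndarray]:
    """Simulate one trial: ``data = mixing @ sources + noise``.

    Returns the (un-normalized) trial and its source matrix.  ``snr`` is the
    linear clean-power to noise-power ratio; ``np.inf`` yields noise-free
    data (rank bounded by the number of sources).  The same seed always
    produces the identical array.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(seed)
    envelope, annotation = make_stimulus_track(meta, cfg.rate_hz)
    n = samples_for_duration(meta.length_s, cfg.rate_hz)
    sources = _trial_sources(meta, cfg, rng, envelope, annotation, n)
    if mixing.shape[1] != sources.shape[0]:
        raise ValueError("mixing column count must equal the number of sources")
    clean = mixing @ sources
    if np.isfinite(snr):
        noise = _pink_noise(rng, clean.shape)
        p_signal = np.mean(clean**2)
        noise *= np.sqrt(p_signal / snr)
        data = clean + noise
    else:
        data = clean
    trial = Trial(
        subject="S01",
        condition=cfg.condition,
        stimulus_id=meta.id,
        block=1,
        data=data,
        rate_hz=cfg.rate_hz,
    )
    return trial, sources


def _subject_mixing(
    base: np.ndarray, rng: np.random.Generator, variability: float
) -> np.ndarray:
    n_ch, k = base.shape
    pert = rng.standard_normal((n_ch, k)) / np.sqrt(n_ch)
    m = base + variability * pert
    return m / np.linalg.norm(m, axis=0, keepdims=True)


def _base_mixing(rng: np.random.Generator, n_ch: int, k: int) -> np.ndarray:
    """Base forward matrix: broad same-sign topographies plus random detail.

    Cortical sources project with a spatially extended field over the scalp,
    so each column gets a positive broad loading on top of channel-specific
    structure; columns are normalized to unit norm.
    """
    broad = rng.uniform(0.5, 1.0, size=(1, k))
    detail = rng.standard_normal((n_ch, k))
    m = broad + detail
    return m / np.linalg.norm(m, axis=0, keepdims=True)


def design_metadata(cfg: SyntheticConfig) -> pd.DataFrame:
    """Trial metadata table of the design, without synthesizing signals.

    Useful for combinatorial analyses (fold and triplet counts) that do not
    need EEG data.
    """
    rows = []
    i = 0
    for subject in cfg.subjects:
        for block in range(1, cfg.n_blocks + 1):
            for meta in cfg.stimuli:
                rows.append(
                    {
                        "trial_id": i,
                        "subject": subject,
                        "condition": cfg.condition,
                        "stimulus_id": meta.id,
                        "block": block,
                        "rate_hz": cfg.rate_hz,
                    }
                )
                i += 1
    return pd.DataFrame(rows)


def simulate_dataset(
    cfg: SyntheticConfig, normalize: bool = True
) -> tuple[TrialSet, SyntheticGroundTruth]:
    """Simulate the full trial set plus ground truth.

    Trials are generated in (subject, block, stimulus) order, all in the
    perception condition.  With ``normalize=True`` each trial is normalized
    to zero mean and range [-1, 1] per channel, matching the preprocessing
    applied to real recordings.
    """
    montage = biosemi64_montage()
    n_ch = montage.size
    root = np.random.SeedSequence([int(cfg.seed), 77])
    base_rng = np.random.default_rng(root.spawn(1)[0])
    base = _base_mixing(base_rng, n_ch, cfg.n_sources)

    mixing: dict[str, np.ndarray] = {}
    trials: list[Trial] = []
    sources: list[np.ndarray] = []
    for si, subject in enumerate(cfg.subjects):
        subj_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 88, si]))
        mixing[subject] = _subject_mixing(base, subj_rng, cfg.subject_variability)
        for block in range(1, cfg.n_blocks + 1):
            for meta in cfg.stimuli:
                ss = np.random.SeedSequence([int(cfg.seed), 99, si, block, meta.id])
                trial, src = simulate_trial(meta, mixing[subject], cfg.snr, ss, cfg)
                trial = Trial(
                    subject=subject,
                    condition=cfg.condition,
                    stimulus_id=meta.id,
                    block=block,
                    data=trial.data,
                    rate_hz=cfg.rate_hz,
                )
                if normalize:
                    trial = normalize_trial(trial)
                trials.append(trial)
                sources.append(src)

    stimuli = {m.id: m for m in cfg.stimuli}
    ts = TrialSet(trials, montage, stimuli)
    annotations = {}
    envelopes = {}
    for meta in cfg.stimuli:
        env, ann = make_stimulus_track(meta, cfg.rate_hz)
        annotations[meta.id] = ann
        envelopes[meta.id] = env
    gt = SyntheticGroundTruth(
        mixing=mixing,
        sources=sources,
        labels=ts.metadata(),
        bar_tempo={m.id: m.bar_tempo_bpm for m in cfg.stimuli},
        annotations=annotations,
        envelopes=envelopes,
        source_names=SOURCE_NAMES[: cfg.n_sources],
    )
    return ts, gt
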