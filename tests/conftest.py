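import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from miirkit.core import ChannelMontage, StimulusMeta, Trial, TrialSet, clip_trials, default_stimuli
from miirkit.synthetic import SyntheticConfig, simulate_dataset

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def light_trialset(n_subjects: int, n_blocks: int, stimuli=None) -> TrialSet:
    """Metadata-complete trial set with dummy 1-channel data.

    Cheap stand-in for combinatorial tests (folds, triplets) that never look
    at the signal.
    """
    stimuli = stimuli or default_stimuli()
    montage = ChannelMontage(("T7",))
    trials = [
        Trial(
            subject=f"S{s + 1:02d}",
            condition=1,
            stimulus_id=meta.id,
            block=b,
            data=np.zeros((1, 2)),
            rate_hz=64.0,
        )
        for s in range(n_subjects)
        for b in range(1, n_blocks + 1)
        for meta in stimuli
    ]
    return TrialSet(trials, montage, {m.id: m for m in stimuli})


@pytest.fixture(scope="session")
def design540() -> TrialSet:
    """The full 9-subject x 5-block x 12-stimulus perception design."""
    return light_trialset(9, 5)


@pytest.fixture(scope="session")
def reduced_dataset():
    """Reduced-scale high-SNR synthetic dataset (4 subjects, 3 blocks),
    normalized and clipped — the standard method-validation conditions."""
    cfg = SyntheticConfig(n_subjects=4, n_blocks=3, snr=20.0, seed=1)
    ts, gt = simulate_dataset(cfg)
    ts, n_samples = clip_trials(ts)
    return ts, gt, n_samples


@pytest.fixture(scope="session")
def recovery_dataset():
    """Parameter-recovery conditions: a single class-informative source with
    one shared mixing column, high SNR, no per-channel normalization."""
    cfg = SyntheticConfig(
        n_subjects=4,
        n_blocks=3,
        snr=20.0,
        seed=1,
        n_sources=1,
        source_amps=(1.0,),
        subject_variability=0.0,
    )
    ts, gt = simulate_dataset(cfg, normalize=False)
    ts, _ = clip_trials(ts)
    return ts, gt
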