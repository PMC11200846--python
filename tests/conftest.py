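"""Shared fixtures: small synthetic epoch sets generated at test time."""

import numpy as np
import pytest

from mvpakit.containers import EpochsSet
from mvpakit.synthetic import SimulationSpec, generate_subject


@pytest.fixture(scope="session")
def tiny_spec() -> SimulationSpec:
    """A fast, low-resolution cohort spec for unit tests."""
    return SimulationSpec(
        n_subjects=2,
        n_trials=40,
        n_channels_meg=8,
        n_channels_eeg=12,
        sfreq=100.0,
        epoch_window=(-0.2, 0.6),
        effect_amplitude=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_subject(tiny_spec):
    """One (meg, eeg) pair from the tiny spec."""
    return generate_subject(tiny_spec, 0)


def make_epochs(
    data: np.ndarray,
    labels=None,
    sfreq: float = 100.0,
    t_min: float = -0.2,
    modality: str = "meg",
) -> EpochsSet:
    """Wrap a raw array in a valid EpochsSet with paired labels."""
    n_trials, n_channels, n_times = data.shape
    if labels is None:
        labels = np.tile([0, 1], n_trials // 2 + 1)[:n_trials]
    labels = np.asarray(labels, dtype=int)
    pair_ids = np.zeros(n_trials, dtype=int)
    for lab in (0, 1):
        idx = np.flatnonzero(labels == lab)
        pair_ids[idx] = np.arange(len(idx))
    return EpochsSet(
        data=data,
        labels=labels,
        pair_ids=pair_ids,
        times=t_min + np.arange(n_times) / sfreq,
        sfreq=sfreq,
        channel_ids=[f"CH{i}" for i in range(n_channels)],
        modality=modality,
        subject_id="T00",
    )
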