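"""Core data container for epoched multichannel recordings.

An :class:`EpochsSet` holds a ``trials x channels x timepoints`` array of
evoked responses together with the per-trial metadata the decoding pipeline
needs: binary condition labels, sentence-body pair identifiers (each stimulus
body occurs once per condition in the paired design), a uniform time grid,
and modality bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Sentinel pair id used when pairing has been invalidated (e.g. after
#: pseudo-trial averaging).
PAIR_ID_NONE = -1

#: Recognised modality tags.
MODALITIES = ("meg", "eeg", "fused")


@dataclass
class EpochsSet:
    """Epoched data plus trial/channel/time metadata.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_times)`` in physical-scale
        units (tesla-like for ``meg``, volt-like for ``eeg``).
    labels
        Per-trial condition, ``0`` = congruent, ``1`` = incongruent.
    pair_ids
        Per-trial integer linking the two conditions of one sentence body;
        ``PAIR_ID_NONE`` marks trials whose pairing is no longer meaningful.
    times
        Time stamps in seconds, a strictly increasing uniform grid.
    sfreq
        Sampling frequency in Hz.
    channel_ids
        One string per channel.
    modality
        One of ``{"meg", "eeg", "fused"}``.
    subject_id
        Free-form subject identifier.
    """

    data: np.ndarray
    labels: np.ndarray
    pair_ids: np.ndarray
    times: np.ndarray
    sfreq: float
    channel_ids: list[str]
    modality: str
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.pair_ids = np.asarray(self.pair_ids, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.channel_ids = [str(c) for c in self.channel_ids]
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check all container invariants; raise ``ValueError`` on violation."""
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x timepoints")
        n_trials, n_channels, n_times = self.data.shape
        if len(self.labels) != n_trials or len(self.pair_ids) != n_trials:
            raise ValueError("labels/pair_ids length must equal n_trials")
        if len(self.times) != n_times:
            raise ValueError("times length must equal data.shape[2]")
        if len(self.channel_ids) != n_channels:
            raise ValueError("channel_ids length must equal data.shape[1]")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must take values in {0, 1}")
        if n_times > 1:
            dt = np.diff(self.times)
            if not (dt > 0).all():
                raise ValueError("times must be strictly increasing")
            if np.abs(dt - 1.0 / self.sfreq).max() > 1e-9:
                raise ValueError("times spacing must equal 1/sfreq (tol 1e-9)")
        # each pair id occurs at most once per label value
        for lab in (0, 1):
            pids = self.pair_ids[(self.labels == lab) & (self.pair_ids != PAIR_ID_NONE)]
            if len(np.unique(pids)) != len(pids):
                raise ValueError(f"duplicate pair_id within label {lab}")

    # ------------------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def class_counts(self) -> tuple[int, int]:
        """Trial counts for (congruent, incongruent)."""
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())

    def select_trials(self, index: Sequence[int] | np.ndarray) -> "EpochsSet":
        """Return a new set restricted to the given trial indices (in order)."""
        index = np.asarray(index, dtype=int)
        return replace(
            self,
            data=self.data[index],
            labels=self.labels[index],
            pair_ids=self.pair_ids[index],
        )

    def select_channels(self, mask: np.ndarray) -> "EpochsSet":
        """Return a new set restricted to channels where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            data=self.data[:, mask, :],
            channel_ids=[c for c, m in zip(self.channel_ids, mask) if m],
        )

    def time_mask(self, t_min: float, t_max: float) -> np.ndarray:
        """Boolean mask of timepoints within ``[t_min, t_max]`` (inclusive)."""
        return (self.times >= t_min - 1e-12) & (self.times <= t_max + 1e-12)

    def copy(self) -> "EpochsSet":
        return replace(
            self,
            data=self.data.copy(),
            labels=self.labels.copy(),
            pair_ids=self.pair_ids.copy(),
            times=self.times.copy(),
            channel_ids=list(self.channel_ids),
        )
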