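"""Epoch conditioning and SNR-collapse operators.

Baseline correction, z-score epoch flagging, anti-aliased resampling,
sliding-window averaging, within-condition pseudo-trial averaging and class
balancing. Every operator consumes and produces an :class:`EpochsSet`; only
the trial and/or time axes change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace, asdict
from fractions import Fraction

import numpy as np
from scipy import signal as sp_signal

from .containers import EpochsSet, PAIR_ID_NONE

__all__ = [
    "CollapseConfig",
    "baseline_correct",
    "flag_bad_epochs",
    "resample_epochs",
    "sliding_window_average",
    "average_trials",
    "balance_epochs",
    "apply_time_collapse",
]


@dataclass
class CollapseConfig:
    """One SNR-collapse variant.

    ``resample_hz``/``window_len_ms`` of ``None`` disable the respective
    operator; ``avg_group_size = 1`` means single-trial analysis.
    """

    resample_hz: float | None = 200.0
    window_len_ms: float | None = None
    window_step_fraction: float = 0.6
    avg_group_size: int = 1
    baseline_interval: tuple[float, float] = (-0.2, 0.0)
    zscore_threshold: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.baseline_interval = tuple(self.baseline_interval)

    def validate(self, sfreq: float | None = None) -> None:
        if not (0 < self.window_step_fraction <= 1):
            raise ValueError("window_step_fraction must lie in (0, 1]")
        if self.avg_group_size < 1:
            raise ValueError("avg_group_size must be >= 1")
        if self.resample_hz is not None:
            if self.resample_hz <= 0:
                raise ValueError("resample_hz must be positive")
            if sfreq is not None and self.resample_hz > sfreq + 1e-9:
                raise ValueError("resample_hz must not exceed the native sfreq")
        if self.zscore_threshold is not None and self.zscore_threshold <= 0:
            raise ValueError("zscore_threshold must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def baseline_correct(E: EpochsSet, interval: tuple[float, float] | None = None) -> EpochsSet:
    """Subtract, per trial and channel, the mean over ``interval``.

    Idempotent; the corrected data average to zero over the interval.
    """
    if interval is None:
        interval = (E.times[0], 0.0)
    t0, t1 = interval
    mask = E.time_mask(t0, t1)
    if not mask.any():
        raise ValueError(f"baseline interval {interval} contains no samples")
    base = E.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(E, data=E.data - base)


def flag_bad_epochs(E: EpochsSet, threshold: float) -> tuple[EpochsSet, np.ndarray]:
    """Reject trials whose max |z| exceeds ``threshold``.

    z-scores are computed per channel across all trials and timepoints; the
    per-trial summary is the max of |z| over channels and timepoints.
    Returns the surviving epochs (pairing metadata preserved) and the sorted
    indices of rejected trials.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mean = E.data.mean(axis=(0, 2), keepdims=True)
    sd = E.data.std(axis=(0, 2), keepdims=True)
    sd[sd == 0] = 1.0
    z = np.abs((E.data - mean) / sd)
    trial_stat = z.max(axis=(1, 2))
    rejected = np.flatnonzero(trial_stat > threshold)
    if len(rejected) == E.n_trials:
        raise ValueError(
            "all trials flagged as bad; raise the z-score threshold"
        )
    kept = np.setdiff1d(np.arange(E.n_trials), rejected)
    return E.select_trials(kept), rejected


def resample_epochs(E: EpochsSet, target_hz: float) -> EpochsSet:
    """Anti-aliased polyphase resampling of the time axis to ``target_hz``."""
    if target_hz <= 0:
        raise ValueError("target_hz must be positive")
    if target_hz > E.sfreq + 1e-9:
        raise ValueError("target_hz must not exceed the native sfreq")
    if abs(target_hz - E.sfreq) < 1e-9:
        return E.copy()
    frac = Fraction(target_hz / E.sfreq).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    data = sp_signal.resample_poly(E.data, up, down, axis=2, padtype="line")
    n_new = data.shape[2]
    times = E.times[0] + np.arange(n_new) / target_hz
    return replace(E, data=data, times=times, sfreq=float(target_hz))


def sliding_window_average(
    E: EpochsSet, window_len_ms: float, step_fraction: float = 0.6
) -> EpochsSet:
    """Average over sliding windows anchored at the epoch start.

    Window length ``L`` samples at the current sfreq; the step is
    ``round(step_fraction * L)`` samples (at least 1), so the output grid is
    uniform. Only windows lying wholly inside the epoch are kept; output
    timestamps are window centres.
    """
    if not (0 < step_fraction <= 1):
        raise ValueError("step_fraction must lie in (0, 1]")
    L = int(round(window_len_ms / 1000.0 * E.sfreq))
    if L < 1:
        raise ValueError("window shorter than one sample at the current sfreq")
    if L > E.n_times:
        raise ValueError("window longer than the epoch")
    step = max(1, int(round(step_fraction * L)))
    n_windows = (E.n_times - L) // step + 1
    starts = np.arange(n_windows) * step
    if L == 1:
        data = E.data[:, :, starts].copy()
    else:
        # cumulative sum gives each window mean in O(1)
        csum = np.concatenate(
            [np.zeros(E.data.shape[:2] + (1,)), np.cumsum(E.data, axis=2)], axis=2
        )
        data = (csum[:, :, starts + L] - csum[:, :, starts]) / L
    centers = E.times[starts] + (L - 1) / (2.0 * E.sfreq)
    return replace(E, data=data, times=centers, sfreq=E.sfreq / step)


def average_trials(E: EpochsSet, group_size: int, seed: int = 0) -> EpochsSet:
    """Average disjoint random groups of ``group_size`` same-condition trials.

    Each group becomes one pseudo-trial; leftover trials are dropped so
    pseudo-trial noise variance stays homogeneous. Pair ids are invalidated.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if group_size == 1:
        return E.copy()
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for lab in (0, 1):
        idx = np.flatnonzero(E.labels == lab)
        if len(idx) < group_size:
            raise ValueError(
                f"condition {lab} has {len(idx)} trials, fewer than group_size={group_size}"
            )
        perm = rng.permutation(idx)
        n_groups = len(idx) // group_size
        grouped = perm[: n_groups * group_size].reshape(n_groups, group_size)
        blocks.append(E.data[grouped].mean(axis=1))
        labels.append(np.full(n_groups, lab))
    data = np.concatenate(blocks, axis=0)
    labels = np.concatenate(labels)
    return replace(
        E,
        data=data,
        labels=labels,
        pair_ids=np.full(len(labels), PAIR_ID_NONE),
    )


def balance_epochs(E: EpochsSet, seed: int = 0) -> EpochsSet:
    """Downsample the majority class (seeded) to the minority count."""
    n0, n1 = E.class_counts()
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to balance")
    if n0 == n1:
        return E.copy()
    rng = np.random.default_rng(seed)
    minority = min(n0, n1)
    keep = []
    for lab in (0, 1):
        idx = np.flatnonzero(E.labels == lab)
        if len(idx) > minority:
            idx = np.sort(rng.choice(idx, size=minority, replace=False))
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    return E.select_trials(keep)


def apply_time_collapse(E: EpochsSet, config: CollapseConfig) -> EpochsSet:
    """Apply the time-axis operators of ``config``: resampling then windowing."""
    config.validate(E.sfreq)
    out = E
    if config.resample_hz is not None and abs(config.resample_hz - out.sfreq) > 1e-9:
        out = resample_epochs(out, config.resample_hz)
    if config.window_len_ms is not None:
        out = sliding_window_average(
            out, config.window_len_ms, config.window_step_fraction
        )
    return out
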