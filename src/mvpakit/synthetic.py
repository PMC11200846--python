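"""Synthetic multi-subject, dual-modality evoked epochs.

The generator emulates the statistical structure a time-resolved decoding
analysis of a semantic-congruity (N400-style) experiment assumes:

* a paired design — each sentence body occurs once per condition, trials
  presented in pseudo-random order;
* shared evoked components present in both conditions (early auditory-like
  bumps) plus a condition-difference component, a smooth Hann-tapered bump
  centred near 400 ms, projected onto a fixed random spatial pattern over a
  subset of channels;
* temporally coloured AR(1) noise mixed through a squared-exponential
  spatial kernel, plus white sensor noise;
* per-subject amplitude scaling and latency jitter;
* a null mode (``effect_amplitude = 0``) in which labels are statistically
  independent of the data by construction.

Random streams are split per ``(seed, subject, role)`` with
``numpy.random.SeedSequence`` so adding subjects never perturbs earlier
subjects' data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
from scipy import signal as sp_signal

from .containers import EpochsSet

__all__ = [
    "NoiseModel",
    "SubjectVariability",
    "SimulationSpec",
    "generate_subject",
    "generate_cohort",
    "generate_modality",
    "generate_subject_modality",
]

# role offsets for per-(subject, role) random streams
_ROLE_PARAMS = 0
_ROLE_ORDER = 1
_ROLE_PATTERN_MEG = 2
_ROLE_PATTERN_EEG = 3
_ROLE_NOISE_MEG = 4
_ROLE_NOISE_EEG = 5


@dataclass
class NoiseModel:
    """Additive noise parameters (internal, pre-scale units).

    ``noise_sd`` is the marginal SD of the spatially correlated AR(1)
    component per channel; ``sensor_noise_sd`` is the SD of the independent
    white sensor noise added on top.
    """

    ar1_coefficient: float = 0.9
    spatial_correlation_length: float = 5.0  # in units of channel index
    noise_sd: float = 1.0
    sensor_noise_sd: float = 0.5


@dataclass
class SubjectVariability:
    """Across-subject variation of the condition effect."""

    amplitude_sd: float = 0.2  # multiplicative, around 1
    latency_jitter_sd: float = 0.02  # seconds


@dataclass
class SimulationSpec:
    """Generative parameters for a synthetic evoked cohort.

    Defaults mirror the study conditions the pipeline targets: 6 subjects,
    196 trials split over two congruity conditions with sentence-body
    pairing, 40 magnetometer-scale and 64 electrode-scale channels, epochs
    from -200 ms to 1000 ms at 1000 Hz, and a condition-difference bump at
    400 ms.
    """

    n_subjects: int = 6
    n_trials: int = 196
    n_channels_meg: int = 40
    n_channels_eeg: int = 64
    sfreq: float = 1000.0
    epoch_window: tuple[float, float] = (-0.2, 1.0)
    effect_latency: float = 0.40
    effect_width: float = 0.15
    effect_amplitude: float = 0.08
    effect_channel_fraction: float = 0.5
    shared_components: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.10, 0.08, 1.5), (0.25, 0.12, 1.0)]
    )
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    subject_variability: SubjectVariability = field(default_factory=SubjectVariability)
    meg_scale: float = 1e-13  # tesla-like
    eeg_scale: float = 1e-6  # volt-like
    condition_imbalance: int = 0  # extra trials removed from condition 1
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.noise_model, dict):
            self.noise_model = NoiseModel(**self.noise_model)
        if isinstance(self.subject_variability, dict):
            self.subject_variability = SubjectVariability(**self.subject_variability)
        self.epoch_window = tuple(self.epoch_window)
        self.shared_components = [tuple(c) for c in self.shared_components]

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_trials < 2 or self.n_trials % 2 != 0:
            raise ValueError("n_trials must be an even count >= 2")
        if self.n_channels_meg < 1 or self.n_channels_eeg < 1:
            raise ValueError("n_channels_meg/n_channels_eeg must be >= 1")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        t_min, t_max = self.epoch_window
        if not (t_min < 0 < t_max):
            raise ValueError("epoch_window must satisfy t_min < 0 < t_max")
        if self.effect_amplitude < 0:
            raise ValueError("effect_amplitude must be >= 0")
        if not (0 < self.effect_channel_fraction <= 1):
            raise ValueError("effect_channel_fraction must lie in (0, 1]")
        if self.effect_width <= 0:
            raise ValueError("effect_width must be positive")
        if not (0 <= self.noise_model.ar1_coefficient < 1):
            raise ValueError("noise_model.ar1_coefficient must lie in [0, 1)")
        if self.noise_model.noise_sd < 0 or self.noise_model.sensor_noise_sd < 0:
            raise ValueError("noise_model SDs must be >= 0")
        if self.condition_imbalance < 0 or self.condition_imbalance >= self.n_trials // 2:
            raise ValueError("condition_imbalance must lie in [0, n_trials/2)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        return cls(**d)

    @property
    def times(self) -> np.ndarray:
        t_min, t_max = self.epoch_window
        n = int(round((t_max - t_min) * self.sfreq))
        return t_min + np.arange(n) / self.sfreq


def _hann_bump(times: np.ndarray, latency: float, width: float) -> np.ndarray:
    """Smooth unimodal bump: Hann taper of total support ``width`` at ``latency``."""
    u = (times - latency) / width
    out = np.zeros_like(times)
    inside = np.abs(u) <= 0.5
    out[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * u[inside]))
    return out


def _rng(spec_seed: int, subject_index: int, role: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(spec_seed), int(subject_index), int(role)])
    )


def _spatial_mixing(n_channels: int, length: float) -> np.ndarray:
    """Cholesky factor of a squared-exponential kernel over 1-D channel order."""
    if length <= 0:
        return np.eye(n_channels)
    idx = np.arange(n_channels, dtype=float)
    K = np.exp(-0.5 * ((idx[:, None] - idx[None, :]) / length) ** 2)
    K[np.diag_indices_from(K)] += 1e-8
    L = np.linalg.cholesky(K)
    # normalise rows so marginal channel variance is exactly 1
    L /= np.sqrt((L**2).sum(axis=1, keepdims=True))
    return L


def _colored_noise(
    rng: np.random.Generator,
    n_trials: int,
    n_channels: int,
    n_times: int,
    model: NoiseModel,
) -> np.ndarray:
    """AR(1)-in-time, spatially correlated noise plus white sensor noise.

    The AR(1) process starts in its stationary distribution (exact initial
    state, no burn-in); spatial mixing runs trial-by-trial through BLAS to
    keep the working set cache-sized.
    """
    out = np.zeros((n_trials, n_channels, n_times))
    if model.noise_sd > 0:
        a = model.ar1_coefficient
        innov_sd = model.noise_sd * np.sqrt(1.0 - a**2)
        white = rng.standard_normal((n_trials, n_channels, n_times))
        if a > 0:
            # zi = a * y[-1] with y[-1] drawn from the stationary marginal
            zi = a * model.noise_sd * rng.standard_normal((n_trials, n_channels, 1))
            colored, _ = sp_signal.lfilter(
                [innov_sd], [1.0, -a], white, axis=-1, zi=zi
            )
        else:
            colored = white * innov_sd
        L = _spatial_mixing(n_channels, model.spatial_correlation_length)
        for i in range(n_trials):
            np.matmul(L, colored[i], out=out[i])
    if model.sensor_noise_sd > 0:
        sensor = rng.standard_normal((n_trials, n_channels, n_times))
        sensor *= model.sensor_noise_sd
        out += sensor
    return out


def _trial_structure(
    spec: SimulationSpec, subject_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-random paired trial order shared by both modalities."""
    rng = _rng(spec.seed, subject_index, _ROLE_ORDER)
    n_pairs = spec.n_trials // 2
    labels = np.tile([0, 1], n_pairs)
    pair_ids = np.repeat(np.arange(n_pairs), 2)
    order = rng.permutation(spec.n_trials)
    labels, pair_ids = labels[order], pair_ids[order]
    if spec.condition_imbalance > 0:
        drop = np.flatnonzero(labels == 1)[: spec.condition_imbalance]
        keep = np.setdiff1d(np.arange(len(labels)), drop)
        labels, pair_ids = labels[keep], pair_ids[keep]
    return labels, pair_ids


def _subject_params(spec: SimulationSpec, subject_index: int) -> tuple[float, float]:
    """Per-subject effect amplitude factor and jittered latency."""
    rng = _rng(spec.seed, subject_index, _ROLE_PARAMS)
    sv = spec.subject_variability
    amp_factor = max(0.05, 1.0 + rng.standard_normal() * sv.amplitude_sd)
    latency = spec.effect_latency + rng.standard_normal() * sv.latency_jitter_sd
    return amp_factor, latency


def generate_modality(
    spec: SimulationSpec,
    subject_index: int,
    labels: np.ndarray,
    pair_ids: np.ndarray,
    modality: str,
) -> EpochsSet:
    n_channels = spec.n_channels_meg if modality == "meg" else spec.n_channels_eeg
    scale = spec.meg_scale if modality == "meg" else spec.eeg_scale
    pattern_role = _ROLE_PATTERN_MEG if modality == "meg" else _ROLE_PATTERN_EEG
    noise_role = _ROLE_NOISE_MEG if modality == "meg" else _ROLE_NOISE_EEG

    times = spec.times
    amp_factor, latency = _subject_params(spec, subject_index)

    rng_pat = _rng(spec.seed, subject_index, pattern_role)
    # shared components, both conditions
    shared = np.zeros((n_channels, len(times)))
    for lat, width, amp in spec.shared_components:
        pat = rng_pat.standard_normal(n_channels)
        pat /= np.sqrt(np.mean(pat**2))
        shared += amp * np.outer(pat, _hann_bump(times, lat, width))

    # condition-difference component on a channel subset
    k = int(np.ceil(spec.effect_channel_fraction * n_channels))
    chosen = rng_pat.choice(n_channels, size=k, replace=False)
    weights = rng_pat.standard_normal(k)
    weights /= np.sqrt(np.mean(weights**2))
    effect_map = np.zeros(n_channels)
    effect_map[chosen] = weights
    effect = (
        spec.effect_amplitude
        * amp_factor
        * np.outer(effect_map, _hann_bump(times, latency, spec.effect_width))
    )

    rng_noise = _rng(spec.seed, subject_index, noise_role)
    data = _colored_noise(rng_noise, len(labels), n_channels, len(times), spec.noise_model)
    data += shared[None, :, :]
    data[labels == 1] += effect[None, :, :]
    data *= scale

    prefix = "MEG" if modality == "meg" else "EEG"
    return EpochsSet(
        data=data,
        labels=labels,
        pair_ids=pair_ids,
        times=times,
        sfreq=spec.sfreq,
        channel_ids=[f"{prefix}{i:03d}" for i in range(n_channels)],
        modality=modality,
        subject_id=f"S{subject_index:02d}",
    )


def generate_subject(
    spec: SimulationSpec, subject_index: int
) -> tuple[EpochsSet, EpochsSet]:
    """Generate one subject's (meg, eeg) epoch pair.

    Both modalities share labels, pair ids and the time grid; spatial
    patterns and noise are modality-specific. Deterministic given
    ``(spec.seed, subject_index)``.
    """
    spec.validate()
    labels, pair_ids = _trial_structure(spec, subject_index)
    meg = generate_modality(spec, subject_index, labels, pair_ids, "meg")
    eeg = generate_modality(spec, subject_index, labels, pair_ids, "eeg")
    return meg, eeg


def generate_subject_modality(
    spec: SimulationSpec, subject_index: int, modality: str
) -> EpochsSet:
    """Generate a single modality for one subject (cheaper than both)."""
    if modality not in ("meg", "eeg"):
        raise ValueError("modality must be 'meg' or 'eeg'")
    spec.validate()
    labels, pair_ids = _trial_structure(spec, subject_index)
    return generate_modality(spec, subject_index, labels, pair_ids, modality)


def generate_cohort(
    spec: SimulationSpec, seed: int | None = None
) -> list[tuple[EpochsSet, EpochsSet]]:
    """Generate ``spec.n_subjects`` subjects; ``seed`` overrides ``spec.seed``."""
    spec.validate()
    eff = replace(spec, seed=spec.seed if seed is None else int(seed))
    return [generate_subject(eff, i) for i in range(spec.n_subjects)]
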