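"""Spatial feature reduction.

Train-fitted standardization, variance-threshold PCA and univariate channel
selection by a paired permutation t-test with Benjamini-Hochberg control
across channels. All fitting uses training rows only, so test data never
leak into the learned transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sp_stats

from .containers import EpochsSet, PAIR_ID_NONE

__all__ = [
    "ReducerSpec",
    "StandardizerParams",
    "fit_standardizer",
    "apply_standardizer",
    "pca_reduce",
    "univariate_select_channels",
    "bh_adjust",
]


@dataclass
class ReducerSpec:
    """Configuration of the spatial reduction step."""

    method: str = "pca"  # {none, pca, univariate}
    pca_var_threshold: float = 0.99
    select_window: tuple[float, float] = (0.2, 0.6)
    n_permutations: int = 1000
    alpha: float = 0.05
    bh_q: float = 0.05
    paired: bool = True
    parametric: bool = False  # paired-t fallback instead of permutations
    seed: int = 0

    def __post_init__(self) -> None:
        self.select_window = tuple(self.select_window)

    def validate(self) -> None:
        if self.method not in ("none", "pca", "univariate"):
            raise ValueError("method must be one of {'none', 'pca', 'univariate'}")
        if not (0 < self.pca_var_threshold <= 1):
            raise ValueError("pca_var_threshold must lie in (0, 1]")
        if self.select_window[0] >= self.select_window[1]:
            raise ValueError("select_window must be an increasing interval")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StandardizerParams:
    mean: np.ndarray
    sd: np.ndarray  # zero-SD features flagged by sd == 0


def fit_standardizer(train_matrix: np.ndarray) -> StandardizerParams:
    """Per-feature mean/SD estimated on training rows only."""
    train_matrix = np.asarray(train_matrix, dtype=float)
    if train_matrix.ndim != 2 or train_matrix.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 training rows")
    return StandardizerParams(
        mean=train_matrix.mean(axis=0), sd=train_matrix.std(axis=0)
    )


def apply_standardizer(params: StandardizerParams, matrix: np.ndarray) -> np.ndarray:
    """Apply train-fitted scaling; zero-SD features map to 0."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] != params.mean.shape[0]:
        raise ValueError(
            f"feature count mismatch: {matrix.shape[1]} vs {params.mean.shape[0]}"
        )
    zero = params.sd == 0
    if zero.any():
        warnings.warn("zero-SD features mapped to 0 after standardization")
    sd = np.where(zero, 1.0, params.sd)
    out = (matrix - params.mean) / sd
    out[:, zero] = 0.0
    return out


def pca_reduce(
    train_matrix: np.ndarray,
    test_matrix: np.ndarray,
    var_threshold: float = 0.99,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Project both matrices onto the leading principal components.

    The number of components is the smallest ``m`` whose cumulative explained
    variance on the training data reaches ``var_threshold``. The rotation is
    fit on training rows only.
    """
    if not (0 < var_threshold <= 1):
        raise ValueError("var_threshold must lie in (0, 1]")
    train_matrix = np.asarray(train_matrix, dtype=float)
    test_matrix = np.asarray(test_matrix, dtype=float)
    if train_matrix.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    mean = train_matrix.mean(axis=0)
    Xc = train_matrix - mean
    # principal axes via the feature-space Gram matrix (n_features is small
    # in the per-timepoint hot loop, so this beats a thin SVD)
    w, V = np.linalg.eigh(Xc.T @ Xc)
    var = np.maximum(w[::-1], 0.0)
    V = V[:, ::-1]
    total = var.sum()
    if total == 0:
        raise ValueError("training matrix has zero variance")
    # rank cap: eigenvalues below numerical noise carry no variance
    ratio = np.cumsum(var) / total
    m = int(np.searchsorted(ratio, var_threshold - 1e-12) + 1)
    m = min(m, V.shape[1], min(train_matrix.shape[0] - 1, train_matrix.shape[1]))
    W = V[:, :m]
    return Xc @ W, (test_matrix - mean) @ W, m


def bh_adjust(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: reject hypotheses with p <= p_(i*).

    ``i*`` is the largest index with ``p_(i) <= (i/m) q`` (boundary
    inclusive). Returns a boolean rejection mask aligned with the input.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = q * (np.arange(1, m + 1) / m)
    passing = np.flatnonzero(sorted_p <= crit)
    mask = np.zeros(m, dtype=bool)
    if passing.size:
        cutoff = sorted_p[passing[-1]]
        mask = p <= cutoff
    return mask


def _paired_differences(E: EpochsSet, window: tuple[float, float]) -> np.ndarray:
    """Per-pair condition difference of window-mean amplitude, pairs x channels."""
    tmask = E.time_mask(*window)
    if not tmask.any():
        raise ValueError(f"select_window {window} contains no samples")
    amp = E.data[:, :, tmask].mean(axis=2)  # trials x channels
    pid = E.pair_ids
    valid = pid != PAIR_ID_NONE
    common = np.intersect1d(pid[valid & (E.labels == 0)], pid[valid & (E.labels == 1)])
    if common.size == 0:
        raise ValueError("no complete pairs available")
    idx0 = {p: i for i, p in zip(np.flatnonzero(E.labels == 0), pid[E.labels == 0])}
    idx1 = {p: i for i, p in zip(np.flatnonzero(E.labels == 1), pid[E.labels == 1])}
    rows0 = [idx0[p] for p in common]
    rows1 = [idx1[p] for p in common]
    return amp[rows1] - amp[rows0]


def _one_sample_t(diffs: np.ndarray) -> np.ndarray:
    """Vectorised one-sample t over axis 0 (observations)."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    sd = np.where(sd == 0, np.inf, sd)
    return mean / (sd / np.sqrt(n))


def univariate_select_channels(E: EpochsSet, spec: ReducerSpec) -> np.ndarray:
    """Channels whose condition effect survives a permutation t-test + BH.

    Per channel the score is the t-statistic of the condition difference of
    per-trial mean amplitude over ``spec.select_window``, paired across
    ``pair_ids`` when available. The permutation null flips signs within
    pairs (or shuffles labels in the unpaired fallback); two-sided p-values
    use the add-one rule ``(1 + #{|t_perm| >= |t_obs|}) / (1 + B)`` and are
    BH-adjusted at ``spec.bh_q`` across channels.
    """
    spec.validate()
    if spec.n_permutations < 100 and not spec.parametric:
        warnings.warn("n_permutations < 100 gives coarse p-values")
    rng = np.random.default_rng(spec.seed)

    use_paired = spec.paired and (E.pair_ids != PAIR_ID_NONE).any()
    if use_paired:
        diffs = _paired_differences(E, spec.select_window)  # pairs x channels
        t_obs = _one_sample_t(diffs)
        if spec.parametric:
            p = 2 * sp_stats.t.sf(np.abs(t_obs), df=diffs.shape[0] - 1)
        else:
            B = spec.n_permutations
            signs = rng.choice([-1.0, 1.0], size=(B, diffs.shape[0]))
            count = np.zeros(diffs.shape[1])
            for b in range(B):
                t_perm = _one_sample_t(diffs * signs[b][:, None])
                count += np.abs(t_perm) >= np.abs(t_obs)
            p = (1.0 + count) / (1.0 + B)
    else:
        tmask = E.time_mask(*spec.select_window)
        amp = E.data[:, :, tmask].mean(axis=2)
        t_obs = _welch_t(amp[E.labels == 1], amp[E.labels == 0])
        if spec.parametric:
            n1, n0 = (E.labels == 1).sum(), (E.labels == 0).sum()
            p = 2 * sp_stats.t.sf(np.abs(t_obs), df=min(n0, n1) - 1)
        else:
            B = spec.n_permutations
            count = np.zeros(amp.shape[1])
            labels = E.labels.copy()
            for _ in range(B):
                perm = rng.permutation(labels)
                t_perm = _welch_t(amp[perm == 1], amp[perm == 0])
                count += np.abs(t_perm) >= np.abs(t_obs)
            p = (1.0 + count) / (1.0 + B)

    mask = bh_adjust(p, spec.bh_q)
    if not mask.any():
        warnings.warn("no channel survived BH selection; caller decides fallback")
    return mask


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    va = a.var(axis=0, ddof=1) / a.shape[0]
    vb = b.var(axis=0, ddof=1) / b.shape[0]
    denom = np.sqrt(va + vb)
    denom = np.where(denom == 0, np.inf, denom)
    return (a.mean(axis=0) - b.mean(axis=0)) / denom
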