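"""Mutual information between benchmark and reduced representations.

Quantifies how much information a reduction operation (channel, trial or
temporal) preserves about the full-channel data. Observations are
per-(trial, timepoint) channel vectors paired through the reduction mapping.
The estimator (i) fits Gaussian mixtures (AIC-selected component count) to
the benchmark, operated and joint samples, (ii) draws Monte-Carlo samples
from the joint mixture, and (iii) estimates MI on those samples with the
Kraskov-Stoegbauer-Grassberger (KSG) k-nearest-neighbour estimator, with the
mixture-density log-ratio retained as a diagnostic. A closed-form Gaussian
MI serves as the independent oracle in tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats
from scipy.special import digamma
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import KDTree

from . import collapse as clps
from .containers import EpochsSet
from .dimreduction import ReducerSpec, pca_reduce

__all__ = [
    "ReductionPair",
    "MIResult",
    "CorrelationResult",
    "build_reduction_pairs",
    "fit_gmm_aic",
    "ksg_mi",
    "estimate_mi",
    "gaussian_mi_closed_form",
    "mi_accuracy_correlation",
    "mi_dimension_ttests",
]


@dataclass
class ReductionPair:
    """Row-aligned benchmark/reduced observation matrices."""

    benchmark: np.ndarray  # observations x d_x
    operated: np.ndarray  # observations x d_y
    mapping: dict = field(default_factory=dict)
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.benchmark = np.atleast_2d(np.asarray(self.benchmark, dtype=float))
        self.operated = np.atleast_2d(np.asarray(self.operated, dtype=float))
        if self.benchmark.shape[0] != self.operated.shape[0]:
            raise ValueError("benchmark and operated must have equal row counts")


@dataclass
class MIResult:
    """KSG mutual-information estimate with fitting metadata."""

    mi_per_repeat: np.ndarray
    mi_mean: float
    mi_density_per_repeat: np.ndarray
    n_components_x: int
    n_components_y: int
    n_components_joint: int
    n_mc_samples: int
    k_nn: int
    seed: int


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    x_label: str = "mi"
    y_label: str = "accuracy_difference"


# ----------------------------------------------------------------------
# reduction pairs
# ----------------------------------------------------------------------

def _flatten_observations(E: EpochsSet) -> np.ndarray:
    """(trial, timepoint) channel vectors: (n_trials * n_times) x n_channels."""
    return np.transpose(E.data, (0, 2, 1)).reshape(-1, E.n_channels)


def build_reduction_pairs(
    E: EpochsSet,
    operation: clps.CollapseConfig | ReducerSpec | np.ndarray,
    max_observations: int | None = 20000,
    seed: int = 0,
) -> ReductionPair:
    """Pair each (trial, timepoint) observation with its reduced counterpart.

    ``operation`` may be a boolean channel mask, a :class:`ReducerSpec`
    (PCA channel reduction), or a :class:`CollapseConfig` describing trial
    averaging, resampling or sliding-window reduction. Observations are the
    full channel vectors at each (trial, timepoint) sample; the operated row
    is the representation the operation assigns to that sample.
    """
    X = _flatten_observations(E)
    n_trials, n_times = E.n_trials, E.n_times

    if isinstance(operation, np.ndarray):
        mask = np.asarray(operation, dtype=bool)
        Y = _flatten_observations(E.select_channels(mask))
        mapping = {"dimension": "channel", "kind": "mask", "n_kept": int(mask.sum())}
    elif isinstance(operation, ReducerSpec):
        operation.validate()
        if operation.method != "pca":
            raise ValueError("channel reduction supports method='pca' or a mask")
        # unsupervised fit on the full observation set (no labels involved)
        Yfit, _, m = pca_reduce(X, X[:1], operation.pca_var_threshold)
        Y = Yfit
        mapping = {"dimension": "channel", "kind": "pca", "n_components": int(m)}
    elif isinstance(operation, clps.CollapseConfig):
        operation.validate(E.sfreq)
        if operation.avg_group_size > 1:
            Y, mapping = _trial_average_pairs(E, operation)
        elif operation.resample_hz is not None and abs(operation.resample_hz - E.sfreq) > 1e-9:
            red = clps.resample_epochs(E, operation.resample_hz)
            # each original sample maps to the nearest decimated timepoint
            idx = np.clip(
                np.round((E.times - red.times[0]) * red.sfreq).astype(int),
                0,
                red.n_times - 1,
            )
            Y = np.transpose(red.data[:, :, idx], (0, 2, 1)).reshape(-1, red.n_channels)
            mapping = {"dimension": "temporal", "kind": "resample",
                       "target_hz": float(operation.resample_hz)}
        elif operation.window_len_ms is not None:
            red = clps.sliding_window_average(
                E, operation.window_len_ms, operation.window_step_fraction
            )
            # nearest window centre contains/represents each original sample
            idx = np.abs(E.times[:, None] - red.times[None, :]).argmin(axis=1)
            Y = np.transpose(red.data[:, :, idx], (0, 2, 1)).reshape(-1, red.n_channels)
            mapping = {"dimension": "temporal", "kind": "sliding_window",
                       "window_len_ms": float(operation.window_len_ms)}
        else:
            raise ValueError("CollapseConfig describes no reduction operation")
    else:
        raise ValueError(f"unsupported operation type: {type(operation)!r}")

    if X.shape[0] != Y.shape[0]:  # pragma: no cover - internal consistency
        raise RuntimeError("row alignment failed")
    if max_observations is not None and X.shape[0] > max_observations:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(X.shape[0], size=max_observations, replace=False))
        X, Y = X[keep], Y[keep]
    return ReductionPair(benchmark=X, operated=Y, mapping=mapping,
                         subject_id=E.subject_id)


def _trial_average_pairs(
    E: EpochsSet, operation: clps.CollapseConfig
) -> tuple[np.ndarray, dict]:
    """Operated row = the pseudo-trial vector of the group containing the trial."""
    k = operation.avg_group_size
    rng = np.random.default_rng(operation.seed)
    pseudo = np.zeros_like(E.data)
    member = np.zeros(E.n_trials, dtype=bool)
    for lab in (0, 1):
        idx = np.flatnonzero(E.labels == lab)
        if len(idx) < k:
            raise ValueError(f"condition {lab} has fewer trials than group_size={k}")
        perm = rng.permutation(idx)
        n_groups = len(idx) // k
        grouped = perm[: n_groups * k].reshape(n_groups, k)
        means = E.data[grouped].mean(axis=1)
        for g in range(n_groups):
            pseudo[grouped[g]] = means[g]
            member[grouped[g]] = True
    sub = E.select_trials(np.flatnonzero(member))
    Y = np.transpose(pseudo[member], (0, 2, 1)).reshape(-1, E.n_channels)
    # benchmark must drop the leftover trials too; rebuild both aligned
    X = _flatten_observations(sub)
    if X.shape[0] != Y.shape[0]:  # pragma: no cover
        raise RuntimeError("trial-average alignment failed")
    mapping = {"dimension": "trial", "kind": "average", "group_size": int(k)}
    return Y, mapping


# ----------------------------------------------------------------------
# density fitting and MI estimation
# ----------------------------------------------------------------------

def fit_gmm_aic(
    samples: np.ndarray,
    k_candidates: range | list[int] = range(1, 11),
    covariance_type: str | None = None,
    seed: int = 0,
) -> GaussianMixture:
    """Fit one Gaussian mixture per candidate size; keep the minimum-AIC fit.

    With fewer observations than ~5x the dimensionality a diagonal
    covariance is enforced for stability.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n, d = samples.shape
    if covariance_type is None:
        covariance_type = "full" if n >= 5 * d else "diag"
    best, best_aic = None, np.inf
    errors = []
    for k in k_candidates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm = GaussianMixture(
                    n_components=int(k),
                    covariance_type=covariance_type,
                    reg_covar=1e-6,
                    random_state=seed,
                    n_init=1,
                ).fit(samples)
            aic = gm.aic(samples)
        except Exception as exc:  # singular fit for this k
            errors.append(str(exc))
            continue
        if np.isfinite(aic) and aic < best_aic:
            best, best_aic = gm, aic
    if best is None:
        raise RuntimeError(
            "every mixture fit failed; try covariance_type='diag': "
            + "; ".join(errors[:2])
        )
    return best


def ksg_mi(x: np.ndarray, y: np.ndarray, k: int = 3) -> float:
    """KSG (algorithm 1) k-nearest-neighbour MI estimate in nats."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have equal sample counts")
    n = x.shape[0]
    if n <= k:
        raise ValueError("need more samples than k")
    joint = np.hstack([x, y])
    tree = KDTree(joint, metric="chebyshev")
    # distance to the k-th neighbour (excluding the point itself)
    dist, _ = tree.query(joint, k=k + 1)
    eps = dist[:, -1]
    tree_x = KDTree(x, metric="chebyshev")
    tree_y = KDTree(y, metric="chebyshev")
    # strictly-inside counts, excluding the query point itself
    nx = tree_x.query_radius(x, eps - 1e-12, count_only=True) - 1
    ny = tree_y.query_radius(y, eps - 1e-12, count_only=True) - 1
    return float(
        digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    )


def estimate_mi(
    pair: ReductionPair,
    n_mc_samples: int = 10000,
    k_nn: int = 3,
    repeats: int = 10,
    k_candidates: range | list[int] = range(1, 11),
    seed: int = 0,
) -> MIResult:
    """Monte-Carlo KSG estimate of MI between benchmark and operated data.

    Per repeat: fit AIC-selected Gaussian mixtures to the benchmark rows,
    the operated rows and their joint concatenation; draw ``n_mc_samples``
    points from the joint mixture; compute the KSG estimate on the sampled
    pairs (the mixture log-density ratio is kept as a diagnostic). The final
    value is the repeat mean, clipped at zero.
    """
    if n_mc_samples < 100:
        raise ValueError("n_mc_samples must be >= 100")
    X, Y = pair.benchmark, pair.operated
    d_x, d_y = X.shape[1], Y.shape[1]
    if Y.std(axis=0).max() == 0 or X.std(axis=0).max() == 0:
        warnings.warn("degenerate (zero-variance) data; MI = 0")
        zeros = np.zeros(repeats)
        return MIResult(zeros, 0.0, zeros, 0, 0, 0, n_mc_samples, k_nn, seed)
    joint = np.hstack([X, Y])

    mi_knn, mi_density = [], []
    ncx = ncy = ncj = 0
    for r in range(repeats):
        rep_seed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31))
        gm_x = fit_gmm_aic(X, k_candidates, seed=rep_seed)
        gm_y = fit_gmm_aic(Y, k_candidates, seed=rep_seed)
        gm_j = fit_gmm_aic(joint, k_candidates, seed=rep_seed)
        ncx, ncy, ncj = gm_x.n_components, gm_y.n_components, gm_j.n_components
        samples, _ = gm_j.sample(n_mc_samples)
        # sample order from sklearn is component-sorted; shuffle for safety
        rng = np.random.default_rng(rep_seed)
        samples = samples[rng.permutation(n_mc_samples)]
        sx, sy = samples[:, :d_x], samples[:, d_x:]
        logr = (
            gm_j.score_samples(samples)
            - gm_x.score_samples(sx)
            - gm_y.score_samples(sy)
        )
        mi_density.append(float(np.mean(logr)))
        mi_knn.append(ksg_mi(sx, sy, k=k_nn))

    mi_knn = np.asarray(mi_knn)
    return MIResult(
        mi_per_repeat=mi_knn,
        mi_mean=float(max(0.0, mi_knn.mean())),
        mi_density_per_repeat=np.asarray(mi_density),
        n_components_x=ncx,
        n_components_y=ncy,
        n_components_joint=ncj,
        n_mc_samples=n_mc_samples,
        k_nn=k_nn,
        seed=seed,
    )


def gaussian_mi_closed_form(
    joint_covariance: np.ndarray, d_x: int, d_y: int
) -> float:
    """MI of a jointly Gaussian pair: 1/2 [ln det Sx + ln det Sy - ln det S]."""
    S = np.asarray(joint_covariance, dtype=float)
    if S.shape != (d_x + d_y, d_x + d_y):
        raise ValueError("joint covariance shape must be (d_x+d_y, d_x+d_y)")
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise ValueError("joint covariance must be positive definite") from exc
    sx = S[:d_x, :d_x]
    sy = S[d_x:, d_x:]
    return float(
        0.5
        * (
            np.linalg.slogdet(sx)[1]
            + np.linalg.slogdet(sy)[1]
            - np.linalg.slogdet(S)[1]
        )
    )


# ----------------------------------------------------------------------
# downstream statistics
# ----------------------------------------------------------------------

def mi_accuracy_correlation(
    mi_values: np.ndarray,
    accuracy_differences: np.ndarray,
    x_label: str = "mi",
    y_label: str = "accuracy_difference",
) -> CorrelationResult:
    """Pearson correlation between MI and peak-accuracy differences.

    The two-sided p-value comes from ``t = r sqrt((n-2)/(1-r^2))`` on n-2
    degrees of freedom.
    """
    x = np.asarray(mi_values, dtype=float)
    y = np.asarray(accuracy_differences, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in an input")
    res = sp_stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), p=float(res.pvalue), n=len(x),
        x_label=x_label, y_label=y_label,
    )


def mi_dimension_ttests(
    mi_by_dimension: dict[str, np.ndarray],
) -> dict[tuple[str, str], tuple[float, float]]:
    """Pairwise Welch two-sided t-tests of MI across reduction dimensions."""
    for dim, vals in mi_by_dimension.items():
        if len(np.asarray(vals)) < 2:
            raise ValueError(f"dimension {dim!r} needs >= 2 values")
    out = {}
    for a, b in itertools.combinations(sorted(mi_by_dimension), 2):
        t, p = sp_stats.ttest_ind(
            mi_by_dimension[a], mi_by_dimension[b], equal_var=False
        )
        out[(a, b)] = (float(t), float(p))
    return out
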