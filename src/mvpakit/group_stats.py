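"""Cross-subject inference on decoding curves.

With six subjects, large-sample approximations to the Wilcoxon signed-rank
null are invalid, so the one-sided test against chance is computed exactly by
enumerating the distribution of the positive rank sum over all 2^n sign
assignments (via a subset-sum count, so midranks from ties are handled
exactly). No correction is applied across timepoints: significance is read
per timepoint, a deliberate and documented caveat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .decoding import AccuracyCurve

__all__ = [
    "GroupResult",
    "wilcoxon_signed_rank_exact",
    "group_significance",
    "difference_curves",
]

#: Above this n the exact enumeration switches to a normal approximation.
EXACT_N_MAX = 25


@dataclass
class GroupResult:
    """Per-timepoint group test of decoding accuracy against a reference."""

    times: np.ndarray
    mean_accuracy: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    alpha: float
    n_subjects: int
    alternative: str = "greater"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean_accuracy = np.asarray(self.mean_accuracy, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        self.significant = np.asarray(self.significant, dtype=bool)
        if (self.p_values < 0).any() or (self.p_values > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        if not np.array_equal(self.significant, self.p_values <= self.alpha):
            raise ValueError("significant mask must equal p <= alpha")


def _exact_p_greater(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ >= w_obs) under the exact sign-flip null.

    ``ranks`` are midranks of |diffs| (multiples of 0.5). The distribution
    of the positive rank sum is built by subset-sum counting over all 2^n
    sign patterns on the doubled-integer scale.
    """
    r2 = np.round(ranks * 2).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w2 = int(np.ceil(np.round(w_obs * 2, 6) - 1e-9))
    w2 = max(0, min(w2, total + 1))
    return float(counts[w2:].sum() / 2.0 ** len(r2))


def wilcoxon_signed_rank_exact(
    diffs: np.ndarray, alternative: str = "greater"
) -> float:
    """One-sided signed-rank p-value, exact for n <= 25.

    Zeros are dropped before ranking; ties receive midranks. For larger n a
    tie-corrected normal approximation with continuity correction is used.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    diffs = np.asarray(diffs, dtype=float)
    if alternative == "less":
        return wilcoxon_signed_rank_exact(-diffs, "greater")
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        warnings.warn("all differences are zero; returning p = 1")
        return 1.0
    ranks = sp_stats.rankdata(np.abs(diffs))
    w_plus = float(ranks[diffs > 0].sum())
    if n <= EXACT_N_MAX:
        return _exact_p_greater(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = (w_plus - mean - 0.5) / np.sqrt(var)
    return float(sp_stats.norm.sf(z))


def _check_common_grid(curves: list[AccuracyCurve]) -> np.ndarray:
    times = curves[0].times
    for c in curves[1:]:
        if len(c.times) != len(times) or np.abs(c.times - times).max() > 1e-9:
            raise ValueError("curves must share a common time grid")
    return times


def group_significance(
    curves: list[AccuracyCurve], chance: float = 0.5, alpha: float = 0.05
) -> GroupResult:
    """Per-timepoint one-sided exact Wilcoxon of subject accuracies vs chance."""
    if not curves:
        raise ValueError("need at least one curve")
    times = _check_common_grid(curves)
    acc = np.stack([c.accuracy for c in curves])  # subjects x timepoints
    diffs = acc - chance
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-zero columns legitimately give p = 1
        p = np.array(
            [wilcoxon_signed_rank_exact(diffs[:, t]) for t in range(diffs.shape[1])]
        )
    return GroupResult(
        times=times,
        mean_accuracy=acc.mean(axis=0),
        p_values=p,
        significant=p <= alpha,
        alpha=alpha,
        n_subjects=len(curves),
    )


def difference_curves(
    curves_a: list[AccuracyCurve],
    curves_b: list[AccuracyCurve],
    alpha: float = 0.05,
) -> GroupResult:
    """One-sided test of per-subject accuracy differences (a - b) against zero."""
    ids_a = [c.subject_id for c in curves_a]
    ids_b = [c.subject_id for c in curves_b]
    if sorted(ids_a) != sorted(ids_b):
        raise ValueError("subject sets differ between the two curve lists")
    by_id = {c.subject_id: c for c in curves_b}
    ordered_b = [by_id[i] for i in ids_a]
    times = _check_common_grid(list(curves_a) + ordered_b)
    diff = np.stack(
        [a.accuracy - b.accuracy for a, b in zip(curves_a, ordered_b)]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = np.array(
            [wilcoxon_signed_rank_exact(diff[:, t]) for t in range(diff.shape[1])]
        )
    return GroupResult(
        times=times,
        mean_accuracy=diff.mean(axis=0),
        p_values=p,
        significant=p <= alpha,
        alpha=alpha,
        n_subjects=len(curves_a),
    )
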