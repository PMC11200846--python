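"""Null-model calibration experiments.

Empirical checks that the decoding pipeline and the group test behave
correctly when labels carry no information: the cross-validated accuracy of
the default pipeline should sit at chance, and the per-timepoint exact
Wilcoxon test should reject at most its nominal rate. Both experiments
regenerate their synthetic cohorts from scratch at every call.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .collapse import CollapseConfig
from .decoding import PipelineConfig, decode_timecourse
from .group_stats import group_significance
from .synthetic import SimulationSpec, generate_subject_modality

__all__ = ["null_chance_accuracy", "null_rejection_rate"]


def null_chance_accuracy(
    n_replicates: int = 20,
    n_subjects: int = 2,
    seed: int = 0,
) -> dict:
    """Mean default-pipeline accuracy on null cohorts (no condition effect).

    Generates ``n_replicates`` cohorts of ``n_subjects`` magnetometer
    subjects with ``effect_amplitude = 0`` (192 balanced trials, 40
    channels, 1000 Hz), runs the default pipeline (resample to 200 Hz, PCA
    at 99% variance, LDA, stratified 10-fold) per subject, and averages
    accuracy over timepoints, subjects and replicates.
    """
    base = SimulationSpec(
        n_subjects=n_subjects, n_trials=192, effect_amplitude=0.0
    )
    means = []
    for r in range(1, n_replicates + 1):
        spec = replace(base, seed=int(seed) + r)
        config = PipelineConfig(seed=int(seed) + r)
        for s in range(n_subjects):
            E = generate_subject_modality(spec, s, "meg")
            curve = decode_timecourse(E, config)
            means.append(curve.accuracy.mean())
    means = np.asarray(means)
    return {
        "mean_accuracy": float(means.mean()),
        "sd_across_decodes": float(means.std()),
        "n_replicates": n_replicates,
        "n_subjects": n_subjects,
        "n_timepoints": 240,
    }


def null_rejection_rate(
    n_cohorts: int = 200,
    n_subjects: int = 6,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Per-timepoint rejection rate of the group test on null cohorts.

    Simulates ``n_cohorts`` cohorts of ``n_subjects`` null subjects on a
    reduced 50-timepoint grid (native 50 Hz over -0.2..0.8 s, 64 trials, 40
    channels), decodes each subject with the default reducer/classifier/CV
    (no resampling needed at the native grid), applies the one-sided exact
    Wilcoxon against chance at each timepoint, and reports the fraction of
    significant (timepoint, cohort) pairs.
    """
    base = SimulationSpec(
        n_subjects=n_subjects,
        n_trials=64,
        sfreq=50.0,
        epoch_window=(-0.2, 0.8),
        effect_amplitude=0.0,
    )
    n_sig = 0
    n_total = 0
    for c in range(1, n_cohorts + 1):
        spec = replace(base, seed=int(seed) + c)
        config = PipelineConfig(
            collapse=CollapseConfig(resample_hz=None), seed=int(seed) + c
        )
        curves = [
            decode_timecourse(generate_subject_modality(spec, s, "meg"), config)
            for s in range(n_subjects)
        ]
        result = group_significance(curves, chance=0.5, alpha=alpha)
        n_sig += int(result.significant.sum())
        n_total += len(result.significant)
    return {
        "rejection_rate": n_sig / n_total,
        "n_significant": n_sig,
        "n_tests": n_total,
        "alpha": alpha,
        "n_cohorts": n_cohorts,
        "n_subjects": n_subjects,
    }
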