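"""Comparative experiment grids.

Runs the full per-subject decode plus group inference while one pipeline
axis varies and everything else (including seeds) is held fixed, and renders
the overlaid mean-curve / significance-disc comparison plot.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochsSet
from .decoding import PipelineConfig, decode_timecourse, fuse_modalities
from .group_stats import GroupResult, group_significance

__all__ = ["GRID_AXES", "apply_axis_level", "run_experiment_grid", "plot_group_results"]

GRID_AXES = ("dr", "subsample", "window", "avg_trials", "classifier", "cv", "modality")


def apply_axis_level(config: PipelineConfig, axis: str, level) -> PipelineConfig:
    """Return a config with one axis set to ``level``; all else untouched."""
    if axis == "dr":
        if level not in ("none", "pca", "univariate"):
            raise ValueError(f"unknown dr level {level!r}")
        return replace(config, reducer=replace(config.reducer, method=level))
    if axis == "subsample":
        hz = None if level in (None, "none") else float(level)
        return replace(config, collapse=replace(config.collapse, resample_hz=hz))
    if axis == "window":
        ms = None if level in (None, "none") else float(level)
        return replace(config, collapse=replace(config.collapse, window_len_ms=ms))
    if axis == "avg_trials":
        return replace(
            config, collapse=replace(config.collapse, avg_group_size=int(level))
        )
    if axis == "classifier":
        if level not in ("lda", "ridge", "svm_sigmoid"):
            raise ValueError(f"unknown classifier level {level!r}")
        return replace(config, classifier=replace(config.classifier, kind=level))
    if axis == "cv":
        return replace(config, cv_folds=int(level))
    if axis == "modality":
        if level not in ("meg", "eeg", "fused"):
            raise ValueError(f"unknown modality level {level!r}")
        return config  # modality is resolved on the data side
    raise ValueError(f"unknown axis {axis!r}; valid axes: {GRID_AXES}")


def _epochs_for_level(
    subject: tuple[EpochsSet, EpochsSet], axis: str, level, seed: int
) -> EpochsSet:
    meg, eeg = subject
    if axis != "modality" or level == "meg":
        return meg
    if level == "eeg":
        return eeg
    return fuse_modalities(meg, eeg, seed=seed)


def run_experiment_grid(
    cohort: list[tuple[EpochsSet, EpochsSet]],
    base_config: PipelineConfig,
    axis: str,
    levels: list,
    alpha: float = 0.05,
    out_dir: str | Path | None = None,
) -> dict:
    """Decode every subject at every level of one axis and test at group level.

    Returns ``{level: GroupResult}``; when ``out_dir`` is given, also writes
    a tidy CSV of (level, time_s, mean_accuracy, p, significant) and the
    comparison figure.
    """
    # validate all levels before any computation
    for level in levels:
        apply_axis_level(base_config, axis, level)

    results: dict = {}
    for level in levels:
        config = apply_axis_level(base_config, axis, level)
        curves = [
            decode_timecourse(
                _epochs_for_level(subj, axis, level, base_config.seed), config
            )
            for subj in cohort
        ]
        results[level] = group_significance(
            curves, chance=config.chance_level, alpha=alpha
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = [
            {
                "level": str(level),
                "time_s": t,
                "mean_accuracy": a,
                "p": p,
                "significant": bool(s),
            }
            for level, gr in results.items()
            for t, a, p, s in zip(
                gr.times, gr.mean_accuracy, gr.p_values, gr.significant
            )
        ]
        pd.DataFrame(rows).to_csv(out_dir / f"grid_{axis}.csv", index=False)
        plot_group_results(
            results,
            chance=base_config.chance_level,
            title=f"axis: {axis}",
            path=out_dir / f"grid_{axis}.png",
        )
    return results


def plot_group_results(
    results: dict[object, GroupResult],
    chance: float = 0.5,
    title: str = "",
    path: str | Path | None = None,
):
    """Overlaid mean decoding curves with significance discs and peak markers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    disc_base = chance - 0.06
    for i, (level, gr) in enumerate(results.items()):
        (line,) = ax.plot(gr.times, gr.mean_accuracy, label=str(level), lw=1.3)
        color = line.get_color()
        if gr.significant.any():
            y = np.full(gr.significant.sum(), disc_base - 0.012 * i)
            ax.plot(gr.times[gr.significant], y, ".", ms=3, color=color)
        peak = int(np.argmax(gr.mean_accuracy))
        ax.plot(
            gr.times[peak], gr.mean_accuracy[peak], "v", ms=6, color=color
        )
    ax.axhline(chance, color="k", lw=0.8, ls="--")
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("decoding accuracy")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
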