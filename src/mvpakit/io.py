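"""File formats and run provenance.

HDF5 is the canonical interchange format (self-describing and exact); FIF is
supported for ecosystem interoperability via MNE. Pipeline and simulation
configurations round-trip through YAML.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import yaml

from .containers import EpochsSet
from .decoding import PipelineConfig
from .synthetic import SimulationSpec

__all__ = [
    "read_epochs",
    "write_epochs",
    "epochs_to_mne",
    "epochs_from_mne",
    "load_pipeline_config",
    "save_pipeline_config",
    "load_simulation_spec",
    "save_simulation_spec",
    "RunManifest",
]

_REQUIRED_DATASETS = ("data", "labels", "pair_ids", "times")
_REQUIRED_ATTRS = ("sfreq", "modality", "subject_id", "channel_ids")


def write_epochs(E: EpochsSet, path: str | Path) -> None:
    """Write an :class:`EpochsSet` to the HDF5 layout (bit-exact round trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=E.data)
        f.create_dataset("labels", data=E.labels)
        f.create_dataset("pair_ids", data=E.pair_ids)
        f.create_dataset("times", data=E.times)
        f.attrs["sfreq"] = E.sfreq
        f.attrs["modality"] = E.modality
        f.attrs["subject_id"] = E.subject_id
        f.attrs["channel_ids"] = [str(c) for c in E.channel_ids]


def _read_hdf5(path: str | Path) -> EpochsSet:
    with h5py.File(path, "r") as f:
        missing = [k for k in _REQUIRED_DATASETS if k not in f] + [
            a for a in _REQUIRED_ATTRS if a not in f.attrs
        ]
        if missing:
            raise ValueError(f"epochs file {path} is missing fields: {missing}")
        return EpochsSet(
            data=f["data"][()],
            labels=f["labels"][()],
            pair_ids=f["pair_ids"][()],
            times=f["times"][()],
            sfreq=float(f.attrs["sfreq"]),
            modality=str(f.attrs["modality"]),
            subject_id=str(f.attrs["subject_id"]),
            channel_ids=[str(c) for c in f.attrs["channel_ids"]],
        )


def epochs_to_mne(E: EpochsSet):
    """Convert to an :class:`mne.EpochsArray` (labels in events, pairs in metadata)."""
    import mne
    import pandas as pd

    ch_type = {"meg": "mag", "eeg": "eeg", "fused": "misc"}[E.modality]
    info = mne.create_info(
        ch_names=list(E.channel_ids), sfreq=E.sfreq, ch_types=ch_type
    )
    events = np.column_stack(
        [
            np.arange(E.n_trials) * (E.n_times + 1),
            np.zeros(E.n_trials, dtype=int),
            E.labels + 1,
        ]
    ).astype(int)
    metadata = pd.DataFrame({"pair_id": E.pair_ids, "label": E.labels})
    return mne.EpochsArray(
        E.data,
        info,
        events=events,
        tmin=float(E.times[0]),
        event_id={"congruent": 1, "incongruent": 2},
        metadata=metadata,
        verbose="error",
    )


def epochs_from_mne(epochs, modality: str, subject_id: str = "unknown") -> EpochsSet:
    """Build an :class:`EpochsSet` from an MNE epochs object written by this package."""
    if epochs.metadata is None or "pair_id" not in epochs.metadata:
        raise ValueError("FIF file lacks pair_id metadata; fields missing: ['pair_id']")
    return EpochsSet(
        data=epochs.get_data(copy=True),
        labels=epochs.metadata["label"].to_numpy(),
        pair_ids=epochs.metadata["pair_id"].to_numpy(),
        times=epochs.times,
        sfreq=float(epochs.info["sfreq"]),
        channel_ids=list(epochs.ch_names),
        modality=modality,
        subject_id=subject_id,
    )


def read_epochs(path: str | Path, format: str | None = None) -> EpochsSet:
    """Read epochs from HDF5 (canonical) or FIF (via MNE)."""
    path = Path(path)
    if format is None:
        format = "fif" if path.suffix == ".fif" else "hdf5"
    if format == "hdf5":
        try:
            return _read_hdf5(path)
        except OSError as exc:
            raise ValueError(f"cannot read {path} as HDF5: {exc}") from exc
    if format == "fif":
        import mne

        epochs = mne.read_epochs(path, preload=True, verbose="error")
        ch_type = set(epochs.get_channel_types())
        modality = "meg" if ch_type <= {"mag", "grad"} else (
            "eeg" if ch_type == {"eeg"} else "fused"
        )
        return epochs_from_mne(epochs, modality)
    raise ValueError("format must be 'hdf5' or 'fif'")


def write_epochs_fif(E: EpochsSet, path: str | Path) -> None:
    epochs_to_mne(E).save(path, overwrite=True, verbose="error")


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

def save_pipeline_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def save_simulation_spec(spec: SimulationSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


def load_simulation_spec(path: str | Path) -> SimulationSpec:
    return SimulationSpec.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    """Provenance record tying outputs to their config, inputs and seeds."""

    config: dict
    input_paths: list[str] = field(default_factory=list)
    output_paths: list[str] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    software_version: str = ""
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def to_json(self, path: str | Path | None = None) -> str:
        blob = json.dumps(asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(blob)
        return blob
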