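"""Epoch archive container: one HDF5 array file per subject + JSON sidecar.

The payload is a ``channels x samples x trials`` float32 dataset (microvolts)
named ``epochs``; the sidecar carries everything needed to interpret it:
subject id, sampling rate, time grid endpoints, channel names, per-trial
labels, and free-form provenance (seed, generator parameters). Keeping the
metadata in plain JSON next to the binary payload means a cohort directory is
self-describing without opening HDF5.

Round-trips are bit-exact at float32 precision. A payload whose shape
disagrees with its sidecar (e.g. a truncated copy) raises
:class:`IntegrityError` rather than returning a partial read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .features import EpochSet

__all__ = ["SCHEMA_VERSION", "write_epoch_archive", "read_epoch_archive",
           "read_cohort", "import_raw_epochs"]

SCHEMA_VERSION = 1


class IntegrityError(IOError):
    """Archive payload and sidecar disagree."""


class SchemaVersionError(IOError):
    """Archive written by an incompatible schema version."""


def _sidecar_path(h5_path: Path) -> Path:
    return h5_path.with_suffix(".json")


def write_epoch_archive(
    epoch_set: EpochSet, path: str | Path, extra_meta: dict | None = None
) -> Path:
    """Write one subject's epochs; returns the HDF5 path."""
    path = Path(path)
    data = epoch_set.to_array().astype(np.float32)
    times = epoch_set.times_ms
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=data)
        f.attrs["schema_version"] = SCHEMA_VERSION
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": epoch_set.subject_id,
        "sampling_rate_hz": epoch_set.sampling_rate_hz,
        "times_ms_start": float(times[0]),
        "n_samples": int(times.size),
        "channel_names": list(epoch_set.channel_names),
        "labels": [int(x) for x in epoch_set.labels],
        "n_trials": len(epoch_set),
    }
    if extra_meta:
        sidecar["meta"] = extra_meta
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_epoch_archive(path: str | Path) -> EpochSet:
    """Read one subject archive, verifying sidecar/payload consistency."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise IntegrityError(f"missing sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    version = sidecar.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"archive schema version {version} != supported {SCHEMA_VERSION}; "
            "re-export the archive with a matching tool version"
        )
    try:
        with h5py.File(path, "r") as f:
            data = f["epochs"][()]
    except OSError as exc:
        raise IntegrityError(f"unreadable payload {path}: {exc}") from exc
    expected = (
        len(sidecar["channel_names"]),
        sidecar["n_samples"],
        sidecar["n_trials"],
    )
    if data.shape != expected:
        raise IntegrityError(
            f"payload shape {data.shape} != sidecar shape {expected} for {path}"
        )
    if len(sidecar["labels"]) != sidecar["n_trials"]:
        raise IntegrityError(f"label count mismatch in sidecar {sidecar_file}")
    fs = float(sidecar["sampling_rate_hz"])
    times = sidecar["times_ms_start"] + np.arange(sidecar["n_samples"]) * 1000.0 / fs
    return EpochSet.from_array(
        data.astype(float),
        times,
        sidecar["labels"],
        fs,
        sidecar["channel_names"],
        sidecar["subject_id"],
    )


def read_cohort(directory: str | Path) -> list[EpochSet]:
    """Read all subject archives in a directory (sorted by filename) and check
    that they share one label sequence."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.h5"))
    if not paths:
        raise FileNotFoundError(f"no .h5 archives in {directory}")
    cohort = [read_epoch_archive(p) for p in paths]
    ref = cohort[0].labels
    for es in cohort[1:]:
        if not np.array_equal(es.labels, ref):
            raise IntegrityError(
                f"label sequence of subject {es.subject_id!r} differs from "
                f"{cohort[0].subject_id!r}; cohort archives must share one "
                "trial sequence"
            )
    return cohort


def import_raw_epochs(
    path: str | Path,
    channel_map: Sequence[str],
    event_id: dict[str, int],
    tmin_s: float = -0.1,
    tmax_s: float = 0.7,
    subject_id: str = "",
) -> EpochSet:
    """Import externally recorded epochs from an EDF/BDF file via MNE.

    ``channel_map`` selects (and orders) the channels to keep; ``event_id``
    maps annotation names to the +-1 condition labels. Requires the optional
    ``mne`` dependency.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF/BDF import requires the optional 'mne' package") from exc
    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    raw.pick(list(channel_map))
    events, mapping = mne.events_from_annotations(raw, verbose="error")
    keep = {k: v for k, v in mapping.items() if k in event_id}
    epochs = mne.Epochs(
        raw, events, event_id=keep, tmin=tmin_s, tmax=tmax_s,
        baseline=None, preload=True, verbose="error",
    )
    data_uv = epochs.get_data() * 1e6  # trials x channels x samples, V -> uV
    code_to_label = {v: event_id[k] for k, v in keep.items()}
    labels = [code_to_label[code] for code in epochs.events[:, 2]]
    times_ms = epochs.times * 1000.0
    return EpochSet.from_array(
        np.moveaxis(data_uv, 0, -1), times_ms, labels,
        float(raw.info["sfreq"]), list(channel_map), subject_id,
    )
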