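"""Multichannel EEG recordings and their on-disk array-archive format.

A :class:`Recording` is the raw input of the pipeline: a channels x samples
matrix with a sampling rate and ordered channel labels, plus the cohort
metadata (subject, group, eye state) that is propagated down to every
mini-epoch.

The array-archive format is a compressed ``.npz`` holding the sample matrix
next to a JSON sidecar with labels, sampling rate and metadata.  It is the
fixture/synthetic-cohort format; clinical EDF files are handled by
:mod:`stgcn_eeg.edf`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: Recognised group labels for the two-class problem.
GROUPS = ("AD-like", "HC-like")
#: Eye states of the resting-state protocol.
EYE_STATES = ("EC", "EO")


@dataclass
class Recording:
    """Labelled multichannel EEG segment.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``.
    fs
        Sampling rate in Hz.
    channel_labels
        Unique channel names, one per row of ``samples``.
    subject_id, group, eye_state, epoch_index
        Cohort metadata carried through preprocessing.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = ""
    group: str = ""
    eye_state: str = ""
    epoch_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x samples)")
        if self.samples.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray, *, fs: float | None = None,
                     channel_labels: list[str] | None = None) -> "Recording":
        """Copy of this recording with new signal content, same metadata."""
        return replace(
            self,
            samples=samples,
            fs=self.fs if fs is None else fs,
            channel_labels=(self.channel_labels if channel_labels is None
                            else channel_labels),
        )


def save_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as ``<path>.npz`` plus ``<path>.json`` sidecar."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix in {".npz", ".json"} else path
    np.savez_compressed(base.with_suffix(".npz"), samples=rec.samples)
    sidecar = {
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "subject_id": rec.subject_id,
        "group": rec.group,
        "eye_state": rec.eye_state,
        "epoch_index": rec.epoch_index,
        "meta": rec.meta,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return base.with_suffix(".npz")


def load_recording(path: str | Path, format: str = "auto") -> Recording:
    """Read a recording from disk.

    Parameters
    ----------
    path
        ``.npz``/``.json`` base path of an array archive, or an ``.edf`` file.
    format
        ``"array-archive"``, ``"EDF"`` or ``"auto"`` (by extension).
    """
    path = Path(path)
    if format == "auto":
        format = "EDF" if path.suffix.lower() == ".edf" else "array-archive"
    if format.upper() == "EDF":
        from .edf import read_edf

        return read_edf(path)
    if format != "array-archive":
        raise ValueError(f"unknown format {format!r}")

    base = path.with_suffix("") if path.suffix in {".npz", ".json"} else path
    npz_path = base.with_suffix(".npz")
    json_path = base.with_suffix(".json")
    if not npz_path.exists():
        raise FileNotFoundError(npz_path)
    try:
        with np.load(npz_path) as archive:
            samples = archive["samples"]
    except Exception as exc:  # zipfile/format problems -> uniform I/O error
        raise OSError(f"unreadable array archive {npz_path}: {exc}") from exc
    if not json_path.exists():
        raise ValueError(f"missing sidecar {json_path} (channel labels required)")
    sidecar = json.loads(json_path.read_text())
    if "channel_labels" not in sidecar or "fs" not in sidecar:
        raise ValueError(f"sidecar {json_path} lacks channel_labels/fs")
    return Recording(
        samples=samples,
        fs=float(sidecar["fs"]),
        channel_labels=sidecar["channel_labels"],
        subject_id=sidecar.get("subject_id", ""),
        group=sidecar.get("group", ""),
        eye_state=sidecar.get("eye_state", ""),
        epoch_index=int(sidecar.get("epoch_index", 0)),
        meta=sidecar.get("meta", {}),
    )
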