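"""Reading and writing recordings.

The native on-disk format is a plain ``<subject>.npy`` channels x samples
matrix with a ``<subject>.json`` sidecar (labels, rate, group, MoCA) and a
cohort-level ``manifest.csv``.  EDF files are read through MNE when it is
installed (``pip install eegdtf[edf]``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Union

import numpy as np

from .recording import EEGRecording

__all__ = ["save_recording", "load_recording", "load_dir", "read_edf", "read_matrix"]


def save_recording(rec: EEGRecording, out_dir: Union[str, Path]) -> Path:
    """Write ``<subject_id>.npy`` + ``<subject_id>.json`` into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not rec.subject_id:
        raise ValueError("recording needs a subject_id to be saved")
    np.save(out_dir / f"{rec.subject_id}.npy", rec.data)
    sidecar = {
        "subject_id": rec.subject_id,
        "channel_labels": list(rec.channel_labels),
        "sample_rate": rec.sample_rate,
        "group": rec.group,
        "moca": rec.moca,
    }
    path = out_dir / f"{rec.subject_id}.json"
    path.write_text(json.dumps(sidecar, indent=2))
    return path


def load_recording(base: Union[str, Path]) -> EEGRecording:
    """Load one recording from ``<base>.npy`` + ``<base>.json`` (``base``
    may include either extension or none)."""
    base = Path(base)
    stem = base.with_suffix("") if base.suffix in {".npy", ".json"} else base
    meta = json.loads(Path(f"{stem}.json").read_text())
    data = np.load(f"{stem}.npy")
    return EEGRecording(
        data=data,
        channel_labels=tuple(meta["channel_labels"]),
        sample_rate=float(meta["sample_rate"]),
        subject_id=meta.get("subject_id", stem.name),
        group=meta.get("group"),
        moca=meta.get("moca"),
    )


def load_dir(in_dir: Union[str, Path]) -> List[EEGRecording]:
    """Load every ``*.npy``/``*.json`` recording pair in a directory,
    sorted by subject id."""
    in_dir = Path(in_dir)
    recs = [load_recording(p) for p in sorted(in_dir.glob("*.npy"))]
    if not recs:
        raise FileNotFoundError(f"no recordings found in {in_dir}")
    return recs


def read_matrix(
    matrix_path: Union[str, Path],
    sidecar_path: Optional[Union[str, Path]] = None,
) -> EEGRecording:
    """Read a plain-text numeric channels x samples matrix (whitespace- or
    comma-delimited) with a JSON sidecar describing labels and rate."""
    matrix_path = Path(matrix_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else matrix_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    try:
        data = np.loadtxt(matrix_path, delimiter=",")
    except ValueError:
        data = np.loadtxt(matrix_path)
    return EEGRecording(
        data=np.atleast_2d(data),
        channel_labels=tuple(meta["channel_labels"]),
        sample_rate=float(meta["sample_rate"]),
        subject_id=meta.get("subject_id", matrix_path.stem),
        group=meta.get("group"),
        moca=meta.get("moca"),
    )


def read_edf(
    path: Union[str, Path],
    subject_id: str = "",
    group: Optional[str] = None,
    moca: Optional[float] = None,
) -> EEGRecording:
    """Read an EDF file via MNE (optional dependency); data returned in uV."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading EDF requires mne; install with `pip install eegdtf[edf]`"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(
        data=data,
        channel_labels=tuple(raw.ch_names),
        sample_rate=float(raw.info["sfreq"]),
        subject_id=subject_id or Path(path).stem,
        group=group,
        moca=moca,
    )
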