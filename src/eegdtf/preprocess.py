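"""Preprocessing chain for resting-state EEG.

Order of operations: common average reference -> optional external artifact
cleaning hook -> 1-30 Hz zero-phase Butterworth bandpass -> segmentation into
non-overlapping 5-s epochs -> per-epoch baseline (mean) correction.

The artifact-removal hook exists because ICA-based cleaning needs manual
component labelling and therefore cannot be reproduced automatically; callers
who have their own cleaning function can inject it, otherwise the stage is a
no-op.
"""

from __future__ import annotations

import warnings
from typing import Callable, Optional

import numpy as np
from scipy import signal

from .recording import EEGRecording, EpochSet

__all__ = [
    "average_reference",
    "bandpass",
    "epoch",
    "baseline_correct",
    "preprocess_recording",
]


def average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the common average: subtract the cross-channel mean
    at every sample.  Requires at least two channels."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data)


def bandpass(rec: EEGRecording, lo: float = 1.0, hi: float = 30.0, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth bandpass, applied forward-backward per channel.

    ``order`` is the one-pass filter order (default 4; the forward-backward
    application doubles the effective order and cancels the phase response).
    """
    nyq = rec.sample_rate / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"band ({lo}, {hi}) Hz outside (0, {nyq}) Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.sample_rate, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return rec.copy_with(data)


def epoch(rec: EEGRecording, epoch_length_s: float = 5.0) -> EpochSet:
    """Cut into floor(duration / epoch_length_s) contiguous non-overlapping
    epochs; the trailing remainder is discarded.

    A 300-s recording at 250 Hz with 5-s epochs yields 60 epochs of 1250
    samples.  A recording shorter than one epoch yields an empty EpochSet
    (with a warning).
    """
    if epoch_length_s <= 0:
        raise ValueError("epoch_length_s must be positive")
    n_per = int(round(epoch_length_s * rec.sample_rate))
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        warnings.warn(
            f"recording of {rec.duration_s:.1f}s shorter than one "
            f"{epoch_length_s}s epoch; returning 0 epochs",
            stacklevel=2,
        )
    used = rec.data[:, : n_epochs * n_per]
    epochs = used.reshape(rec.n_channels, n_epochs, n_per).transpose(1, 0, 2)
    return EpochSet(
        epochs=epochs.copy(),
        epoch_length_s=epoch_length_s,
        sample_rate=rec.sample_rate,
        channel_labels=rec.channel_labels,
        subject_id=rec.subject_id,
        group=rec.group,
        moca=rec.moca,
        provenance={"epoch_length_s": epoch_length_s},
    )


def baseline_correct(eps: EpochSet) -> EpochSet:
    """Subtract each epoch's per-channel mean (the only baseline available in
    continuous resting-state data is the epoch itself)."""
    corrected = eps.epochs - eps.epochs.mean(axis=-1, keepdims=True)
    return EpochSet(
        epochs=corrected,
        epoch_length_s=eps.epoch_length_s,
        sample_rate=eps.sample_rate,
        channel_labels=eps.channel_labels,
        subject_id=eps.subject_id,
        group=eps.group,
        moca=eps.moca,
        provenance={**eps.provenance, "baseline": "per-epoch mean"},
    )


def preprocess_recording(
    rec: EEGRecording,
    lo: float = 1.0,
    hi: float = 30.0,
    epoch_length_s: float = 5.0,
    filter_order: int = 4,
    artifact_hook: Optional[Callable[[EEGRecording], EEGRecording]] = None,
) -> EpochSet:
    """Full chain: reference -> (hook) -> bandpass -> epoch -> baseline."""
    rec = average_reference(rec)
    if artifact_hook is not None:
        rec = artifact_hook(rec)
    rec = bandpass(rec, lo, hi, order=filter_order)
    eps = epoch(rec, epoch_length_s)
    eps = baseline_correct(eps)
    eps.provenance.update({"lo_hz": lo, "hi_hz": hi, "filter_order": filter_order})
    return eps
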