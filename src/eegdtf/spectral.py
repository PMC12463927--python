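"""Welch power spectral density and canonical band power.

Band power is the *mean* PSD over the in-band frequency bins (scale-free
across frequency resolutions); band edges follow the half-open convention
[lo, hi) so the 4 Hz bin belongs to theta, not delta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import preprocess_recording
from .recording import EEGRecording, EpochSet

__all__ = [
    "Band",
    "DEFAULT_BANDS",
    "PSDResult",
    "welch_psd",
    "band_power",
    "cohort_band_table",
]


@dataclass(frozen=True)
class Band:
    """A named frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name}: f_lo must be < f_hi")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.f_lo) & (freqs < self.f_hi)


#: Canonical resting-state bands: delta 1-4, theta 4-7, alpha 8-13 Hz.
DEFAULT_BANDS: Tuple[Band, ...] = (
    Band("delta", 1.0, 4.0),
    Band("theta", 4.0, 7.0),
    Band("alpha", 8.0, 13.0),
)


@dataclass
class PSDResult:
    """Per-channel Welch PSD on a common frequency grid (power in uV^2/Hz)."""

    freqs: np.ndarray
    power: np.ndarray  # channels x frequencies
    channel_labels: Tuple[str, ...]
    params: Dict[str, object]

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.channel_labels), len(self.freqs)):
            raise ValueError("power must be channels x frequencies")


def welch_psd(
    eps: EpochSet,
    segment_s: float = 2.0,
    overlap_frac: float = 0.5,
    window: str = "hamming",
) -> PSDResult:
    """Welch PSD averaged over the segments of every epoch.

    Frequency resolution is 1/segment_s Hz.  Defaults (2-s Hamming segments,
    50% overlap) give >= 3 segments per 5-s epoch at 0.5 Hz resolution.
    """
    nperseg = int(round(segment_s * eps.sample_rate))
    if eps.n_epochs and nperseg > eps.epochs.shape[2]:
        raise ValueError(
            f"segment of {nperseg} samples longer than epoch of {eps.epochs.shape[2]}"
        )
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    noverlap = int(round(overlap_frac * nperseg))
    freqs, pxx = signal.welch(
        eps.epochs, fs=eps.sample_rate, window=window,
        nperseg=nperseg, noverlap=noverlap, axis=-1,
    )
    power = pxx.mean(axis=0) if eps.n_epochs else np.zeros((eps.n_channels, len(freqs)))
    return PSDResult(
        freqs=freqs,
        power=power,
        channel_labels=eps.channel_labels,
        params={
            "segment_s": segment_s,
            "overlap_frac": overlap_frac,
            "window": window,
            "n_epochs": eps.n_epochs,
        },
    )


def band_power(psd: PSDResult, band: Band) -> np.ndarray:
    """Mean PSD over bins f with f_lo <= f < f_hi; one scalar per channel."""
    mask = band.mask(psd.freqs)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band.name} "
                         f"[{band.f_lo}, {band.f_hi}) Hz")
    return psd.power[:, mask].mean(axis=1)


def cohort_band_table(
    recordings: Sequence[EEGRecording],
    bands: Iterable[Band] = DEFAULT_BANDS,
    segment_s: float = 2.0,
    overlap_frac: float = 0.5,
    window: str = "hamming",
    lo: float = 1.0,
    hi: float = 30.0,
    epoch_length_s: float = 5.0,
) -> pd.DataFrame:
    """Run preprocess -> Welch -> band power for each subject.

    Returns a long-format table with one row per subject x electrode x band
    and columns (subject_id, group, moca, electrode, band, power).
    """
    bands = tuple(bands)
    if not recordings:
        return pd.DataFrame(columns=["subject_id", "group", "moca", "electrode", "band", "power"])
    ref_labels = recordings[0].channel_labels
    ref_rate = recordings[0].sample_rate
    rows: List[dict] = []
    for rec in recordings:
        if rec.channel_labels != ref_labels or rec.sample_rate != ref_rate:
            raise ValueError(f"inconsistent montage or rate for subject {rec.subject_id!r}")
        eps = preprocess_recording(rec, lo=lo, hi=hi, epoch_length_s=epoch_length_s)
        psd = welch_psd(eps, segment_s=segment_s, overlap_frac=overlap_frac, window=window)
        for band in bands:
            powers = band_power(psd, band)
            for ch, p in zip(rec.channel_labels, powers):
                rows.append({
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "moca": rec.moca,
                    "electrode": ch,
                    "band": band.name,
                    "power": float(p),
                })
    return pd.DataFrame(rows)
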