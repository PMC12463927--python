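"""In-memory containers for continuous and epoched multichannel EEG."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, Optional, Tuple

import numpy as np

__all__ = ["EEGRecording", "EpochSet"]


@dataclass
class EEGRecording:
    """One subject's continuous EEG: channels x samples, in microvolts.

    ``group`` is the cohort label ("NC" or "MCI"); ``moca`` the Montreal
    Cognitive Assessment score in [0, 30] (None when unknown).
    """

    data: np.ndarray
    channel_labels: Tuple[str, ...]
    sample_rate: float
    subject_id: str = ""
    group: Optional[str] = None
    moca: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.channel_labels)} labels"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        """Same metadata, new signal array."""
        return EEGRecording(
            data=data,
            channel_labels=self.channel_labels,
            sample_rate=self.sample_rate,
            subject_id=self.subject_id,
            group=self.group,
            moca=self.moca,
        )


@dataclass
class EpochSet:
    """Contiguous non-overlapping epochs: epochs x channels x samples."""

    epochs: np.ndarray
    epoch_length_s: float
    sample_rate: float
    channel_labels: Tuple[str, ...]
    subject_id: str = ""
    group: Optional[str] = None
    moca: Optional[float] = None
    provenance: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch, channel, sample)")
        expected = int(round(self.epoch_length_s * self.sample_rate))
        if self.epochs.shape[0] and self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} samples, expected {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]
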