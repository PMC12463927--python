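"""Scalp montage: 10-20 electrode labels and their lobe assignment.

The montage groups the 32 electrodes into five scalp regions (frontal,
central, temporal, parietal, occipital).  Region membership drives the
lobe-wise summaries and the bottom-up / top-down classification of
directed edges in :mod:`eegdtf.report`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Tuple

__all__ = ["MontageSpec", "REGIONS", "default_montage", "UnknownElectrodeError"]

#: Valid region names, anterior last (the orientation rank order lives in report).
REGIONS: Tuple[str, ...] = ("frontal", "central", "temporal", "parietal", "occipital")


class UnknownElectrodeError(KeyError):
    """An electrode label is not part of the montage."""


# 32 labels of the default 10-20 montage, in recording order.
_DEFAULT_LABELS: Tuple[str, ...] = (
    "FP1", "FP2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "PO4", "PO8", "Oz",
)

_DEFAULT_REGION_OF: Mapping[str, str] = {
    # frontal (incl. prefrontal -- the two are treated as one region)
    "FP1": "frontal", "FP2": "frontal", "AF3": "frontal", "AF4": "frontal",
    "F7": "frontal", "F3": "frontal", "Fz": "frontal", "F4": "frontal",
    "F8": "frontal", "FC5": "frontal", "FC1": "frontal", "FC2": "frontal",
    "FC6": "frontal",
    "C3": "central", "Cz": "central", "C4": "central",
    "T7": "temporal", "T8": "temporal",
    "CP5": "parietal", "CP1": "parietal", "CP2": "parietal", "CP6": "parietal",
    "P7": "parietal", "P3": "parietal", "Pz": "parietal", "P4": "parietal",
    "P8": "parietal",
    "PO7": "occipital", "PO3": "occipital", "PO4": "occipital",
    "PO8": "occipital", "Oz": "occipital",
}


@dataclass(frozen=True)
class MontageSpec:
    """An ordered 32-electrode montage with a region label per electrode.

    Parameters
    ----------
    channel_labels
        Ordered tuple of exactly 32 unique electrode names.
    region_of
        Mapping from every label to one of :data:`REGIONS`.
    """

    channel_labels: Tuple[str, ...] = _DEFAULT_LABELS
    region_of: Mapping[str, str] = field(default_factory=lambda: dict(_DEFAULT_REGION_OF))

    def __post_init__(self) -> None:
        labels = tuple(self.channel_labels)
        object.__setattr__(self, "channel_labels", labels)
        if len(labels) != 32:
            raise ValueError(f"montage must have exactly 32 channels, got {len(labels)}")
        if len(set(labels)) != len(labels):
            raise ValueError("montage labels must be unique")
        missing = [c for c in labels if c not in self.region_of]
        if missing:
            raise ValueError(f"labels without a region: {missing}")
        bad = {c: r for c, r in self.region_of.items() if r not in REGIONS}
        if bad:
            raise ValueError(f"unknown regions: {bad}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def index(self, label: str) -> int:
        """Channel index of ``label`` (case-insensitive fallback)."""
        try:
            return self.channel_labels.index(label)
        except ValueError:
            lowered = [c.lower() for c in self.channel_labels]
            if label.lower() in lowered:
                return lowered.index(label.lower())
            raise UnknownElectrodeError(label) from None

    def region(self, label: str) -> str:
        """Scalp region of ``label``."""
        if label in self.region_of:
            return self.region_of[label]
        # tolerate case variants such as "CZ"
        for known, reg in self.region_of.items():
            if known.lower() == label.lower():
                return reg
        raise UnknownElectrodeError(label)


def default_montage() -> MontageSpec:
    """The default 32-channel 10-20 montage."""
    return MontageSpec()
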