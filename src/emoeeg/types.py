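"""Shared data containers: recordings, epochs, ratings."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import check_channels


@dataclass
class Recording:
    """A continuous multi-channel EEG recording of one video clip.

    data is channels x samples in microvolts; channel order follows
    channel_names, which must be drawn from the 32-channel montage.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    subject_id: str
    clip_label: str  # "positive" | "negative"
    clip_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        self.channel_names = check_channels(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(
            data=data,
            fs=self.fs,
            channel_names=list(self.channel_names),
            subject_id=self.subject_id,
            clip_label=self.clip_label,
            clip_id=self.clip_id,
        )

    def pick(self, channels: list[str]) -> "Recording":
        """Sub-select channels by name (order as given)."""
        idx = [self.channel_names.index(c) for c in check_channels(channels)]
        return Recording(
            data=self.data[idx].copy(),
            fs=self.fs,
            channel_names=list(channels),
            subject_id=self.subject_id,
            clip_label=self.clip_label,
            clip_id=self.clip_id,
        )


@dataclass
class LabeledEpoch:
    """One fixed-length segment with its emotion label.

    The epoch is the unit of classification: a channels x N array cut from a
    preprocessed recording, carrying the clip's stimulus tag as its label.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    label: str  # "positive" | "negative"
    subject_id: str
    clip_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class RatingRecord:
    """Self-report ratings on the 9-point valence/arousal/dominance/liking scales."""

    valence: float
    arousal: float
    dominance: float
    liking: float

    def __post_init__(self) -> None:
        for name in ("valence", "arousal", "dominance", "liking"):
            v = getattr(self, name)
            if not 1.0 <= v <= 9.0:
                raise ValueError(f"{name}={v} outside the 1-9 rating scale")

    @property
    def high_valence(self) -> bool:
        """Strictly above the 4.5 midpoint counts as high valence."""
        return self.valence > 4.5

    @property
    def low_valence(self) -> bool:
        return self.valence < 4.5
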