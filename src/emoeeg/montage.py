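"""The 32-channel 10-20 montage used throughout the package.

Electrode names follow the extended international 10-20 system (modified
32-channel cap). Frontal-polar electrodes Fp1/Fp2 are the "forehead" pair
used by the dual-channel processing path.
"""

from __future__ import annotations

# Ordered montage; the order is the canonical channel order of every
# Recording produced by the synthetic generator.
MONTAGE_32: tuple[str, ...] = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FT9", "FC5", "FC1", "FC2", "FC6", "FT10",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Iz", "O2",
)

#: Frontal weighting used to build the ocular reference template: blinks and
#: eye movements project most strongly onto the frontal-polar sites and decay
#: toward posterior sites.
FRONTAL_WEIGHTS: dict[str, float] = {
    "Fp1": 1.0, "Fp2": 1.0,
    "F7": 0.45, "F3": 0.45, "Fz": 0.45, "F4": 0.45, "F8": 0.45,
    "FT9": 0.2, "FC5": 0.2, "FC1": 0.2, "FC2": 0.2, "FC6": 0.2, "FT10": 0.2,
}


class MontageError(ValueError):
    """Raised when a channel name is not part of the montage."""


def check_channels(channels) -> list[str]:
    """Validate channel names against the montage, preserving order."""
    channels = list(channels)
    unknown = [c for c in channels if c not in MONTAGE_32]
    if unknown:
        raise MontageError(f"unknown channel name(s): {unknown}")
    return channels


def frontal_weight(channel: str) -> float:
    """Ocular-projection weight for one electrode (0.05 floor posteriorly)."""
    return FRONTAL_WEIGHTS.get(channel, 0.05)
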