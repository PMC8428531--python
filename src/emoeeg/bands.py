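"""Canonical EEG frequency bands within the 0.5-45 Hz analysis pass-band.

The five main bands partition (0.5, 45] Hz; delta, alpha, beta and gamma are
additionally split into low/high sub-bands for the energy features. Band
edges are the conventional clinical choices; they are configurable because
no single standard exists for the sub-band splits.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_lo < self.f_hi:
            raise ValueError(
                f"band {self.name!r}: need 0 <= f_lo < f_hi, got "
                f"({self.f_lo}, {self.f_hi})"
            )


#: Analysis band: everything the preprocessing band-pass keeps.
TOTAL_BAND = BandDefinition("total", 0.5, 45.0)

#: The five main bands; they partition the analysis band.
MAIN_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)

#: Low/high sub-band splits (delta at 2, alpha at 10, beta at 20, gamma at 38 Hz).
SUB_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("low_delta", 0.5, 2.0),
    BandDefinition("high_delta", 2.0, 4.0),
    BandDefinition("low_alpha", 8.0, 10.0),
    BandDefinition("high_alpha", 10.0, 13.0),
    BandDefinition("low_beta", 13.0, 20.0),
    BandDefinition("high_beta", 20.0, 30.0),
    BandDefinition("low_gamma", 30.0, 38.0),
    BandDefinition("high_gamma", 38.0, 45.0),
)

BAND_BY_NAME: dict[str, BandDefinition] = {
    b.name: b for b in (TOTAL_BAND, *MAIN_BANDS, *SUB_BANDS)
}

MAIN_BAND_NAMES: tuple[str, ...] = tuple(b.name for b in MAIN_BANDS)


def get_band(name: str) -> BandDefinition:
    try:
        return BAND_BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; known: {sorted(BAND_BY_NAME)}"
        ) from None
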