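"""Canonical frequency-band definitions used throughout the pipeline.

The six bands tile [4, 200) Hz with half-open intervals [lo, hi), so every
analysis frequency at or above 4 Hz belongs to exactly one band.  Frequencies
below 4 Hz are present on the analysis grid but are not assigned to any band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with half-open range [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def contains(self, freq: float) -> bool:
        return self.lo <= freq < self.hi

    @property
    def center(self) -> float:
        """Geometric-centre frequency of the band in Hz."""
        return math.sqrt(self.lo * self.hi)


BAND_ORDER = ("theta", "alpha", "beta", "low_gamma", "high_gamma", "hyper_gamma")

BANDS = {
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 15.0),
    "beta": BandDefinition("beta", 15.0, 30.0),
    "low_gamma": BandDefinition("low_gamma", 30.0, 60.0),
    "high_gamma": BandDefinition("high_gamma", 60.0, 100.0),
    "hyper_gamma": BandDefinition("hyper_gamma", 100.0, 200.0),
}


def get_band(name: str) -> BandDefinition:
    try:
        return BANDS[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; expected one of {', '.join(BAND_ORDER)}"
        ) from None


def band_of(freq: float) -> str | None:
    """Name of the band containing ``freq``, or None below 4 Hz / at+above 200 Hz."""
    for name in BAND_ORDER:
        if BANDS[name].contains(freq):
            return name
    return None
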