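"""Canonical EEG frequency bands.

Band intervals are half-open ``[low, high)`` so that a shared edge (8 Hz,
12 Hz, 25 Hz) belongs to exactly one band and the four bands partition
the analysed 4-45 Hz range without double counting.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Band:
    """A named frequency band ``[low, high)`` in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.high > self.low:
            raise ValueError(f"band {self.name!r}: high ({self.high}) must exceed low ({self.low})")

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, freq_hz: float) -> bool:
        return self.low <= freq_hz < self.high


THETA = Band("theta", 4.0, 8.0)
ALPHA = Band("alpha", 8.0, 12.0)
BETA = Band("beta", 12.0, 25.0)
GAMMA = Band("gamma", 25.0, 45.0)

#: The four bands, in ascending frequency order.
BANDS: tuple[Band, ...] = (THETA, ALPHA, BETA, GAMMA)

BAND_BY_NAME: dict[str, Band] = {b.name: b for b in BANDS}

#: Upper edge of the gamma band; the sampling rate must resolve it.
MAX_ANALYSIS_HZ = GAMMA.high
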