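"""Classical direct-method spectral estimation and band-average PSD.

The spectral estimate is the plain single-segment periodogram (rectangular
window, no averaging, no overlap): the squared magnitude of the DFT scaled
to a one-sided density, so that the integral of the PSD over frequency
equals the epoch's mean squared amplitude (Parseval).  The band summary is
the average PSD over a band,

    G_b = (1 / (b_hi - b_lo)) * integral of P(f) df over [b_lo, b_hi),

integrated by the rectangle rule on the DFT grid.  A 60-s epoch gives a
grid spacing of 1/60 Hz, i.e. at least 240 bins in the narrowest band, so
the rectangle/trapezoid difference is negligible and the rectangle rule
matches the Parseval scaling exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import BANDS, Band
from .recording import Epoch


@dataclass
class PowerSpectrum:
    """One-sided PSD of one epoch: frequencies 0..Nyquist, density units²/Hz."""

    freqs: np.ndarray
    psd: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs.shape != self.psd.shape:
            raise ValueError("freqs and psd must have identical shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.psd < 0):
            raise ValueError("psd must be non-negative")

    def total_power(self) -> float:
        """Integral of the PSD over all frequencies (= mean squared amplitude)."""
        return float(self.psd.sum() * self.resolution)


@dataclass
class BandPowerSet:
    """Average PSD of the four canonical bands for one epoch."""

    G_theta: float
    G_alpha: float
    G_beta: float
    G_gamma: float
    start_min: float = 0.0

    def __post_init__(self) -> None:
        for name in ("G_theta", "G_alpha", "G_beta", "G_gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def value(self, band_name: str) -> float:
        return getattr(self, f"G_{band_name}")


def periodogram(epoch: Epoch) -> PowerSpectrum:
    """Direct-method (rectangular-window) one-sided periodogram of an epoch."""
    x = epoch.samples
    if x.size < 2:
        raise ValueError("epoch must have at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("epoch contains non-finite samples")
    freqs, psd = sps.periodogram(
        x, fs=epoch.sampling_rate, window="boxcar", detrend=False, scaling="density"
    )
    return PowerSpectrum(freqs=freqs, psd=psd, resolution=epoch.sampling_rate / x.size)


def band_average(spectrum: PowerSpectrum, band: Band) -> float:
    """Average PSD over ``[band.low, band.high)``: band integral / bandwidth."""
    if band.high > spectrum.freqs[-1] + spectrum.resolution:
        raise ValueError(
            f"band {band.name} [{band.low}, {band.high}) Hz exceeds the spectrum's "
            f"Nyquist limit {spectrum.freqs[-1]:.2f} Hz"
        )
    mask = (spectrum.freqs >= band.low) & (spectrum.freqs < band.high)
    if not mask.any():
        raise ValueError(
            f"no frequency bins inside band {band.name} [{band.low}, {band.high}) Hz "
            f"at resolution {spectrum.resolution:.4f} Hz"
        )
    integral = spectrum.psd[mask].sum() * spectrum.resolution
    return float(integral / band.width)


def band_powers(epoch: Epoch) -> BandPowerSet:
    """The four band-average PSD values of one epoch."""
    spec = periodogram(epoch)
    values = {b.name: band_average(spec, b) for b in BANDS}
    return BandPowerSet(
        G_theta=values["theta"],
        G_alpha=values["alpha"],
        G_beta=values["beta"],
        G_gamma=values["gamma"],
        start_min=epoch.start_min,
    )


def band_power_series(epochs: list[Epoch]) -> list[BandPowerSet]:
    """One BandPowerSet per epoch, ordered by epoch start time."""
    if not epochs:
        raise ValueError("no epochs supplied")
    return [band_powers(e) for e in sorted(epochs, key=lambda e: e.start_min)]


def band_power_frame(sets: list[BandPowerSet]) -> pd.DataFrame:
    """Tabulate band powers (columns: start_min, G_theta, G_alpha, G_beta, G_gamma)."""
    return pd.DataFrame(
        [(s.start_min, s.G_theta, s.G_alpha, s.G_beta, s.G_gamma) for s in sets],
        columns=["start_min", "G_theta", "G_alpha", "G_beta", "G_gamma"],
    )
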