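"""Band-power ratio indices of driving fatigue.

Three classical drowsiness ratios computed from the band-average PSD
values of each 1-min epoch:

* ``R_ab``     = G_alpha / G_beta — rises as fast-wave activity declines;
* ``R_t_ab``   = G_theta / (G_alpha + G_beta);
* ``R_at_ab``  = (G_alpha + G_theta) / (G_alpha + G_beta).

All three are scale-free: multiplying every band power by the same
positive constant leaves them unchanged.  By construction
``R_at_ab − R_t_ab = G_alpha / (G_alpha + G_beta)`` lies in (0, 1)
whenever the band powers are positive.

Ratios are computed per epoch and only then averaged across epochs or
subjects (mean of ratios, not ratio of mean powers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import BandPowerSet


class UndefinedIndexError(ZeroDivisionError):
    """A ratio index is undefined because its denominator is zero."""


def ratio_alpha_beta(G: BandPowerSet) -> float:
    """Alpha/beta band-power ratio, the headline fatigue index."""
    if G.G_beta == 0:
        raise UndefinedIndexError("alpha/beta index undefined: G_beta is zero")
    return G.G_alpha / G.G_beta


def ratio_theta_ab(G: BandPowerSet) -> float:
    """Theta over (alpha + beta)."""
    denom = G.G_alpha + G.G_beta
    if denom == 0:
        raise UndefinedIndexError("theta/(alpha+beta) index undefined: G_alpha + G_beta is zero")
    return G.G_theta / denom


def ratio_alphatheta_ab(G: BandPowerSet) -> float:
    """(Alpha + theta) over (alpha + beta)."""
    denom = G.G_alpha + G.G_beta
    if denom == 0:
        raise UndefinedIndexError(
            "(alpha+theta)/(alpha+beta) index undefined: G_alpha + G_beta is zero"
        )
    return (G.G_alpha + G.G_theta) / denom


INDEX_NAMES = ("R_ab", "R_t_ab", "R_at_ab")

_INDEX_FUNCS = {
    "R_ab": ratio_alpha_beta,
    "R_t_ab": ratio_theta_ab,
    "R_at_ab": ratio_alphatheta_ab,
}


@dataclass
class FatigueIndexSeries:
    """Per-epoch values of the three ratio indices for one subject/condition."""

    start_min: np.ndarray
    R_ab: np.ndarray
    R_t_ab: np.ndarray
    R_at_ab: np.ndarray
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.start_min = np.asarray(self.start_min, dtype=float)
        for name in INDEX_NAMES:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
            if getattr(self, name).shape != self.start_min.shape:
                raise ValueError(f"{name} length differs from start_min")

    def __len__(self) -> int:
        return self.start_min.size

    def value_at_minute(self, minute: float, index: str = "R_ab") -> float:
        """The index value of the 1-min epoch *ending* at ``minute``.

        "The value at minute m" means the epoch covering (m−1, m]; e.g. the
        30-min value of a 30-min recording is its last epoch.
        """
        target = minute - 1.0
        pos = np.flatnonzero(np.isclose(self.start_min, target))
        if pos.size != 1:
            raise KeyError(
                f"no epoch starting at minute {target} "
                f"(available: {self.start_min.tolist()})"
            )
        return float(getattr(self, index)[pos[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "condition": self.condition,
                "start_min": self.start_min,
                "R_ab": self.R_ab,
                "R_t_ab": self.R_t_ab,
                "R_at_ab": self.R_at_ab,
            }
        )


def index_series(
    band_powers: list[BandPowerSet], subject_id: str = "", condition: str = ""
) -> FatigueIndexSeries:
    """Compute all three indices for each epoch's band powers (order preserved)."""
    if not band_powers:
        raise ValueError("no band powers supplied")
    cols = {name: [f(G) for G in band_powers] for name, f in _INDEX_FUNCS.items()}
    return FatigueIndexSeries(
        start_min=np.array([G.start_min for G in band_powers]),
        subject_id=subject_id,
        condition=condition,
        **{k: np.array(v) for k, v in cols.items()},
    )
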