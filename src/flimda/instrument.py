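"""Instrument model and fluorophore library.

The acquisition is frequency-domain FLIM: a pulsed laser at repetition rate
``rep_rate_hz`` excites the sample, and each pixel accumulates a photon-count
histogram over ``n_bins`` time bins spanning exactly one laser period.  The
phasor transform evaluates the first-harmonic Fourier coefficients of that
histogram at the angular frequency ``omega = 2*pi*harmonic*rep_rate_hz``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError


@dataclass(frozen=True)
class InstrumentConfig:
    """Laser/detector geometry shared by simulation and analysis.

    Parameters
    ----------
    rep_rate_hz : float
        Laser repetition frequency. Default 80 MHz (Ti:Sapphire).
    n_bins : int
        Time bins per laser period (>= 16).
    width_px, height_px : int
        Image dimensions in pixels.
    harmonic : int
        Fourier harmonic used by the phasor transform (>= 1).
    """

    rep_rate_hz: float = 8.0e7
    n_bins: int = 256
    width_px: int = 256
    height_px: int = 256
    harmonic: int = 1

    def __post_init__(self) -> None:
        if self.rep_rate_hz <= 0:
            raise ContractError("rep_rate_hz must be > 0")
        if self.n_bins < 16:
            raise ContractError("n_bins must be an integer >= 16")
        if self.width_px < 1 or self.height_px < 1:
            raise ContractError("image dimensions must be >= 1 pixel")
        if self.harmonic < 1:
            raise ContractError("harmonic must be an integer >= 1")

    @property
    def period_s(self) -> float:
        """Laser period T = 1 / rep_rate_hz, in seconds."""
        return 1.0 / self.rep_rate_hz

    @property
    def angular_freq_rad_s(self) -> float:
        """omega = 2*pi*harmonic*rep_rate_hz; always derived, never stored."""
        return 2.0 * math.pi * self.harmonic * self.rep_rate_hz

    @property
    def bin_centers_s(self) -> np.ndarray:
        """t_k = (k + 0.5) * T / n_bins — midpoints of the time bins."""
        k = np.arange(self.n_bins)
        return (k + 0.5) * self.period_s / self.n_bins

    @property
    def bin_edges_s(self) -> np.ndarray:
        return np.linspace(0.0, self.period_s, self.n_bins + 1)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) — numpy row-major image shape."""
        return (self.height_px, self.width_px)

    def to_dict(self) -> dict:
        return {
            "rep_rate_hz": self.rep_rate_hz,
            "n_bins": self.n_bins,
            "width_px": self.width_px,
            "height_px": self.height_px,
            "harmonic": self.harmonic,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentConfig":
        return cls(
            rep_rate_hz=d["rep_rate_hz"],
            n_bins=int(d["n_bins"]),
            width_px=int(d.get("width_px", 256)),
            height_px=int(d.get("height_px", 256)),
            harmonic=int(d.get("harmonic", 1)),
        )


@dataclass(frozen=True)
class FluorSpecies:
    """A mono-exponential emitter. ``lifetime_ns = 0`` encodes an
    instantaneous, scattering-like signal (third harmonic generation)."""

    name: str
    lifetime_ns: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.lifetime_ns) or self.lifetime_ns < 0:
            raise ContractError(
                f"lifetime_ns must be finite and >= 0, got {self.lifetime_ns}"
            )


# Endogenous / reference fluorophores used throughout the analysis.
FREE_NADH = FluorSpecies("free_NADH", 0.38)
BOUND_NADH = FluorSpecies("bound_NADH", 3.4)  # NADH bound to lactate dehydrogenase
OXIDIZED_LIPID = FluorSpecies("oxidized_lipid", 7.89)
COUMARIN6 = FluorSpecies("coumarin6", 2.5)  # calibration standard (in ethanol)
RHO110 = FluorSpecies("Rho110", 4.0)  # calibration standard for the THG path
THG = FluorSpecies("THG", 0.0)

SPECIES_LIBRARY: dict[str, FluorSpecies] = {
    sp.name: sp
    for sp in (FREE_NADH, BOUND_NADH, OXIDIZED_LIPID, COUMARIN6, RHO110, THG)
}
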