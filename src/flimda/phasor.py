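"""Phasor transform, calibration and phasor geometry.

Each pixel's decay histogram I_k is mapped to first-harmonic Fourier
coordinates

    g = sum_k I_k cos(omega t_k) / sum_k I_k
    s = sum_k I_k sin(omega t_k) / sum_k I_k

with t_k the bin centers and omega the laser angular frequency.  A
mono-exponential decay of lifetime tau lands on the universal semicircle at

    g = 1 / (1 + (omega tau)^2),   s = omega tau / (1 + (omega tau)^2),

and mixtures land inside the semicircle on the chord joining their
components, weighted by emitted intensity.  Instrument phase and modulation
errors are removed by referencing a fluorophore of known lifetime: the
transform that rotates/scales the reference's measured mean phasor onto its
theoretical position is applied to every pixel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ContractError, DegenerateReferenceError, EmptyResultError
from .instrument import InstrumentConfig


@dataclass
class DecayImage:
    """Per-pixel photon-count histograms: ``counts[y, x, k]`` photons in
    time bin k.  The raw FLIM record."""

    counts: np.ndarray  # (height, width, n_bins), non-negative
    cfg: InstrumentConfig

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 3:
            raise ContractError("counts must be (height, width, n_bins)")
        if self.counts.shape != (*self.cfg.shape, self.cfg.n_bins):
            raise ContractError(
                f"counts shape {self.counts.shape} does not match config "
                f"{(*self.cfg.shape, self.cfg.n_bins)}"
            )
        if np.any(self.counts < 0):
            raise ContractError("photon counts must be non-negative")

    @property
    def intensity(self) -> np.ndarray:
        """Total photons per pixel."""
        return self.counts.sum(axis=2)


@dataclass
class PhasorImage:
    """Per-pixel (g, s) with total intensity.  Pixels failing the photon
    threshold are masked (``mask`` False, g/s NaN)."""

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    mask: np.ndarray  # True where (g, s) is defined
    calibrated: bool
    cfg: InstrumentConfig

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_gs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(g, s, intensity) restricted to unmasked pixels, flattened."""
        return self.g[self.mask], self.s[self.mask], self.intensity[self.mask]


@dataclass(frozen=True)
class CalibrationTransform:
    """Rotation by ``phase_shift_rad`` about the origin plus radial scaling
    by ``modulation_factor``, mapping raw phasors onto calibrated ones."""

    phase_shift_rad: float
    modulation_factor: float
    reference_lifetime_ns: float

    def __post_init__(self) -> None:
        if self.modulation_factor <= 0:
            raise ContractError("modulation_factor must be > 0")

    def apply(self, g: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        z = (g + 1j * s) * self.modulation_factor * np.exp(1j * self.phase_shift_rad)
        return z.real, z.imag


def theoretical_phasor(lifetime_ns: float, cfg: InstrumentConfig) -> tuple[float, float]:
    """Closed-form phasor of a mono-exponential decay; lies exactly on the
    universal semicircle (g - 1/2)^2 + s^2 = 1/4.

    ``lifetime_ns = 0`` gives (1, 0) — the instantaneous (THG) point.
    """
    if lifetime_ns < 0:
        raise ContractError("lifetime must be >= 0")
    wt = cfg.angular_freq_rad_s * lifetime_ns * 1e-9
    denom = 1.0 + wt * wt
    return 1.0 / denom, wt / denom


def phasor_transform(img: DecayImage, min_photons: int = 20) -> PhasorImage:
    """Discrete first-harmonic phasor transform of every pixel.

    Pixels with total intensity below ``min_photons`` are masked; if that
    leaves no pixel, an :class:`EmptyResultError` is raised (distinct from a
    contract violation — the image itself was valid).
    """
    if min_photons < 0:
        raise ContractError("min_photons must be >= 0")
    cfg = img.cfg
    wt = cfg.angular_freq_rad_s * cfg.bin_centers_s
    cosw = np.cos(wt)
    sinw = np.sin(wt)
    intensity = img.counts.sum(axis=2)
    mask = intensity >= max(min_photons, np.finfo(float).tiny)
    if not mask.any():
        raise EmptyResultError(
            f"no pixel reaches the photon threshold ({min_photons})"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        g = (img.counts @ cosw) / intensity
        s = (img.counts @ sinw) / intensity
    g[~mask] = np.nan
    s[~mask] = np.nan
    return PhasorImage(g=g, s=s, intensity=intensity, mask=mask,
                       calibrated=False, cfg=cfg)


def fit_calibration(
    reference_raw: PhasorImage, reference_lifetime_ns: float
) -> CalibrationTransform:
    """Derive the (phase, modulation) correction from a reference stack.

    The intensity-weighted mean raw phasor of the reference is mapped onto
    ``theoretical_phasor(reference_lifetime_ns)`` by a rotation about the
    origin and a radial scaling.
    """
    if reference_raw.n_valid < 1:
        raise ContractError("reference image has no unmasked pixel")
    g, s, w = reference_raw.valid_gs()
    wsum = w.sum()
    if wsum <= 0:
        raise ContractError("reference image has zero total intensity")
    z_meas = complex(np.sum(w * g) / wsum, np.sum(w * s) / wsum)
    if abs(z_meas) < 1e-12:
        raise DegenerateReferenceError(
            "reference mean phasor is at the origin; cannot calibrate"
        )
    gt, st = theoretical_phasor(reference_lifetime_ns, reference_raw.cfg)
    z_true = complex(gt, st)
    ratio = z_true / z_meas
    return CalibrationTransform(
        phase_shift_rad=math.atan2(ratio.imag, ratio.real),
        modulation_factor=abs(ratio),
        reference_lifetime_ns=reference_lifetime_ns,
    )


def calibrate_phasor(
    raw: PhasorImage,
    reference_raw: PhasorImage,
    reference_lifetime_ns: float,
) -> tuple[PhasorImage, CalibrationTransform]:
    """Calibrate ``raw`` against a reference stack of known lifetime.

    Returns the calibrated image and the transform that was applied.
    """
    tr = fit_calibration(reference_raw, reference_lifetime_ns)
    g, s = tr.apply(raw.g, raw.s)
    out = replace(raw, g=g, s=s, calibrated=True)
    return out, tr


def invert_lifetime(
    g: float, s: float, cfg: InstrumentConfig
) -> tuple[float, float]:
    """Phase and modulation lifetimes (ns) from a phasor point.

    tau_phase = s / (omega g); tau_mod = (1/omega) sqrt(1/(g^2+s^2) - 1).
    For on-semicircle (single-exponential) points the two agree.  For points
    outside the unit circle (g^2 + s^2 > 1) tau_mod is undefined and
    returned as NaN rather than raising.
    """
    if g == 0.0 and s == 0.0:
        raise ContractError("(g, s) = (0, 0) has no finite lifetime")
    omega = cfg.angular_freq_rad_s
    tau_phase = s / (omega * g) * 1e9 if g != 0.0 else math.inf
    m2 = g * g + s * s
    if m2 > 1.0:
        tau_mod = math.nan  # unphysical modulation > 1; flagged, not thrown
    else:
        tau_mod = math.sqrt(1.0 / m2 - 1.0) / omega * 1e9
    return tau_phase, tau_mod


def median_filter_phasor(ph: PhasorImage, window: int = 3) -> PhasorImage:
    """Median-filter g and s independently over unmasked neighbours.

    Intensity and the mask are untouched; ``window=1`` is the identity.
    Masked pixels are excluded from every neighbourhood median (NaN-aware).
    """
    if window < 1 or window % 2 == 0:
        raise ContractError("window must be an odd integer >= 1")
    if window == 1:
        return replace(ph)

    def nanmed(values: np.ndarray) -> float:
        vals = values[~np.isnan(values)]
        return float(np.median(vals)) if vals.size else np.nan

    g = ndimage.generic_filter(ph.g, nanmed, size=window, mode="nearest")
    s = ndimage.generic_filter(ph.s, nanmed, size=window, mode="nearest")
    g[~ph.mask] = np.nan
    s[~ph.mask] = np.nan
    return replace(ph, g=g, s=s)
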