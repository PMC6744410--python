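"""Colocalization of a THG-like channel with long-lifetime phasor pixels.

Lipid droplets appear both in third-harmonic-generation (THG) images and as
a long-lifetime (7.89 ns, oxidized lipid) population in the FLIM phasor
plot.  Their overlap is quantified with Mander's split coefficients: M1 is
the fraction of THG intensity inside the FLIM selection, M2 the fraction of
FLIM intensity inside the THG selection; 1 is perfect overlap, 0 none.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from skimage.filters import threshold_otsu

from .errors import ContractError
from .instrument import OXIDIZED_LIPID
from .phasor import PhasorImage, theoretical_phasor

DEFAULT_CURSOR_RADIUS = 0.05


def phasor_cursor_mask(
    ph: PhasorImage,
    center: tuple[float, float] | None = None,
    radius: float = DEFAULT_CURSOR_RADIUS,
) -> np.ndarray:
    """Boolean mask of pixels whose phasor lies within ``radius`` of a
    cursor.  The default cursor sits on the oxidized-lipid position
    (7.89 ns on the universal semicircle)."""
    if radius <= 0:
        raise ContractError("radius must be > 0")
    if center is None:
        center = theoretical_phasor(OXIDIZED_LIPID.lifetime_ns, ph.cfg)
    d2 = (ph.g - center[0]) ** 2 + (ph.s - center[1]) ** 2
    with np.errstate(invalid="ignore"):
        return ph.mask & (d2 <= radius * radius)


def thg_threshold_mask(
    thg_intensity: np.ndarray, threshold: float | None = None
) -> np.ndarray:
    """THG channel mask: Otsu's threshold by default, or a fixed absolute
    threshold."""
    thg = np.asarray(thg_intensity, dtype=float)
    if threshold is None:
        threshold = threshold_otsu(thg)
    return thg > threshold


def manders_split(
    thg_intensity: np.ndarray,
    flim_intensity: np.ndarray,
    thg_mask: np.ndarray,
    flim_mask: np.ndarray,
) -> tuple[float, float]:
    """Mander's split coefficients (M1, M2).

    M1 = sum of THG intensity over (thg_mask AND flim_mask) / sum over
    thg_mask; M2 symmetrically with the FLIM-channel intensity.  Both lie in
    [0, 1] and are invariant to uniform rescaling of either channel.  A
    channel with zero in-mask intensity has an undefined coefficient,
    returned as NaN with a warning.
    """
    thg = np.asarray(thg_intensity, dtype=float)
    flim = np.asarray(flim_intensity, dtype=float)
    if not (thg.shape == flim.shape == thg_mask.shape == flim_mask.shape):
        raise ContractError("intensity maps and masks must share one shape")
    overlap = thg_mask & flim_mask

    def coeff(inten: np.ndarray, own: np.ndarray, name: str) -> float:
        denom = inten[own].sum()
        if denom <= 0:
            warnings.warn(f"{name} undefined: zero intensity in its own mask",
                          stacklevel=3)
            return math.nan
        return float(inten[overlap].sum() / denom)

    return coeff(thg, thg_mask, "M1"), coeff(flim, flim_mask, "M2")
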