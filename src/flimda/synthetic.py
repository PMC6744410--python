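"""Synthetic FLIM data: decay forward model, embryo phantoms and cohorts.

The forward model is the periodic steady state of a pulsed excitation: with
the laser firing every T = 1/rep_rate seconds, a fluorophore of lifetime tau
reaches the wrapped decay

    I(t) ∝ exp(-t/tau) / (1 - exp(-T/tau)),   t in [0, T),

which is what a frequency-domain FLIM detector integrates.  This matters for
long lifetimes: at 80 MHz a 7.89 ns emitter wraps substantially across the
12.5 ns period.  Photon noise is Poisson per time bin.

Embryo phantoms place a species mixture (free NADH, bound NADH, oxidized
lipid) on a filled-disc region; cohorts draw per-embryo bound-NADH fractions
from group-specific normal distributions so that healthy (H) and unhealthy
(UH) groups differ by a controlled effect size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError
from .instrument import (
    BOUND_NADH,
    FREE_NADH,
    OXIDIZED_LIPID,
    FluorSpecies,
    InstrumentConfig,
)
from .phasor import DecayImage

#: Developmental stages in chronological order.
STAGES: tuple[str, ...] = (
    "2cell",
    "4cell",
    "morula",
    "early_compaction",
    "compaction",
    "early_blastocyst",
    "blastocyst",
)


def _species_bin_weights(
    species: FluorSpecies, cfg: InstrumentConfig, delay_s: float = 0.0
) -> np.ndarray:
    """Per-bin probability mass of one species' periodic decay (sums to 1).

    ``delay_s`` circularly shifts the decay in time before bin integration
    (used to emulate an instrument phase error); the result stays an exact
    non-negative probability mass.
    """
    tau = species.lifetime_ns * 1e-9
    n = cfg.n_bins
    T = cfg.period_s
    if tau == 0.0:
        w = np.zeros(n)
        w[int((delay_s % T) / T * n) % n] = 1.0
        return w

    def cum(x: np.ndarray) -> np.ndarray:
        # integral of the periodic unit-mass decay from 0 to x, extended so
        # that cum(x + T) = cum(x) + 1; stable for tau >> T via expm1
        wraps = np.floor(x / T)
        frac = x - wraps * T
        within = np.expm1(-frac / tau) / np.expm1(-T / tau)
        return wraps + within

    edges = cfg.bin_edges_s - (delay_s % T)
    c = cum(edges)
    return c[1:] - c[:-1]


def decay_curve(
    species_mix: list[tuple[FluorSpecies, float]],
    cfg: InstrumentConfig,
    photons: float,
) -> np.ndarray:
    """Expected per-bin intensity of a species mixture.

    ``species_mix`` pairs each species with its intensity fraction; fractions
    must sum to 1.  The returned length-``n_bins`` vector is non-negative and
    sums to ``photons`` exactly (each component's periodic decay is
    integrated over each bin, so no photon mass is lost to truncation).
    """
    if photons < 0:
        raise ContractError("photons must be >= 0")
    fracs = np.array([f for _, f in species_mix], dtype=float)
    if np.any(fracs < 0):
        raise ContractError("species fractions must be non-negative")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ContractError(f"species fractions must sum to 1, got {fracs.sum()}")
    out = np.zeros(cfg.n_bins)
    for (sp, frac) in species_mix:
        out += frac * _species_bin_weights(sp, cfg)
    return out * photons


@dataclass
class EmbryoPhantom:
    """Ground-truth description of one simulated embryo.

    ``species_fractions`` maps species name -> per-pixel intensity-fraction
    map; the maps sum to 1 at every pixel.  ``total_intensity`` is the
    expected photon count per pixel (zero outside the embryo disc).
    """

    embryo_id: str
    stage: str
    species_fractions: dict[str, np.ndarray]
    total_intensity: np.ndarray
    label: str = "unknown"  # H | UH | unknown

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ContractError(f"unknown stage {self.stage!r}; valid: {STAGES}")
        if self.label not in ("H", "UH", "unknown"):
            raise ContractError("label must be H, UH or unknown")
        total = None
        for name, frac in self.species_fractions.items():
            frac = np.asarray(frac, dtype=float)
            if np.any(frac < -1e-12) or np.any(frac > 1 + 1e-12):
                raise ContractError(f"fractions for {name} outside [0, 1]")
            total = frac if total is None else total + frac
        if total is None or np.any(np.abs(total - 1.0) > 1e-9):
            raise ContractError("per-pixel species fractions must sum to 1")
        self.total_intensity = np.asarray(self.total_intensity, dtype=float)
        if np.any(self.total_intensity < 0):
            raise ContractError("total_intensity must be >= 0 everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        return self.total_intensity.shape


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a labelled two-group cohort.

    ``effect_delta`` is the difference in mean bound-NADH fraction between
    the healthy and unhealthy groups (healthy higher: more oxidative
    metabolism).  ``within_group_sd`` is the embryo-to-embryo SD of that
    fraction.  Fractions falling outside [0, 1] are clipped with a warning.
    """

    n_healthy: int = 30
    n_unhealthy: int = 30
    effect_delta: float = 0.2
    within_group_sd: float = 0.02
    photon_budget: float = 1000.0
    seed: int = 0
    stage: str = "early_compaction"
    healthy_bound_fraction: float = 0.55

    def __post_init__(self) -> None:
        if self.n_healthy < 1 or self.n_unhealthy < 1:
            raise ContractError("group sizes must be >= 1")
        if not 0.0 <= self.effect_delta <= 1.0:
            raise ContractError("effect_delta must be in [0, 1]")
        if self.within_group_sd < 0:
            raise ContractError("within_group_sd must be >= 0")
        if self.photon_budget < 0:
            raise ContractError("photon_budget must be >= 0")
        if self.stage not in STAGES:
            raise ContractError(f"unknown stage {self.stage!r}")


def _disc_mask(cfg: InstrumentConfig, radius_frac: float = 0.4) -> np.ndarray:
    h, w = cfg.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = radius_frac * min(h, w)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def stage_lipid_fraction(stage: str) -> float:
    """Oxidized-lipid intensity fraction, rising with developmental stage.

    Long-lifetime lipid signal accumulates as embryos progress toward the
    blastocyst; the ramp 0.02 -> 0.11 is a generator convention, not a
    measured biological series.
    """
    return 0.02 + 0.015 * STAGES.index(stage)


def make_phantom(
    embryo_id: str,
    stage: str,
    bound_fraction: float,
    cfg: InstrumentConfig,
    photon_budget: float,
    label: str = "unknown",
    radius_frac: float = 0.4,
) -> EmbryoPhantom:
    """Uniform-composition disc phantom with the given bound-NADH share.

    ``bound_fraction`` is the bound share of the NADH pool; the stage's
    oxidized-lipid fraction is carved out first, free NADH takes the rest.
    """
    if not 0.0 <= bound_fraction <= 1.0:
        raise ContractError("bound_fraction must be in [0, 1]")
    lipid = stage_lipid_fraction(stage)
    f_bound = bound_fraction * (1.0 - lipid)
    f_free = (1.0 - bound_fraction) * (1.0 - lipid)
    mask = _disc_mask(cfg, radius_frac)
    ones = np.ones(cfg.shape)
    return EmbryoPhantom(
        embryo_id=embryo_id,
        stage=stage,
        species_fractions={
            FREE_NADH.name: f_free * ones,
            BOUND_NADH.name: f_bound * ones,
            OXIDIZED_LIPID.name: lipid * ones,
        },
        total_intensity=photon_budget * mask.astype(float),
        label=label,
    )


def generate_decay_image(
    phantom: EmbryoPhantom,
    cfg: InstrumentConfig,
    seed: int = 0,
    noise: bool = True,
) -> DecayImage:
    """Render a phantom into a per-pixel decay stack.

    Noise-free output is the exact per-pixel expectation; with ``noise``,
    each time bin is an independent Poisson draw (deterministic by seed).
    """
    if phantom.shape != cfg.shape:
        raise ContractError(
            f"phantom shape {phantom.shape} does not match config {cfg.shape}"
        )
    expected = np.zeros((*cfg.shape, cfg.n_bins))
    from .instrument import SPECIES_LIBRARY

    for name, frac_map in phantom.species_fractions.items():
        sp = SPECIES_LIBRARY[name]
        w = _species_bin_weights(sp, cfg)
        expected += (frac_map * phantom.total_intensity)[:, :, None] * w[None, None, :]
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(np.float64)
    else:
        counts = expected
    return DecayImage(counts=counts, cfg=cfg)


def generate_cohort(
    spec: CohortSpec, cfg: InstrumentConfig, noise: bool = True
) -> list[tuple[EmbryoPhantom, DecayImage]]:
    """Simulate a labelled H/UH cohort.

    Healthy embryos draw their bound-NADH fraction from
    Normal(healthy_bound_fraction, within_group_sd); unhealthy embryos from
    the same distribution shifted down by ``effect_delta``.  Fractions are
    clipped to [0, 1] with a warning.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[tuple[EmbryoPhantom, DecayImage]] = []
    plan = [("H", spec.healthy_bound_fraction, spec.n_healthy),
            ("UH", spec.healthy_bound_fraction - spec.effect_delta,
             spec.n_unhealthy)]
    idx = 0
    for label, mean_frac, n in plan:
        for i in range(n):
            bf = rng.normal(mean_frac, spec.within_group_sd)
            if not 0.0 <= bf <= 1.0:
                warnings.warn(
                    f"bound fraction {bf:.3f} clipped to [0, 1]; consider "
                    "smaller effect_delta or within_group_sd",
                    stacklevel=2,
                )
                bf = float(np.clip(bf, 0.0, 1.0))
            phantom = make_phantom(
                embryo_id=f"{label}{i + 1:03d}",
                stage=spec.stage,
                bound_fraction=bf,
                cfg=cfg,
                photon_budget=spec.photon_budget,
                label=label,
            )
            img = generate_decay_image(
                phantom, cfg,
                seed=int(rng.integers(0, 2**31 - 1)),
                noise=noise,
            )
            records.append((phantom, img))
            idx += 1
    return records


def generate_calibration_stack(
    species: FluorSpecies,
    cfg: InstrumentConfig,
    distortion: tuple[float, float] = (0.0, 1.0),
    photons: float = 10_000.0,
    seed: int = 0,
    noise: bool = False,
) -> DecayImage:
    """Homogeneous field of a reference fluorophore with an instrument
    distortion applied in frequency space.

    The phase error is a true detection delay ``phase_rad / omega`` applied
    to the continuous decay before bin integration (rotates harmonic n by
    ``n * phase_rad``); the modulation error mixes the delayed curve with a
    uniform (DC) background, ``m * curve + (1 - m) * uniform``, which scales
    every AC harmonic by exactly ``modulation_factor``.  The first-harmonic
    phasor of the output is therefore the species' theoretical phasor
    rotated by ``phase_rad`` about the origin and scaled by
    ``modulation_factor``; total intensity is preserved and counts stay
    non-negative for ``modulation_factor <= 1``.
    """
    phase_rad, mod = distortion
    if mod <= 0:
        raise ContractError("modulation_factor must be > 0")
    delay = phase_rad / cfg.angular_freq_rad_s
    w = _species_bin_weights(species, cfg, delay_s=delay)
    if mod != 1.0:
        w = mod * w + (1.0 - mod) / cfg.n_bins
        if np.any(w < 0):
            warnings.warn(
                "modulation_factor > 1 produced negative expectations; "
                "clipping to zero distorts the injected modulation",
                stacklevel=2,
            )
            w = np.clip(w, 0.0, None)
    curve = w * photons
    expected = np.broadcast_to(curve, (*cfg.shape, cfg.n_bins)).copy()
    if noise:
        rng = np.random.default_rng(seed)
        expected = rng.poisson(expected).astype(np.float64)
    return DecayImage(counts=expected, cfg=cfg)
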