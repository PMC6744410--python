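"""Per-embryo phasor summaries, developmental trajectories and the
free/bound-NADH chord.

An embryo is summarized by the intensity-weighted mean of its pixel phasors.
Stage-wise means and SDs of those summaries, ordered through development,
form the developmental (D-) trajectory.  Positions along the chord between
the free-NADH phasor (0.38 ns, right side of the plot) and the
enzyme-bound-NADH phasor (3.4 ns, left side) — the metabolic (M-)
trajectory — report the glycolytic/oxidative balance: by phasor linearity a
mixture's coordinates are the intensity-weighted combination of the two
endpoints, so the projected position IS the free-NADH intensity fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, EmptyResultError
from .instrument import BOUND_NADH, FREE_NADH, InstrumentConfig
from .phasor import PhasorImage, theoretical_phasor
from .synthetic import STAGES


@dataclass(frozen=True)
class EmbryoPhasorSummary:
    """Intensity-weighted mean phasor of one embryo."""

    embryo_id: str
    stage: str
    mean_g: float
    mean_s: float
    n_pixels: int


@dataclass(frozen=True)
class ChordReference:
    """Endpoints of a two-species mixing chord in phasor space."""

    endpoint_free: tuple[float, float]
    endpoint_bound: tuple[float, float]

    def __post_init__(self) -> None:
        if np.allclose(self.endpoint_free, self.endpoint_bound):
            raise ContractError("chord endpoints must be distinct")

    @classmethod
    def nadh(cls, cfg: InstrumentConfig) -> "ChordReference":
        """The metabolic chord: free NADH (0.38 ns) to bound NADH (3.4 ns)."""
        return cls(
            endpoint_free=theoretical_phasor(FREE_NADH.lifetime_ns, cfg),
            endpoint_bound=theoretical_phasor(BOUND_NADH.lifetime_ns, cfg),
        )


def embryo_mean_phasor(
    ph: PhasorImage,
    embryo_id: str = "",
    stage: str = STAGES[0],
    region: np.ndarray | None = None,
) -> EmbryoPhasorSummary:
    """Intensity-weighted mean (g, s) over unmasked pixels.

    ``region`` optionally restricts to a boolean sub-region; by default the
    whole image above the photon threshold contributes.
    """
    sel = ph.mask if region is None else (ph.mask & region)
    n = int(sel.sum())
    if n == 0:
        raise EmptyResultError("no unmasked pixel in the requested region")
    w = ph.intensity[sel]
    wsum = w.sum()
    return EmbryoPhasorSummary(
        embryo_id=embryo_id,
        stage=stage,
        mean_g=float(np.sum(w * ph.g[sel]) / wsum),
        mean_s=float(np.sum(w * ph.s[sel]) / wsum),
        n_pixels=n,
    )


def stage_summary(summaries: list[EmbryoPhasorSummary]) -> pd.DataFrame:
    """Across-embryo mean +/- sample SD of (g, s) per developmental stage.

    Rows are ordered chronologically (2cell -> blastocyst) regardless of
    input order; this ordered sequence is the D-trajectory.  Stages with a
    single embryo are reported with SD = NaN.
    """
    if not summaries:
        raise EmptyResultError("no embryo summaries provided")
    df = pd.DataFrame(
        {
            "stage": [e.stage for e in summaries],
            "mean_g": [e.mean_g for e in summaries],
            "mean_s": [e.mean_s for e in summaries],
        }
    )
    rows = []
    for stage in STAGES:
        sub = df[df.stage == stage]
        if sub.empty:
            continue
        n = len(sub)
        if n < 2:
            warnings.warn(f"stage {stage!r} has {n} embryo(s); SD undefined",
                          stacklevel=2)
        rows.append(
            {
                "stage": stage,
                "n": n,
                "mean_g": sub.mean_g.mean(),
                "sd_g": sub.mean_g.std(ddof=1) if n > 1 else math.nan,
                "mean_s": sub.mean_s.mean(),
                "sd_s": sub.mean_s.std(ddof=1) if n > 1 else math.nan,
            }
        )
    return pd.DataFrame(rows)


def component_fractions(
    point: tuple[float, float], chord: ChordReference
) -> tuple[float, bool]:
    """Fraction of free NADH at a phasor point, by orthogonal projection
    onto the metabolic chord.

    Returns ``(fraction_free, clipped)``: 0 at the bound endpoint, 1 at the
    free endpoint; projections falling outside the segment are clipped to
    [0, 1] and flagged.
    """
    p = np.asarray(point, dtype=float)
    b = np.asarray(chord.endpoint_bound, dtype=float)
    f = np.asarray(chord.endpoint_free, dtype=float)
    axis = f - b
    t = float(np.dot(p - b, axis) / np.dot(axis, axis))
    clipped = not (0.0 <= t <= 1.0)
    return float(np.clip(t, 0.0, 1.0)), clipped


def g_shift_test(
    group_a: list[float] | np.ndarray,
    group_b: list[float] | np.ndarray,
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t-test on per-embryo mean g values.

    The default is the pooled-variance Student form; ``welch=True`` switches
    to the unequal-variance Welch form.  With zero pooled variance the
    statistic is undefined: (0, 1) is returned for equal means, (inf-signed,
    NaN) with a warning otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ContractError("each group needs >= 2 embryos")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        diff = a.mean() - b.mean()
        if diff == 0.0:
            return 0.0, 1.0
        warnings.warn("zero pooled variance; p-value undefined", stacklevel=2)
        return math.copysign(math.inf, diff), math.nan
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
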