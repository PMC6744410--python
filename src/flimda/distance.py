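"""Distance Analysis (DA): the variance-weighted distance classifier and
the Embryo Viability Index (EVI).

Pipeline: each embryo's calibrated phasor image is tallied into a 3D
histogram — a 2D (g, s) grid stratified into 4 intensity sections.  Each
section contributes 6 parameters: the center of mass (g_cm, s_cm), the two
second axial moments (a, b) after diagonalizing the (g, s) covariance, the
principal-axis angle, and the pixel count — 24 parameters per embryo.  The
20 shape parameters (pixel counts excluded) enter a per-group
variance-weighted squared distance

    D_G(x) = sum_i w_i (x_i - mu_G,i)^2 / var_G,i,     G in {H, UH},

whose difference r = D_H - D_UH is the raw score: negative means the embryo
sits closer to the healthy training centroid.  Weights w in [0, 1]^20 are
optimized to maximize the separation of the two training groups'
raw scores; the EVI maps |r| affinely onto [1, 10] with the training
maximum pinned at 10, signed so that (by default) healthy is negative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skmetrics

from .errors import ContractError, EmptyResultError, OptimizationError
from .phasor import PhasorImage

#: Parameter names per section, in feature-vector order.
SECTION_PARAMS = ("g_cm", "s_cm", "a", "b", "angle_deg", "n_pixels")
N_SECTIONS = 4
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"sec{sec}_{p}" for sec in range(1, N_SECTIONS + 1) for p in SECTION_PARAMS
)
#: Indices of the 20 weighted parameters (pixel counts carry no weight).
WEIGHTED_INDICES: tuple[int, ...] = tuple(
    i for i, name in enumerate(FEATURE_NAMES) if not name.endswith("n_pixels")
)

DEFAULT_G_RANGE = (-0.2, 1.2)
DEFAULT_S_RANGE = (-0.2, 0.8)
DEFAULT_GRID_BINS = 128


@dataclass
class PhasorHistogram3D:
    """Sectioned 2D tally of pixel phasors.

    ``counts`` is the total (g, s) histogram; ``section_counts[k]`` the
    histogram of section k+1's pixels; ``section_assignment`` maps each
    image pixel to its section in {1..4} (0 for masked pixels).
    """

    bin_edges_g: np.ndarray
    bin_edges_s: np.ndarray
    counts: np.ndarray
    section_counts: np.ndarray  # (4, n_g, n_s)
    section_assignment: np.ndarray
    mode: str = "intensity"

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class SliceFeatures:
    """Moment summary of one histogram section."""

    g_cm: float
    s_cm: float
    a: float  # major axial SD (sqrt of larger covariance eigenvalue)
    b: float  # minor axial SD
    angle_deg: float  # principal-axis orientation vs the g axis, [-90, 90)
    n_pixels: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.g_cm, self.s_cm, self.a, self.b, self.angle_deg,
             float(self.n_pixels)]
        )


@dataclass
class DAModel:
    """Trained group statistics, optimized weights and EVI scaling."""

    mu_H: np.ndarray
    var_H: np.ndarray
    mu_UH: np.ndarray
    var_UH: np.ndarray
    weights: np.ndarray  # length 20, in [0, 1], aligned with WEIGHTED_INDICES
    evi_scale: float
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(WEIGHTED_INDICES),):
            raise ContractError(
                f"weights must have length {len(WEIGHTED_INDICES)}"
            )
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ContractError("weights must lie in [0, 1]")
        if self.evi_scale <= 0:
            raise ContractError("evi_scale must be positive")


@dataclass(frozen=True)
class EVIResult:
    """Signed viability score for one embryo."""

    embryo_id: str
    raw_score: float
    evi: float
    predicted: str  # H | UH


def build_histogram3d(
    ph: PhasorImage,
    grid_bins: int = DEFAULT_GRID_BINS,
    g_range: tuple[float, float] = DEFAULT_G_RANGE,
    s_range: tuple[float, float] = DEFAULT_S_RANGE,
    mode: str = "intensity",
) -> PhasorHistogram3D:
    """Tally unmasked pixels over a fixed (g, s) grid, split into 4 sections.

    ``mode="intensity"`` (default) assigns each pixel to a quartile of the
    per-pixel photon count, so every section is guaranteed (near-)equally
    populated.  ``mode="zlevel"`` instead slices by histogram occupancy:
    a pixel's section is set by which quarter of the maximum bin count its
    own (g, s) bin reaches.
    """
    if mode not in ("intensity", "zlevel"):
        raise ContractError(f"unknown section mode {mode!r}")
    if ph.n_valid == 0:
        raise EmptyResultError("phasor image has no unmasked pixel")
    g, s, inten = ph.valid_gs()
    edges_g = np.linspace(*g_range, grid_bins + 1)
    edges_s = np.linspace(*s_range, grid_bins + 1)
    # clip into range so that out-of-grid pixels land in edge bins and the
    # histogram conserves the pixel count
    gi = np.clip(np.searchsorted(edges_g, g, side="right") - 1, 0, grid_bins - 1)
    si = np.clip(np.searchsorted(edges_s, s, side="right") - 1, 0, grid_bins - 1)

    counts = np.zeros((grid_bins, grid_bins))
    np.add.at(counts, (gi, si), 1)

    if mode == "intensity":
        qs = np.quantile(inten, [0.25, 0.5, 0.75])
        sec = np.searchsorted(qs, inten, side="left") + 1  # 1..4
    else:
        per_pixel_occ = counts[gi, si]
        top = counts.max()
        sec = np.ceil(4.0 * per_pixel_occ / top).astype(int)
        sec = np.clip(sec, 1, 4)

    assignment = np.zeros(ph.g.shape, dtype=int)
    assignment[ph.mask] = sec
    section_counts = np.zeros((N_SECTIONS, grid_bins, grid_bins))
    for k in range(N_SECTIONS):
        in_k = sec == k + 1
        np.add.at(section_counts[k], (gi[in_k], si[in_k]), 1)
    return PhasorHistogram3D(
        bin_edges_g=edges_g,
        bin_edges_s=edges_s,
        counts=counts,
        section_counts=section_counts,
        section_assignment=assignment,
        mode=mode,
    )


def extract_slice_features(h: PhasorHistogram3D, section: int) -> SliceFeatures:
    """Center of mass, axial SDs and orientation of one section.

    The count-weighted 2x2 covariance of (g, s) bin centers is
    diagonalized; a and b are the square roots of its eigenvalues (a >= b),
    the angle is the a-eigenvector's orientation w.r.t. the g axis in
    degrees, wrapped to [-90, 90).  Equal eigenvalues (isotropy) make the
    orientation undefined; 0 is returned by convention.  An empty section
    yields all-zero features with a warning.
    """
    if not 1 <= section <= N_SECTIONS:
        raise ContractError(f"section must be in 1..{N_SECTIONS}")
    w = h.section_counts[section - 1]
    n = w.sum()
    if n == 0:
        warnings.warn(f"section {section} is empty; features set to zero",
                      stacklevel=2)
        return SliceFeatures(0.0, 0.0, 0.0, 0.0, 0.0, 0)
    cg = 0.5 * (h.bin_edges_g[:-1] + h.bin_edges_g[1:])
    cs = 0.5 * (h.bin_edges_s[:-1] + h.bin_edges_s[1:])
    gg, ss = np.meshgrid(cg, cs, indexing="ij")
    p = w / n
    mg = float(np.sum(p * gg))
    ms = float(np.sum(p * ss))
    dg = gg - mg
    ds = ss - ms
    cov = np.array(
        [
            [np.sum(p * dg * dg), np.sum(p * dg * ds)],
            [np.sum(p * dg * ds), np.sum(p * ds * ds)],
        ]
    )
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lo, hi = max(evals[0], 0.0), max(evals[1], 0.0)
    a, b = math.sqrt(hi), math.sqrt(lo)
    if hi - lo < 1e-14:
        angle = 0.0  # isotropic: orientation undefined
    else:
        vg, vs = evecs[:, 1]
        angle = math.degrees(math.atan2(vs, vg))
        angle = (angle + 90.0) % 180.0 - 90.0  # wrap to [-90, 90)
    return SliceFeatures(mg, ms, a, b, angle, int(n))


def assemble_feature_vector(h: PhasorHistogram3D) -> np.ndarray:
    """The 24-parameter DA feature vector: sections 1..4 x
    (g_cm, s_cm, a, b, angle_deg, n_pixels), in FEATURE_NAMES order."""
    parts = [extract_slice_features(h, k).as_array()
             for k in range(1, N_SECTIONS + 1)]
    return np.concatenate(parts)


def features_from_phasor(ph: PhasorImage, **histogram_kwargs) -> np.ndarray:
    """Convenience: histogram + feature extraction in one call."""
    return assemble_feature_vector(build_histogram3d(ph, **histogram_kwargs))


def fit_group_stats(
    training: list[tuple[np.ndarray, str]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-parameter sample mean and variance for the H and UH groups.

    Variances are floored at ``1e-12 + 1e-6 * scale^2`` (scale = pooled RMS
    of the parameter) so that tiny training sets — down to the 5 H + 7 UH
    of a single experiment — cannot produce infinite distance terms.
    """
    X = {lbl: [] for lbl in ("H", "UH")}
    for x, lbl in training:
        if lbl not in X:
            raise ContractError(f"label must be H or UH, got {lbl!r}")
        x = np.asarray(x, dtype=float)
        if x.shape != (len(FEATURE_NAMES),):
            raise ContractError(
                f"feature vector must have length {len(FEATURE_NAMES)}"
            )
        X[lbl].append(x)
    for lbl, rows in X.items():
        if len(rows) < 2:
            raise ContractError(f"group {lbl} needs >= 2 embryos")
    pooled = np.vstack(X["H"] + X["UH"])
    floor = 1e-12 + 1e-6 * np.mean(pooled**2, axis=0)
    stats = []
    for lbl in ("H", "UH"):
        arr = np.vstack(X[lbl])
        stats.append(arr.mean(axis=0))
        stats.append(np.maximum(arr.var(axis=0, ddof=1), floor))
    return tuple(stats)  # mu_H, var_H, mu_UH, var_UH


def weighted_distance(x: np.ndarray, model: DAModel, group: str) -> float:
    """Variance-weighted squared distance of x from one group's centroid,
    over the 20 weighted parameters (pixel counts excluded)."""
    if group == "H":
        mu, var = model.mu_H, model.var_H
    elif group == "UH":
        mu, var = model.mu_UH, model.var_UH
    else:
        raise ContractError("group must be H or UH")
    idx = list(WEIGHTED_INDICES)
    x = np.asarray(x, dtype=float)
    d = (x[idx] - mu[idx]) ** 2 / var[idx]
    return float(np.sum(model.weights * d))


def raw_score(x: np.ndarray, model: DAModel) -> float:
    """r = D_H(x) - D_UH(x); negative means closer to the healthy centroid."""
    return weighted_distance(x, model, "H") - weighted_distance(x, model, "UH")


def _score_matrix(
    X: np.ndarray, mu_H, var_H, mu_UH, var_UH
) -> np.ndarray:
    """Per-embryo, per-weighted-parameter score contributions Z such that
    raw_score = Z @ w."""
    idx = list(WEIGHTED_INDICES)
    dH = (X[:, idx] - mu_H[idx]) ** 2 / var_H[idx]
    dUH = (X[:, idx] - mu_UH[idx]) ** 2 / var_UH[idx]
    return dH - dUH


def _separation(r_H: np.ndarray, r_UH: np.ndarray) -> float:
    """J = (mean_UH - mean_H)^2 / (var_H + var_UH) of the raw scores."""
    denom = r_H.var(ddof=1) + r_UH.var(ddof=1)
    if denom == 0.0:
        return math.inf if r_UH.mean() != r_H.mean() else 0.0
    return (r_UH.mean() - r_H.mean()) ** 2 / denom


WEIGHT_GRID = np.round(np.linspace(0.0, 1.0, 11), 1)


def optimize_weights(
    training: list[tuple[np.ndarray, str]],
    init_weights: np.ndarray | None = None,
    budget: int = 100,
) -> DAModel:
    """Fit group statistics and optimize the 20 weights by deterministic
    cyclic coordinate search.

    Each weight in turn is scanned over the grid {0, 0.1, ..., 1} in fixed
    order with first-improvement acceptance; cycles repeat until a full
    cycle makes no change or ``budget`` cycles elapse.  The EVI scale is set
    so the largest training |raw score| maps to EVI magnitude 10.
    """
    if budget < 1:
        raise ContractError("budget must be >= 1")
    mu_H, var_H, mu_UH, var_UH = fit_group_stats(training)
    X = np.vstack([np.asarray(x, dtype=float) for x, _ in training])
    labels = np.array([lbl for _, lbl in training])
    Z = _score_matrix(X, mu_H, var_H, mu_UH, var_UH)
    is_H = labels == "H"

    def objective(w: np.ndarray) -> float:
        r = Z @ w
        return _separation(r[is_H], r[~is_H])

    n_w = len(WEIGHTED_INDICES)
    w = (np.ones(n_w) if init_weights is None
         else np.asarray(init_weights, dtype=float).copy())
    if w.shape != (n_w,) or np.any(w < 0) or np.any(w > 1):
        raise ContractError(f"init_weights must be {n_w} values in [0, 1]")
    best = objective(w)
    if not math.isfinite(best):
        raise OptimizationError("separation objective is not finite; "
                                "training groups are degenerate")
    cycles = 0
    converged = False
    for cycles in range(1, budget + 1):
        changed = False
        for j in range(n_w):
            for cand in WEIGHT_GRID:
                if cand == w[j]:
                    continue
                w_try = w.copy()
                w_try[j] = cand
                val = objective(w_try)
                if val > best + 1e-12:  # first improvement wins
                    w, best = w_try, val
                    changed = True
                    break
        if not changed:
            converged = True
            break

    r_train = Z @ w
    max_abs = float(np.max(np.abs(r_train)))
    evi_scale = 1.0 / max_abs if max_abs > 0 else 1.0
    if best <= 1e-12:
        warnings.warn(
            "training groups are statistically indistinguishable "
            "(separation ~ 0); optimizer stopped without separating them",
            stacklevel=2,
        )
    return DAModel(
        mu_H=mu_H, var_H=var_H, mu_UH=mu_UH, var_UH=var_UH,
        weights=w, evi_scale=evi_scale,
        training_meta={
            "budget": budget,
            "cycles_used": cycles,
            "converged": converged,
            "objective": best,
            "n_H": int(is_H.sum()),
            "n_UH": int((~is_H).sum()),
        },
    )


def evi_score(
    x: np.ndarray,
    model: DAModel,
    embryo_id: str = "",
    healthy_negative: bool = True,
) -> EVIResult:
    """Embryo Viability Index of one feature vector.

    evi = sign(r) * min(10, 1 + 9 |r| * evi_scale), so |EVI| is in [1, 10];
    with the default sign convention negative EVI predicts healthy (raw
    score closer to the H centroid).  ``healthy_negative=False`` flips the
    reported sign only.  A raw score of exactly 0 is predicted H by
    tie-break, with a warning.
    """
    r = raw_score(x, model)
    if r == 0.0:
        warnings.warn(f"raw score exactly 0 for {embryo_id!r}; "
                      "predicted H by tie-break", stacklevel=2)
        predicted = "H"
        evi = -1.0
    else:
        predicted = "H" if r < 0 else "UH"
        evi = math.copysign(min(10.0, 1.0 + 9.0 * abs(r) * model.evi_scale), r)
    if not healthy_negative:
        evi = -evi
    return EVIResult(embryo_id=embryo_id, raw_score=r, evi=evi,
                     predicted=predicted)


def roc_curve(
    scores: list[float] | np.ndarray, labels: list[str] | np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC of raw scores against true labels (lower score => healthy).

    UH is the positive class.  Returns (fpr, tpr, auc); the AUC is the
    probability that a random UH embryo scores above a random H embryo
    (ties counted half, the Mann-Whitney convention).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    present = set(labels.tolist())
    if present != {"H", "UH"}:
        raise ContractError(
            f"both labels H and UH must be present, got {sorted(present)}"
        )
    y = (labels == "UH").astype(int)
    fpr, tpr, _ = _skmetrics.roc_curve(y, scores)
    auc = float(_skmetrics.auc(fpr, tpr))
    return fpr, tpr, auc
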