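# Methods

## Signal model

The instrument model is frequency-domain FLIM: a pulsed laser at repetition
rate f (default 80 MHz, period T = 1/f = 12.5 ns) excites the sample and
each pixel accumulates photon counts over `n_bins` time bins spanning one
period (default 256). Because the pulse train is infinite, a fluorophore of
lifetime τ reaches the *periodic steady state*

    I(t) ∝ exp(−t/τ) / (1 − exp(−T/τ)),  t ∈ [0, T),

i.e. the tail of every previous pulse folds into the current period. This
wrapping is negligible for τ ≪ T but substantial for the 7.89 ns oxidized-
lipid species at 80 MHz; using single-pulse decays instead would displace
its phasor visibly. Simulated bin contents are the exact integrals of this
density over each bin (so noise-free stacks conserve the photon budget to
machine precision), and photon noise is independent Poisson per bin. τ = 0
encodes an instantaneous, scattering-like signal (third harmonic
generation), which carries all its mass in the first bin and maps to the
phasor point (1, 0).

An instrument response function is not convolved explicitly. Real
frequency-domain systems are corrected through a reference fluorophore
rather than by IRF deconvolution, so the generator exposes the instrument
error in exactly the form the correction removes: a detection delay
(rotating harmonic n of the decay by n·φ) plus a demodulation factor
(implemented as mixing with a uniform background, which scales every AC
harmonic by m ≤ 1 while keeping counts non-negative and total intensity
fixed).

## Phasor transform and calibration

The discrete transform evaluates the first-harmonic Fourier quotient at bin
centers t_k = (k + ½)T/N:

    g = Σ I_k cos(ω t_k) / Σ I_k,   s = Σ I_k sin(ω t_k) / Σ I_k,

ω = 2πf (first harmonic only; higher harmonics are configurable but
unused). Bin-center sampling keeps the discretization bias of the
transform at O(1/N²): at 256 bins the recovered modulation lifetime of a
simulated single-exponential decay is within 0.1% of truth, and the
agreement with direct numerical quadrature of the continuous Fourier
integrals reaches 1e-6 at 8192 bins. Pixels with fewer than `min_photons`
total photons (default 20) are masked; below that the shot-noise scatter of
(g, s) dominates any biological signal.

Calibration fits one global rotation-about-origin plus radial scaling that
maps the *intensity-weighted* mean phasor of a reference stack (coumarin 6,
τ = 2.5 ns, or Rho110, τ = 4 ns on the THG path) onto its closed-form
position; intensity weighting is the maximum-likelihood pooling under
Poisson statistics. The same transform is applied to every pixel of the
target image. Lifetime inversion provides both the phase lifetime
s/(ωg) and the modulation lifetime √(1/(g²+s²) − 1)/ω; they agree on the
semicircle and bracket the component lifetimes for interior mixture points.
A modulation > 1 (outside the unit circle, unphysical) yields NaN rather
than an exception. An optional NaN-aware median filter (odd window,
default off) can be applied to g and s before histogramming; it never
touches intensities or the mask.

## Phantoms and cohorts

Phantoms place a spatially uniform three-species mixture — free NADH
(0.38 ns), bound NADH (3.4 ns), oxidized lipid (7.89 ns) — on a filled
disc (radius 0.4 of the image side) over a zero-intensity background. The
DA features are histogram statistics, so blastomere-scale texture would add
realism without changing what the tests probe; it is deliberately absent.

A cohort draws each healthy embryo's bound-NADH share of the NADH pool from
Normal(0.55, 0.02), and each unhealthy embryo's from the same distribution
shifted down by `effect_delta` (default 0.2) — unhealthy embryos skew
glycolytic (more free NADH, shorter lifetimes), matching the direction of
metabolic shift the classifier exploits. The oxidized-lipid fraction ramps
with developmental stage (0.02 + 0.015 × stage index over 2cell →
blastocyst) to mimic lipid oxidation accumulating toward the blastocyst.
Default photon budget is 1000 photons/pixel. Out-of-range draws are clipped
to [0, 1] with a warning. These numbers are generator conventions chosen to
be physiologically plausible, not measured mouse values; no per-stage
fractions are published for this system. All randomness flows from a single
integer seed per call.

What passing tests on these cohorts demonstrate: the pipeline detects a
controlled shift in species composition against Poisson noise at realistic
photon budgets, and behaves at chance when no shift exists. What they do
not demonstrate: performance on real embryos, where within-embryo spatial
heterogeneity, autofluorescence background, motion and segmentation errors
all add variance not modelled here.

## Distance Analysis

Pixels above the photon threshold are tallied on a fixed 128 × 128 (g, s)
grid over [−0.2, 1.2] × [−0.2, 0.8]; out-of-grid pixels are clipped into
the edge bins so counts are conserved. The third histogram dimension is an
intensity stratification into 4 sections. The default assigns pixels to
quartiles of their total photon count using value-based thresholds: tied
intensities share a section, which preserves invariance to pixel order (a
rank-based split would not) at the cost of degenerating to one populated
section for exactly-constant images. The alternative reading — slicing by
histogram occupancy (which quarter of the maximum bin count a pixel's bin
reaches) — is available as `mode="zlevel"`.

Each section yields 6 parameters: count-weighted center of mass (g_cm,
s_cm); a, b = square roots of the eigenvalues of the count-weighted 2×2
covariance of bin centers (axial SDs, a ≥ b, commensurate with the
coordinates); the orientation of the major axis w.r.t. the g axis in
degrees, wrapped to [−90, 90), set to 0 when a = b (isotropy leaves the
orientation undefined); and the pixel count. Empty sections produce all-zero
features with a warning. 4 × 6 = 24 parameters; the 4 pixel counts are
excluded from weighting, leaving 20.

Group statistics are per-parameter sample means and variances of the
training vectors, with variances floored at 1e-12 + 1e-6·(pooled RMS)² so
that training sets as small as 5 + 7 embryos cannot produce infinite
distance terms. Angles are treated as plain bounded numbers after wrapping;
circular statistics are intentionally not used, and the variance floor
guards the wrap point.

The raw score is r = D_H − D_UH with D_G the variance-weighted squared
distance above; negative r means closer to the healthy centroid, and the
default sign convention reports healthy as negative EVI (a configuration
flag flips the reported sign only). Weights are optimized by cyclic
coordinate search over the grid {0, 0.1, …, 1}, initialized at all-ones,
first-improvement acceptance, at most 100 cycles, maximizing
J(w) = (mean_UH(r) − mean_H(r))² / (var_H(r) + var_UH(r)). The procedure is
derivative-free and fully deterministic: identical training data give
identical weights.

A caveat this package documents rather than hides: J is an *in-sample*
objective. With iid nuisance parameters the sample-fitted group statistics
give every parameter a small positive in-sample separation, so the search
will spread weight onto noise features and the training-set J (and AUC)
overstate generalization. Evaluation must therefore use held-out embryos,
as the acceptance checks do; with 20 weights and cohorts of tens of
embryos, training AUC ≈ 1 is expected even under the null.

The EVI maps the raw score as sign(r)·min(10, 1 + 9·|r|·c) with c chosen so
the largest training |r| hits magnitude 10 — an affine clip that preserves
ranking and reproduces the ±[1, 10] index range; the magnitude mapping
itself is a package convention. ROC analysis sweeps thresholds on r with
UH as the positive class (standard midrank tie handling); AUC equals the
normalized Mann–Whitney statistic, which the tests verify by brute-force
pair counting.

## Colocalization

Mander's split coefficients are intensity-weighted: M1 is the fraction of
THG-channel intensity inside both masks relative to the THG mask, M2 the
mirror image with the FLIM-channel intensity. The FLIM mask is a circular
phasor cursor (default radius 0.05, comparable to shot-noise spread at
10³ photons/pixel) centered on the oxidized-lipid position; the THG mask
defaults to Otsu's threshold, with an absolute-threshold override. Both
coefficients are invariant to uniform rescaling of either channel and are
NaN (with a warning) when a channel has no intensity inside its own mask.

## Numerical and testing choices

- Cohort-level tests and the reproduction script run at 32 × 32 px and 64
  bins — the histogram-moment features do not benefit from more pixels, and
  a full 60-embryo train/score loop completes in ~2 s. Physics checks use
  the native 256 bins, or finer (4096–8192) where a tolerance of 1e-6
  requires discretization error below the bin bias of 256 bins.
- File formats are deliberately plain: multi-page TIFF (one page per time
  bin, uint32) with a JSON sidecar naming the repetition rate, bin count,
  harmonic and pixel order; models and calibrations as JSON; tables as CSV.
  Vendor FLIM formats are out of scope, with `read_decay_stack` as the
  documented shim point.
- Known limitations: no IRF shape beyond phase/modulation error, no spatial
  texture in phantoms, no second emission channel, no cross-validation
  beyond a single train/test split, value-based quartile ties as described
  above, and EVI magnitudes are comparable only within one trained model
  (the scale is training-set relative).
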