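# flimda

Phasor-FLIM simulation and Distance Analysis (DA) viability scoring for
pre-implantation embryos.

Label-free fluorescence lifetime imaging (FLIM) records, at every pixel, a
photon-arrival histogram over one laser period instead of a single intensity.
The endogenous fluorophores of an embryo — free NADH (τ ≈ 0.38 ns),
enzyme-bound NADH (τ ≈ 3.4 ns), oxidized lipids (τ ≈ 7.89 ns) — have
distinct lifetimes, so the shape of each pixel's decay encodes the embryo's
metabolic state. `flimda` implements the full analysis chain on that signal,
together with a synthetic-data generator so every stage is testable without
microscope data:

1. **Forward simulation** (`flimda.synthetic`) — periodic steady-state
   multi-exponential decays with Poisson photon noise; embryo phantoms and
   labelled healthy/unhealthy (H/UH) cohorts; reference-fluorophore
   calibration stacks with injected instrument distortions.
2. **Phasor transform** (`flimda.phasor`) — each pixel's decay *I(t)* maps to

   *g* = ∫ I(t) cos(ωt) dt / ∫ I(t) dt,  *s* = ∫ I(t) sin(ωt) dt / ∫ I(t) dt

   at ω = 2π·80 MHz. Single exponentials land on the universal semicircle
   (g−½)² + s² = ¼ at g = 1/(1+(ωτ)²), s = ωτ/(1+(ωτ)²); mixtures land
   inside, on intensity-weighted chords. Calibration against a fluorophore
   of known lifetime (coumarin 6, τ = 2.5 ns, or Rho110, τ = 4 ns) removes
   instrument phase/modulation errors; lifetime inversion recovers τ from
   (g, s).
3. **Trajectories** (`flimda.trajectory`) — per-embryo mean phasors,
   stage-ordered developmental (D-)trajectory summaries, free/bound-NADH
   fractions by projection onto the metabolic (M-)chord, and the Student
   t-test on g used for group comparisons.
4. **Distance Analysis** (`flimda.distance`) — the classifier: the phasor
   histogram is split into 4 intensity sections; each contributes center of
   mass (g, s), the two axial second moments a ≥ b after diagonalization,
   the principal-axis angle and the pixel count (24 parameters, 20
   weighted). An embryo's distance from each group is

   D_G(x) = Σᵢ wᵢ (xᵢ − μ_G,ᵢ)² / σ²_G,ᵢ,  G ∈ {H, UH},

   and the raw score r = D_H − D_UH (negative ⇒ healthier). Weights are
   optimized by deterministic coordinate search to maximize the separation
   (μ_UH(r) − μ_H(r))² / (σ²_H(r) + σ²_UH(r)). The **Embryo Viability
   Index** maps |r| onto [1, 10], signed so healthy is negative, and
   performance is read from the ROC/AUC.
5. **Colocalization** (`flimda.coloc`) — Mander's split coefficients between
   a THG-like lipid channel and a long-lifetime phasor cursor selection.
6. **Files & CLI** (`flimda.io`, `flimda.cli`) — multi-page TIFF + JSON
   sidecar stacks, CSV feature/EVI tables, JSON models, and a `flimda`
   command with `simulate / calibrate / phasor / features / train / score /
   roc / coloc` subcommands.

## Worked example

Train on one simulated cohort, score a second, held-out cohort:

```python
from flimda import InstrumentConfig, CohortSpec, generate_cohort, roc_curve
from flimda.pipeline import cohort_feature_rows, train_model, score_rows

cfg = InstrumentConfig(n_bins=64, width_px=32, height_px=32)  # 80 MHz
train = cohort_feature_rows(generate_cohort(
    CohortSpec(n_healthy=15, n_unhealthy=15, effect_delta=0.2, seed=1), cfg))
test = cohort_feature_rows(generate_cohort(
    CohortSpec(n_healthy=15, n_unhealthy=15, effect_delta=0.2, seed=2), cfg))

model = train_model(train, budget=100)
results = score_rows(test, model)
fpr, tpr, auc = roc_curve([r.raw_score for r in results],
                          [label for _, _, label, _ in test])
for r in results[:3] + results[-3:]:
    print(f"{r.embryo_id}: raw={r.raw_score:+9.1f}  EVI={r.evi:+6.2f}"
          f"  -> {r.predicted}")
print(f"held-out AUC: {auc:.3f}")
```

Output:

```
H001: raw=    -18.6  EVI= -3.16  -> H
H002: raw=    -22.6  EVI= -3.63  -> H
H003: raw=     -3.9  EVI= -1.46  -> H
UH013: raw=    +36.1  EVI= +5.20  -> UH
UH014: raw=    +62.7  EVI= +8.30  -> UH
UH015: raw=    +71.8  EVI= +9.37  -> UH
held-out AUC: 1.000
```

Healthy embryos score negative (closer to the healthy training centroid),
unhealthy positive; |EVI| grades how far an embryo sits from the training
set, capped at 10. With a 0.2 shift in mean bound-NADH fraction between
groups — a strong metabolic effect — the held-out cohort separates
perfectly. `effect_delta=0` gives AUC ≈ 0.5, the null behaviour.

The same pipeline from a shell:

```sh
flimda simulate --out cohort/ --n-healthy 15 --n-unhealthy 15 --seed 1
flimda features --cohort cohort/ --out features.csv
flimda train    --features features.csv --out model.json
flimda score    --features features.csv --model model.json --out evi.csv
flimda roc      --evi evi.csv --out roc.csv
```

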