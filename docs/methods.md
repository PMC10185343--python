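# Methods

`qflim` quantifies protein–protein binding in live cells from fast FLIM-FRET
(qF³-style) measurements, and ships a synthetic-data generator that emulates
the full acquisition so every stage can be validated against known ground
truth. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic benchmarks do and do not
demonstrate.

## The measurement model

A donor fluorophore (mCerulean3-like, lifetime τ_free = 3.8 ns) is fused to
an anti-apoptotic protein; an acceptor (Venus-like) is fused to the query
protein. When the two proteins bind, FRET shortens the donor lifetime to
τ_bound (< 3.4 ns observed; 2.4 ns is the package default, efficiency
E ≈ 0.37). Per-pixel TCSPC histograms record photon arrival times after
pulsed excitation (12.5 ns repetition period, 256 bins by default).

### Phasor transform

A decay histogram with counts c_i at bin centers t_i maps to

    g = Σ c_i cos(ω t_i) / Σ c_i,   s = Σ c_i sin(ω t_i) / Σ c_i,
    ω = 2π/T (first harmonic)

Single exponentials lie on the universal semicircle g = 1/(1+(ωτ)²),
s = ωτ/(1+(ωτ)²); mixtures lie on chords, weighted by each species' photon
contribution. The transform is linear: the phasor of pooled decays is the
photon-weighted mean of component phasors (tested exactly).

Because the bins tile one full period and the transform is evaluated at a
harmonic of 1/T, the periodic truncation of the decay drops out exactly; the
only discretization left is the midpoint rule, whose relative error at 256
bins is ~(2π/256)²/24 ≈ 2×10⁻⁵ — negligible against photon noise.

*Phase lifetime*: τ_φ = (s/g)/ω. At 10⁵ photons per region the estimator's
accuracy (bias) is below 1% for τ between 0.5 and 6 ns; its single-shot
precision is ~0.3% at τ = 0.5 ns, growing to ~2% at τ = 6 ns. Tests of the
1% accuracy claim therefore average ~50 replicate decays rather than assert
on one Poisson draw.

*Calibration*: a fluorescein reference (known lifetime 4.0 ns) measured in
the same session defines a complex rotation-and-scale that maps the measured
reference onto its theoretical phasor; the same correction is applied to all
sample phasors. Quenched fluorescein serves as a quality check (it should
map near (1, 0)), not as a second constraint. The distort-then-calibrate
round trip is identity to 10⁻⁶.

### The binding statistic Δω

Δω = (φ_donor − φ_sample)/φ_donor, with φ = atan2(s, g) and φ_donor taken
from a per-session donor-only reference (photon-weighted mean phasor of
ROIs from cells expressing donor without acceptor). Δω is zero for unbound
donor, increases strictly monotonically with the bound donor fraction at
fixed lifetimes, and reaches ≈ 0.193 at full binding for the default
lifetime pair. The literature definition of this statistic is not fully
standardized; any monotone rescaling leaves the downstream dissociation
constants and % Resistance essentially unchanged, because those are
recovered from the *shape* of the binding curve, not its absolute scale.

## From images to binding curves

1. **Segmentation.** Watershed on the time-summed TCSPC (donor intensity)
   channel: background threshold → Laplacian-of-Gaussian enhancement →
   local-maxima markers under a structuring element → watershed on the
   inverted enhanced image → minimum-size filter → optional erosion (applied
   after the size filter). The published parameter set (threshold 1000,
   kernel 7, sigma 0.13, structuring element 43, min size 6, erode 0) is the
   `SegParams` default; synthetic scenes use values scaled to their own gain
   and cell size. Alternatively, ROIs can be defined from an organelle
   landmark channel (mCherry intensity = hyperspectral sum over 592–660 nm),
   which yields elongated mesh-like ROIs for ER landmarks and punctate ones
   for mitochondrial landmarks.
2. **Concentration conversion.** Mean donor/acceptor intensity per ROI is
   converted to µM through linear standard curves fitted to recombinant-
   protein standards imaged on the same plate. Analysis windows: donor
   1–3 µM, acceptor 0–50 µM.
3. **Free acceptor.** B_max is first estimated as the median Δω of ROIs
   with 30–50 µM *total* acceptor, the implied bound fraction
   f = clip(Δω/B_max, 0, 1) gives A_free = max(0, A_total − f·D_total),
   and one refinement pass re-estimates B_max on the free-acceptor axis.
   The ordering is a package choice; the circularity is mild because donor
   is capped at 3 µM.
4. **Binning and fitting.** ROIs are binned along A_free with non-uniform
   edges (0, 1, 2, 3, 4, 5, 7.5, 10, 15, 20, 25, 30, 40, 50 µM): fine at low
   concentration so the half-saturation of tight binders (K_d of a few µM)
   is resolved, coarse toward saturation. A uniform 5 µM grid folds the
   entire rising limb of a K_d ≈ 2 µM curve into one bin and inflates the
   recovered constant by ~25%. Per-bin mean, SE, and count feed a weighted
   (1/SE²) least-squares Hill fit

       Δω(A_free) = B_max · A_free / (K_d + A_free)

   with K_d parameterized on a log scale (positivity structural) and the
   Hill coefficient fixed at 1 (1:1 binding; a flag frees it for
   exploration). B_max is initialized at the window median and bounded to
   [0.5×, 4×] of it (capped at 0.6): the window median anchors the scale,
   but for weak binders (K_d ≳ 30 µM) the 30–50 µM window sits well below
   saturation, so a symmetric ±50% clamp would force B_max low and bias K_d
   down by ~35%; the asymmetric upper bound lets the fit reach saturation.
   90% confidence intervals come from a seeded percentile bootstrap
   (500 ROI resamples, the whole chain re-run per resample).
5. **Classification.** sRatio = weighted RSS of the best straight line
   through the origin (collision model) divided by the weighted RSS of the
   Hill fit, computed on the binned curve. The Hill family nests the line
   (K_d → ∞), so the ratio is ≥ 1 by construction and the nesting is
   enforced explicitly when the bounded fit stops short of the limit.
   sRatio ≥ 1.5 together with a dynamic-range pass (positive-minus-negative
   control Δω > 0.05 in the 10–20 µM window) ⇒ binding; a converged fit
   with sRatio < 1.5 ⇒ collision; otherwise indeterminate. At 500 ROIs per
   condition this rule separates saturating (K_d ≤ 20 µM) from linear
   conditions essentially without error.
6. **% Resistance.** Both fitted curves (without/with inhibitor) are
   evaluated at A* = 2 × 2 µM (acceptor:donor ratio two at the 2 µM donor
   reference, the midpoint of the analysis window);
   % Resistance = 100 · Δω_drug(A*)/Δω_control(A*), clipped to [0, 100].
   Invariant to common rescaling of the binding signal.

### Known bias of the apparent K_d

Δω is slightly concave in the bound fraction (the phasor angle is not
linear along the chord, and photon weighting favors the longer-lived free
species), so fitting the Hill form to Δω overestimates the true K_d by
~10–15% under the default lifetime pair — part of what makes the recovered
constant "apparent". End-to-end recovery on synthetic scenes stays within
the 20% acceptance band at every anchor (2–40 µM); converting Δω to bound
fraction via the full chord geometry would remove the bias but would depart
from the established analysis.

## The synthetic-data generator

The generator defines the study conditions; its defaults are not tuned per
experiment.

- **Populations**: donor ~ lognormal(median 2 µM, σ_log 0.4) so ~80% of
  cells fall in the 1–3 µM window; acceptor ~ lognormal(median 10 µM,
  σ_log 1.0) truncated at 50 µM by resampling, leaving ~9% of cells in the
  30–50 µM saturation window. Complex concentration from exact 1:1 mass
  action, C = 2DA/(b + √(b² − 4DA)) with b = D + A + K_d (numerically
  stable form; matches a bisection oracle to 10⁻⁹ µM).
- **Decays**: amplitude mixture f·e^(−t/τ_bound) + (1−f)·e^(−t/τ_free),
  exact per-bin integrals, Poisson counts. ~5×10⁴ photons per typical ROI
  (donor gain 100 photons/µM/pixel, cell areas ~150–300 px).
- **Scenes**: 256×256 px, ellipse cells (radius 7–10 px) with nuclei,
  non-overlapping placement with bounded retries; the time-summed TCSPC
  stack *is* the donor channel (photon bookkeeping exact). ER-like
  landmarks are thin ridge bands of a smoothed noise field; mitochondria-
  like landmarks are scattered puncta.
- **Instrument**: no IRF broadening is simulated; instead a synthetic
  instrument offset (modulation 0.9, phase 0.2 rad) is injected into every
  measured phasor and removed by fluorescein calibration, so the
  calibration path is exercised on every pipeline run.
- **Plate fixtures**: %FRET series (back, F_D, F_DA) with Gaussian read
  noise around a programmed one-phase displacement curve; SMAC-release
  supernatant/pellet pairs around programmed release fractions.

What passing on synthetic data does *not* show: robustness to real
instrument response functions, detector afterpulsing, autofluorescence,
segmentation of touching or irregular cells, chromatic misregistration, or
expression distributions unlike the lognormal model. The generator is a
physics-faithful idealization, not a microscope.

## Problem sizes and determinism

End-to-end recovery runs use 900 cells (~700 retained ROIs) per seed and
3–5 seeds per condition — enough that the median recovery error is
dominated by the method's own bias rather than sampling noise, while one
condition completes in seconds on a single core. All generators take
explicit seeds; every stage is bit-reproducible given its seed, and
configurations round-trip through YAML with a stable content hash.

## Open choices made here

- Δω definition fixed as the fractional phase-angle decrease (see above).
- Watershed marker scheme (LoG local maxima) and raster-order tie-breaking:
  the published description names the algorithm but not these details.
- Erosion applied after the size filter.
- Doses are treated as µM throughout (one source text says "2.5 mM" where
  the figures say 2.5 µM).
- Heatmap cells average replicate K_d's (a pooled-fit mode is available
  through `analyze_binding` on concatenated ROI tables).
- Population (n) standard deviation in the expression-positivity threshold.
- Background for colocalization: mode of non-cell pixels, overridable.
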