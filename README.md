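# qflim

Quantitative FLIM-FRET (qF³) binding analysis in live cells: from TCSPC
photon-count images to apparent dissociation constants, binding-vs-collision
classification, and resistance of protein complexes to competitive
inhibitors.

## Who this is for

Labs measuring protein–protein interactions by donor-lifetime FRET — for
example, BH3-only proteins (PUMA, BIM, tBID) binding to anti-apoptotic
BCL-2 family proteins, and their displacement by BH3-mimetic drugs. The
package also implements the companion plate-reader computations (in-vitro
%FRET with unlabeled-acceptor controls, one-phase displacement curves,
SMAC-mCherry mitochondrial-release assays) and per-cell colocalization /
cell-death scoring.

## The method

Per pulsed-laser repetition period T, a TCSPC decay maps to phasor
coordinates

    g = Σ cᵢ cos(ω tᵢ)/Σ cᵢ,  s = Σ cᵢ sin(ω tᵢ)/Σ cᵢ,  ω = 2π/T

Binding quenches the donor lifetime (3.8 ns free → ~2.4 ns in the FRET
complex), rotating the phasor. The binding statistic is the fractional
phase-angle change relative to a donor-only reference,
Δω = (φ_donor − φ_sample)/φ_donor, which grows monotonically with the bound
donor fraction.

Regions of interest come from watershed segmentation of the TCSPC intensity
channel (or from an organelle-landmark mask); ROI intensities are converted
to concentrations through standard curves; ROIs with 1–3 µM donor and
0–50 µM acceptor are binned along free acceptor and fit to a 1:1 Hill curve

    Δω(A_free) = B_max · A_free / (K_d + A_free)

yielding the apparent dissociation constant. Saturating binding is
distinguished from diffusive collisions by the sRatio (residual ratio of the
best origin line to the Hill fit, threshold 1.5). Resistance of a complex to
a competitive inhibitor is the ratio of fitted binding signal with/without
drug at an acceptor:donor ratio of two:
% Resistance = 100 · Δω_drug(A*)/Δω_control(A*) at A* = 4 µM.

A first-class synthetic-data module generates everything the pipeline
consumes — equilibrium cell populations (exact 1:1 mass action), rendered
multi-channel scenes with per-pixel Poisson TCSPC stacks, plate tables —
with full ground truth, so the entire chain is validated by parameter
recovery. See `docs/methods.md` for models, defaults, and limitations.

## Worked example

Simulate a population at a known K_d of 6 µM, image it, and recover the
constant end-to-end:

```python
from qflim import io as qio
from qflim.pipeline import run_binding_experiment

cfg = qio.RunConfig(kd_true=6.0, seed=1, n_cells=300)
fit, rois = run_binding_experiment(cfg, n_boot=200)
print(f"retained ROIs : {len(rois)}")
print(f"apparent Kd   : {fit.kd_apparent:.2f} uM "
      f"(90% CI {fit.ci90_kd[0]:.2f}-{fit.ci90_kd[1]:.2f})")
print(f"Bmax          : {fit.bmax:.3f}")
print(f"sRatio        : {fit.sratio:.1f}")
print(f"classification: {fit.classification}")
```

prints

    retained ROIs : 234
    apparent Kd   : 6.67 uM (90% CI 6.14-7.35)
    Bmax          : 0.190
    sRatio        : 813.0
    classification: binding

234 of 300 simulated cells survive segmentation and the 1–3 µM donor
window. The apparent K_d of 6.67 µM sits ~11% above the generating value —
the expected apparent-K_d bias of fitting the Hill form directly to Δω
(see `docs/methods.md`) — and the enormous sRatio says the curve is far
better described by saturation than by a straight line, i.e. genuine
binding rather than collisions.

The same stages are exposed on the command line (`qflim --help`):
`simulate`, `segment`, `phasor`, `bind`, `resist`, `plate`, `coloc`,
`death`, and `run` for a full configured pipeline.

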