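# Methods

## Sensor model

The probe is treated as a two-state system: free sensor S (fluorescent
in the SiR channel) and the GSH adduct SG (dark), with mass action
S + G ⇌ SG. At equilibrium the bound fraction is the Langmuir isotherm
f = g/(K_d + g). The FP reference channel is independent of GSH, so the
expected intensities per expression unit E are

    I_FP  = E · b_FP
    I_SiR = E · b_SiR0 / (1 + g/K_d)

and the ratio R = I_FP/I_SiR = R_0·(1 + g/K_d) with R_0 = b_FP/b_SiR0.
This affine response is the reason a straight-line calibration is valid
across the physiological window; it is enforced internally (the
brightness quotient must equal R_0, and k_off/k_on must equal K_d when
rates are set).

No apparent K_d for the sensor is published; the package default,
K_d = 10 mM, centres the dynamic range on the 1–20 mM window over which
the ratiometric response is linear and physiological concentrations
fall. It is an explicit assumption, settable on `SensorParams`. The
default rates k_on = 0.01 mM⁻¹s⁻¹ and k_off = 0.1 s⁻¹ are likewise
assumptions consistent with K_d = 10 mM and with equilibration on the
minutes timescale of a plate-reader loop.

Kinetics use the pseudo-first-order approximation
k_obs = k_on·g + k_off, valid because the sensor (~15 µM in vitro) is
three orders of magnitude below GSH (≥ 1 mM). The full second-order ODE
is integrated only as an independent oracle in the tests, where the two
agree to well under 0.5% for g ≥ 1 mM. The g = 0 limit, k_obs = k_off,
is the regime after free GSH is scavenged with N-ethylmaleimide.

### Glutathione-pool arithmetic

A total pool T in GSH equivalents with molar GSH:GSSG ratio r implies
[GSH] = T·r/(r + q), with q = 2 equivalents per GSSG (the dimer carries
two glutathione units). For T = 19 mM and r = 6 this gives 14.25 mM,
reported as 14.3 at one decimal. Reporting uses half-up rounding
(`round_half_up`), since banker's rounding would print 14.2. A q = 1
molar-count convention is selectable (`gssg_equivalents=1`; it would
give 16.3 mM for the same inputs).

### Titration fitting

`TitrationModel` fits either the raw turn-off curve
F(g) = F₀/(1 + g/K_d) + c or the ratio model R(g) = R₀(1 + g/K_d) by
nonlinear least squares (`scipy.optimize.curve_fit`). Weighting is
relative by default — residuals scaled by the response — because
plate-reader noise is approximately proportional to signal; absolute
weighting is available. Non-convergence and inestimable covariance are
flagged on the results object, never silent; a constant (GSH-
insensitive) series raises before fitting. Monte-Carlo checks in the
tests show < 0.1% mean bias in K_d at 2% multiplicative noise with 12
points (300 replicates).

## Synthetic data generator

The generator emulates fields of view of transfected adherent cells:

- **Geometry** — non-overlapping rotated ellipses, semi-axes uniform in
  8–14 px, placed by rejection sampling (≤ 1000 attempts per cell)
  wholly inside a 16 px border margin. A 2 px exclusion gap separates
  cells so threshold segmentation cannot merge neighbours; under-full
  packing is reported in `GroundTruth.warnings`, never silently.
- **Biology** — one GSH concentration per cell, drawn from a normal
  truncated at 0 (default) or a moment-matched lognormal. Presets carry
  the measured population values per compartment: whole cell
  18.9 ± 9.4 mM, ER 9.2 ± 5.3 mM, mitochondria 4.8 ± 0.7 mM, nucleus
  14.0 ± 6.7 mM. Expression is lognormal (median 1, σ = 0.4),
  reflecting transient-transfection heterogeneity. An optional
  two-compartment mode renders a concentric inner ellipse at a GSH
  offset for nucleus-versus-cytosol demonstrations.
- **Camera** — expected photon images pass through Poisson shot noise,
  then additive Gaussian read noise (σ = 3 photons), then clipping at
  zero — the standard sCMOS model. Real gain/offset are unknown, so
  images are in photon units with a configurable `exposure_scale`. The
  defaults put ~400 photons/px in the SiR channel of a typical cell,
  i.e. shot-noise-limited SNR ≈ 20.
- **Determinism** — one `numpy` Generator seeded from the config;
  identical config + seed gives byte-identical arrays.

Default FOVs are 256×256 px with 15 cells; ten FOVs (~150 cells)
reproduce the scale of one imaging condition while keeping a full
recovery run under a second.

The time-lapse generator keeps one set of cells across frames
(default 49 frames at 0.5 h — a 24 h experiment imaged every 30 min),
moves centroids by a 2 px/frame random walk, and assigns each cell the
piecewise-linear population profile plus a fixed per-cell offset
(σ = 2 mM). The bundled cell-cycle preset rises slightly over the first
1.5 h after release from an S-phase block, declines steadily to 12 h,
then plateaus; the magnitudes of rise and plateau are free parameters
of the preset, not measured claims. Expression may drift linearly to
emulate ongoing labelling of newly synthesised protein.

What the generator does **not** model: realistic organelle morphology,
point-spread blur (optional Gaussian blur exists but is off by default
so per-pixel identities stay exact), photobleaching, chromatic
registration error, or cell division geometry. Passing recovery tests
therefore demonstrates correctness of the analysis chain under the
stated noise model, not robustness to every artefact of real
microscopy.

## Image pipeline

- **Background** — scalar per channel: the mean over all blank-FOV
  pixels excluding an edge margin (default 16 px; standard practice
  fixes only that edges are excluded, so the width is a package
  choice), averaged across blanks. Manual
  cell-free ROIs can be supplied as blanks equivalently. Subtraction
  clips negatives to zero and counts them.
- **Segmentation** — threshold on the background-subtracted FP channel.
  The Otsu threshold is computed on log1p intensities: cell brightness
  spans an order of magnitude (lognormal expression), and on the raw
  scale Otsu places the cut inside the foreground spread, losing dim
  cells; on the log scale background/foreground are cleanly bimodal. A
  fixed threshold is available. Components under `min_area_px` or
  touching the border-margin frame are dropped (partial cells);
  surviving labels are renumbered in raster order of first pixel.
- **Ratio** — FP divided by SiR pixel-by-pixel inside ROIs only
  (reference over sensor, so the value rises with GSH); pixels with
  SiR ≤ eps (default 1 photon) are excluded and counted. Per-cell means
  use all valid pixels of a label; cells with under half their pixels
  valid are dropped. FOV means (plate-type calibration imaging) average
  defined pixels in the interior, one data point per FOV.
- **Calibration** — ordinary least squares of ratio on concentration
  restricted to standards inside the validity range (default 1–20 mM),
  via `scipy.stats.linregress`; a non-positive slope is flagged as a
  failed/inverted sensor. Inversion g = (R − intercept)/slope handles
  out-of-range values by policy: `flag` (default; report as-is with the
  `extrapolated` flag, matching interpolate/extrapolate practice),
  `clip`, or `drop`. Curves carry their pH; no pH correction is
  modelled — curves at different pH are distinct objects.
- **Outliers** — proprietary robust-regression screens are replaced by
  a median/MAD rule: flag |x − median| > k·1.4826·MAD with k = 3.5,
  chosen to flag ~1% of clean normal data. If MAD = 0 on non-constant
  data the screen falls back to a 1.5·IQR fence and records that.
- **Despeckle** — 3×3 median with edge replication, exposed only on the
  image-export path (`traqg quantify --despeckle`); statistics are
  always computed on raw ratios.

All image operations are validated against naive loop-based reference
implementations on random small images, and the end-to-end chain
against simulator ground truth (population mean within 5%, per-cell
RMSE < 1.5 mM on the nucleus preset at SNR ≈ 20).

## Tracking

Greedy mutually-nearest centroid linking per adjacent frame pair with a
displacement gate (default 15 px per 30-min frame), ties broken by
smaller label id, which makes the result independent of detection
order. Unmatched detections open new tracks; a track unmatched for more
than `gap_frames` (default 1) closes as lost. When new detections
appear within the gate of a just-vanished track they are annotated with
its `parent_id` — a deliberately simple, auditable division heuristic;
no mitosis classification or appearance model is attempted. Population
summaries report per-frame mean, SD and n across live tracks; frames
with no live track are marked gaps, never interpolated.

## Numerical notes

- Coordinates are row-major, 0-based, pixel-centred.
- All randomness flows through explicitly seeded `numpy` Generators.
- `curve_fit` initial guesses: K_d at the median positive
  concentration, amplitude at the response span; failures are returned
  as flagged results with the guess and infinite SEs.
- Equality tolerances in tests distinguish exact identities (bitwise or
  1e−12) from statistical recoveries (3·SE bands or stated percentage
  bounds at fixed seeds).
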