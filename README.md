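# traqg

Ratiometric quantification of glutathione (GSH) from two-channel
fluorescence microscopy with the TRaQ-G chemogenetic sensor.

GSH is the main intracellular redox buffer, present at millimolar
concentrations that differ between organelles and fluctuate with the
cell cycle. TRaQ-G measures it in a chosen compartment: a spirocyclic
silicon-rhodamine (SiR) ligand becomes fluorescent — and GSH-reactive —
only after covalent capture by a HaloTag protein fused to a
GSH-insensitive fluorescent protein (FP, e.g. mGold). GSH reversibly
attacks the SiR chromophore and quenches it, so the per-pixel ratio

    R = I_FP / I_SiR

cancels expression level and optical path and increases with GSH. With
apparent dissociation constant K_d, the two-state equilibrium gives a
SiR signal proportional to 1/(1 + g/K_d) and hence an exactly affine
readout

    R(g) = R_0 · (1 + g / K_d),

which justifies a linear calibration curve over the physiological
1–20 mM window and its inversion g = (R − intercept)/slope. Relaxation
to equilibrium is pseudo-first-order, k_obs = k_on·g + k_off, because
the sensor (~15 µM) is vastly outnumbered by GSH.

The package provides:

- `traqg.sensor` — the forward model: binding isotherm, ratiometric
  response, relaxation kinetics, glutathione-pool arithmetic, and
  nonlinear titration fitting (`TitrationModel.fit()` returns a results
  object with estimates, standard errors and a `summary()`).
- `traqg.simulate` — a synthetic two-channel FOV generator with full
  ground truth (elliptical cells, population GSH distributions per
  compartment preset, lognormal expression, Poisson + Gaussian camera
  noise), blanks, time-lapse sequences and titration tables.
- `traqg.pipeline` — the image analysis chain: blank-based background
  estimation, FP-channel threshold segmentation, pixel-wise ratio maps,
  per-cell / per-FOV means, OLS calibration (`CalibrationModel`),
  inversion to mM GSH, and a median/MAD outlier screen.
- `traqg.tracking` — conservative nearest-centroid linking of per-cell
  measurements into GSH(t) tracks with population summaries.
- `traqg.cli` — `traqg simulate | titrate | calibrate | quantify | track`.

## Worked example

```python
import numpy as np
from traqg import (preset_config, generate_fov, generate_blank,
                   estimate_background, subtract_background, segment,
                   ratio_map, per_cell_means, apply_calibration,
                   ratio_response, CalibrationModel, DEFAULT_SENSOR)

# calibration from standards measured with the purified sensor
g = np.arange(1.0, 21.0)
cal = CalibrationModel(g, ratio_response(g, DEFAULT_SENSOR)).fit()
print(cal.summary())

# one synthetic nuclear FOV (truth: 14.0 ± 6.7 mM population)
cfg = preset_config("nucleus", seed=7)
pair, _, truth = generate_fov(cfg)
bg = estimate_background([generate_blank(cfg.replace(n_cells=0, seed=8))])
sub, _ = subtract_background(pair, bg)
labels = segment(sub.fp)
cells = apply_calibration(per_cell_means(ratio_map(sub, labels), labels),
                          cal.curve)
gs = np.array([c.gsh_mM for c in cells])
print(f"{len(cells)} cells, [GSH] = {gs.mean():.1f} ± {gs.std(ddof=1):.1f} mM")
```

prints

```
Ratio-to-GSH calibration (OLS)
==============================================
validity range: 1-20 mM at pH 7.4
n points used:  20
slope:          0.05 +/- 0 per mM
intercept:      0.5 +/- 0
R^2:            1.000000
15 cells, [GSH] = 11.7 ± 5.8 mM
```

The calibration slope is R_0/K_d = 0.5/10 = 0.05 per mM and the
intercept is R_0 = 0.5, exactly as the forward model dictates. The
recovered single-FOV population (11.7 ± 5.8 mM) matches this FOV's true
sampled population (11.6 ± 5.8 mM); one 15-cell draw from a 14.0 ±
6.7 mM population routinely lands a few mM off the population mean.

The same chain from the shell:

```sh
traqg simulate --preset nucleus --n-fov 3 --seed 7 --out sim/
traqg calibrate --csv standards.csv --out curve.json
traqg quantify --images sim/fov_000.tif --blanks sim/blank_000.tif \
               --calibration curve.json --out quant/
```

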