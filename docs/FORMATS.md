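# File formats

## Images (TIFF)

- **FOV stacks** — 2-plane float32 TIFF, channel order FP (reference)
  first, SiR (sensor) second. Channel order is a convention, not
  metadata; every reader takes `--channel-order {fp-first,sir-first}`.
- **Label maps** — single-plane 16-bit TIFF; 0 = background, positive
  integers = cell ids (not necessarily contiguous after filtering).
- **Ratio images** — single-plane 32-bit float TIFF; NaN marks
  undefined pixels (outside ROIs or failing the divide guard). When a
  calibration is applied the pixel values are mM GSH.

## Tables (CSV, header required, LF or CRLF)

- **Titration** — `conc_mM,response,sd`; concentrations strictly
  ascending, `sd` optional per-point replicate SD.
- **Calibration standards** — `conc_mM,ratio`, one FOV mean per row.
- **Per-cell measurements** —
  `fov,label,area_px,row,col,mean_ratio,gsh_mM,extrapolated,outlier,n_valid_px`;
  `gsh_mM` and `extrapolated` are absent in uncalibrated runs.
- **Ground truth** (simulator) —
  `label,row,col,semi_a,semi_b,theta_rad,gsh_mM,expression,true_ratio`
  (+ `gsh_nuc_mM` in two-compartment mode).
- **Tracks** —
  `track_id,parent_id,frame,time_h,label,row,col,mean_ratio,gsh_mM`
  (`parent_id` 0 = no parent).
- **Track summary** — `time_h,mean,sd,n` per frame.

## JSON

- **Calibration curve** — `slope`, `intercept`, `range_mM` ([lo, hi]),
  `r_squared`, `ph`, plus a `units` block.
- **Sensor parameters** — the `SensorParams` fields plus `units`.
- **Run manifest** — written by every CLI stage: `stage`,
  `schema_version`, `software_version`, `seed`, `config`,
  `config_hash` (sha256 prefix of the canonicalised config),
  `outputs` (relative paths), `counts` (cells found, pixels clipped,
  pixels excluded). Re-running a deterministic stage with the
  manifest's config and seed reproduces its outputs byte-identically.

## YAML

- **Quantify config** — optional file for `traqg quantify --config`;
  keys `min_area, border, policy, eps, min_valid_fraction,
  channel_order`. Unknown keys are rejected.
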