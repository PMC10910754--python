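# ngrscreen

Quantification pipeline for imaging-based drug screens that use the
normalized growth rate (NGR) readout: per-well viability and growth,
control-anchored NGR normalization, sigmoidal growth-rate (GR) dose–response
fitting with a single outlier refit, NGR50 and normalized area-over-curve
(AOC) sensitivity metrics, signed AOC fold changes, and replicate-level
two-way ANOVA with Dunnett-style contrasts against a reference (wild-type)
cell line. A seeded synthetic 384-well plate generator makes the whole
analysis runnable with no external data.

## Method summary

* **Viability** per well: `V = max(0, total_brightfield_area - dead_area)`.
* **Growth**: `G = (V(t) - V(0)) / V(0)`.
* **NGR**: `G_drug / median(G_vehicle)` for growing wells,
  `-(G_drug / median(G_positive))` for shrinking wells, clipped to
  `[-1, 1]`. Anchors: vehicle-like growth → +1, complete growth inhibition
  → 0, killing like the staurosporine control → −1.

  Note on the negative branch: the formula as commonly typeset
  (`NGR = G_drug / G_medPos`) would map complete killing to **+1**,
  contradicting the stated classification (−1 = complete killing). This
  package applies the sign-corrected form `-(G_drug / G_medPos)` so the
  classification and the anchor identities hold; the discrepancy is treated
  as a typesetting loss of a minus sign and is not hidden.
* **Dose–response model**: `GR(c) = GRinf + (1 - GRinf) / (1 + (c/GEC50)^h)`,
  fitted per cell line × drug × replicate by nonlinear least squares
  (initial guesses 0.1 / median dose / 2; bounds GRinf ∈ [−1,1],
  GEC50 ∈ [c_min/10, c_max·10], h ∈ (0, 10]). After the first fit, points
  with `|residual| > 2.5 × mean(|residual|)` **and** `|residual| > 0.25`
  are flagged as outliers and the model is refitted once on the retained
  points (skipped if fewer than 4 points would remain).
* **NGR50**: closed-form solution of `GR(c) = 0.5`; reported as `> c_max`
  when the curve never reaches 0.5 or the crossing lies beyond the tested
  range.
* **AOC**: `∫ (1 - GR) d(log10 c)` over the tested range, normalized by the
  maximum attainable area `2 × log10(c_max/c_min)`, so AOC ∈ [0, 1]
  (0 = inert, 0.5 = pure cytostasis, 1 = complete killing everywhere).
* **Fold change**: signed ratio convention — `+test/ref` when the test AOC
  is larger, `−ref/test` when smaller, so |value| ≥ 1 and the sign encodes
  direction.
* **Statistics**: two-way ANOVA (cell line × drug, with interaction) on
  replicate AOCs; Dunnett-style contrasts of each line against the
  reference within each drug, family-wise error controlled jointly across
  all contrasts at α = 0.05 via the multivariate-t max-|T| law (seeded
  Monte-Carlo evaluation, 1e5 draws).

## CLI

```
ngrscreen scenarios                                   # list built-in scenarios
ngrscreen simulate --scenario wt_3d_sensitive --seed 1 --out plate.csv
ngrscreen ngr      --in plate.csv --out ngr.csv        # per-well NGR (last timepoint)
ngrscreen fit      --in ngr.csv --out metrics.csv --curve-out curves.csv
ngrscreen compare  --in metrics.csv --reference wildtype --out cmp.json --fold-out fc.csv
ngrscreen report   --in metrics.csv --out report.csv   # AOC mean ± SD table
ngrscreen run      --scenario g2032r_like_resistant --seed 7 --out-dir out/
```

`run` executes all stages and writes a `manifest.json` with the seed,
config hash and per-stage status; identical seeds give byte-identical
outputs.

Input CSVs are long-format, one row per well per timepoint, with columns
`plate_id, well, cell_line, drug, concentration_nM, timepoint_h,
total_area, dead_area, replicate_id`. Control wells are marked by the drug
labels `vehicle` / `positive_control` with concentration 0. A YAML plate
map (`--plate-map`) can supply the annotation columns for bare measurement
files and declares the dose grid.

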