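# wormtrace

Batch processing and visualization of *C. elegans* embryo cell-tracking
data.

The *C. elegans* embryo develops through an invariant, fully mapped cell
lineage. Live 4D confocal imaging of histone-labeled embryos, segmented and
tracked by StarryNite and curated in AceTree, yields per-embryo tables with
one row per (cell, timepoint): the Sulston cell name, the ordinal
timepoint, nuclear position (x, y in pixels; z in image planes) and
optional reporter-expression channels (conventionally a column named
`blot`). `wormtrace` takes it from there — scriptable, reproducible, and
batch-capable — for researchers quantifying lineage-resolved gene
expression or comparing mutant and wild-type embryos.

## What it does

- **I/O** — read/write "CD" comma-separated tables, parse raw StarryNite
  `.zip` archives, read TIME files (ordinal timepoint → elapsed minutes),
  and apply voxel-size metadata to convert pixels/planes to microns.
- **Sulston cell search** — name validation, parent/daughter algebra over
  the founder lineage (P0 → AB, P1 → EMS, P2 → …), ancestry tests, and
  single-letter wildcard patterns: `Cxp` selects {Cap, Cpp}, optionally
  with all observed descendants.
- **Canonical orientation** — embryos are imaged in arbitrary poses. At a
  reference timepoint, PCA over nuclear positions finds the long
  (anterior–posterior) axis; landmark cell groups (defaults: posterior
  `Cxp`, dorsal `Cxaa`, right `MSap`, left `MSpp`) fix its sign and the
  roll about it, producing a rigid transform into the frame
  *anterior → +x, left → +y, dorsal → +z*. Given roll groups that disagree,
  the roll is the circular mean of the per-group solutions, which minimizes
  the summed squared angular deviation for small spreads.
- **Depth correction** — fluorescence attenuates with imaging depth. Across
  replicate embryos the package fits, by least squares on the log scale,

  ```
  log E_ij = a_i − k · z_ij + ε        (shared decay rate k, per-embryo scale a_i)
  ```

  and corrects expression to a reference depth via
  `E_corr = E · exp(k·(z − z_ref))`. A fitted model can be saved and applied
  to embryos imaged under equivalent conditions.
- **Time alignment** — shift each embryo's time axis so a developmental
  event (birth or last observation of a named blastomere) occurs at t = 0,
  making expression directly comparable across embryos.
- **Expression summaries** — per-cell mean expression, and per-timepoint
  mean trajectories over arbitrary lineage selections across many embryos.
- **Figures** — 3D nuclear-position plots (expression-colored, clamped
  color range, pattern highlighting), expression-colored lineage trees
  (time downward, canonical sibling order), trajectory plots; export to
  PNG/SVG/PDF.
- **Synthetic embryos** — a generator with a stereotyped division schedule,
  known orientation, and a programmed expression pattern with known depth
  decay, so every step can be validated against ground truth.

## Worked example

```python
import wormtrace as wt

# simulate three replicate embryos of the same strain
params = wt.SimulationParams()
reps = wt.simulate_replicates(params, 3, seeds=[0, 1, 2])
tables = [t for t, _ in reps]

# learn the depth-decay model across the replicates (before rotation)
model = wt.fit_depth_model(tables, expr_column="blot")
print(f"fitted decay rate k = {model.decay_rate:.4f} /um "
      f"(simulated with k = {params.decay_rate})")

# correct, rotate into the canonical frame, align on the birth of MSap
corrected = [wt.apply_depth_model(t, model) for t in tables]
rotated = [wt.apply_transform(t, wt.fit_orientation(t)) for t in corrected]
aligned, result = wt.align_times(rotated, "MSap", kind="birth")
print("alignment offsets:", result.offsets)

# mean expression trajectory over the MS lineage
traj = wt.lineage_trajectory(aligned, ["MS"], expr_column="blot")
print(traj.head(4).to_string(index=False))
```

prints

```
fitted decay rate k = 0.0359 /um (simulated with k = 0.04)
alignment offsets: {'rep00': -19.0, 'rep01': -19.0, 'rep02': -19.0}
embryo_id condition  time  mean_expression  n_cells
    rep00     rep00 -12.0        17.431761        1
    rep00     rep00 -11.0        19.035398        1
    rep00     rep00 -10.0        16.964755        1
    rep00     rep00  -9.0        20.288338        1
```

The fitted decay rate lands near the simulated 0.04 /µm (the simulated
embryos carry a lineage-restricted reporter, which leaves some residual
confounding — see `docs/methods.md`). All three replicates share the
deterministic division schedule, so the MSap birth offsets coincide, and
the trajectory starts 12 frames before MS itself is born with mean
expression at the depth-attenuated baseline level. The same workflow runs
from the shell:

```
wormtrace simulate --n 3 --seed 0 --output-dir sim/
wormtrace depthfit sim/embryo*.csv --out depth.txt
wormtrace depthapply sim/embryo*.csv --model depth.txt --output-dir dc/
wormtrace rotate dc/*_dc.csv --output-dir rot/
wormtrace align rot/*_rot.csv --event-cell MSap --output-dir aligned/
wormtrace traj aligned/*_aligned.csv --pattern MS --out traj.csv
wormtrace tree aligned/embryo00_dc_rot_aligned.csv --root MS --out tree.svg
```

Batch runs continue past corrupt inputs, report per-file diagnostics, and
exit nonzero on partial failure. A YAML/JSON `--config` file can supply any
flag.

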