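# Methods

This note documents the models and procedures implemented in `wormtrace`,
the assumptions they make, the defaults and why, and what the synthetic
test-bed does and does not establish about real data.

## Data model

An `EmbryoTable` is a long-format record set: one row per (cell,
timepoint) with position, optional expression channels, and per-embryo
identity. Two flags track provenance: `units` (`pixel`: x/y in pixels, z in
image planes — the native StarryNite frame — vs `micron`) and `time_units`
(`ordinal` 1-based frame index, `minutes` elapsed time, or `aligned` signed
axis after event alignment). Conversions are explicit and non-idempotent by
design: `apply_metadata` refuses already-micron tables rather than silently
re-scaling, because a double-scaled table is a silent catastrophe downstream.
Missing expression is stored as missing (NaN), never as zero — zero is a
legitimate measurement.

Coordinates are treated as continuous point coordinates as given; no
0/1-based pixel-index adjustment is applied. z is kept in plane units in CD
files and converted to microns only through the voxel metadata.

### File dialects

- **CD**: comma-separated, header line, required columns `cell, time, x, y,
  z` matched case-insensitively with whitespace stripped (files originate
  from several legacy exporters); every other column is an expression
  channel unless named `diameter`/`ordinal`. Rows with unparseable numeric
  fields abort the read with line-number diagnostics. Writers emit ≥ 10
  significant digits and UNIX line endings; the round trip is exact to well
  below 1e-6. Because the format carries no time flag, the reader infers one
  on re-read: positive integer times with no `ordinal` column are ordinal
  frame indices; otherwise the axis is a converted one (`aligned` when any
  time ≤ 0, else `minutes`), which lets pipeline outputs flow back in
  without extra arguments.
- **StarryNite zip**: one nuclei text file per timepoint; the supported
  record layout is comma-separated `index, valid, predecessor, successor1,
  successor2, x, y, z, diameter, identity, expression`, with the timepoint
  taken from the last digit run in the member name (`t042-nuclei` → 42).
  Only valid-flagged nuclei produce rows. Other layouts are rejected with
  file+line diagnostics rather than guessed at; the dialect should be
  confirmed against a given archive source before batch use.
- **TIME**: two columns (ordinal, elapsed minutes), comma- or
  whitespace-separated; a single header line is auto-detected by its first
  field failing to parse as a number. Elapsed times must be strictly
  increasing.

## Sulston name algebra

Names parse as the longest founder prefix from {P0, P1, P2, P3, P4, AB,
EMS, MS, E, C, D, Z2, Z3} followed by division letters `a/p/l/r/d/v`
("EMS" is the founder EMS, never E + "ms"). Anything else is a literal
label: retained in tables and figures, excluded from algebra, with queries
returning a distinct `UNKNOWN` sentinel rather than raising, so stray
labels ("polar body", "Nuc123") cannot crash a batch run.

Parentage is suffix stripping plus the fixed founder table (AB,P1 → P0;
EMS,P2 → P1; MS,E → EMS; C,P3 → P2; D,P4 → P3; Z2,Z3 → P4). Daughters of a
suffixed name without observational context are the six nomenclaturally
possible extensions (explicitly flagged as *potential* — real divisions
produce one letter pair); with an observed-name set, only observed
daughters are returned. The wildcard `x` matches exactly one division
letter — `Cxp`, `Cxaa` — keeping expansions finite; variable-depth
wildcards are deliberately not supported (selection of whole sublineages is
instead the `include_descendants` flag, which takes observed descendants of
each match).

Canonical display order is a<p, l<r, d<v, with founder pairs ordered as in
the parent table. This is convention, not biology.

## Rigid-body orientation

At a reference timepoint (default: the last), PCA over all nuclear
positions gives the long axis; the anatomical identity of its ends comes
from landmark groups. The axis convention — anterior → +x, left → +y,
dorsal → +z, a right-handed frame — is stated prominently because every
downstream figure depends on it.

Procedure: center on the centroid of *all* cells at the reference time
(not only landmarks); rotate the first principal axis onto x̂ with its sign
chosen so the anterior (or minus the posterior) landmark centroid projects
positively; then roll about x. Each provided roll group (dorsal, ventral,
left, right) independently determines the roll angle that would place its
centroid direction, in the post-AP-rotation y–z plane, on its target
half-axis (ventral and right are the dorsal/left targets rotated by π). The
final roll is the **circular mean** of the candidates. For candidate
spreads below ~30° this agrees with the minimizer of the summed squared
angular deviation to within 0.01 rad (checked against a 0.001-rad grid
search); with a single roll group the placement is exact. When both DV and
LR groups are supplied they are genuinely linked constraints, so neither
lands perfectly — the compromise is the circular mean, and this choice is
an approximation wherever the original acquisition protocol implies a
different weighting.

Default landmark groups are posterior `Cxp`, dorsal `Cxaa`, right `MSap`,
left `MSpp`; all are overridable, and landmark resolution includes observed
descendants so a reference time after those cells divide still works.
Landmark centroids are unweighted means at the reference time only (no
temporal pooling). Degenerate cases error loudly: fewer than 4 cells, two
leading principal variances equal within 1e-6 relative ("ambiguous long
axis"), an empty landmark group (named), or a roll group lying on the AP
axis.

The transform (centering translation + proper rotation, det = +1 within
1e-9) applies to the reference timepoint only or to all timepoints;
application preserves pairwise distances to 1e-9 and is exactly invertible.
Transforms serialize to a small text file for reuse. Mirror-image
(chirality) correction and non-rigid registration are out of scope.

## Depth correction

Model: `log E_ij = a_i − k·z_ij + ε`, a single decay rate `k` (per micron)
shared across replicate embryos with one intercept per embryo absorbing
brightness differences, fitted by ordinary least squares over all rows with
positive expression (log undefined otherwise; such rows are still corrected
at apply time, where the multiplicative factor is defined for any value).
Pointwise fitting, no z-binning, no robust loss — the simplest model
consistent with the attenuation being exponential. Fitting requires micron
units, at least 10 usable points, and a nonzero depth range; it must run on
tables *before* rotation to a common frame, since z must remain optical
depth.

Correction: `E_corr = E · exp(k·(z − z_ref))`, raw values preserved under a
`_raw` suffix. Default `z_ref` = 0 µm (top of stack), so for k > 0 the
correction only boosts, keeping corrected values comparable to shallow-cell
raw values. Only `k` and `z_ref` are used at apply time — per-embryo
intercepts cannot exist for unseen embryos — which is what makes a saved
model transferable to embryos imaged under equivalent conditions. The model
file is a small canonical key–value text format (version line, 17
significant digits, sorted embryo ids) so save→load→save is byte-identical.

**Assumption that matters in practice**: the fitted channel should be
(approximately) uniformly expressed across cells within each embryo — a
ubiquitous nuclear marker. If expression is lineage-restricted, the
biological signal correlates with depth within each embryo and biases the
slope; with few replicates in random poses this inflates cohort-to-cohort
spread (observed at the ~10% level on 5 synthetic replicates carrying the
default lineage-restricted program, versus ~1% with a uniform reporter at
the same noise). Spatially varying (x,y-dependent) attenuation,
photobleaching over time, and background subtraction are out of scope.

## Time alignment

Events are name-appearance based: *birth* is the first frame at which the
exact name is observed, *last-seen* the last — only names and times are
guaranteed by the data model, so no division-geometry inference is
attempted. Alignment subtracts the event time per embryo, so the event sits
at t = 0 (not the cohort mean — a deliberate choice keeping single-embryo
and batch behavior identical); earlier times become negative, ordinal
indices are preserved in an `ordinal` column, and within-embryo time
differences are untouched. Aligning twice is a no-op. Mixed time flags
across a cohort are an error, not a silent coercion. Rate renormalization
(time warping) between embryos is out of scope.

## Expression summaries

Arithmetic means throughout: per-cell over the timepoints where a value
exists, and per-timepoint over the selected cells present at that
timepoint. Timepoints with no contributing cell are omitted — no
interpolation, so plots show gaps rather than invented data. Trajectories
are emitted per embryo with a condition label; aggregation across
replicates is left to plotting so both overlay and summary displays remain
possible. A heuristic warns when multi-embryo trajectories are computed on
axes that look unaligned (all-positive times with mismatched starts).

## Figures

Lineage trees run with time increasing downward, leaves at uniform x
spacing in canonical sibling order, each parent at the midpoint of its
daughters' x range; each observed (cell, time) row contributes one colored
sub-segment, so the tree is an honest display of the sampling density.
Cells attach to their nearest *observed* ancestor, so tracking gaps do not
break the tree. Branch x-positions encode ordering only. 3D plots draw one
marker per cell at the chosen time, in the table's frame (stated on the
axis labels) with equal aspect; expression colors use a perceptually
uniform sequential colormap with explicit min/max clamping (out-of-range
values render at the end colors, never wrap) and grey for missing values.
Export is PNG/SVG/PDF via matplotlib; SVG output is genuinely vector.

## Synthetic embryos

The generator exists so that every pipeline stage can be tested against
known ground truth without external data. It emulates: a deterministic
division schedule over Sulston names (stereotyped times to a ~40-cell
final stage by default; depths and timings are configurable fixture
constants, not biological claims); placement inside a 25×15×15 µm
ellipsoid where each daughter is displaced along the axis its division
letter implies, keeping the default landmark groups geometrically
meaningful; Gaussian position jitter (default 0.3 µm) at birth; an
arbitrary acquisition pose (uniform random rotation + translation, stack
lifted so the shallowest nucleus sits at 2 µm); and a reporter program
(default: MS lineage at level 300 from frame 13, baseline 20) attenuated by
`exp(−k·z)` in the acquired frame (default k = 0.04 /µm) with multiplicative
lognormal noise (default σ = 0.1).

The stored canonical table is produced by one orientation fit+apply at
generation time, making it an exact fixed point of the fit; because the fit
is equivariant under rigid motions, fitting the acquired table and applying
the result recovers the canonical table to machine precision. This is what
the orientation-recovery checks measure.

What passing these tests does **not** show: real embryos have cell
movement, division-axis variability, segmentation errors, uneven
illumination and non-exponential attenuation tails; none are emulated. The
synthetic results validate the algebra and numerics of the pipeline, not
the biology of any particular dataset.

## Numerical choices and problem sizes

Rotation matrices are validated orthogonal/proper to 1e-9; PCA degeneracy
threshold 1e-6 relative on the two leading variances; roll comparison grid
0.001 rad; CD floats written with 10 significant digits (round-trip
tolerance 1e-6); model/transform files with 17 (exact float round trip).
Tie-breaks: eigen-sign ambiguity is resolved by landmarks, sibling order by
the canonical letter order. The validation suite uses 50 embryos for
orientation recovery, 100 configurations for roll averaging, 20 repeats of
a 5-embryo × 200-cell depth simulation, ~10⁴ names for the lineage algebra
(exhaustive to suffix depth 4 through the daughter expansion, sampled to
depth 8), 100 random tables for I/O and alignment properties, and a
depth-10 binary lineage (1024 leaves) for tree-layout invariants — sizes
chosen so the whole suite and the acceptance script each complete in
seconds while still exercising every branch of interest.
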