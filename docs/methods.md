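# Methods and design notes

This note records what the package computes, the conventions it fixes
where the formats and the literature leave room, and what the synthetic
tests do and do not demonstrate.

## CIF layer

The CIF reader/writer implements the CIF 1.1 data-file subset: `data_`
blocks, `_category.keyword` items, `loop_` tables, `'…'`/`"…"` quoting,
semicolon-delimited multiline text, `#` comments, and the placeholders
`?` (missing) and `.` (inapplicable). Save frames, nested loops and CIF2
bracket values are out of scope — sasCIF *data* files use none of them
(dictionaries do, but this package does not parse dictionaries).

Choices a CIF implementation must make, and the ones taken here:

* **Order.** Blocks, categories, items and rows are kept in insertion
  order through parse → serialize; serialization is a pure function of
  the model, so writing, re-parsing and writing again is byte-stable.
* **Names** are compared case-insensitively, stored and emitted
  lowercase. Block labels keep their case.
* **Placeholders** are modelled as value kinds, not magic strings: a
  text value `?` is written quoted (`'?'`) so it never turns into a
  missing-value marker on a round trip.
* **Quoting** prefers single quotes, falls back to double quotes when
  the value contains a single quote followed by whitespace, and to a
  semicolon block when it contains a newline or both quote styles. A
  value containing both a newline and a line starting with `;` is not
  representable in CIF 1.1 and raises an error rather than being
  silently corrupted.
* **Numbers are text.** The core never reformats numeric values it did
  not create; whatever text was parsed is what is written. Only the
  entry-assembly layer formats numbers (see below).
* A loop whose value count is not an exact multiple of its item count,
  an unterminated quote or semicolon block, an item before any `data_`
  directive, and a category appearing twice in one block are all syntax
  errors carrying the offending line number.

## The sasCIF entry model

The category vocabulary ships as a YAML registry
(`sascifio/data/sascif_categories.yaml`): per category the items, their
value domains (free text, number, enumeration), key items, and
parent–child links (`sas_model_fitting_details.model_id` →
`sas_model.id`). Item names follow the published sasCIF 0.5 outline
where it names them; a few additions the outline mentions but does not
spell (e.g. the deuteration level, the molecular-mass-estimate items)
carry locally chosen names and are marked `provenance: local` in the
registry, so they can be renamed without touching code. Unknown
categories and items are *preserved verbatim* on round trip and produce
validation warnings, never errors — losslessness beats strictness for an
exchange format.

Block structure: `MAIN`, `MAIN2`, … for measurements; `MODEL`/`MODEL2`…
and `FIT`/`FIT2`… for models and fits, with 1-based integer ids linking
fits to models. Fits and models attach to the first MAIN block on
splitting; one fit pairs with one (curve, model) combination. The
momentum-transfer unit is an enumeration (`1/angstrom`, `1/nm`) recorded
per scan; r values in a distance distribution follow the curve's unit
and are not tagged per file.

Validation reports findings rather than raising: enumeration violations,
non-numeric text in number items, missing key items, dangling parent
links, and a non-monotone intensity grid are errors; anything outside
the registry warns.

Numbers written by the assembly/converter layer use `%.6e` for table
values and scalars derived from floats, `%8.3f`/fixed columns for PDB
coordinates, matching instrument precision; values routed verbatim from
file headers or configs keep their original text, which is what makes
header metadata round-trip byte-identically.

## Legacy formats

* `.dat`: header lines are `name : value` pairs (split at the first `:`
  or `=`); the table is two or three numeric columns. Writing always
  emits three columns, with zeros when errors are absent (a flag
  restores genuine two-column output). Unrecognised header names
  survive through a passthrough loop (`sas_scan_metadata`).
* `.out`: the canonical layout written here is a labeled header (Dmax,
  Rg, I(0)), a five-column reciprocal-space block (s, I_exp, σI, I_reg,
  I_ext) whose leading extrapolated rows (s below the first measured
  point, down to s = 0) carry only (s, I_ext), and a three-column p(r)
  block. The reader is deliberately tolerant: parameters are located by
  label search and the tables by column-count runs, not byte offsets, so
  historically formatted files parse as long as their tables are well
  formed. Byte-compatibility with any particular historical layout is a
  non-goal.
* `.fit`/`.fir`: three and four columns respectively (`.fir` carries
  experimental errors). The header is scanned for `Chi^2`/`Chi2`/
  `chi-square` and `p-value` tokens; both statistics are optional. χ² is
  always the *reduced* χ².
* PDB: fixed-column ATOM/HETATM records; only the first model of a
  multi-model file is read; all other record types are ignored.

## Converters

Insertion is block-scoped and conflict-checked: a converter touches only
its target block, refuses to overwrite an existing category under the
default policy, and is idempotent under `replace`. Extraction of a fit
never emits experimental errors from the FIT block — they are stored
once, with the curve — but `cif2fit` can re-attach them for the `.fir`
dialect when the fit grid matches the stored curve grid exactly.

**Re-binning.** Indirect-transform programs may store the regularized
fit with a larger Δs than the measured curve. On extraction the stored
intensities are translated back onto the experimental bins by *linear
interpolation* (`rebin_to_grid`); points outside the stored range are
absent, and the extrapolated section below the first measured point
stays on its stored grid. Linear interpolation was chosen because it is
exact on locally linear data and trivially oracle-testable; it is exact
to machine precision on affine intensities, and on identical grids it is
the identity. Accuracy on oscillating curves is quantified against the
sphere's closed form: with a source grid 2× coarser than the
destination the worst deviation is ≈0.09 % *of I(0)* (0.47 % at 3×).
The deviation is normalized by the curve scale I(0) because a pointwise
relative error is singular near the intensity zeros that any compact
body produces — no interpolation method can bound it there.

`cif2sub` flattens all populated scalar metadata to `name : value`
pairs named `<category-without-sas>_<item>` (`sas_sample.name` →
`sample_name`); structural `id` items are skipped. `collect` accepts
exactly this layout back, so a metadata dump is a valid build
configuration. `cif2all` runs every extractor, isolates per-component
failures in its manifest, and derives file names from the scan title.

## The synthetic generator

The generator emulates one complete measurement of a **homogeneous
sphere**, the one body for which everything has a closed form:
I(s) = I(0)·[3(sin sR − sR·cos sR)/(sR)³]², p(r) ∝ r²(1 − 3r/4R +
r³/16R³) on [0, 2R], Rg = R√(3/5), Dmax = 2R, first intensity zero at
sR ≈ 4.4934. p(r) is normalised with the I(0) = 4π∫p dr convention.

Default conditions: R = 50 Å, I(0) = 1000 (arbitrary units), 200 curve
points on s ∈ [0.01, 0.30] Å⁻¹, 101 p(r) points, 10 extrapolation
points down to s = 0, 200 beads, and Gaussian noise with σ(s) = 1 %·I(s)
(intensities are in arbitrary units, so a Poisson model would add
nothing). The error column stores exactly the σ used to draw the noise,
which is what makes the generated fit's reduced χ² a calibration check:
its expectation is 1 with standard deviation √(2/(N−1)) ≈ 0.1 at
N = 200. A single seed is therefore a coin toss against any tight band
around 1 (the package's default seed, 42, happens to draw 0.78 — a
~1 % tail event of a correct distribution); σ-consistency is checked on
the mean over a fixed ten-seed corpus, whose standard error is ≈0.03.

Bead models are drawn uniformly inside the sphere by rejection
sampling, as `DUM` residues on chain A with unit occupancy, with bead
radius R·N<sup>−1/3</sup>. All randomness flows from one
`numpy.random.Generator` seeded from the truth record, so a seed
determines the file set byte-for-byte.

**Guinier estimator.** `guinier_rg` iterates the classic window
s·Rg ≤ 1.3 to self-consistency but fits ln I against s² to *second*
order, taking Rg from the linear coefficient and I(0) from the
intercept. A plain straight-line fit picks up the curvature of compact
bodies — for the sphere it overestimates Rg by ≈2 % at s·Rg ≤ 1.3 and
still ≈1 % at s·Rg ≤ 0.8 — while the curvature-corrected fit is exact
on Gaussians by construction and recovers the sphere's Rg to 0.14 %
noise-free. With 1 % noise the estimate scatters by roughly ±2 %
(seed-dependent); the window falls back to a line when only three
points remain.

## What the synthetic tests do not show

The generator omits instrumental smearing, concentration effects and
inter-particle structure factors, and its noise is Gaussian and
uncorrelated. Passing round trips therefore demonstrate *format and
pipeline* fidelity and the internal consistency of the physics
helpers — not robustness to the systematics of real beamline data.
Similarly, the `.out` reader is tested against this package's canonical
layout plus label-tolerant variations, not against every historical
file in circulation.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: curves of
40–200 points, 10-entry round-trip corpora, ≤ 200-bead models. Every
quantity reported is recomputed at run time from these inputs; nothing
is hard-coded.
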