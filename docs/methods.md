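# Methods

This document records the models, parameters, and numerical choices made by
`cypsrs`. Defaults are given with units; all coordinates are 1-based and all
intervals are inclusive `(start, end)` in residue coordinates.

## Sequence alignment

Pairwise global protein alignment uses Biopython's `PairwiseAligner` in
global mode with:

- substitution matrix: **BLOSUM62** (default, configurable via
  `AlignmentParams.matrix`);
- gap open penalty: **10.0**, gap extend penalty: **0.5** (a gap run of
  length L costs `open + (L − 1) · extend`);
- end gaps are penalized like internal gaps (true global alignment).

When several alignments are co-optimal, the library's first enumerated
alignment is taken; this is deterministic for fixed inputs, and the test
suite verifies the *score* against an exhaustive brute-force oracle rather
than pinning a particular traceback. Alignments are stored as a column list
of `(position_a | None, position_b | None)` pairs.

## SRS projection

A reference SRS annotation is six ordered, non-overlapping intervals
(SRS1–SRS6). To project onto an aligned query:

- take all alignment columns whose reference position falls in the interval;
- the projected interval is the min/max of the query positions present in
  those columns. Boundary columns that are gaps on the query side therefore
  **shrink the interval inward** rather than guessing an extension;
- an interval whose columns are all query-side gaps projects to `None`.

Multi-reference consensus projection intersects the per-reference projected
intervals region by region; an empty intersection yields `None` for that
region.

## Identity profiles

For a region (on either sequence), an alignment column belongs to the region
if *either* side's position lies in that side's interval. Identity is
`100 · matches / columns` over those columns, with gap columns counted as
mismatches. `full_length` identity uses every alignment column, including
end gaps. An empty region scores 0.0. Identity is computed on a canonical
(sorted-pair) alignment so the matrix is exactly symmetric. Reports round to
whole percent; the JSON report keeps unrounded values.

## ExxR motif

`find_exxr` scans for `E..R` with the glutamate required to *start* inside
the given window; the arginine may extend up to three residues past the
window end. The first match is returned. SRS5 hotspots are anchored at fixed
offsets downstream of the motif glutamate: **E+5** and **E+9** (configurable
`offsets`). Hotspot candidates use the placeholder residue `X` unless a
replacement panel is supplied.

## Variant grammar

- Substitution: `([A-Z])(\d+)([A-Z])` — e.g. `A99I` (ref, 1-based position,
  new residue).
- Segment swap: `(\d+)([A-Z]*)::([A-Z]*)` — e.g. `473DDP::EL` replaces the
  3-residue segment starting at 473 with `EL` (net length −1). The removed
  segment may not be empty.
- Multiple edits are space-separated (`S235G Y236F`), must not overlap, and
  are stored sorted by position. Application validates the reference
  residues against the sequence and applies edits in reverse positional
  order so earlier coordinates stay valid. The edited record's id gains the
  variant text as a suffix (spaces become underscores).

## Mutation candidate rules

- **hotspot_srs5** — positions E+5 and E+9 relative to the ExxR glutamate;
  offsets that fall past the sequence end are skipped with a warning.
- **reciprocal** — contiguous runs of non-identical aligned SRS columns
  (membership tested on either side's intervals) become candidates. A run
  containing any gap becomes one segment swap (the `473DDP::EL` form); a
  gap-free run becomes one substitution per column, carrying the donor
  residue. Candidates are sorted by (rule, position) and carry provenance
  text naming the donor position.
- **equivalent_position** — maps a position through the alignment to the
  homolog's coordinate (or `None` at a gap).

## Quantification

- **IS normalization** — each (strain, variant, replicate, timepoint_h)
  group must contain exactly one internal-standard row (`compound == "IS"`)
  with positive area; analyte response = area / IS area (dimensionless).
  Violations raise with messages naming the "internal-standard" and
  "non-positive" conditions.
- **relative_yield** — per strain/compound mean, sample SD (ddof = 1), and n
  over replicates.
- **fold_change** — ratio of mean responses; ∞ when the reference is zero,
  NaN for 0/0.
- **standard curves** — `scipy.stats.linregress` of response on
  concentration (mg/L); requires ≥ 2 distinct concentrations and a positive
  slope. Titer = `max(0, (response − intercept) / slope)` mg/L.
- **response routing** — compounds without their own standard are quantified
  on a surrogate curve via a response map; the default map `{"3": "2",
  "7": "2"}` reflects that minor products are read off the main product's
  curve. A mapped compound without a fitted curve raises; an unmapped,
  curve-less compound is skipped with a warning.
- **specificity metrics** — over compounds {1, 2, 3, 7}: total titer (mg/L),
  oxygenated % = 100 · (total − titer₁)/total, content-of-2 % =
  100 · titer₂/total; both are 0 when the total is 0. Reports round
  percentages to integers and titers to 0.1 mg/L.
- **group comparison** — Welch's t-test (`scipy.stats.ttest_ind`,
  `equal_var=False`); the degenerate both-groups-constant case returns
  p = 1 for equal means and p = 0 otherwise. The test suite cross-checks
  p-values against a permutation test.
- **timecourse stagnation** — production has stagnated when the increase
  over the final interval is below `threshold · final_value`
  (default threshold 0.10).

## Synthetic data

### Family simulator

Generates an ancestor of length **500** with SRS intervals
(95,114), (200,209), (235,244), (290,301), (361,372), (470,483) — 78 SRS
residues — and an ExxR motif planted at position **356** (E356 and R359 are
pinned and never mutated). The region between SRS4 and the motif is
generated without glutamate so the planted motif is always the first match
downstream of SRS4. Descendants mutate SRS positions at `srs_sub_prob`
(default **0.15**) and scaffold positions at `non_srs_sub_prob` (default
**0.10**); every planted edit is logged in ancestor coordinates. With
`srs6_indel_prob`, a deletion of `srs6_indel_length` residues (default 1)
is placed in SRS6 and that descendant's annotation shrinks accordingly
(78 → 77 SRS residues for a 1-residue deletion). The simulator is fully
deterministic in `seed` (NumPy `default_rng`).

What it does **not** emulate: realistic phylogenies (descendants are
independent draws from one ancestor), insertion events, transition/
transversion structure, or residue-specific substitution preferences.

### Screen simulator

Peak areas are `titer · response_factor · run_IS · exp(N(0, σ))` with
σ = log(1 + CV); default CV **0.10**, **3** replicates, IS area **10⁶**.
Default planted titers are the bundled reference values for a wild-type and
an `A99I` strain over compounds 1, 2, 3, 7, with response factors
{1: 0.10, 2: 0.09, 3: 0.09, 7: 0.09} (response per mg/L). Calibration
tables cover compounds 1 and 2 at 1–100 mg/L (7 levels), noiseless. The
ground-truth table carries the planted titers and fold changes versus the
reference strain. Not emulated: retention-time drift, co-elution, detector
saturation, or between-day batch effects.

### Reference tables

`reference_tables()` returns four fixed DataFrames: pairwise SRS identity
percentages for six homolog pairs, per-variant fold changes, per-strain
shake-flask titers with specificity percentages, and a product-profile
table. The unprinted compound-7 titer is derived per row as
`max(0, round(total − (titer₁+titer₂+titer₃), 1))`, which reproduces every
printed percentage within one point.

## Numerical conventions

- Percentages round half-to-even to integers in human-readable reports;
  machine-readable JSON keeps full precision.
- Titers report at 0.1 mg/L resolution.
- Negative fitted concentrations clip to 0 mg/L.
- All random processes take explicit integer seeds and use
  `numpy.random.default_rng`.

## Problem sizes exercised

Tests and the acceptance script run on: 500-residue synthetic families (up
to 20 seeds), brute-force alignment verification up to length 8 (the oracle
is exponential), screens of 2 strains × 4 compounds × 3 replicates (100
noisy repetitions for bias estimation), and the 10-strain reference titer
table.
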