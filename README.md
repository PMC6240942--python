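# cypsrs

Substrate-recognition-site (SRS) mapping, mutation design, and GC-MS
quantification for cytochrome P450 enzyme engineering.

## Scientific problem

Plant cytochrome P450s of the same family often share high overall sequence
identity yet produce different oxidation products from the same diterpene
substrate. Product specificity is concentrated in six short substrate
recognition sites, SRS1–SRS6, so a practical route to redirecting an enzyme's
product profile is *semi-rational* engineering: align the enzyme against
homologs with the desired specificity, find the SRS positions where they
differ, and swap in the homolog's residues. The classic anchor for this is
the absolutely conserved ExxR motif of the K-helix, which pins the reading
frame of SRS5 (hotspots sit at fixed offsets E+5 and E+9 downstream of the
motif's glutamate).

`cypsrs` implements that workflow end to end:

1. **srs_mapping** — read protein FASTA and SRS annotation tables, align
   sequences globally (BLOSUM62, affine gaps), project reference SRS
   intervals onto unannotated homologs, compute per-SRS and full-length
   identity profiles, and locate the ExxR motif.
2. **mutation_design** — propose mutation candidates: SRS5 hotspots anchored
   on ExxR, reciprocal swaps at non-identical aligned SRS positions
   (including indel swaps such as `473DDP::EL`), and equivalent-position
   mapping between homologs. Variants use a compact text grammar
   (`A99I`, `S235G Y236F`, `473DDP::EL`) that parses, renders, and applies
   to sequences losslessly.
3. **quantification** — turn GC-MS peak tables into internal-standard-
   normalized relative yields, fold changes, least-squares standard curves,
   absolute titers (mg/L), per-strain specificity metrics (total titer,
   oxygenated fraction, content of the target product), Welch t-tests, and
   timecourse stagnation summaries.
4. **synthetic_data** — ground-truthed simulators for a P450 family (planted
   SRS/scaffold substitutions and SRS6 indels, with an edit log) and a
   quantification screen (planted titers, response factors, lognormal
   multiplicative noise), plus `reference_tables()` holding published-style
   identity/fold-change/titer fixtures used by the tests.
5. **cli_reporting** — a `cypsrs` command-line tool wrapping the above.

## Running the tests

```bash
python -m pytest -q tests/
```

## Worked example

Simulate a small family, map SRS identities, and propose mutations:

```console
$ cypsrs simulate --kind family --seed 7 --out-dir family
wrote synthetic family data to family

$ cypsrs map-srs --sequences family/family.fasta \
    --annotations family/family_srs.tsv --pairs anc:seq1 --out-dir maps
wrote 1 identity profiles to maps

$ cat maps/identity.tsv
pair	SRS1 (%)	SRS2 (%)	SRS3 (%)	SRS4 (%)	SRS5 (%)	SRS6 (%)	Total SRS (%)	Total sequence (%)
anc and seq1	90	100	90	67	67	71	81	89

$ cypsrs propose --sequences family/family.fasta \
    --annotations family/family_srs.tsv --target anc --donor seq1 \
    --out candidates.tsv
wrote 17 candidates to candidates.tsv

$ head -6 candidates.tsv
target_id	rule	variant_text	provenance
anc	hotspot_srs5	W361X	ExxR at 356 + 5
anc	hotspot_srs5	R365X	ExxR at 356 + 9
anc	reciprocal	R97K	seq1 position 97
anc	reciprocal	P99A	seq1 position 99
anc	reciprocal	P235I	seq1 position 235
```

Simulate a screen and quantify it:

```console
$ cypsrs simulate --kind screen --seed 0 --out-dir screen
wrote synthetic screen data to screen

$ cypsrs quantify --peaks screen/peaks.csv \
    --calibration screen/calibration.csv --reference-strain WT \
    --out-dir quant
wrote quantification reports to quant

$ cypsrs report --metrics quant/metrics.tsv
Name  Total mg/L  Oxygenated (%)  1 mg/L  2 mg/L  3 mg/L  7 mg/L  Content of 2 (%)
  WT        43.7              62    16.6    23.1     0.2     3.9                53
A99I        82.7              99     0.9    81.4     0.4     0.0                98
```

A key=value config file can supply defaults for any option
(`cypsrs --config run.conf simulate ...`); explicit flags win. On any error
the CLI exits non-zero and removes partially written outputs.

## Layout

```
src/cypsrs/
  srs_mapping.py       alignment, SRS projection, identity, ExxR motif
  mutation_design.py   variant grammar, candidate rules
  quantification.py    IS normalization, curves, titers, metrics, stats
  synthetic.py         family & screen simulators, reference tables
  cli.py               cypsrs command-line interface
docs/methods.md        model, parameters, and numerical choices
scripts/acceptance.py  headline-quantity reproduction script
tests/                 unit, property, end-to-end, and acceptance tests
```
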