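# svmeta

Ensemble ("meta") calling of structural variants (SVs) from long-read
sequencing call sets: fuzzy call matching, sensitive/stringent call-set
integration, benchmarking against high-confidence truth sets, trio
Mendelian-consistency (allele-drop-in) evaluation, and a caller-behavior
simulator for end-to-end validation.

## The problem

Low-coverage long-read (PacBio-style) sequencing is an attractive,
affordable route to SV discovery, but single SV callers behave very
differently at 2–15X coverage: split-read callers see deletions well,
discordance-based callers see insertions well, clipped-tail callers see
almost no insertions at all. Combining callers helps — if you can decide
when two imprecise calls are *the same event* and how to merge them.
`svmeta` implements that downstream layer, independent of the aligners and
callers themselves.

Two calls are equivalent when:

* **deletions** (and other span events of equal type) have **reciprocal
  overlap ≥ 0.5** — with intervals *A*, *B* and overlap *O*,
  `min(|O|/|A|, |O|/|B|) ≥ 0.5`;
* **insertions** (single-breakpoint events) have breakpoints within
  **δ = 500 bp**; inserted length is ignored.

Matching between two call sets is one-to-one (best score first, greedy),
and a matched pair merges by **averaging start and end positions**. From a
Sniffles-role set `SNIF` and the two complementary PBHoney-role sets
`SPOT` and `TAIL`, the ensemble sets are

```
sensitive  =  SNIF ∪ (SPOT ∪ TAIL)     # maximizes recall
stringent  =  SNIF ∩ (SPOT ∪ TAIL)     # maximizes precision
```

with a generalized *detected-by-≥k-callers* operator for arbitrary
ensembles. Benchmarking against a truth set reports, per SV type (DEL/INS,
≥ 200 bp),

```
precision = TP/(TP+FP)   recall = TP/(TP+FN)   F1 = 2·P·R/(P+R)
```

and the trio evaluator reports the allele-drop-in (ADI) rate: the fraction
of offspring calls matching neither parent — a proxy for the calling error
rate, since de novo SVs are rare.

## Worked example

Simulate a heterozygous truth set (150 deletions + 150 insertions on two
5-Mb chromosomes), emulate three callers at 10X, build the ensemble sets
and benchmark them:

```sh
cat > cfg.yaml <<'YAML'
simulator:
  chrom_sizes: {"1": 5000000, "2": 5000000}
  n_del: 150
  n_ins: 150
  seed: 7
  coverage: 10
YAML

svmeta simulate -c cfg.yaml -o sim
svmeta merge --snif sim/SNIF.bed --spot sim/SPOT.bed --tail sim/TAIL.bed \
             -d bed6sv -o meta
svmeta benchmark --calls meta.stringent.bed --truth sim/truth.bed \
                 -d annovar_bed --truth-dialect bed6sv
```

The merge step logs `sensitive: 320 calls`, `stringent: 271 calls` (of
294/287/70 input calls), and the benchmark prints:

```
svtype  tp   fp  fn  precision  recall    f1
DEL     114  3   13  0.974359   0.897638  0.934426
INS     102  0   11  1.000000   0.902655  0.948837
```

The same command on `meta.sensitive.bed` gives recall 0.984 (DEL) and
1.000 (INS) at lower precision (0.919/0.926) — the sensitive set trades
precision for recall, the stringent set the reverse.

Library use mirrors the CLI: `read_callset` / `read_vcf` load VCF,
BED-style and pre-formatted spot/tail tables into `CallSet` objects;
`match_callsets`, `union_callsets`, `intersect_callsets`,
`build_sensitive`, `build_stringent`, `build_generalized`,
`build_truthset`, `benchmark`, `trio_adi` and the `simulator` module do
the rest. Output region files are 1-based inclusive and directly usable
with ANNOVAR.

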