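# Methods

## Call equivalence and merging

Coordinates are 1-based inclusive internally (VCF convention); BED input
and output converts at the boundary, and the ANNOVAR-style output keeps
1-based inclusive coordinates because ANNOVAR region files are 1-based.

Two deletion calls (or two span calls of any equal type tag — INV, DUP,
...) are the same event when their reciprocal overlap reaches the
threshold: with overlap length `ov = max(0, min(e1,e2) - max(s1,s2) + 1)`,
the score is `min(ov/len1, ov/len2)` and the default threshold is 0.5.
The comparison is `≥` by default; a `strict_overlap` switch changes the
boundary to `>` because the two phrasings ("at least half" vs "more than
half") are both in circulation. Insertions are single-breakpoint events
(`start == end`, inserted length kept separately); two insertion calls are
the same event when their breakpoints are within `ins_delta` = 500 bp.
500 bp is the conventional compromise for low-coverage long-read data
between a 100 bp radius (too strict when breakpoints are imprecise) and a
1000 bp radius (merges distinct events). Inserted length is deliberately
not compared: length estimates at low coverage are unreliable.

Matching two call sets is resolved **one-to-one**: all candidate pairs
satisfying the rule are ranked best-first (descending reciprocal overlap
for span events; ascending breakpoint distance for insertions), ties
broken deterministically by (chrom, start of A, start of B, id of A, id of
B), and accepted greedily. One-to-one matching prevents a single broad
call from absorbing several truth entries and inflating TP counts. The
indexed implementation (interval tree for span events, bisection for
insertion breakpoints) is cross-checked in the tests against an
independent full-enumeration implementation.

Merging a matched pair floor-averages start and end (integer, platform
independent). A merged deletion's length is recomputed from the averaged
coordinates; a merged insertion takes the floor-mean length. Support is
the **max** of the two calls — the callers observed the same reads, so
summing would double-count. Sources (caller labels) are unioned; this is
what the generalized ≥k-caller operator counts.

## Ensemble sets

The three-caller workflow computes `sensitive = SNIF ∪ (SPOT ∪ TAIL)` and
`stringent = SNIF ∩ (SPOT ∪ TAIL)` with exactly this association order:
fuzzy union is not exactly associative, so fixing the order makes results
reproducible. The generalized operator folds the union left-to-right over
any list of call sets and takes as stringent the calls corroborated by at
least `min_callers` (default 2) distinct labels; for three well-separated
call sets the two stringent definitions agree, and the literal two-step
formula is the authoritative one where they could differ. When one caller
is run under several aligners, callers are expected to contribute one call
set each (the user picks the better aligner's set); the operators do not
auto-select.

Truth-set construction follows the two-step retention procedure: filter
each deep-coverage call set to read support ≥ 20, retain an initial
high-quality call iff it matches at least one call in at least one
filtered set, keep the retained call's original coordinates (retention,
not merging), then drop calls under 200 bp.

## Benchmarking and trio evaluation

Benchmarks are computed per SV type for deletions and insertions only;
other types are carried through I/O and set algebra but only counted,
because high-confidence truth sets for them are generally unavailable.
Both sides are filtered to length ≥ 200 bp first (a 200 bp call is kept):
below that size short-read sequencing already detects events reliably and
long-read precision is poor, so the interesting regime starts at 200 bp.
TP/FP/FN come from one-to-one matching, so `tp+fp = #calls` and
`tp+fn = #truth` hold exactly. Zero denominators (empty call or truth
side) report the metric as 0 together with an explicit `*_defined = False`
flag rather than NaN, keeping tables plottable without hiding the
degeneracy; F1 of (0, 0) is 0.

Allele drop-in (ADI) is presence/absence only — no genotypes: an
offspring call is an ADI event iff it matches no father call and no mother
call (the parent checks are independent ORs, and parent matching is
existence-only, not one-to-one). The ADI rate is events / offspring calls,
reported per SV type. Allele drop-out is not computed; without a gold
standard for the parents it is not interpretable.

## Simulator

The generator emulates the *downstream* situation only — call sets, not
reads. A truth set of `n_del` deletions and `n_ins` insertions is placed
uniformly (chromosome chosen proportional to length) with a 2 kb exclusion
gap between any two SV footprints, by rejection sampling with a bounded
retry count (a `CapacityError` is raised when the genome is too crowded).
Lengths are truncated log-normal: deletions median 500 bp, sigma 0.9;
insertions median 400 bp, sigma 0.8; bounds [50, 100000] bp — a heavy
right tail resembling real SV spectra while keeping most events in the
hundreds-of-bp range. Defaults put 150 + 150 SVs on two 5-Mb chromosomes,
a density high enough for stable metrics and small enough to run in
seconds. The exclusion gap (> 2·ins_delta + typical jitter) makes
truth-vs-call matching unambiguous, which is what lets the oracle tests be
exact.

A caller profile emulates detection as a thinned Poisson process: at
fold-coverage `c` with allele fraction `f` (default 0.5, heterozygous) and
per-type bias `b`, the supporting-read count is `X ~ Poisson(c·f·b)` and
the call is emitted iff `X ≥ min_support` (default 2, the sensitive
low-coverage setting; the analytic tail `P(X ≥ m)` is exposed as
`expected_detection` and the emulator is calibrated against it in the
tests). The model's sanity anchor: a caller demanding 10 supporting reads
needs ~20X to see a heterozygous SV (λ = 20·0.5 = 10). Reported
breakpoints get independent rounded-Gaussian jitter (truncated so
positions stay ≥ 1; an inverted deletion span is re-sorted); insertion
lengths are copied from the truth — length error is not modelled. False
positives arrive as `Poisson(fp_rate · genome_Mb · c/10)` calls placed
uniformly, with lengths resampled from the truth length distribution and
type drawn from the truth type mix, **independently across callers** —
the assumption that makes intersection precision-boosting testable. This
is a modelling choice, not a claim about real callers, whose false calls
cluster in repeats and segmental duplications.

The three default profiles are archetypes, not fits: `SNIF` (bias
DEL 1.0 / INS 0.8, jitter SD 10 bp, 0.5 FP/Mb/10X), `SPOT` (0.8 / 1.0,
20 bp, 0.5), `TAIL` (0.27 / 0.001, 30 bp, 0.2) — the last modelling a
clipped-tail detector that sees about a quarter of deletions and
essentially no insertions. The titration runner re-enacts a down-sampling
design (2/4/6/8/10/12/15X, five replicates per coverage) with a fixed
truth set across coverages, mirroring down-sampling of one genome, and
benchmarks every caller plus both ensemble sets per replicate.

What passing simulator-based tests does **not** show about real data: no
alignment artifacts, no repeat-mediated FP clustering (so intersection
gains are idealized), no coverage heterogeneity, no length-estimation
error, no genotypes. The simulator validates the *algebra and accounting*
of the toolkit and the qualitative coverage–recall/precision trade-offs,
not absolute performance numbers of any real caller.

## Randomness and determinism

All stages derive generators from one seed via
`numpy.random.SeedSequence([seed, crc32(stage_tag), ...])`; titration
replicates use per-(coverage, replicate, profile) child seeds reduced
below 2^31. Identical configuration and seed give byte-identical outputs,
including the written TSV/BED files.

## I/O contracts

VCF reading (cyvcf2) takes SVTYPE from INFO; deletion extent prefers
INFO/END over SVLEN when both are present and inconsistent (coordinates
are what matching consumes; a warning is logged and the length is
recomputed). Read support is looked up as INFO/RE, then INFO/SUPPORT, then
FORMAT/DV of the first sample — caller versions disagree on the field —
else 0. Records without SVTYPE, or span records with neither END nor
SVLEN, are skipped with a warning. The `pbhoney_spots`/`pbhoney_tails`
dialects (chrom, start, end, `SVTYPE=...;SIZE=...;SUPPORT=...`) are this
package's documented contract for pre-formatted spot/tail tables; native
outputs of such callers may need a one-line `awk` reshaping into it.
Unknown attribute keys are preserved as opaque extras. Writers are atomic
(temp file + rename), so a failed run never leaves a partial output.

## Known limitations

Breakend (BND) pairing, sequence-resolved insertion merging, genotype
aware Mendelian classification and breakpoint-accuracy statistics are out
of scope. The greedy one-to-one matching is order-deterministic but not
globally optimal (it is not a maximum-weight matching); for the
well-separated events this toolkit targets the two coincide, and the
brute-force cross-check in the tests covers crowded instances.
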