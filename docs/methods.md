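# Methods

## Coordinate conventions

All interval arithmetic is 0-based half-open `[start, end)`, so
`length = end − start` and abutting intervals do not overlap. The
packaged 68-region reference table is ingested verbatim under this
convention: every printed row satisfies `end − start = Length`, so no ±1
adjustment is applied. Chromosome names are canonicalised to the
`chr`-prefixed form; bare names are accepted.

One row of the source table carries more position labels than gene
symbols (an artifact of text extraction); the loader pads the missing
symbol with an empty string so the two lists stay aligned, and the
filtered gene view drops empty entries. Gene symbols are stored exactly
as printed, including `LOC*`/`MIR*` entries, OCR oddities and
parenthesised aliases (`C2orf18(SLC35F6)`); a helper extracts the primary
symbol.

## Coverage model

Fragments with MAPQ ≤ 25 are removed (strictly-greater-than rule);
fragments with no recorded MAPQ are kept, a deliberate permissive choice
for inputs that omit the column. Duplicates — identical (chromosome,
5′ position, strand) — collapse to the first occurrence.

Every fragment is set to exactly 200 bp from its 5′ end: shorter
fragments are extended at the 3′ end, longer ones truncated. This single
"set to length 200" rule avoids a special case for long fragments.
Extended fragments are clipped at position 0 and at the declared
chromosome end.

A bin's value is the number of extended-fragment **bases** it contains
(base mass, not fragment count): this makes conservation exact — total
track mass equals the summed clipped extended lengths — and the tests
verify it against per-base brute force. Whether the upstream vendor
pipeline stores base mass or fragment counts per bin is not documented
anywhere we could check; base mass was chosen for its testability, and
since region quantification normalises to reads-per-million, the choice
does not affect ranks under uniform scaling (also tested). Chromosome
lengths come from a chrom-sizes table when given, else the maximum
extended coordinate rounded up to a bin boundary. Region tag mass
prorates partially overlapped bins linearly (a bin's mass is treated as
uniform within the bin).

## SE calling

Stitching is single-linkage chaining of start-sorted peaks per
chromosome: consecutive peaks join iff `next.start − prev.end <
stitch_distance` (default 12,500 bp; the boundary is exclusive, so a gap
of exactly 12.5 kb separates). Overlapping or abutting peaks always
merge. The implementation is verified against a brute-force
transitive-closure oracle on random instances.

Ranking sorts by reads-per-million tag count descending with a total,
deterministic tie-break: region length descending, then (chromosome,
start) ascending. The super-enhancer count is `max(1, floor(0.05 × N))`
— floor because "top 5 %" is ambiguous at small N and floor is the
conservative reading. No promoter/TSS exclusion is applied and no input
chromatin track is subtracted; neither step is part of the procedure this
package implements.

## Differential calls and intersection

"Gain" is presence/absence by overlap: a treated SE with zero bp of
overlap against every parental SE is gained. The reported quantity in
the source analysis is a discrete count of gained/lost peaks with no
fold-change threshold, so set-difference semantics is the default; a
minimum treated/parental signal ratio is available (`min_fold`) but off.
The overlap threshold is ≥ 1 bp — no reciprocal-overlap fraction is
stated anywhere, and the planted-truth tests show 1 bp suffices at
realistic signal separations.

Cross-line intersection groups the combined gain set by transitive ≥1 bp
overlap (union-find over a sweep); only components with a contributor
from each line are reported, as the union-span hull, with ids assigned
in (chromosome, start) order. The operation is symmetric in its inputs.

## Annotation

Genes within `window` (default 50 kb) of a region are reported. The
window is not stated in the source procedure; 50 kb is the conventional
enhancer-to-target assignment span, and all 68 reference regions are
shorter than 80 kb. A ≥1 bp overlap is `in gene` regardless of window;
otherwise the relation is read region-relative-to-gene and strand-aware:
the region is `upstream` of a gene when it lies entirely on the gene's
TSS side. Because the original gene build and window are unknown,
relation-level agreement with the printed table is checked only for
self-consistency (synthetic gene spans placed per the printed relations
re-annotate correctly), never asserted against the original annotations.

## Prognostic screen

* **Upregulation**: Welch's two-sided t-test on log2 expression, raw
  p < 0.05 and tumor mean > normal mean. No multiple-testing correction
  is applied at this step, matching the stated significance convention
  of the source analysis.
* **Median split**: value > median → high; ties go low (deterministic,
  matches the "high > median" reading). A degenerate split (either arm
  empty) is an error.
* **Survival**: times are administratively censored at 1,825 days before
  testing, matching a 5-year overall-survival horizon (configurable).
  Kaplan–Meier and the 1-df log-rank test are delegated to lifelines;
  a hand-computed hypergeometric instance and a 500-replicate null
  uniformity check pin the behavior.
* **Alteration**: a tumor is altered for a gene iff its Z-score against
  the whole tumor cohort's mean/sd (log2 scale) is ≥ 0. This diverges
  from cBioPortal's diploid-referenced Z-scores, which require
  copy-number calls this package does not model; with a cohort baseline,
  Z ≥ 0 reduces to "above the cohort mean".
* **Mutual exclusivity**: per unordered pair, a 2×2 table of altered
  calls, two-sided Fisher exact p (verified against exhaustive
  hypergeometric enumeration for all tables with n ≤ 20), log2 odds
  ratio with Haldane 0.5 correction when any cell is zero, and BH
  q-values over the pair family. Tendency is co-occurrence iff OR > 1.
* **GSEA**: preranked, implemented in-package. Ranking metric is the
  difference of log2 means between altered-in-any and non-altered
  tumors. The enrichment score is the signed maximum deviation of the
  weighted Kolmogorov–Smirnov walk (hit weight |score|^1, miss weight
  1/(N−n_set)); the null permutes gene labels (equivalently, draws
  random same-size sets) with a seeded generator; nominal p uses the
  (k+1)/(m+1) estimator against same-sign null scores; NES divides by
  the mean |null ES| of matching sign, and FDR compares the observed and
  pooled-null NES distributions, sign-stratified. BH for exclusivity and
  the GSEA FDR are computed within their own families, separately.

## Synthetic data

The generator reproduces the study's design: two cell lines × two
conditions, and a cohort of 300 tumors / 30 normals (mirroring the
~314/30 cohort the screen is modelled on).

Defaults: 2 chromosomes × 5 Mb; 12 planted SEs per treated condition, of
which 5 are gains shared between lines (identical coordinates) and 1 is
line-specific, leaving 6 baseline SEs present in both conditions; 5–8
member windows of 1 kb per SE with gaps drawn from [1,000, 11,000) bp so
12.5-kb stitching always joins them; one negative-control locus per line
with gaps in [13,000, 16,000) bp that must never stitch; 10× fragment
enrichment over background in planted windows; 300 background peak
windows at 3×; exactly 200,000 fragments of 75 bp per line × condition
(single-end read length of the emulated protocol); 2 % of fragments get
MAPQ 10 to exercise the filter.

Background peaks are placed ≥ 13 kb from each other and from planted
loci (an exact-count compressed-coordinate scheme). This keeps the
stitched-region census stable — roughly 318 regions, so the top-5 % cut
(15) always covers the 12 planted SEs, whose tag mass exceeds any
background region's by an order of magnitude — and prevents background
peaks from bridging planted loci. Within a line, background/baseline
fragment realizations are drawn from per-component substreams keyed by
(seed, line, component) and the treated condition converts part of the
background budget into gain-window signal: the enhancer landscape is
stable across conditions, so differential calls reflect planted signal
rather than background resampling noise.

The cohort: per-gene baselines ~ U(3, 8) log2 units with N(0, 0.5)
noise; planted genes (the genes nearest the shared-gain loci) get +1.0
log2 in tumors; tumor survival is exponential with hazard
ln2/2500 days⁻¹ multiplied by 2 per planted gene whose expression is
above its cohort median, with independent uniform censoring on
[200, 3,650] days.

What the generator does **not** emulate: read-level sequence, GC and
mappability bias, copy-number structure, peak-caller noise (peaks are
emitted from truth windows), fractional or correlated gains, and
condition-dependent background drift. Passing recovery tests therefore
demonstrates the pipeline's logic under its stated model — not
robustness to real-data artifacts. One known, accepted artifact of the
design: a few parental background regions reach the top-5 % cut and,
having no treated-SE partner, are reported as "lost"; the truth tables
assert gains only, and lost calls carry no planted truth.

## Problem sizes and runtimes

The test suite exercises: oracle equivalence on 1,000 random ≤100-peak
stitching instances and 1,000 random ≤50+50 intersection instances;
coverage conservation on ≤10-kb toy chromosomes against per-base brute
force; the full pipeline at default generator scale across 10 seeds for
planted recovery; 500 null replicates for log-rank uniformity; and all
10,625 2×2 tables with n ≤ 20 for the Fisher oracle. The whole suite
runs in a few minutes on one CPU.

## Known limitations

* Gains are binary presence/absence; quantitative differential-binding
  models (dispersion-aware fold changes) are out of scope.
* The abstract of the source work counts 64 loci where its table and
  figures count 68; the packaged table follows the printed 68 rows and
  records, not resolves, the discrepancy. Similarly the table lists more
  gene entries than the text's "131 genes"; both raw and filtered views
  are exposed and neither count is asserted.
* Annotation cannot regenerate the original table's relation labels
  without the original gene build; only internal consistency is tested.
* The screen's Z-scores, GSEA variant and survival handling are the
  documented standard formulations above, not a reverse-engineered copy
  of any web service's options.
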