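# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open (BED). Every interval carries
an assembly tag and set operations refuse to mix assemblies — in a pipeline
that shuttles regions between two genome builds, silent coordinate-space
confusion is the failure mode worth engineering against. Coordinate pairs
printed in prose (e.g. knockout deletion spans like
chr5:122,092,252–122,094,768) are 1-based fully-closed; `span_length_1based`
converts such a pair to a length (that example spans 2,517 bp). Merging uses
gap = 0 by default, so book-ended intervals merge, matching the default of
the standard merging utility. The centre of an even-length interval is the
lower median (floor), keeping integer arithmetic deterministic.

## Replicate consensus

Biological replicates of one condition are combined by the best-p overlap
rule: a peak is confirmed iff it overlaps at least one peak in every other
replicate, and confirmed overlapping peaks merge into one interval carrying
the maximum −log10 *p* among contributors. No p-value is ever synthesised; a
weighted meta-analytic combination (e.g. Fisher-style replicate combination)
is deliberately out of scope — the stringency control lives downstream in
the catalogue gate. Significance is exchanged exclusively as −log10 *p*, so
*p* ≈ 10⁻³⁰⁰ needs no special handling and the gate *p* ≤ 10⁻¹⁰ is the
threshold 10.0.

## Cross-assembly mapping

Chain files are parsed with strict arithmetic validation (block sums must
reproduce the declared end coordinates). Mapping applies three criteria:

* **coverage** — ≥ 50 % of the region's bases must project through
  alignment blocks (`min_fraction`, exposed);
* **uniqueness** — all projected bases must lie on a *single chain*. This is
  stricter than a single chromosome and deterministic; only chains
  contributing ≥ 1 projected base count toward uniqueness, so merely
  touching chains cannot poison a mapping;
* **reciprocality** — the target, mapped back with the reverse chain set
  under the same rules, must land on the original chromosome and overlap
  the original region by ≥ 50 % of its length. The published criterion
  ("uniquely map back to the original region") states no tolerance; reusing
  the same 50 % figure is this package's choice and is exposed as a flag.

The mapped target is the minimal interval spanning all projected bases
(liftOver semantics): alignment gaps inside the span are tolerated.
Reciprocal filtering can only remove mappings, never alter a forward
target — asserted as a property test.

## Promoter exclusion

A peak is promoter-proximal when its centre lies within 1.5 kb (inclusive)
of any TSS; the boundary is tested explicitly (1,500 → promoter, 1,501 →
enhancer). Because very large enriched regions can span a promoter while
their centre escapes the window, TSS ± 1.5 kb windows are additionally
subtracted from the surviving enhancer peaks. The subtraction is applied
per-condition to the peaks *before* merging, with fragments inheriting their
parent peak's *p*: this keeps the per-condition evidence map coherent (the
alternative — subtracting from merged regions — would need an arbitrary rule
for re-assigning evidence to fragments). Either order leaves the final
catalogue free of TSS-window bases.

## Catalogue construction

The union of all condition peak sets is merged; each merged region's
evidence map records, per condition, the best −log10 *p* among overlapping
peaks. A condition with no overlapping peak is *absent* from the map rather
than 0, so breadth of observation is countable. The significance gate
applies to the best evidence across conditions (a region needs one
condition at *p* ≤ 10⁻¹⁰, not all). Gating before or after blacklist
removal yields the same final set (asserted as a test); the implementation
gates first. Blacklist handling defaults to dropping any region sharing
≥ 1 base with a blacklisted interval, because scores are region-level;
`blacklist_mode="subtract"` trims instead for users who prefer it.

## Scoring

The per-condition score of region *r* with evidence *p_r* is the empirical
rank

&nbsp;&nbsp;&nbsp;&nbsp;*s_c(r)* = |{*p′* in condition *c* : *p′* ≥ *p_r*}| / *N_c*,

the fraction of that condition's peaks with equal-or-weaker enrichment,
computed over the condition's final (post-consensus, post-mapping,
promoter-free) peak set. Ties share a score through the ≥-count rule; the
condition's strongest peak scores exactly 1 and its weakest 1/*N_c*. The
complementary "probability of equal-or-better enrichment" reading — under
which stronger peaks would score *lower*, contradicting a 0 = weakest,
1 = strongest scale — is retained as `variant="literal"` for sensitivity
analysis only. Raw class scores sum *s_c* over all evidence-bearing
conditions (combined) or over prenatal / postnatal conditions only;
conditions without evidence contribute 0, so a region observed at median
enrichment in *k* conditions has raw combined score ≈ *k*/2 — the breadth
criterion enters linearly. Each class is normalised by its catalogue-wide
raw maximum, recorded in provenance: scores are comparable only within one
catalogue version. Replicates merged into one manifest condition count once
in the sum.

## Calibration

Catalogue regions and tested elements pair when they share ≥ 500 bp;
elements overlapping promoter windows or the blacklist are excluded first,
and an element straddling several regions contributes one pair per region
(but counts once in the rediscovery rate). The validation rate is estimated
by regressing the 0/1 outcome on the score with a natural cubic regression
spline, 3 degrees of freedom, fitted by ordinary least squares (the
`cr()` basis from patsy, coefficients via statsmodels). OLS on a binary
outcome is the simplest model consistent with "cubic spline, df = 3"; a
binomial-GLM refit on the same basis is available via `link="logit"`, and
regression on the scaled score *rank* rather than the score value via
`x="rank"`. Predictions are clamped to [0, 1] and held constant beyond the
observed score range — a deliberately conservative extrapolation. Fits with
fewer than 10 pairs are refused; all-identical outcomes yield a flagged
degenerate constant curve.

## Annotation

Gene distances are anchored at the region centre: distance = |centre − TSS|,
signed positive when the TSS lies at the greater coordinate. LD expansion is
not performed; the package consumes a pre-expanded proxy table and filters
to *r*² ≥ 0.8 within 500 kb of the lead variant (leads pass trivially). A
variant hits a region iff start ≤ pos < end (half-open, matching BED); SNP
tables are read 1-based by default (VCF convention) with a `coords=0`
escape.

## Synthetic worlds

The generator emulates the statistical structure of a multi-condition
cardiac ChIP-seq compendium, not its sequence content. Defaults, chosen to
be desk-scale while preserving every stressor the pipeline must survive:

* **Genome**: 2 chromosomes × 5 Mb on each of two assemblies, linked by
  segment-wise chain files (250 kb segments, 30–60 kb blocks, ≤ 100 bp
  indel gaps, 5 % inverted segments). Intervals straddling segment
  boundaries project onto two chains and come out ambiguous, as with real
  chain files. Optional duplication / non-reciprocality rates plant
  segments that trigger `ambiguous` and `non_reciprocal` statuses.
* **Conditions**: 8 (4 prenatal / 4 postnatal; half on the second assembly,
  requiring mapping), mixing H3K27ac and p300 — mirroring a realistic
  prenatal-heavy mouse series plus human fetal/adult samples.
* **Planted enhancers**: 300, lengths 1–3 kb, strength θ ~ Gamma(2, 1).
  Each condition is active with probability 0.10 + 0.20·θ (≥ 1 active
  condition forced), so breadth of observation correlates with strength —
  the biological analogue of the combined score's breadth criterion.
  Active conditions emit a peak with boundary jitter (σ = 100 bp) and
  −log10 *p* ~ Normal(10 + 5θ, 3) truncated below at the gate.
* **Background**: 20 peaks/Mb per condition, lengths 0.5–2 kb,
  −log10 *p* = 2 + Exponential(1.5) — a calling-floor-plus-tail shape under
  which a few background peaks clear the 10⁻¹⁰ gate per run, so precision
  is genuinely below 1, as in real data.
* **Validation labels**: 100 planted + 50 background elements (padded to
  ≥ 1.2 kb so qualifying overlaps can reach 500 bp), heart-positive with
  probability logistic(−2 + 1.5·θ).
* **Variants**: 30 lead SNPs (half placed inside enhancers) with ~8 proxies
  each at *r*² ~ U(0.6, 1) and distances up to 600 kb, so both LD filters
  are exercised.

Placement avoids TSS windows, the blacklist and other enhancers (with
jitter-sized margins) and requires a clean reciprocal mapping of the padded
interval, so every active condition of a planted enhancer can emit a peak
that survives the pipeline — which is what makes "recall among
gate-exceeding planted enhancers" a sharp correctness probe rather than a
property of the noise. What the generator does **not** emulate: read-level
noise, signal tracks, sequence composition, inter-condition correlation of
background, and real chain-file pathologies beyond
duplication/inversion/non-reciprocality. Passing tests therefore certify
the integration logic, not peak-calling quality on real data.

All randomness flows from a single `numpy` generator seeded by the caller;
one seed reproduces every output file byte for byte.

## Numerical and degenerate-input choices

Sorting ties break by (chromosome lexicographic, start, end); score ranking
ties break by raw score then genomic position, making ranked output
independent of input order. Empty peak inputs give an empty catalogue with
a warning; an empty score table, an empty replicate list, zero validation
positives and sub-minimum calibration samples are all refused loudly rather
than guessed at. Zero-length BED records are rejected with a logged warning
naming the line.

## Known limitations

The catalogue's scores are rank-based within one run and not comparable
across catalogues built from different manifests. The reciprocality
tolerance (50 % round-trip overlap) and the OLS spline are documented
package choices where the published procedure is underspecified; both have
exposed alternatives. Promoter catalogues are emitted but not scored or
calibrated. Test-suite and acceptance runs use the default desk-scale world
(300 planted enhancers over 10 Mb); the pipeline itself is O(n log n) in
peak count and handles genome-scale inputs, but its statistical behaviour at
that scale is not certified by the synthetic tests.
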