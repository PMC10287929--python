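# Methods

This note documents the models and procedures the package implements, the
defaults that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## TE curation and stitching

Curation is a two-pass projection: instances shorter than `min_length`
(default 300 bp) are removed first, then every family whose copy number
*after* the length filter is below `min_copies` (default 50). The order
matters — a family with 50 copies of which one is short drops to 49 and is
removed entirely — and the instance-level reading ("shorter than X bp" as
an exclusion preceding family counting) is the one implemented. Copy
number is counted genome-wide per family on unstitched instances.

Stitching merges same-family, same-chromosome, same-strand fragments whose
successive gaps are ≤ `max_gap` into one element, in a single
left-to-right sweep (equivalent to the transitive closure over the
pairwise gap relation; the tests verify this against a union–find oracle).
The default `max_gap` of 500 bp accommodates the LTR interruptions that
fragment internal ERVK elements at toy scale; "adjacent" has no canonical
gap value, so the parameter is exposed. Stitching is idempotent on the
spans it produces.

"Full-length" selection for a family (used for per-element correlation on
MERVL) is a plain length threshold, default 4500 bp for MERVL-internal
elements — chosen as just under the ~5 kb consensus length of the internal
sequence; no published length rule exists for this set, so it is
configurable.

## Coverage tracks and per-element enrichment

Tracks are stepwise-constant runs with bedGraph semantics; construction
canonicalizes (sorts, drops zero runs, merges adjacent equal-value runs),
so equal tracks have identical run lists, and overlapping input runs are
rejected as ambiguous rather than summed.

RPGC-style 1× normalization scales a track by genome size over total
signal so the genome-wide mean per-bp coverage is exactly 1; it is
idempotent and scale-invariant up to floating-point rounding (the tests
check 1e−12).

Per-element enrichment is computed on **mean** per-bp coverage (not
summed counts), making elements of different lengths comparable:

    log2_fe = log2((mean_obs + c) / (mean_input + c))

with pseudocount `c = 0.1` on the 1×-normalized scale, which bounds the
statistic at uncovered elements without visibly biasing covered ones.
Factor–mark agreement across elements is Pearson's r on the paired
log2-FE values with a two-sided p from the t distribution with n − 2 df;
fewer than 3 pairs or a zero-variance vector is an error, not a NaN.

Peak curation keeps fold enrichment **strictly** above the threshold
(default 2), so FE = 2.0 is removed.

## Differential calling

The differential module applies fixed decision rules — genes significant
at BH padj < 0.01 and linear |FC| > 2, TE families at padj < 0.01 and
|FC| > 1.5, differential binding sites at raw p < 0.05 and |FC| > 1.5
(the confidence thresholds of differential-binding pipelines use raw p) —
to any table carrying (feature_id, log2fc, pvalue[, padj]). A
negative-binomial Wald test makes the pipeline self-contained when no
external DE engine output is available:

* library-size factors by median-of-ratios against the per-feature
  geometric mean (all-positive features; total-count ratios as fallback);
* per-feature log2 fold change of normalized means with pseudocount 0.5;
* dispersion by method of moments per condition, pooled across conditions
  by residual df, then **shared across features** as the experiment-wide
  mean of the per-feature estimates (floor 1e−8);
* Wald statistic on the log difference with a delta-method standard error
  under Var = μ + αμ², two-sided normal p (floored at 1e−300).

The across-feature sharing is the load-bearing choice: at 2–3 replicates a
per-feature plug-in dispersion is so noisy that the Wald test is strongly
anti-conservative (measured null p < 0.05 rate ≈ 0.12 at 3v3), while the
shared estimate keeps the null rate at ≈ 0.05–0.07 and preserves power for
4-fold changes. This is the same information-sharing principle mature DE
engines use, reduced to its simplest form. All-zero features are skipped;
with a single replicate in a condition the fold change is reported with a
missing p.

Genes and TE families are tested **jointly** in one run
(`joint_de_test`), mirroring TE-aware counting practice: size factors and
the BH correction come from the combined matrix. A family-only matrix of a
handful of features makes median-of-ratios normalization and the FDR
unstable; the combined run is both more realistic and more reproducible.

## Association

The Jaccard statistic is intersection-bp over union-bp after merging each
set internally; both-empty is defined as 0. An element is "bound" iff it
overlaps a curated peak by ≥ `min_overlap_bp` (default 1 bp; half-open
intervals, so abutting features share nothing). Family-level binding
aggregates instance flags by absolute count (default ≥ 10 bound copies) or
by fraction — exactly one rule is configured, because "directly bound" has
no canonical definition at family level.

TSS-to-element distance is 0 when the TSS lies inside the element,
otherwise the distance to the nearer edge; ties go to the element with the
smaller start coordinate so results are deterministic. The
foreground-vs-background comparison (up-regulated genes against bound vs
other TEs) is a one-sided Mann–Whitney test of "stochastically smaller",
exact when both groups have n ≤ 20, tie-corrected normal approximation
otherwise.

The peak annotator assigns the first matching category in priority order
(promoter = TSS ± 2 kb, then TE, exon, intron, intergenic) by ≥ 1 bp
overlap. It is deliberately simple plumbing; its percentages depend on the
priority rule and are not comparable across annotators.

## Nucleosome occupancy

Profiles are fragment bp-coverage in 25-bp bins over ±1 kb around anchor
centers (floor midpoint of the peak); windows crossing a chromosome edge
are dropped with a warning. Coverage, not fragment-midpoint counting, is
the default unit because occupancy trackers integrate protected bp;
midpoint counting is available as an option.

Median normalization of meta-profiles shown together divides each profile
by its own median and multiplies by the median over all the profiles'
medians. The median of an even number of values is the mean of the two
central values — stated because the post-condition (every normalized
profile's median equals the median-of-medians exactly) depends on it. A
zero-median profile cannot be normalized and raises an error naming the
group.

A site is nucleosome depleted iff its central 200 bp tag count (8 central
bins) is strictly below the mean central count over all sites; "the
average" is read as the across-site mean, the natural reading when sites
are rank-ordered by central count. The strict comparison carries a 1e−9
relative guard so float accumulation on identical profiles can never
produce spurious calls; uniform scaling of all profiles leaves the calls
unchanged.

Peak strength classes C1–C3 are equal-size tertiles by fold enrichment
(C1 strongest; remainder to the strongest classes; FE ties ordered by
coordinate). Occupancy comparison median-normalizes the two conditions'
meta-profiles jointly, then reports the per-anchor central-window delta
(depleted − control); an anchor is "reduced" iff delta < −t with t = 0
(strict) by default. With t = 0, anchors without a planted effect are
called at chance (~50%) by symmetric noise while genuinely eroded anchors
approach 100%; the threshold is exposed for users who want a margin.

## Single-cell statistics

Smart-seq2 QC keeps cells with > 500 expressed genes and a between-cell
Pearson correlation > 0.60, both strict; the correlation is each cell's
maximum against any other cell (the aggregation is ambiguous in common
usage, so the mean is available as an alternative). Droplet QC removes
cells with < 200 expressed genes or > 10% mitochondrial reads — boundary
values are retained, since the rule is phrased as an exclusion.

The marker-score classifier is an explicit stand-in for graph clustering:
score = mean log1p expression over 2C markers (Zscan4/Usp17l/Gm13119/
Gm4027-style) minus the same over pluripotency markers (Pou5f1, Nanog);
"totipotent-like" iff score > margin (default 0, strict). External cluster
labels are accepted through the same table interface. Fractions are
numerator/denominator pairs with percentages rounded to 2 decimals only on
report; fold changes are computed on the unrounded percentages.

## Synthetic data

The generator emulates the *structure* of a degron-depletion chromatin
study at desk scale: 3 chromosomes × 1 Mb, ~600 TE instances in 8 families
spanning ERVL/ERVK/ERV1/LINE/SINE (one family all-short and one low-copy so
curation has work to do; 40% of IAPEz-int copies emitted as 2–3 adjacent
fragments with 50–300 bp gaps to exercise stitching), ~300 genes, one
factor peak on a configured fraction of each family's copies plus
TE-free decoy peaks straddling the FE-2 curation boundary, Poisson
coverage tracks in 25-bp bins (background rate 20/bin; planted log2
amplitudes N(2, 0.8)), MNase fragments with lengths ~N(147, 10) truncated
to [100, 200], NB counts (dispersion 0.1, 3 vs 3), and 9122/8432 cells per
condition with planted totipotent-like fractions 1.06% and 7.38% (the
planted count is the rounded fraction, so recovery error comes only from
classifier mistakes).

Planted structure: H3K9me2 amplitude rides on the factor amplitude at
bound ERVL copies with log2 noise sd 1.5 — sized so the *realized*
per-element correlation after the log2-FE transform (which compresses
high amplitudes and mixes in the unbound background cluster) centers on
the target r ≈ 0.7; H3K9me3 behaves the same way at bound ERVK/ERV1
copies. The depletion condition multiplies planted factor/remodeler means
by 0.1, mark means by 0.5, and MNase anchor depth by 0.5 at the eroded
(ERVK/ERVL-bound) anchors. 80% of the 40 "2C genes" are placed with their
TSS within 1 kb of a bound TE; their planted log2 fold changes are uniform
on [1.5, 7], so a subset clears the strong-early-2C bar (log2FC > 5).
MERVL-int and MT2_Mm family counts are planted up 4-fold.

One global seed fans out to named substreams (genome, TEs, genes, binding,
tracks, MNase, counts, cells), so the same seed reproduces every output
byte-for-byte and each data type can be regenerated independently.

What the generator does **not** emulate: sequence content, mappability and
multimapper ambiguity, alignment artifacts, peak-calling behavior,
GC/digestion bias, batch effects, doublets, or the correlation structure
of real single-cell expression beyond the marker genes. Passing recovery
tests therefore demonstrates that the *analysis logic* is correct under
the stated statistical model, not that the pipeline is robust to the
failure modes of real sequencing data.

Problem sizes were chosen so the complete synthetic analysis (generation
plus every downstream stage) runs in a few seconds on one CPU while
keeping every per-family and per-class recovery statistic adequately
powered.

## Known limitations

* The NB stand-in has no dispersion trend over the mean and no LFC
  shrinkage; borderline fold changes near the thresholds will disagree
  with mature DE engines even though the calls are calibrated.
* Enrichment uses mean coverage with a fixed pseudocount; very short
  elements on sparse tracks remain noisy.
* The peak annotator's category percentages are priority-rule dependent.
* The NFR rule compares against the across-site mean; a different
  reference (e.g. flank-matched) would call different sites.
* Interval operations are in-memory and quadratic in places; they are
  sized for desk-scale genomes, not mm10.
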