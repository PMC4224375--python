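# Methods

This note documents the models, conventions and numerical choices behind
`ctrlpool`, and what the synthetic scenarios do and do not establish.

## Reads, binning and coordinates

Mapped reads are reduced to (chromosome, 5′ position, strand) with
0-based half-open coordinates throughout; the 5′ end of a minus-strand
record spanning `[start, end)` is `end − 1`. tagAlign and BED6 files
(plain or gzip) are accepted and written; round-tripping preserves the
read multiset exactly. Duplicate reads are retained — inputs are assumed
to be pre-filtered to uniquely mapping reads, and deduplication is out of
scope.

The genome is tiled into contiguous, non-overlapping bins of 200 bp by
default (the standard ChIP-seq bin size; configurable). Each read is
extended from its 5′ end in the strand direction to the average fragment
length (default 150 bp, configurable per sample — fragment-length
estimation, e.g. by cross-correlation, is out of scope) and the fragment
is assigned to **exactly one bin, the one containing its midpoint**,
clamped to chromosome bounds. The midpoint rule gives an exact
conservation invariant (`sum of counts + skipped = depth`) and makes
count vectors comparable across depths; an `overlap` mode that increments
every overlapped bin exists but is not the default because it counts one
read several times. Reads on chromosomes absent from the layout are
excluded and reported in a `skipped` tally.

Subsampling draws exactly `round(fraction × depth)` reads (round half to
even, so repeat counts are deterministic) uniformly without replacement
from a PCG64 generator; the same seed always yields the same sub-multiset,
and nested subsampling composes exactly. Pooling is multiset union.

## Baseline peak caller

The framework needs only one property from a peak caller: a ranked peak
list whose quality depends on the depth and fidelity of the control.
Sophisticated background models (negative binomial with covariates,
mappability/GC corrections) are deliberately out of scope; externally
produced peak BEDs plug in unchanged through `import_peaks`.

Per bin, the expected ChIP count under the background model is
`(chip.total / control.total) × (control + pseudocount)` (pseudocount
default 1), the p-value is the upper-tail Poisson probability of the
observed ChIP count at that expectation, and Benjamini–Hochberg at the
requested FDR (default 0.05) selects bins. Selected bins separated by at
most `min_gap_bins` (default 1) non-selected bins merge into one region.
The region score is −log₁₀ of the minimum constituent bin p-value,
computed via `poisson.logsf` so that very strong peaks keep distinct
scores instead of tying at the float-underflow cap (ties there would make
rank-agreement comparisons artifactual); ranks are assigned by score
descending with deterministic coordinate tie-breaks.

Treating the observed control count as the background mean makes the test
anti-conservative where control counts are low and overdispersed; on flat
backgrounds with ≥ 30 expected reads/bin and planted folds ≥ 8 the caller
recovers planted regions with recall ≥ 0.95 and precision ≥ 0.9, which is
the regime its tests pin down. On heavy-tailed backgrounds it calls
excess isolated false positives — a property shared by any
single-observation Poisson background, and in fact the very mechanism by
which a deeper (pooled) control improves ranking fidelity.

## Similarity, classes and the pooling recommendation

Sample similarity is the Pearson correlation of bin-count vectors
restricted to bins overlapping (≥ 1 bp) a master list of ChIP-enriched
regions — the merged union (book-ended intervals included) of peak sets,
either imported or produced by the baseline caller from an initial ChIP
vs pooled-control comparison. The restriction depends only on layout and
master list, so every sample's vector is identically aligned.
Correlations are computed on raw counts (a `log1p` option exists for
heavy-tailed data). A zero-variance vector makes the correlation
undefined; such pairs are flagged and classified low, since they indicate
insufficient depth. Normalized Euclidean distance (each vector scaled to
unit total, hence depth-invariant) and average- or complete-linkage
hierarchical clustering are provided for exploration; linkage default is
average.

Pairs are classified high/low against a fixed threshold, default 0.7 —
the midpoint of the empirically observed 0.6–0.8 band between the two
modes of the correlation distribution. Because that band is an empirical
observation rather than theory, a `mixture` method is also offered: a
two-component Gaussian mixture fitted to Fisher-z transformed
correlations, with the threshold at the density crossing between the
component means, falling back to the fixed threshold when the means are
closer than 0.1 in z-space. The recommendation is `pool` iff every pair
in the candidate group is high; the minimum pairwise r is reported as the
deciding statistic, and offending pairs are named.

## Matched-cost designs and unequal-depth schemes

Design M subsamples each replicate control to a per-replicate fraction f
(derived, reproducible seeds per repeat × replicate × fraction); Design P
pools **exactly those subsampled reads**, so the two designs consume
identical control read totals by construction, and the cost ratio between
fractions is exact arithmetic (f = 0.05 vs full depth on equal replicates
is a 20-fold saving). The experiment runner repeats the construction
(default 5 repeats), calls peaks for every ChIP against its gold-standard
(full matching), Design-M and Design-P controls, and is bit-reproducible
given its base seed.

For replicates of very different depths (n₁ ≤ n₂), three pooling schemes
with matched gold standards are built, all gold standards drawn from the
deeper replicate: pool₁ = (n₁/2, n₂/2) vs GS₁ = n₁/2 + n₂/2; pool₂ =
(n₁/2, n₁/2) vs GS₂ = n₁; pool₃ = (n₁, n₁) vs GS₃ = 2n₁ (requires
2n₁ ≤ n₂). Within a scheme, draws from the same source are disjoint
whenever the source is deep enough — avoiding information leakage between
a gold standard and the pooled control it judges — and any unavoidable
overlap (e.g. at the 2n₁ = n₂ boundary, where GS₃ is all of R2) is
recorded in `shared_r2_reads`.

## Evaluation

Top-k% overlap sensitivity truncates **both** peak sets to their top
`ceil(k% × N)` peaks by rank and reports the fraction of truncated gold
peaks overlapped (≥ 1 bp, configurable) by a truncated candidate peak,
over k = 5, 10, …, 100 by default. Symmetric truncation was chosen
because the question is ranking fidelity — does the cheap control find
peaks in the same order as the gold standard? Two other modes exist:
`candidate_only` (full gold set) for sensitivity-versus-full-gold
analyses, and `equal_depth` (both lists cut to `ceil(k% × N_gold)`), a
pure ranking-agreement measure that does not reward a candidate for
calling more peaks — the right tool when a biased control inflates the
candidate list, as in the cross-lab pooling scenario. PPV is the fraction
of candidate peaks overlapping any gold peak. Curves are averaged
pointwise across ChIP samples × repeats with sample standard deviations.

Motif occurrence uses JASPAR-style count matrices (parsed with
Biopython), converted to probabilities with pseudocount 10⁻⁴, scored as
log₂ odds against a zero-order background on both strands. The score
threshold for a p-value cutoff (default 0.01) comes from the exact null
score distribution computed by dynamic programming over per-position
scores discretized to 10⁻³ bits; per-position scores are rounded **up**
to the grid, so the realized false-positive rate never exceeds the
nominal p (error at most width × 10⁻³ bits). Peaks whose sequence is more
than 50% ambiguous are excluded from the denominator. Matching a specific
external scanner bit-for-bit is a non-goal.

## Synthetic scenarios

The generator targets the observable classes that drive the pooling
decision, not sequence-level biology. Per-bin background rates are
log-normal: sample i's log-rate is `mean_log + √ρ·Z + √(1−ρ)·Eᵢ` with a
shared field Z and independent fields Eᵢ (both N(0, sd_log²)), so the
pairwise log-rate correlation between any two samples is exactly ρ — one
interpretable dial. Defaults: one 10-Mb chromosome (50,000 bins, keeping
every scenario around a second to generate; scalable via config),
sd_log = 1 (strongly overdispersed, heavy-tailed backgrounds as in real
input libraries), 200 planted enrichment regions of 3–7 bins placed
disjointly in equal slots, fold changes uniform on [8, 15] applied to
ChIP rates only, and 1M reads per sample. Reads are multinomial over
bins, uniform within bin, fair-coin strands.

Preset scenarios map to the multiplexing settings of interest: biological
replicates with shared (ρ = 0.97) or distinct (ρ = 0.3) background —
straddling the 0.6–0.8 decision band after depth attenuation; a 1:3
unequal-depth pair; multiple treatments (four controls, three conditions,
ρ = 0.92, 5% of bins perturbed per condition — the effect size is a free
choice exposed in config); multiple cell lines with high (ρ = 0.93) or
independent (ρ = 0) backgrounds; and a two-lab scenario where one control
carries a smooth multiplicative bias, `exp(1.0·sin)` varying on a ~50-kb
scale, strong enough that samples would cluster by lab before biology.

Because counts add Poisson noise on top of the rates, the measured
count-level correlation attenuates below ρ at low depth and recovers with
coverage — reproducing the depth dependence that makes shallow replicate
controls look less similar than they are, and the rationale for deciding
from candidate-region correlations rather than raw-genome ones.

What passing tests show: the decision rule separates the planted classes,
pooling at matched cost dominates per-sample matching when backgrounds
are shared and inflates false positives when they are not, and all read
operations are exactly conservative and reproducible. What they do not
show: behavior under GC/mappability bias, duplicate reads, paired-end
libraries, or peak callers with richer background models — the synthetic
backgrounds are bin-wise independent fields, with none of the spatial
autocorrelation structure of real chromatin.

## Degenerate inputs and tie-breaks

Empty read files load as empty read sets; empty ChIP counts yield empty
peak sets; a zero-depth control is an error (instructing a
pseudocount-only background); an empty master list warns and yields empty
vectors; an empty gold standard makes sensitivity/PPV undefined (error),
while an empty candidate gives a zero curve and NaN PPV (with a warning).
Peak ranks break score ties by (chromosome order, start). Pooling order
never affects multisets, only file row order; canonical sorting is used
for multiset comparisons.
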