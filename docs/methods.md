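# Methods

## Study design assumed by the pipeline

The data model is a founder-anchored multigenerational design: several
independent lineages, each descending from a common expanded population
(generation 0, the founder), propagated through two-worm bottlenecks
and sampled every two generations up to generation 20.  Lineages carry
a condition label (control, low dose, high dose); condition always
comes from sample metadata, never from sample names.  Missing samples
(library failures) are represented as absent (lineage, generation)
pairs, not as zero columns — every stage distinguishes "not assayed"
from "not observed".

All genomic intervals are 0-based half-open (BED convention)
internally; variant positions are 1-based on input (the VarScan
dialect) and converted once at the I/O boundary.

## Normalization

Median-of-ratios size factors: a pseudo-reference per locus is the
geometric mean of its counts across samples; a sample's factor is the
median over loci of count/pseudo-reference.  Loci containing any zero
are excluded from the median (their geometric mean vanishes on the
count scale); an explicit error is raised when no locus qualifies.
Medians over an even number of loci average the two central ratios.
The log2 transform applies a pseudocount (default 1) so that loci with
sporadic zeros — which survive the all-zero filter — remain finite;
the pseudocount is exposed because analyses differ on this point.

## Epimutation calling

Each (lineage, generation > 0) column of log2 normalized counts is
regressed on that lineage's founder column.  Two models are offered
with identical downstream treatment:

* **loess** (default for gene expression): locally weighted quadratic
  regression with tricube weights, span 0.75.  Above 1000 points the
  local fits are evaluated at 401 quantile-spaced knots and linearly
  interpolated, the same device reference implementations use to keep
  loess linear-time; below that the fit is exact at every point.
  Requires at least 30 loci (smaller tables get a clear error advising
  the linear model).
* **linear** (default for small-RNA class tables): ordinary least
  squares with intercept.

Residuals are standardised per column (mean 0, SD 1 with the *n*−1
denominator); zero residual variance raises a dedicated degenerate-
column error rather than emitting infinities.  Calls are +1 for
z ≥ cutoff, −1 for z ≤ −cutoff, else 0, with the boundary *inclusive*
(the two natural readings of the cutoff differ only on a measure-zero
set; the inclusive one is adopted uniformly and documented here).  The
default cutoff is 2.25.

### Cutoff calibration

`calibrate_cutoff` quantifies whether calls recur across generations
more than chance allows.  Observed inheritance is the percentage of
nonzero calls whose same-direction call recurs at the next sampled
generation of the same lineage (calls in a lineage's final column have
no successor and are excluded).  The null redraws calls independently
per (locus, generation) as a three-way Bernoulli matched to each
column's empirical up/down rates — memoryless by construction, but
honouring per-generation rate heterogeneity.  The Monte-Carlo p-value
uses the add-one estimator (1 + #{null ≥ observed})/(n_sim + 1); the
recommended cutoff is the largest grid value with p < 0.05.

## Inheritance dynamics

A run is a maximal same-direction streak over consecutive sampled
generations of one locus in one lineage.  A zero call ends a run; a
direction flip ends it and starts a new one at the same generation.  A
sampled-but-missing generation bridges a run when both flanking
available generations carry the same direction (an epimutation present
at generations 2 and 4 is taken to exist at the unsampled generation
3, and the same logic extends to missing libraries); `strict=True`
closes runs at any gap instead, for sensitivity analysis.  Durations
are counted in sampled generations; a ×2 organismal-generation column
is also emitted since samples are two generations apart.

Runs whose last generation is the lineage's final available generation
are right-censored.  In the Kaplan–Meier estimate a censored run of
duration *d* leaves the risk set just before *d*: it survived the
continuation trials 1..*d*−1, but its trial at *d* (presence at a
never-assayed later generation) was not observed, so including it in
the at-risk set at *d* would deflate the hazard there.  This convention
recovers the generating geometric distribution exactly in simulation;
the naive convention overestimates mean duration by ~15% at 20%
censoring.  Mean duration is the restricted sum of S(k) over the
integer duration grid.  The inherited fraction (runs lasting ≥ 2
sampled generations) excludes runs starting at the final available
generation, whose inheritance is unobservable.

Group comparisons: k-sample log-rank (lifelines) on run durations with
the same censoring convention; Kruskal–Wallis with a selectable post
hoc (Conover–Iman rank t-tests, or pairwise Mann–Whitney with
Bonferroni); and the Jonckheere–Terpstra test for ordered alternatives,
with J = Σ_{i<j} #{x < y} + ½#{ties}, exact p by multinomial
enumeration when total n ≤ 12 (≤ 34 650 assignments) and the
tie-corrected normal approximation otherwise.  A tie-saturated input
has zero null variance and is reported as z = 0, p = 0.5.

## tRNA fragments

Small-RNA alignments of 18–36 nt are assigned to non-overlapping tRNA
loci by ≥ 1 bp overlap; the read start is converted to tRNA 5′→3′
coordinates (plus strand: read.start − locus.start; minus strand:
locus.end − read.end).  Starts falling outside [0, length) through
partial overlaps are dropped and counted; the module reports a full
accounting (assigned + length-filtered + clamped + unassigned = input).
A fragment is a 3′ half when its start is at or beyond floor(length/2);
"half" is not defined by anticodon position, so the midpoint rule is
the documented choice, with the boundary position belonging to the 3′
side.  Per-type 3′-half counts (summed over loci of a type, divided by
the sample's size factor) feed the linear-model epimutation caller
unchanged.

Argonaute-IP enrichment is (tRNA share of IP reads)/(tRNA share of
paired input reads) after keeping only reads strictly longer than
25 nt (excluding 22G-RNA contamination); zero tRNA reads in an input
make the ratio undefined and it is reported as NaN.

The target scan is an ungapped Hamming search of every genomic window
of fragment length on both strands (reverse complement for minus),
tolerance 3 mismatches by default — the analysis convention; a stricter
2-mismatch scan is one flag away.  Non-ACGT characters mismatch
everything, including themselves.  Hits are intersected with gene-body
intervals at ≥ 1 bp.

## Variant fixation

Per lineage: variant keys (chrom, pos, ref, alt — allele identity, so
two alts at one site stay distinct) observed at generation 0 are
founder baseline and discarded; a key is fixed iff it is observed at
every *assayed* generation from its first observation through the
lineage's last; keys first seen at the last available generation are
unverifiable and discarded.  Unassayed generations never break fixation.
`max_dropout` (default 0) allows a chosen number of missing
intermediate observations, as an escape hatch for call-rate dropouts.
SNPs overlap genes as points; indels by their reference-allele span.

## Association battery

Every association reduces to a 2×2 table.  The two-sided Fisher
p-value is computed by exact integer arithmetic: at fixed margins the
hypergeometric probabilities share a denominator, so tables are
classified by comparing integer numerators — no floating-point
tie-breaking.  The reported odds ratio is the sample cross-product
ratio a·d/(b·c) (+∞ when b·c = 0 with a·d > 0; undefined when both
products vanish); the conditional-MLE estimate is available as a
secondary value.

The stepwise battery tests, per sRNA class: (1) expression change ×
sRNA epimutation over all genes; (2) inherited expression change ×
sRNA epimutation over genes with expression changes; (3) as (2) with
*simultaneous* sRNA epimutation (same lineage, ≥ 1 shared sampled
generation); (4) as (3) over genes with both change types.  The class
comparison splits genes carrying both an expression change and a
class-X epimutation into simultaneous versus not, per class — the
column margins of the published control table (75 + 912 vs 2 + 16)
identify this as the intended layout.  Concordance classifies
simultaneous pairs by direction match and compares each class's odds
against the odds of no simultaneous association within the both-change
background.  tRNA-fragment epimutations are keyed by tRNA type and
attach to genes through the target-scan table, taking the union over
targeting types.

Term enrichment is a Fisher test per annotation term over {test} ×
{annotated}, with a term admitted only when at least five annotated
genes occur in the test or in the background list; excluded terms are
counted and reported.  Correction is Bonferroni by default (matching
the analysis convention), Benjamini–Hochberg optionally.

## Synthetic data generator

The generator is first-class, tested code; it defines the conditions
under which the pipeline's statistical guarantees are demonstrated.

* **Counts.** Founder log2 means uniform on (6, 10) — the moderately-
  to-highly expressed regime where log-scale noise is approximately
  Gaussian.  Per-sample counts are negative binomial with shared
  dispersion α = 0.05 (variance μ + αμ²): overdispersion is the
  realistic stress for a residual statistic.  Six lineages (two per
  condition), generations 0–20 step 2, with the reference design's
  missing samples (C2 g12, H1 g20) omitted by default.
* **Founder.** The founder column is simulated as a deep, low-
  dispersion measurement (depth factor 25, Poisson noise): the
  generation-0 reference is an expanded pre-bottleneck population, not
  a two-worm bottleneck sample.  This is a deliberate design choice
  with a statistical consequence: a noisy founder would inject the
  same sampling error into every generation's residual, serially
  correlating the Z-columns (ρ ≈ 0.5 for equal noise) and
  manufacturing "inheritance" under the null.  With the deep founder,
  null calls are serially independent, as the calibration simulation
  assumes.
* **Epimutations.** Births are Bernoulli (default 10⁻³ per locus per
  lineage per generation — an order-of-magnitude choice, configurable),
  direction ±1 equiprobable, duration geometric on the sampled grid
  with continuation probability `persistence_p` (default 0.5, i.e. a
  mean of 2 sampled = 4 organismal generations), truncated at the last
  generation.  While active, the locus's log2 mean shifts by
  ±`effect_size_sd` × σ_resid, where σ_resid is the locus's expected
  regression-residual SD (generation plus founder noise, delta
  method) — effects are expressed in the same units as the Z cutoff.
* **tRNA reads.** Loci (default 20, lengths 70–90 nt) placed without
  overlap on a synthetic chromosome with alternating strands; read
  starts fall in the 3′ half with probability `bias` (default 0.8),
  lengths uniform 18–36 nt; per-condition multipliers (1 / 1.5 / 2)
  scale depth, emulating a dose-dependent rise in 3′ halves;
  per-type × lineage × generation-window multipliers inject tRNA
  epimutations.
* **Variants.** Four categories with known ground truth: fixed
  (appear at an interior generation, persist to the end), transient
  (miss at least one later assayed generation), founder-baseline
  (present from generation 0), last-generation-only.

What the generator does **not** emulate: locus-specific dispersion,
GC/length biases, correlated co-regulation between loci, selection,
linkage between variants and expression, chromatin signal, and
condition-dependent epimutation rates (unless configured).  Passing
tests therefore demonstrate the statistical machinery under the stated
noise model, not robustness to every artefact of real libraries.

## Problem sizes and numerical choices

The test suite and acceptance script use: 5 000 loci × 10 seeds for
null calibration; 10 000 loci for parameter recovery (≈ 1 000 injected
cells, ≈ 570 runs); 3 000 loci with 100 null simulations per cutoff for
the calibration table; 20 random configurations for fixation recovery;
a 50 kb synthetic genome and 1 000 random reads for the coordinate
oracles; exact Fisher agreement is enumerated over all 2×2 tables with
margins ≤ 30.  All randomness flows from explicit seeds;
rerunning any stage with the same inputs and seed is bit-identical.

Known limitations: the loess knot interpolation makes fitted values
at > 1000 points approximate at the 10⁻³ level relative to an exact
per-point fit (well below calling resolution); the Jonckheere exact
path is limited to n ≤ 12 by enumeration cost; `calibrate_cutoff`'s
add-one Monte-Carlo p cannot go below 1/(n_sim + 1); and the
association battery treats a gene's state as the union over its runs,
so genes with many runs weigh the same as genes with one.
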