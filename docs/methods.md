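# Methods

## The analysis

`devotf` compares TF expression programs between two species across
embryogenesis. Each species contributes a gene × time-point matrix of
log2 expression (microarray intensities or log2 FPKM), boolean presence
calls, a TF catalog mapping genes to DNA-binding-domain families, a
seed-ortholog pair list, and a manually curated time-point alignment.
The chain is: presence calling → utilization profiles → filtering and
Z-normalization → fuzzy c-means clustering → cross-species cluster
pairing → ortholog conservation statistics → per-time-point
transcriptome distance.

### Presence calling

Probe-flag data use the conjunction rule: a gene is present at a
condition only if *every* probe of the gene in *every* replicate is
flagged detected. FPKM data use a strict threshold (present iff
FPKM > 1; FPKM = 1 exactly is absent). Both rules are deliberately
conservative: a single undetected probe vetoes the call.

### Filtering and normalization

Before clustering, genes that are never present across the course are
removed, as are "constant" genes whose max − min expression is below 1
on the log2 scale (less than two-fold change); a range of exactly 1 is
retained (the rule is strict). Remaining profiles are standardized per
gene to mean 0, sd 1 using the population sd (denominator T). The
population/sample-sd distinction is absorbed by the scale invariance of
c-means geometry but is pinned for reproducibility.

Quantile normalization (for multi-array inputs) replaces each column's
sorted values by the across-column mean of sorted values; ties receive
the mean of the reference values over their rank span, so equal inputs
stay equal. Probe-level values are averaged over all probes of a gene
and all replicates of a time point (plain arithmetic means, so the
order of averaging is immaterial). RNA-seq FPKM is transformed as
log2(FPKM + ε) with ε = 0.01 by default; ε must be strictly positive so
zero-FPKM genes stay finite and land far below the constant-expression
filter. ε is recorded in the provenance metadata.

### Fuzzy c-means

Profiles are clustered with the Bezdek alternating scheme,

    u_ik = 1 / Σ_j (d_ik / d_jk)^(2/(m−1)),
    v_i  = Σ_k u_ik^m x_k / Σ_k u_ik^m,

with Euclidean d, c = 7 clusters and fuzzifier m = 1.25. The defaults
mirror the comparative setting this package re-implements: seven
clusters capture the recurring maternal/activated/transient shape
classes, and the small fuzzifier gives near-crisp memberships so the
u > 0.8 hard-assignment threshold is meaningful. Iteration stops when
the largest membership change falls below 1e-6 (max 1000 iterations);
a point coinciding with a center receives membership 1 there.

Initialization is k-means++ center seeding with the best of 10 seeded
restarts by final objective. Uniform random memberships — the textbook
initialization — proved unreliable at m = 1.25: the near-hard updates
freeze early splits, and on well-separated archetype data roughly one
run in three merged two archetypes while splitting a third. k-means++
spreads the initial centers and removed every such failure in testing;
`init="random"` is retained for comparison. Results are deterministic
given the seed.

The membership threshold (0.8, strict) and the per-cluster family test
(two one-sided hypergeometric tails at α = 0.0025, a fixed threshold
absorbing the multiplicity of roughly ten tests per family) follow the
comparative setting. The enrichment background is the set of
hard-assigned genes, not the whole catalog: the quantity of interest is
representation *within clusters*, and unassigned genes are not part of
any cluster. This choice is asserted in the tests.

### Cross-species pairing

Cluster centers are restricted to the aligned time points and each
center row is re-standardized over that common grid before distances
are computed. The re-standardization matters when the two species have
different grids: per-species Z-normalization then uses different
constants, and two noiseless clusters of the same underlying shape
would otherwise sit at a spurious nonzero distance. After it, matched
noiseless clusters sit at distance exactly 0.

Clusters (i, j) pair when their distance is strictly smaller than the
distance from i or j to *any* other cluster of either species — the
strictest reading of mutual-nearest pairing; `mode="within-rows"`
relaxes this to mutual row/column minima of the cross matrix. Exact
distance ties reject the pairing (conservative and reproducible). The
display dendrogram uses average linkage over the combined 2c centers
(a conventional default for profile centers, recorded in the output).

Family composition across species is compared per family with a
2 × (paired clusters) Fisher test: exact by full enumeration when the
table total is ≤ 200, otherwise Monte Carlo under fixed margins with an
add-one p-value; the method is tagged in the output.

### Conservation statistics

An ortholog pair is *eligible* if both genes are hard-assigned, and
*concordant* if its two clusters form a cross-species pair. The
correlation statistic counts ortholog pairs whose Pearson correlation
over the aligned time points is significant at α = 0.05 (two-sided
t-test, T′ − 2 df; Spearman available). Each observed statistic is
compared with 1,000 null sets of the same size, drawn by sampling a
gene uniformly (with replacement) from each species' eligible universe;
the report carries Z = (obs − mean)/sd over the null and the add-one
empirical p, whose floor at 1,000 sets is 1/1001. When the null is
degenerate (sd = 0), Z is reported as undefined while the empirical p
remains valid.

### Hourglass analysis

For every pair of time points (s, t), the distance between the species
is the Euclidean norm of the difference between their Z-normalized
ortholog-expression vectors — genes standardized over their *own*
species' full course, not the common grid, so each species' dynamic
range is respected. The gene universe is ortholog pairs in which both
genes survive the clustering filters. The full |T_A| × |T_B| matrix is
computed; the minimum-distance profile along either axis locates the
stage of maximal similarity, and strict interior local minima flag
secondary convergence periods (boundary minima are reported
separately).

### Ontology enrichment

Annotations are propagated up the child → parent DAG (true-path rule),
and each term with at least 3 annotated background genes (configurable)
is screened with a one-sided hypergeometric test at p < 0.01. The elim
procedure decorrelates the hierarchy: terms are processed from the
deepest level upward (longest-path depth, ties by term id), and a
significant term's study genes are eliminated from its ancestors' gene
pools before those are tested. elim is a fully specified, widely used
decorrelation procedure and is the one implemented here; the output's
`algorithm` column makes the choice explicit, and both the classic and
elim p-values are reported per term.

## The synthetic generator

The generator emulates the comparative setting at desk scale. Defaults
(the simulated study conditions): 700 TFs per species, 7 shared
temporal archetypes, Gaussian noise of sd 0.3 on the log2 scale, 10%
constant genes, 5% never-expressed genes, 300 ortholog pairs with a 50%
concordance fraction, and a mid-development convergence window at
developmental progress 0.40–0.60.

*Archetypes* are smooth parametric shapes of normalized developmental
progress — maternal decay (steep and slow variants), sigmoidal
activation (mid and late), and unimodal transients (early, mid, late) —
each standardized to mean 0, sd 1 on its grid, with small seeded
midpoint jitter. Their pairwise separation (≥ 1 in Z-space across 100
seeds) keeps the planted partition identifiable.

*Species grids and warp.* Species A samples 12 points over one day;
species B samples 14 points over ~2 days, of which 12 are aligned to
A's grid. B's hours map to A-equivalent developmental progress through
the piecewise-linear warp defined by those alignment anchors, so both
species express the same archetype at corresponding progress.

*Expression scale.* An archetype gene's profile is
`baseline + amplitude × shape + N(0, σ²)` with baseline ~ N(6, 0.5)
and amplitude 2.5 × U(0.8, 1.2) log2 units — dynamic ranges of several
log2 units, as in developmental arrays. Never-expressed genes sit at
−2; constant genes sit at the baseline with bounded uniform jitter
(±0.2) rather than Gaussian noise, so their range stays strictly below
the constant filter's threshold and the planted filter classes are
exact, not probabilistic. The presence floor is 4.0 log2 units, between
decayed maternal expression and the constant plateau: maternal-class
genes therefore *lose* their present call late in the course and
activated genes gain it, giving presence calls real dynamics while
every archetype gene still peaks well above the floor.

*Orthologs and concordance.* Exactly round(ρ · n_orth) ortholog pairs
share their archetype ("concordant"); the rest draw independently, so
chance collisions at rate ≈ 1/k are part of the design (and of the
expected recovery numbers). Family labels are sampled per gene from
configurable frequencies, with a planted odds-ratio-5 enrichment of the
zf-C2H2 family in the maternal-decay archetype — mirroring the
early-development over-representation of C2H2 zinc fingers that this
kind of analysis is designed to detect.

*Convergence window.* Concordant pairs' genes receive extra divergence
noise whose sd ramps from 0 inside the window to `divergence_scale`
(default 1.0) over 0.15 progress units outside it. Hourglass-recovery
constructions use a fully concordant ortholog set (ρ = 1): with
discordant pairs present, their archetype-geometry mismatch dominates
the time-point distance landscape and the landscape's minimum reflects
where the archetype curves happen to cross rather than the planted
window. The two-trough construction uses σ = 0 and two single-point
windows aligned with grid points, which makes "exactly two strict
interior minima" a deterministic property (wider windows create
plateaus of tied minima, which are not strict).

What the generator does **not** emulate: count-level RNA-seq noise
(negative binomial), probe-level cross-hybridization structure,
correlated noise across genes, family-dependent expression dynamics
beyond the planted enrichment, and genuinely asynchronous development
(the warp is exact, not estimated). Passing recovery tests therefore
show the pipeline recovers planted structure under idealized noise, not
that real cross-platform comparisons are free of systematic error.

## Numerical choices and degenerate inputs

* Fuzzy memberships: distances below 1e-12 trigger the singleton rule;
  membership rows sum to 1 to 1e-9.
* Quantile normalization: postcondition (sorted columns equal the
  reference) holds to 1e-9 for tie-free input.
* Pairing: exact distance ties → no pair, logged.
* Permutation nulls: null sd uses ddof = 1; degenerate nulls report
  Z as undefined rather than ±inf.
* Correlation: pairs with a constant profile in the common window are
  skipped with a note (r undefined).
* Alignment files with numeric labels are monotonicity-checked at read
  time; label-based alignments are checked at resolution.
* All stochastic steps take explicit integer seeds; the full pipeline
  summary is byte-identical across runs at a fixed seed.

## Problem sizes in the test suite

Recovery and calibration tests run at the generator's default scale
(700 genes × 12/14 time points, 300 ortholog pairs) over 25–50 seeds,
and permutation nulls at the full 1,000 sets; the exhaustive
hypergeometric cross-check enumerates every feasible instance up to
N = 20. These sizes were chosen so the planted effects are comfortably
detectable at the stated noise levels while the whole suite runs in
about a minute and a half.

## Known limitations

* weight01-style enrichment (the elim/weight hybrid) is not
  implemented; elim is the documented decorrelation procedure.
* The MAS5 detection-call algorithm and array background correction are
  out of scope: detection flags and processed intensities are consumed
  as inputs.
* Time alignment is an input, not inferred; no dynamic time warping.
* The 2 × k exact Fisher enumeration is exponential in k for large
  column totals; the Monte-Carlo fallback (total > 200) covers the
  practical range.
* With very small families the hypergeometric screen has little power;
  family floors are configurable but results on families of a handful
  of genes should be read as descriptive.
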