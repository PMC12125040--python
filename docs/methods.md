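# Methods

This note documents the models, conventions and numerical choices behind
`blendevol`, and what the synthetic-data tests do and do not establish
about real data.

## Retention-index calibration and relative amounts

Peaks are calibrated against a per-batch C6–C40 n-alkane ladder by linear
interpolation on the Kovats scale: a peak at retention time `rt` bracketed
by rungs C_n and C_{n+1} gets `RI = 100·(n + (rt − rt_n)/(rt_{n+1} − rt_n))`.
Gaps in the ladder are interpolated across the missing carbons; peaks
outside the ladder span are rejected rather than extrapolated, because the
alignment tolerance below is meaningless outside the calibrated range.
Ladders must be strictly increasing in carbon number; anything else is a
validation error.

The internal standard (2-acetoxytetradecane, spiked at known amount) is
located per chromatogram by its unordered top-ion pair (m/z 43/61) within
a configurable RI window (1585 ± 15 by default). How the original
instrument software recognised the standard is not recoverable from the
data dialects we ingest, so the window-plus-ions rule is this package's
convention; it is robust to batch RI drift, which a hard-coded retention
time is not. Multiple candidates resolve to the one closest to the window
centre; an exact tie is an error, never a guess; a sample without a usable
standard is excluded with a logged reason. All intensities then become
relative amounts (intensity / internal-standard intensity), which makes
every downstream statistic invariant to per-sample scale.

## Peak alignment

Two peaks are the same compound when (i) their two most intense fragment
ions correspond exactly and (ii) their RIs differ by at most 0.8 % —
relative to the *mean* of the two RIs, which keeps the predicate symmetric
(the base of the percentage is otherwise ambiguous); the boundary is
inclusive. Ion comparison is on the unordered pair by default because the
two top ions of a compound can swap rank between runs when their
intensities are close; an ordered-strict mode exists as a flag.

Clustering is greedy consensus-linkage: peaks sorted by RI (ties broken
by sample then intensity, making the result independent of input row
order) are attached to the nearest existing cluster whose *running
consensus* (mean member RI) they match, else they seed a new cluster.
Matching against the consensus rather than any member bounds chain growth.
At most one peak per sample per cluster: on a conflict the peak closer to
the consensus stays (ties to the more intense peak), and the displaced
peak re-enters the placement procedure. The early/mid-late split assigns
compounds with consensus RI ≤ 1600 to the early-eluting (volatile) class,
inclusively; the cutoff is configurable.

## Distances, ordination, dispersion

Blend dissimilarity is Euclidean, optionally after log(x+1). The raw
relative amounts span orders of magnitude and the largest compounds
dominate untransformed Euclidean distance, so `log_plus_one` is the
default for all multivariate steps; the transform used is recorded in
every result file and `none` is available wherever a user wants the raw
scale.

NMDS is Kruskal's non-metric scaling into k = 5 axes by default: the
first start is the classical-scaling configuration, further restarts are
random; each iteration runs isotonic (primary, weak-tie) regression of
configuration distances on the rank order of the input dissimilarities
followed by a Guttman update, with stress-1
`sqrt(Σ(d − d̂)² / Σ d²)` tracked monotonically (an iteration that would
increase stress terminates the start). Non-convergence after `max_iter`
flags the result instead of raising.

Within-species dissimilarity is the mean distance over conspecific pairs
(singleton species excluded, logged). Dispersion is the mean distance of
group members from the group's geometric (spatial) median, computed by
Weiszfeld iteration (tolerance 1e-9, max 10⁴ iterations) with the
Vardi–Zhang step when an iterate lands on a data point; for two-member
groups the minimizer is non-unique and the midpoint is used by convention.

PERMANOVA follows the standard sum-of-squares partition of the distance
matrix (`SS_total = (1/n)Σ_{i<j}d²`, per-group within terms, pseudo-F with
a−1 and n−a degrees of freedom). p-values use the (b+1)/(m+1) correction
over seeded label permutations; 10,000 permutations by default. Welch
t-tests use the unequal-variance statistic with Welch–Satterthwaite
degrees of freedom.

## Phylogenetic comparative layer

The Brownian-motion tip covariance is `C_ij = depth of MRCA(i,j)` from
shared branch lengths (Myr); trees need not be ultrametric. Numerically
singular C (zero-length branches) gets a 1e-10 ridge, always logged.

K_mult is the multivariate generalization of Blomberg's K:
`[tr(EᵀE)/tr(EᵀC⁻¹E)] · (N−1)/(tr C − N/(1ᵀC⁻¹1))` with E the deviations
from the GLS root mean. It is exactly 1 on a star tree, ≈1 in expectation
under BM, and reduces to univariate K for one trait; significance comes
from shuffling trait rows across tips.

Clade rate comparison transforms tip deviations by the symmetric inverse
square root of C; a group's net rate σ²_mult is the mean squared row norm
over its tips divided by the trait count, and the statistic is the max/min
ratio. The literature describing this estimator quotes a permutation test,
but the estimator's own null is Brownian simulation at the pooled rate;
both null methods are implemented, simulation is the default, and the
choice is recorded in the result record.

Rate-shift models treat ordination axes as independent Gaussian traits:
per axis the root mean and rate are profiled out analytically; one clade
shares a single rate multiplier r applied to the stem edge of the shift
node plus every edge of its subtree (the tool this mirrors does not
document its internal convention; including the stem makes small clades
identifiable). r is found by bounded Brent search on log r ∈ [ln 10⁻³,
ln 10³] (tolerance 1e-6), and the single-rate model is the nested r = 1
case, so the shift log-likelihood is guarded never to fall below it. AICc
uses k = 2·axes (+1 for the shift) and effective sample size N·axes; this
is a declared convention and only AICc *differences* under the same
convention are ever compared. The shift search fits every internal
non-root node with ≥ 3 tips, ranks by log-likelihood, and declares a
shift only when the best node's likelihood-ratio statistic exceeds the
95th percentile of best-node statistics from single-rate BM simulations
on the same tree — so the null false-positive rate is 5 % by
construction. Only one shift is searched (`max_shifts = 1`).

Species map to tree tips by exact name; where several subspecies were
sampled, a configured choice selects which subspecies (and its samples)
represents the species, mirroring the practice of picking one subspecies
per species to avoid polytomies. Unmatched species are excluded and
reported.

Sister-pair dissimilarity is the mean blend distance over cross-species
sample pairs by default (species-centroid distance is a flag), regressed
by OLS (Gaussian GLM, identity link) on range overlap with branch length
(divergence time) as covariate. Overlap values are user-supplied numbers.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the structure of a multi-species male-gland GC-MS
study: by default 30 species on a pure-birth tree of depth 10.5 Myr with
3 males each across 3 instrument batches — a modest scale-down of a
~157-sample, 36-species design that keeps every statistical regime
(conspecific replication, batch structure, clade contrasts) while staying
desk-fast. Species mean log relative amounts evolve by BM (rate 0.2 per
Myr per compound) from root states that make the early-eluting fraction
(30 % of 25 compounds) more prominent than the ester matrix, matching the
prominent-volatiles-over-matrix character of the real extracts.
Individuals add N(0, 0.55²) log-scale noise per compound, which puts
within-species log-scale distances near 4 at the default compound count —
the order reported for real conspecific blends. Observed RIs add per-batch
drift (sd 0.5) and per-peak jitter (sd 1.0, so 3σ sits inside the 0.8 %
tolerance at the lowest RI of 700 — the "clean" regime, enforced by
validation); decoy compounds (10 %) reuse a real compound's ion pair at
≥ 6 % RI offset and are the designed adversarial case for the top-2-ion
rule. Ladders are linear in carbon number per batch, so the RI
computation inverts the construction exactly at zero jitter; the
internal-standard intensity is lognormal per sample, so only relative
amounts are recoverable — as in real data.

What passing tests on these fixtures show: the alignment rule and its
implementation recover a known partition perfectly when noise is inside
tolerance and fail visibly when it is not; the comparative statistics are
calibrated (type-I error, BM expectation of K_mult) and recover planted
effects (rate ratios, shift nodes) at realistic sizes. What they do not
show: robustness to co-eluting compounds that share ion pairs within
tolerance, retention-time warping not captured by a constant batch
offset, non-Gaussian trait evolution, missing compounds that are censored
rather than absent, or compound-identification errors — real-data
concerns outside this model.

## Problem sizes and tolerances used in the checks

Acceptance-style checks run at: 100 random ladders (RI exactness to
1e-9); the 30 × 3 clean study for exact alignment recovery; 10,000
permutations against the exhaustive 20-partition PERMANOVA oracle and 500
null replicates for type-I error (accepted band 0.05 ± 0.02); 20 random
trees for the univariate-K identity (1e-8) and 200 BM replicates for the
K_mult mean (band [0.9, 1.1]); 200 replicates at a planted 4× clade rate
(median ratio in [3, 5], power > 0.8) plus 500 null replicates; 100
replicates at a planted 5× shift (> 80 % best-node recovery) and 100
fresh null replicates against the constructed cutoff. Micro-oracles
(Welch, OLS) are checked to 1e-10. These sizes were chosen as the
smallest that make the Monte-Carlo bands meaningful.

## Known limitations

- Alignment is greedy; an adversarial ordering of near-tolerance peaks
  could split or merge clusters that a global optimisation would not.
- NMDS axes feed the shift models as if independent and Gaussian; this is
  a modelling convention, not a property of NMDS output.
- Only one rate shift is searched; nested or multiple shifts are out of
  scope, as are OU/early-burst/lambda model families.
- The pipeline takes deconvolved peak lists as given; deconvolution and
  compound identification are upstream.
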