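# Methods

This note records the models implemented, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would want to know. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Occurrence data and environmental layers

Occurrences are CSV records `lineage,lon,lat[,year]`. Coordinates outside
[−180, 180] × [−90, 90] are rejected at read time with the offending row
number; no further coordinate cleaning is attempted. Records collected
strictly before a cutoff year (default **1990**) are dropped — old, often
misidentified collections are the usual motivation for such a cutoff —
but records with *missing* years are retained, since discarding undated
herbarium material would silently bias geographic coverage. The filter is
idempotent and applies uniformly to all sources.

Environmental layers are read as ESRI ASCII grids (one per variable); all
layers must share extent and resolution, and a cell that is nodata in any
layer is masked in all. The plain-text ASCII format was chosen as the
package's raster interchange format: it is human-inspectable, trivially
versioned, and sufficient for the single-CRS, no-reprojection scope of
this pipeline. Cell membership is half-open ([west, east) × [south,
north)), with points on the extreme east/north boundary assigned to the
last cell so the full extent is covered.

Before niche analysis, duplicate records (same lineage, same raster cell)
are collapsed to one per cell by default (`dedupe_by_cell`, toggleable).
Repeated collections from one cell add no environmental information and
would otherwise inflate the kernel density locally. Note this means the
*effective* per-lineage sample size entering the ordination is the number
of occupied cells, not the number of records.

Collinearity screening drops variables greedily until every retained pair
has Pearson |r| ≤ 0.70 (the conventional threshold): at each step the
variable with the largest mean |r| over currently offending pairs is
removed, ties dropping the later-listed variable so the input variable
order acts as a priority ranking. The greedy solution is checked against
exhaustive minimal drop-set search in the tests for engineered cases.

## Environment-space ordination and occupancy grids

The ordination is a PCA of the **standardized background** — every valid
raster cell, centered and scaled per variable — not of the occurrences.
This makes the axes describe available climate, so different lineages'
occupancy surfaces live in one common space. All axes are returned;
analyses use the first two. Axis signs are fixed by making each axis's
largest-|loading| element positive, so refits are bit-reproducible.

Occupancy grids: scores are binned on an R×R grid (default **R = 100**,
the convention for this family of analyses) spanning the background
scores per axis, expanded by a **5% margin** to avoid truncating kernels
whose mode sits on the envelope boundary. Densities use a Gaussian
product kernel with **per-axis normal-reference (Silverman) bandwidths
computed on the background** and reused for every occurrence density —
the point is comparability: all lineages (and all null replicates) are
smoothed identically. Occurrence scores falling outside the grid are
clipped to the boundary and logged.

Occupancy is `z = o / max(o)` by default (*uncorrected*), with the
availability-corrected variant `z = (o/e) / max(o/e)` (over cells with
e > 0) available by flag; the uncorrected form is the conventional
default for this family of analyses. The comparable quantity is
`p = z / Σz`.
One shared background is used for all lineages by default; per-lineage
backgrounds can be passed explicitly where a range-restricted similarity
null is wanted.

## Overlap, breadth, and the randomization tests

* **Schoener's D** = 1 − ½ Σ|p₁ − p₂|; both grids must be normalized to
  1 within 1e−6.
* **Levins' B** = 1 / Σp², normalized as (B−1)/(n_cells−1).
* **Equivalency** (exchangeability): pooled occurrence scores are
  repartitioned `reps` times (default **100**, matching the conventional
  null-distribution size) into pseudo-groups of the original sizes; grids
  are rebuilt with the *same* axes and bandwidths (the ordination is
  calibrated once on the background, so only group labels change across
  replicates) and p = (1 + #{D_null ≤ D_obs}) / (reps + 1). The test is
  **lower one-tailed**: non-equivalence is declared when observed overlap
  is significantly *below* the null. An `exhaustive=True` mode enumerates
  every partition for small pooled samples; the module also accepts a
  pluggable grid builder, which is how the test suite checks the
  permutation machinery against complete enumeration on a 2-cell space.
* **Similarity** (directional): the null relocates lineage b's observed
  score cloud — shape preserved — to centroids drawn uniformly from b's
  background envelope, clipping to the grid, and recomputes D against a's
  observed grid. Both one-sided p's are reported (p_similar, p_different)
  and the verdict at α = 0.05 is "Similar" / "Different" / "ns". A
  cruder point-resampling null is available behind a flag. The
  shape-preserving shift was chosen because it isolates *position* in
  climate space as the quantity being randomized; it is a documented
  design choice, not a claim about any particular historical
  implementation.
* The add-one p-value convention means p is never 0; with 100 replicates
  the smallest attainable p is 1/101 ≈ 0.0099. Verdicts use α = 0.05
  with no multiple-testing correction by default (a Bonferroni option
  exists), matching common practice for three pairwise comparisons.
* `compare_all` derives per-pair random streams from the seed and the
  *sorted pair labels* (CRC-mixed into a SeedSequence), so results are
  invariant to lineage input order.

Statistical behaviour verified by the acceptance suite: the equivalency
test's type-I error over 200 same-niche replicates (n = 50 per group,
100 permutations) stays near nominal α = 0.05; fully separated niches pin
p at 1/101 in every run; co-located niches earn "Similar" verdicts far
more often than antipodal ones over 100 scenario replicates.

At desk-scale sample sizes the equivalency test will *not* generally
reject for two lineages whose niche centroids differ by well under one
niche standard deviation (as in the default scenario's overlapping pair):
with ~40–50 occupied cells per lineage the observed D is statistically
indistinguishable from repartitioned pooled data. This is correct test
behaviour, not a defect; rejection for subtly different niches requires
sample sizes in the hundreds of occupied cells.

## Mk character evolution and ancestral states

The Mk1 model: all k states exchange at a single rate α with uniform
stationary frequencies; P(t) has the closed form
P_ii = 1/k + (k−1)/k·e^(−kαt), P_ij = (1 − e^(−kαt))/k. Likelihoods use
Felsenstein pruning with per-node rescaling (max-normalization,
accumulated in log space) and a **uniform 1/k root prior**. Missing tip
states contribute a ones-vector. Polytomies are handled as hard
multifurcations. Trees lacking branch lengths get all lengths set to 1.0
with a warning.

The rate is maximized over α ∈ [1e−8, 1e3] on a log₁₀ scale with
bounded Brent search (xatol 1e−8); an estimate within 1e−4 log units of a
bound is flagged (`rate_at_bound`), which is the expected outcome for
invariant characters. Marginal reconstructions combine each node's
downward partials with rest-of-tree partials propagated from the root
(the re-rooting formulation, valid because Mk is time-reversible); node
vectors are normalized and equal brute-force conditional probabilities on
all enumerable test trees. Marginal — not joint — reconstruction is
reported, matching per-node pie-chart style outputs.

Character handling: each character's alphabet is the **set of observed
states** (k = number observed). Lamella height is modelled as an
*unordered* Mk character over its observed states — the Mesquite-style
default for a "k-state" model — rather than an ordered/meristic model; a
state-mapping config supports binning (e.g. low ≤ 2 vs high > 2) when a
coarser coding is wanted. Both conventions are exposed because the
choice is genuinely open for meristic counts; the unordered default keeps
the model to its single parameter.

## Indel coding and haplotype networks

Simple indel coding: every distinct *internal* maximal gap span becomes
one binary character. A sequence scores present (1) when it has exactly
that span, missing (?) when one of its gap runs strictly contains the
span (the longer deletion makes the shorter event unobservable), absent
(0) otherwise; terminal gaps score missing for every character they
span. Coordinates are 1-based inclusive throughout.

Haplotype collapsing treats `-`, `N` and `?` as missing: sequences merge
when they conflict at no doubly-resolved position. Exact duplicates group
first; groups then merge greedily in order of decreasing multiplicity
(ties by lexicographic first id), consensus-resolving missing positions.
A group compatible with several mutually distinct haplotypes joins the
highest-multiplicity one (logged) — a deterministic resolution of a
genuinely ambiguous situation.

The network connects distance-1 pairs (missing-excluded Hamming) directly;
pairs at distance 2..limit are joined through d−1 hypothetical
intermediates only when not already connected, processing pairs by
ascending distance, then descending combined multiplicity, then id, so no
redundant long paths (loops through intermediates) are added. Intermediate
sequences mutate differing positions in left-to-right alignment order — a
determinism device, not a biological claim — and existing nodes with the
same sequence are reused. The **connection limit is a plain integer
(default 10)** rather than the 95% statistical-parsimony probability
bound: observed networks in this problem involve a handful of steps, and
a fixed auditable limit avoids re-deriving the probability estimator
(explicitly out of scope, as is loop resolution).

## Synthetic data

`make_env_rasters` smooths white noise with a Gaussian filter (default
radius 6 cells on an 80×80 grid) and standardizes each layer; optional
mixing injects a known pairwise correlation. Ten layers emulate a
bioclim-style stack. `sample_occurrences` draws raster cells with
probability ∝ exp(−½(env−μ)ᵀΣ⁻¹(env−μ)) — suitability Gaussian in
*environment* space, the niche concept the ordination assumes — and
jitters coordinates within cells; collection years are 1990–2015 with 10%
missing, so default runs are not distorted by the year filter while the
missing-year policy still gets exercised.

The default scenario uses three lineages — two with strongly overlapping
niches (centroids 0.36 standardized environmental units apart, niche σ =
0.35) and one distinct — with sample sizes 100/300/100; the widespread,
densely collected lineage is one of the overlapping pair, mirroring the
typical invasive-species situation. Ground truth (centroids, sample
sizes, which pair overlaps) is attached for downstream assertions.

What the generator does **not** emulate: real climate layers' strong
mutual correlation (synthetic layers are near-independent unless
correlations are injected, so the first two PCA axes explain ~35–40%
rather than the high fractions typical of real bioclim stacks); spatial
sampling bias; coordinate error; microsatellite/inversion features of
real spacer sequences; and rate heterogeneity across characters. Passing
tests therefore demonstrate correctness of the statistical machinery
under known truth, not field realism of any particular dataset.

`simulate_mk_characters` evolves states root-to-tips with the same
closed-form transition used by the likelihood; `make_toy_alignment`
builds a haplotype chain by sequential point mutations at fresh positions
(avoiding indel spans and alignment ends), then applies indels and copy
numbers, returning the expected haplotype map and SIC spans.

## Problem sizes and numerical choices

The acceptance script and test suite run at sizes chosen for a laptop
CPU: R = 100 grids, 100-replicate nulls, 200-replicate calibration
studies, brute-force enumeration confined to trees of ≤ 6 tips and k ≤ 4
and to 6-point permutation spaces, and rate recovery from 500 characters
(11 simulation replicates). Randomization tests cache the fixed
background density across replicates (`precomputed_e`), which is what
makes the calibration studies cheap. Normalization tolerances: occupancy
grids must sum to 1 within 1e−6 at the D interface; PCA explained
fractions sum to 1 within 1e−9; pruning vs enumeration agrees to 1e−9
and re-rooting to 1e−10 in tests. All stochastic code takes either an
integer seed or a `numpy.random.Generator`; every CLI run records its
effective parameters, seed and a config hash in `run_log.json`.

## Known limitations

* No geographic-space projection of niches, no SDM/MaxEnt suitability
  modelling, no niche-dynamics indices; single CRS assumed.
* No tree inference or substitution-model selection; trees are inputs.
* The equivalency/similarity tests inherit kernel-grid discretization:
  p-values at different R are close but not identical (doubling R moves
  D by < 0.02 on smooth cases, per the tests).
* Ordered/meristic Mk variants are out of scope (state binning is the
  supported coarsening).
* The network builder does not resolve ambiguous loops and does not
  compute the statistical-parsimony connection probability.
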