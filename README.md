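# ecodelim

Integrative species delimitation asks whether putative lineages — say,
cryptic molecular clades inside a morphologically messy species complex —
differ enough in ecology, morphology and molecules to be recognized as
separate species. `ecodelim` implements the quantitative core of such an
analysis for georeferenced occurrence data, climate layers, aligned
sequences and dated trees:

* **Niche quantification and comparison in environment space.** A PCA is
  calibrated on the *whole environmental background* of the study area
  (every raster cell, standardized), occurrences are projected onto the
  first two axes, and each lineage's occupancy of climate space is
  estimated by Gaussian kernel smoothing on an R×R grid. Overlap between
  lineages is Schoener's

  *D* = 1 − ½ Σ<sub>cells</sub> |p₁ − p₂| ∈ [0, 1],

  breadth is Levins' inverse concentration *B* = 1 / Σ p², and two
  randomization tests attach significance: the **equivalency** test
  (pooled occurrences repartitioned; niches non-equivalent when observed
  *D* falls in the lower tail of the null) and the directional
  **similarity** test (the focal lineage's occurrence cloud relocated
  uniformly within its available environment; observed *D* compared to
  both tails).

* **Mk ancestral state reconstruction.** Discrete morphological
  characters (e.g. hairpoint orientation: absent/erect/reflexed; lamella
  height in cell rows) evolve under the one-parameter Markov k-state
  model, P<sub>ii</sub>(t) = 1/k + (k−1)/k·e^(−kαt). The single rate α is
  ML-estimated by bounded search, likelihoods use Felsenstein pruning with
  a uniform root prior, and per-node marginal posteriors are reported for
  every internal node of fixed input trees.

* **Indel coding and haplotype networks.** Alignment gaps become binary
  characters under simple indel coding (identical spans = present;
  strictly containing gaps = missing), and haplotypes (gaps treated as
  missing data) are joined into a statistical-parsimony style network with
  hypothetical single-step intermediates up to a connection limit.

* **A ground-truthed synthetic data generator** — spatially
  autocorrelated climate rasters, lineages with Gaussian niches in
  environment space, Mk-evolved characters, and toy alignments with known
  haplotype and indel structure — so the full pipeline is testable without
  any external downloads.

## Worked example

Generate the default synthetic scenario (three lineages: A and B with
strongly overlapping Gaussian niches, C distinct; 100/300/100 records on
ten autocorrelated climate layers) and run the niche workflow:

```bash
ecodelim simulate --seed 11 --out demo
ecodelim niche --occurrences demo/occurrences.csv \
    $(for f in demo/*.asc; do echo --rasters $f; done) \
    --grid-size 100 --reps 100 --seed 11 --out demo/niche
```

which prints (and writes to `demo/niche/niche_comparisons.csv`):

```
lineage_a lineage_b        D  similarity_ab_p similarity_ab_verdict  similarity_ba_p similarity_ba_verdict  equivalency_p       equivalency_verdict
 lineageA  lineageB 0.756229         0.009901               Similar         0.009901               Similar       0.168317 Equivalent (not rejected)
 lineageA  lineageC 0.145374         0.118812                    ns         0.108911                    ns       0.009901                 Different
 lineageB  lineageC 0.217107         0.039604               Similar         0.099010                    ns       0.009901                 Different
```

Reading the table: the engineered overlapping pair A–B shows the highest
overlap (D = 0.76) and is significantly *similar* in both directions —
each niche sits closer to the other than a randomly placed niche of the
same shape would.  The distinct lineage C overlaps little with either
(D ≤ 0.22), and equivalency is rejected (p = 1/101, the smallest
attainable value at 100 replicates) for both pairs involving C.  The
B→C comparison is significantly similar in one direction only, a pattern
that arises when one lineage's niche is nested in the climate envelope
available to the other.  `niche_breadth.csv` adds Levins' B per lineage
(here B = 398, 599 and 260 effective cells — the densely sampled lineage
B occupies the broadest slice of climate space), and
`pca_loadings.csv` records per-axis loadings and explained variance
(34.8% on the first two axes for these synthetic layers).

The phylogenetic workflow runs analogously:

```bash
ecodelim phylo --alignment demo/alignment.fasta --tree demo/tree.nwk \
    --characters demo/characters.csv --out demo/phylo
```

writing the SIC-augmented NEXUS alignment, the haplotype network
(GraphML + DOT) and per-node marginal state probabilities for each
character on each tree.

## Layout

```
src/ecodelim/
  io_env.py         occurrences, ESRI ASCII rasters, year filter, collinearity
  env_space.py      background-calibrated PCA, kernel occupancy grids
  niche_stats.py    Schoener's D, Levins' B, equivalency & similarity tests
  char_evolution.py Mk1 likelihood, rate ML, marginal ASR, NEXUS export
  indel_haplo.py    simple indel coding, haplotype collapsing, networks
  synthetic_data.py ground-truthed generators for all of the above
  cli.py            niche / phylo / simulate subcommands
docs/methods.md     model assumptions, defaults, numerical choices
```
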