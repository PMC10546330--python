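# Methods

## Model and assumptions

The pipeline treats a molecular interaction network as the medium through
which two species' GWAS signals are compared. Its core assumptions are:

- **Propagation.** Trait-associated genes cluster in network neighborhoods,
  so diffusing unit heat from each seed gene by random walk with restart
  (RWR) ranks genes by proximity to the whole seed set. The closed form
  `F = (I − αW)⁻¹(1−α)Y₀` is solved with a sparse LU factorization of
  `I − αW` (tolerance at machine precision; the factorization is reused for
  every null draw). `W` is column-normalized, so on graphs without isolated
  nodes total heat is conserved (`ΣF` = number of in-network seeds); isolated
  nodes are permitted but flagged, since their all-zero columns leak heat.
  The dissipation constant defaults to α = 0.5.
- **Degree-matched null.** Raw heat is dominated by degree, so each gene's
  log-heat is z-scored against 1,000 propagations of random seed sets drawn
  bin-wise from genes of similar degree (sort by degree, fill bins greedily
  to ≥10 genes, never splitting equal-degree genes when avoidable, merging a
  short trailing bin). Natural log is used throughout (the base cancels in
  the z-score if applied consistently). Genes with zero heat in the
  observation or any null draw get NaN and are excluded downstream —
  a pseudo-count would manufacture signal. The recommended substrate is the
  network's largest connected component.
- **Co-localization.** The combined score is the per-gene product of the two
  species' z-scores. Products, not sums, so a gene must be proximal to
  *both* seed sets to score high; negative products are retained (they mark
  discordance). Thresholds are strict inequalities: conserved
  (`NPS_ab > 3`, both singles > 1), a-specific (`NPS_a > 1.5`, `NPS_b < 0`,
  `NPS_a(NPS_b−1) < −4`), b-specific (`NPS_b > 1`, `NPS_a < 0.5`,
  `NPS_b(NPS_a−1) < −2`), expanded (`NPS_a > 1.5` or `NPS_b > 1`). The
  asymmetry in the two specific formulas reflects the species' different
  score spreads; all six cutoffs are configurable.
- **Permutation significance.** One species' scores are shuffled across
  genes within two strata — genes that were seeds in both species (whose
  combined scores are expected high a priori) and all others — 10,000 times;
  subnetwork size and mean combined score are z-tested against the null
  (one-sided upper tail). The empirical permutation p is reported alongside.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.5 | RWR dissipation (restart) probability |
| `n_null` | 1000 | degree-matched null propagations per species |
| `min_bin` | 10 | minimum genes per degree bin |
| `max_seeds` / `n_reps` / `percentile` | 500 / 100 / 75 | weighted-subsampling consensus for large seed sets (linear-interpolation percentile) |
| `n_perm` | 10000 | label permutations for subnetwork significance |
| `window_bp` | 10000 | SNP-to-gene assignment window (1-based inclusive ends) |
| `min_databases` | 3 | ortholog support filter; support ties are dropped, not broken |
| `max_resolution` / `n_steps` / `r_min` | 10 / 20 / 0.1 | geometric Louvain resolution grid |
| `jaccard_min` / `min_persistence` | 0.75 / 5 | cross-resolution community matching |
| `sigma` | 0.75 | containment-index threshold for hierarchy edges (strict) |
| `min_size` | 5 (conserved map), 11 (expanded map) | community size filter |
| `max_dist_bp` | 250000 | locus-independence QC distance (gap between gene spans) |
| `fdr` | 0.05 | BH level inside the ontology traversal |

The hierarchy defaults (`jaccard_min`, `min_persistence`, `n_steps`,
`r_min`, `sigma`) are this package's declared choices in the spirit of
persistence-based multiscale detection; only the maximum resolution is
externally fixed. Louvain runs are seeded, take the best modularity of 3
restarts, and equal-size mutually-contained communities are merged to keep
the size ordering acyclic before transitive reduction.

## What the synthetic generator emulates — and what it does not

`SyntheticConfig` defaults define the study conditions: 2,000 genes, mean
degree 10, a 100-gene planted trait module, 40 seed genes per species of
which half are module members, 10% ortholog ambiguity, a 40-term / 4-branch
ontology whose first branch is annotated with module genes at 10× the
background rate, and one background annotation per phenotyped gene (80% of
genes are phenotyped).

Two design choices deserve emphasis:

- **The planted module is degree-balanced.** Module genes trade external for
  internal edges (80% of their expected degree inside the module), so module
  membership is orthogonal to degree. This is deliberate: the degree-matched
  null is designed to explain away pure-degree signal, so a module of hubs
  (e.g. internal probability 0.2 on top of background degree) is largely
  absorbed by its own null — we verified that conserved-network recall drops
  to ~0.03 in that regime. A real "true trait pathway" detectable by this
  method is precisely one whose cohesion is not reducible to degree.
- **Null calibration uses per-species networks.** When both species are
  propagated on one shared network, their NPS fields are spatially
  autocorrelated on the same topology, and the label-permutation null (which
  treats genes as exchangeable) understates the variance of the subnetwork
  size — we measured type-I rates of 0.08–0.11 at nominal 0.05, worse with a
  planted dense region. With each species scored on its own network
  realization — the cross-species reality, where the two interactomes differ
  — the size z-test rejects at 0.05 and the empirical permutation p at 0.03.
  Users applying the test to two seed sets on one shared interactome should
  regard the z-test p as mildly anticonservative.

What the generator does **not** emulate: linkage disequilibrium and SNP-level
association structure (gene-level p-values are drawn directly: uniform on
(0, threshold] for seeds, (threshold, 1] otherwise), overlapping pathway
structure (one module, not many), weighted or directed edges, and realistic
annotation multiplicity (real phenotype databases annotate genes to many
terms; here one background term per gene keeps ontology branches
unsaturated at this 40-term scale). Passing tests therefore demonstrate the
machinery's correctness and calibration under controlled conditions, not
performance on any real interactome.

## Numerical and procedural choices

- Linear solves (sparse LU), never explicit inverses; heats clipped at 0 to
  absorb −1e−25-scale round-off on far nodes.
- Percentiles use linear interpolation between order statistics.
- SNP-to-gene windows are inclusive at both ends; duplicate gene rows
  collapse to min(start), max(end); lead-SNP ties break to the smallest
  position; Bonferroni uses the number of tested genes in the input table.
- Fisher tests are one-sided ("greater"); the odds ratio is the sample
  ad/bc (+inf when bc = 0 and ad > 0, NaN when both vanish). The universe
  for annotation-based tests is the phenotyped genes; for composition tests,
  all network genes.
- Ontology traversal keeps a child iff its PPV strictly exceeds the
  parent's **and** its BH-adjusted p (within that parent's child set) is
  below the FDR level; only kept children are expanded. The PPV is
  normalized by the phenotype gene set (it rewards coverage of a phenotype),
  which differs from the conventional precision definition — kept
  deliberately, as it is the statistic the traversal is defined over.
- With several null sibling branches, BH within a sibling set controls the
  false-discovery rate, not the family-wise error: the chance that *some*
  null sibling is kept in a given traversal is ≈ the nominal level times the
  number of null siblings × ¾. Branch-level specificity claims should be
  read accordingly.
- The permutation report's observed/expected ratio uses the null mean size;
  its 95% band comes from the 2.5/97.5 percentiles of observed/null-draw
  ratios (infinite when a null draw is empty).

## Problem sizes

Default test and acceptance runs use 2,000-gene networks with 500–1,000
nulls, 500–10,000 permutations, 200-dataset calibration batches at 1,000
genes with 100 nulls, and 20-replicate recovery batches — sizes chosen so a
full run is interactive on one CPU (the factorized solver makes each null
propagation a single triangular solve). All stages accept larger inputs
unchanged.

## Known limitations

- The z-test on permutation nulls of *counts* is slightly anticonservative
  for small expected subnetwork sizes (right-skewed null); the empirical p
  is reported for exactly this reason.
- Shared-network co-localization inherits the autocorrelation caveat above.
- Louvain at high resolution fragments even cliques; fragments are unstable
  across resolutions and are removed by the persistence filter, so leaf
  communities are trustworthy but single-resolution partitions are not
  exposed.
- Ortholog resolution drops support ties rather than breaking them;
  coverage is traded for determinism.
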