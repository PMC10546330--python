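# crossloc — cross-species GWAS network co-localization

GWAS of the same trait in two species (say, human and rat body-mass index)
rarely implicate the same genes: each study yields a mixture of true and
false positives, and true hits may be different members of one shared
pathway. `crossloc` asks whether the two species' association signals
nevertheless converge on the same *neighborhoods* of a molecular interaction
network, and maps the shared biology when they do.

The pipeline:

1. **Seed mapping.** SNP-level results are collapsed to gene-level p-values
   (each gene takes the lowest p of any variant within ±10 kb of its span);
   genes passing a significance threshold become that species' *seed genes*,
   weighted by −log₁₀ p. Cross-species identifiers are reconciled through an
   ortholog table, requiring support from ≥3 databases and dropping ties.
2. **Propagation.** Seeds are diffused over the network by random walk with
   restart: `F = (I − αW)⁻¹ (1−α) Y₀`, with `W` the column-normalized
   adjacency matrix, `Y₀` the seed indicator and `α = 0.5`. Each gene's
   **network proximity score** (NPS) is the z-score of its log-heat against
   1,000 random seed sets matched to the observed set's size and degree
   profile (genes binned by degree, ≥10 per bin). Seed sets larger than 500
   genes are handled by repeated weighted subsampling with a per-gene
   75th-percentile consensus.
3. **Co-localization.** With per-species scores `NPS_a` and `NPS_b`, the
   combined score is the product `NPS_ab = NPS_a ∘ NPS_b`. The *conserved*
   subnetwork collects genes with `NPS_ab > 3`, `NPS_a > 1`, `NPS_b > 1`;
   species-specific and expanded subnetworks use the analogous asymmetric
   formulas. Significance of conserved size and mean `NPS_ab` comes from a
   z-test against 10,000 label permutations of one species' scores
   (dual-seed genes permuted among themselves).
4. **Systems map.** The conserved subnetwork is decomposed by Louvain
   modularity across a geometric grid of resolutions (up to 10); communities
   recurring across ≥5 resolutions (Jaccard ≥ 0.75) are nested by the
   containment index `CI(v,w) = |s(v)∩s(w)| / |s(w)|` (> 0.75) into a
   transitively reduced DAG.
5. **Phenotype validation.** Communities are tested against a phenotype
   ontology: Fisher odds ratios, validation rates (fraction of phenotyped
   genes with a trait-relevant annotation after propagating annotations up
   the DAG), and a top-down traversal keeping child terms whose
   phenotype-normalized PPV `= |community∩phenotype| / |phenotype|` exceeds
   the parent's, with Benjamini–Hochberg correction within each sibling set.

Because the original data products (interactomes, GWAS summary statistics,
phenotype databases) are large external downloads, the package ships a
synthetic-data module that generates networks with a planted trait module,
two species' seed sets, a noisy ortholog map and an annotated ontology — so
every stage is testable end to end on a laptop.

## Worked example

Library use:

```python
from crossloc import run_pipeline

result = run_pipeline(seed=1, n_null=1000, n_perm=10_000)
print(result.summary)
```

Or as numbered analysis steps (equivalently via the `crossloc` CLI):

```bash
python analysis/01_simulate.py 1     # write synthetic dataset to results/data
python analysis/02_map_seeds.py 1    # threshold + ortholog-map both species
python analysis/03_propagate.py 1    # NPS per species, 1,000 nulls
python analysis/04_colocalize.py 1   # subnetworks + permutation test
python analysis/05_communities.py 1  # multiscale systems map
python analysis/06_enrichment.py 1   # phenotype enrichment + traversal
```

Output of steps 02 and 04 on the default dataset (seed 1):

```
seeds: a=40, b mapped=34 (of 1746 resolvable orthologs); overlap=7, hypergeometric p=2.69e-06
conserved: 85 genes (70 from the planted module)
a_specific: 20 genes (0 from the planted module)
b_specific: 107 genes (0 from the planted module)
expanded: 368 genes (97 from the planted module)
conserved size 85: z=14.75, p=1.53e-49; obs/exp=3.24 [2.50, 4.47]
```

Read: of the 100-gene planted module, the conserved subnetwork recovered 70
genes among its 85 members (recall 0.70, precision 0.82) although only 20
seed genes per species were true module members and only 7 seeds were shared
between species — the co-localization signal lives in the network
neighborhood, not in the raw gene overlap. The conserved network is 3.2×
larger than expected under label permutation (z = 14.8). The species-specific
subnetworks contain no module genes, as they should.

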