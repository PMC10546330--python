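"""End-to-end driver: simulate -> map -> propagate x2 -> colocalize -> communities -> enrich.

Chains the library modules on synthetic (or user-supplied) inputs and
collects every intermediate product in a single result object.  All
randomness flows from one integer seed, so a run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import colocalization as coloc
from . import enrichment as enr
from . import hierarchy as hier
from . import propagation as prop
from . import seed_mapping as sm
from . import synthetic as syn
from .ontology import AnnotationSet, PhenotypeOntology


@dataclass
class PipelineResult:
    network: nx.Graph
    truth: syn.SyntheticTruth
    ontology: PhenotypeOntology
    annotations: AnnotationSet
    seeds_a: sm.SeedGeneSet
    seeds_b_mapped: sm.SeedGeneSet
    ortholog_map: sm.OrthologMap
    nps_a: prop.NPSTable
    nps_b: prop.NPSTable
    combined: coloc.CombinedNPS
    conserved: coloc.SubnetworkResult
    a_specific: coloc.SubnetworkResult
    b_specific: coloc.SubnetworkResult
    expanded: coloc.SubnetworkResult
    permutation: coloc.PermutationReport
    hierarchy: hier.CommunityHierarchy | None
    overlap: tuple
    summary: dict = field(default_factory=dict)


def map_species_b_seeds(
    gene_table_b: pd.DataFrame,
    ortholog_pairs: pd.DataFrame,
    threshold: float,
    min_databases: int = 3,
) -> tuple[sm.SeedGeneSet, sm.OrthologMap]:
    """Threshold species-b gene-level p-values and translate to shared ids."""
    seeds_b_native = sm.define_seed_set(gene_table_b, threshold, species="b")
    omap = sm.resolve_orthologs(ortholog_pairs, min_databases=min_databases)
    translated = {
        omap.resolved[g]: w for g, w in seeds_b_native.weights.items() if g in omap.resolved
    }
    if not translated:
        raise sm.SeedMappingError("no species-b seed survived ortholog mapping")
    mapped = sm.SeedGeneSet(
        species="b",
        genes=set(translated),
        weights=translated,
        threshold_used=threshold,
    )
    return mapped, omap


def run_pipeline(
    config: syn.SyntheticConfig | None = None,
    seed: int = 0,
    alpha: float = 0.5,
    n_null: int = 1000,
    n_perm: int = 10_000,
    max_seeds: int = 500,
    n_reps: int = 100,
    min_databases: int = 3,
    detect_communities: bool = True,
    hierarchy_kwargs: dict | None = None,
) -> PipelineResult:
    """Run the whole analysis on one synthetic dataset.

    ``seed`` reseeds the synthetic configuration and every stochastic stage
    (null ensembles, permutations, community detection).
    """
    if config is None:
        config = syn.SyntheticConfig(rng_seed=seed)
    else:
        config = syn.SyntheticConfig(**{**config.__dict__, "rng_seed": seed})
    network, truth, ontology, annotations = syn.generate_all(config)

    seeds_a = sm.define_seed_set(truth.gene_table_a, config.seed_p_threshold, species="a")
    seeds_b, omap = map_species_b_seeds(
        truth.gene_table_b, truth.ortholog_map, config.seed_p_threshold, min_databases
    )
    overlap = sm.seed_overlap_test(seeds_a.genes, seeds_b.genes, network.number_of_nodes())

    propagator = prop.Propagator(network, alpha=alpha)
    rng = np.random.default_rng(seed + 10)

    def score(seed_set: sm.SeedGeneSet, species: str) -> prop.NPSTable:
        records = pd.DataFrame(
            {"gene_id": sorted(seed_set.genes), "p": [10 ** -seed_set.weights[g] for g in sorted(seed_set.genes)]}
        )
        return prop.consensus_nps(
            propagator,
            records,
            max_seeds=max_seeds,
            n_reps=n_reps,
            n_null=n_null,
            rng_seed=rng,
            species=species,
        )

    nps_a = score(seeds_a, "a")
    nps_b = score(seeds_b, "b")
    combined = coloc.combine(nps_a, nps_b)
    conserved = coloc.select_conserved(combined, network=network)
    a_spec = coloc.select_species_specific(combined, "a", network=network)
    b_spec = coloc.select_species_specific(combined, "b", network=network)
    expanded = coloc.select_expanded(combined, network=network)
    permutation = coloc.permutation_test(
        combined, selector=coloc.conserved_mask, n_perm=n_perm, rng_seed=seed + 20
    )

    hierarchy = None
    if detect_communities and conserved.genes:
        sub = network.subgraph(conserved.genes)
        kwargs = dict(rng_seed=seed + 30)
        kwargs.update(hierarchy_kwargs or {})
        communities = hier.detect_multiscale(sub, **kwargs)
        if communities:
            lcc_nodes = max(nx.connected_components(sub), key=lambda c: (len(c), sorted(c)[0]))
            hierarchy = hier.build_hierarchy(communities, all_genes=set(lcc_nodes))
            hierarchy = hier.filter_communities(hierarchy, min_size=5)

    module = truth.module_genes
    universe = set(network.nodes())
    module_enrichment = enr.fisher_enrichment(
        conserved.genes, module, universe, unit_id="conserved", term_id="planted_module"
    )
    vrate = enr.validation_rate(conserved.genes, annotations, truth.trait_terms)
    recall = len(conserved.genes & module) / len(module) if module else float("nan")
    precision = (
        len(conserved.genes & module) / len(conserved.genes) if conserved.genes else float("nan")
    )
    summary = {
        "n_genes": network.number_of_nodes(),
        "n_edges": network.number_of_edges(),
        "n_seeds_a": len(seeds_a.genes),
        "n_seeds_b": len(seeds_b.genes),
        "seed_overlap": overlap[0],
        "seed_overlap_p": overlap[1],
        "conserved_size": len(conserved.genes),
        "a_specific_size": len(a_spec.genes),
        "b_specific_size": len(b_spec.genes),
        "expanded_size": len(expanded.genes),
        "module_recall": recall,
        "module_precision": precision,
        "module_enrichment_or": module_enrichment.odds_ratio,
        "module_enrichment_p": module_enrichment.p,
        "validation_rate": vrate,
        "n_communities": (
            sum(1 for c in hierarchy.communities if c.id != hier.ROOT_ID) if hierarchy else 0
        ),
        **{f"perm_{k}": v for k, v in permutation.to_dict().items() if k != "n_perm"},
    }
    return PipelineResult(
        network=network,
        truth=truth,
        ontology=ontology,
        annotations=annotations,
        seeds_a=seeds_a,
        seeds_b_mapped=seeds_b,
        ortholog_map=omap,
        nps_a=nps_a,
        nps_b=nps_b,
        combined=combined,
        conserved=conserved,
        a_specific=a_spec,
        b_specific=b_spec,
        expanded=expanded,
        permutation=permutation,
        hierarchy=hierarchy,
        overlap=overlap,
        summary=summary,
    )
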