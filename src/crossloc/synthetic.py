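"""Synthetic benchmark data with the statistical structure the pipeline assumes.

The generator plants a single densely connected "true trait module" in a
degree-heterogeneous interaction network, draws two species' GWAS seed sets
as mixtures of module genes and background false positives, produces a noisy
many-to-many ortholog map between the species' identifier spaces, and builds
a small phenotype ontology whose trait branch is preferentially annotated
with module genes.  Every downstream stage of the pipeline is exercisable on
this output without any external download.

Defaults emulate the cross-species GWAS setting at desk scale: a couple of
thousand genes, a 100-gene trait module, tens of seed genes per species of
which about half are true module members.  In the stochastic-block model the
planted module is degree-balanced by default — module genes trade external
for internal edges so that their expected total degree matches the
background.  This keeps module membership orthogonal to degree, which is the
regime the degree-matched propagation null is designed for; a module of
hubs would be partially explained away by the null, as it should be.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .ontology import PhenotypeOntology, propagate_annotations

SPECIES_B_PREFIX = "b:"


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    n_genes: int = 2000
    edge_model: str = "stochastic_block"  # scale_free | configuration | stochastic_block
    mean_degree: float = 10.0
    module_size: int = 100
    seed_size_a: int = 40
    seed_size_b: int = 40
    module_fraction_a: float = 0.5
    module_fraction_b: float = 0.5
    ortholog_ambiguity_rate: float = 0.1
    n_terms: int = 40
    annotation_enrichment: float = 10.0
    rng_seed: int = 0
    # stochastic-block edge probabilities; None -> degree-balanced defaults
    module_p_in: float | None = None
    module_p_out: float | None = None
    internal_degree_fraction: float = 0.8  # of a module gene's expected degree
    seed_p_threshold: float = 1e-4
    n_chromosomes: int = 20
    base_annotation_rate: float = 0.05  # background trait-branch annotation
    background_annotations_per_gene: int = 1
    phenotyped_fraction: float = 0.8

    def __post_init__(self):
        if self.n_genes < 10:
            raise SyntheticError("n_genes must be >= 10")
        if not 0 < self.module_size <= self.n_genes:
            raise SyntheticError("module_size must be in 1..n_genes")
        for s in (self.seed_size_a, self.seed_size_b):
            if not 0 < s <= self.n_genes:
                raise SyntheticError("seed sizes must be in 1..n_genes")
        for r in (
            self.module_fraction_a,
            self.module_fraction_b,
            self.ortholog_ambiguity_rate,
        ):
            if not 0 <= r <= 1:
                raise SyntheticError("rates and fractions must lie in [0, 1]")
        if self.mean_degree <= 0 or self.mean_degree >= self.n_genes:
            raise SyntheticError("mean_degree must be in (0, n_genes)")
        if self.n_terms < 2:
            raise SyntheticError("n_terms must be >= 2")
        if self.annotation_enrichment < 1:
            raise SyntheticError("annotation_enrichment must be >= 1")


@dataclass
class SyntheticTruth:
    module_genes: set
    seeds_a: set  # species-a gene ids
    seeds_b: set  # species-b ("b:"-prefixed) gene ids
    ortholog_map: pd.DataFrame = None
    gene_pvalues_a: dict = field(default_factory=dict)
    gene_pvalues_b: dict = field(default_factory=dict)
    annotations: set = field(default_factory=set)
    gene_table_a: pd.DataFrame = None  # gene_id, chrom, start, end, p
    gene_table_b: pd.DataFrame = None
    trait_terms: set = field(default_factory=set)

    @property
    def seeds_b_on_a(self) -> set:
        """Species-b seeds translated to the shared identifier space (truth)."""
        return {g[len(SPECIES_B_PREFIX):] for g in self.seeds_b}


def gene_ids(n: int) -> list:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def _bernoulli_edges(rng, left, right, p, symmetric):
    """Sparse Bernoulli edge sampling between two node lists."""
    edges = []
    if p <= 0:
        return edges
    if symmetric:
        n = len(left)
        # geometric skipping over the upper triangle
        total = n * (n - 1) // 2
        k = rng.binomial(total, p)
        if k:
            flat = rng.choice(total, size=k, replace=False)
            # map flat index to (i, j), i < j
            i = (np.floor((2 * n - 1 - np.sqrt((2 * n - 1) ** 2 - 8 * flat)) / 2)).astype(int)
            j = (flat - i * (2 * n - 1 - i) // 2 + i + 1).astype(int)
            edges = [(left[a], left[b]) for a, b in zip(i, j)]
    else:
        total = len(left) * len(right)
        k = rng.binomial(total, p)
        if k:
            flat = rng.choice(total, size=k, replace=False)
            i, j = np.divmod(flat, len(right))
            edges = [(left[a], right[b]) for a, b in zip(i, j)]
    return edges


def generate_network(config: SyntheticConfig, rng: np.random.Generator | None = None) -> nx.Graph:
    """Simple undirected gene network under the configured edge model.

    ``stochastic_block`` (the default) plants a module of
    ``config.module_size`` genes with elevated internal edge probability; the
    chosen module is recorded in ``graph.graph['module_genes']`` and is made
    connected (a spanning link is added between components if the random
    draw left it fragmented, which at the default densities is rare).
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    ids = gene_ids(config.n_genes)
    n = config.n_genes
    if config.edge_model == "scale_free":
        m = max(1, round(config.mean_degree / 2))
        if m >= n:
            raise SyntheticError("mean_degree too large for scale_free model")
        g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31 - 1)))
        g = nx.relabel_nodes(g, dict(enumerate(ids)))
    elif config.edge_model == "configuration":
        deg = rng.poisson(config.mean_degree, size=n)
        deg[deg >= n] = n - 1
        if deg.sum() % 2:
            deg[int(np.argmin(deg))] += 1
        try:
            raw = nx.configuration_model(deg.tolist(), seed=int(rng.integers(2**31 - 1)))
        except nx.NetworkXError as exc:  # infeasible degree sequence
            raise SyntheticError(f"infeasible degree sequence: {exc}") from exc
        g = nx.Graph(raw)
        g.remove_edges_from(nx.selfloop_edges(g))
        g = nx.relabel_nodes(g, dict(enumerate(ids)))
    elif config.edge_model == "stochastic_block":
        module = sorted(rng.choice(ids, size=config.module_size, replace=False))
        background = [x for x in ids if x not in set(module)]
        k_in = config.internal_degree_fraction * config.mean_degree
        p_in = config.module_p_in
        if p_in is None:
            p_in = min(1.0, k_in / max(config.module_size - 1, 1))
        p_bg = min(1.0, config.mean_degree / (n - 1))
        p_ext = config.module_p_out
        if p_ext is None:
            p_ext = min(1.0, (config.mean_degree - k_in) / max(n - config.module_size, 1))
            p_ext = max(p_ext, 0.0)
        g = nx.Graph()
        g.add_nodes_from(ids)
        g.add_edges_from(_bernoulli_edges(rng, module, None, p_in, symmetric=True))
        g.add_edges_from(_bernoulli_edges(rng, background, None, p_bg, symmetric=True))
        g.add_edges_from(_bernoulli_edges(rng, module, background, p_ext, symmetric=False))
        # guarantee the planted module induces a connected subgraph
        comps = sorted(nx.connected_components(g.subgraph(module)), key=lambda c: sorted(c)[0])
        for c1, c2 in zip(comps, comps[1:]):
            g.add_edge(sorted(c1)[0], sorted(c2)[0])
        g.graph["module_genes"] = set(module)
        g.graph["p_in"], g.graph["p_out"] = p_in, p_ext
    else:
        raise SyntheticError(f"unknown edge_model {config.edge_model!r}")
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def _gene_coordinates(ids: list, n_chromosomes: int) -> pd.DataFrame:
    """Synthetic coordinates: genes laid out sequentially across chromosomes,
    20 kb spans separated by 80 kb gaps."""
    rows = []
    per_chrom = int(np.ceil(len(ids) / n_chromosomes))
    for i, gene in enumerate(ids):
        chrom = f"chr{i // per_chrom + 1}"
        start = (i % per_chrom) * 100_000 + 1
        rows.append((gene, chrom, start, start + 19_999))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def _draw_pvalues(rng, ids, seeds, threshold):
    # seeds uniform on (0, threshold], background uniform on (threshold, 1]
    p = {}
    for g in ids:
        u = rng.random()
        if g in seeds:
            p[g] = threshold * (1.0 - u)  # in (0, threshold]
            p[g] = p[g] if p[g] > 0 else threshold
        else:
            p[g] = threshold + (1.0 - threshold) * (1.0 - u)
    return p


def generate_seed_sets(
    network: nx.Graph, config: SyntheticConfig, rng: np.random.Generator | None = None
) -> SyntheticTruth:
    """Two species' seed sets as module/background mixtures, with p-values.

    Species x draws ``round(module_fraction_x * seed_size_x)`` genes from the
    planted module and fills the rest uniformly from the remaining genes.
    Gene-level p-values straddle ``config.seed_p_threshold`` so that seeds
    (and only seeds) survive thresholding downstream.  Species-b identifiers
    carry the ``b:`` prefix, making ortholog mapping a real step.
    """
    rng = np.random.default_rng(config.rng_seed + 1) if rng is None else rng
    ids = sorted(network.nodes())
    module = network.graph.get("module_genes")
    if module is None:
        # carve a connected module by breadth-first growth from a random gene
        start = ids[int(rng.integers(len(ids)))]
        module = set()
        for node in nx.bfs_tree(network, start):
            module.add(node)
            if len(module) >= config.module_size:
                break
        if len(module) < config.module_size:
            raise SyntheticError("network component too small for the planted module")
    module = set(module)

    def one_species(seed_size, fraction):
        n_mod = round(fraction * seed_size)
        if n_mod > len(module):
            raise SyntheticError("module_fraction * seed_size exceeds module_size")
        picked = set(rng.choice(sorted(module), size=n_mod, replace=False))
        pool = sorted(set(ids) - picked)
        picked |= set(rng.choice(pool, size=seed_size - n_mod, replace=False))
        return picked

    seeds_a = one_species(config.seed_size_a, config.module_fraction_a)
    seeds_b_underlying = one_species(config.seed_size_b, config.module_fraction_b)
    p_a = _draw_pvalues(rng, ids, seeds_a, config.seed_p_threshold)
    p_b_underlying = _draw_pvalues(rng, ids, seeds_b_underlying, config.seed_p_threshold)

    coords = _gene_coordinates(ids, config.n_chromosomes)
    table_a = coords.copy()
    table_a["p"] = table_a["gene_id"].map(p_a)
    table_b = coords.copy()
    table_b["gene_id"] = SPECIES_B_PREFIX + table_b["gene_id"]
    table_b["p"] = [p_b_underlying[g] for g in coords["gene_id"]]

    return SyntheticTruth(
        module_genes=module,
        seeds_a=seeds_a,
        seeds_b={SPECIES_B_PREFIX + g for g in seeds_b_underlying},
        gene_pvalues_a=p_a,
        gene_pvalues_b={SPECIES_B_PREFIX + g: v for g, v in p_b_underlying.items()},
        gene_table_a=table_a,
        gene_table_b=table_b,
    )


def generate_ortholog_map(
    network: nx.Graph, config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Noisy many-to-many ortholog table between the two identifier spaces.

    Every gene maps to its own cross-species counterpart with a database
    support count drawn uniformly from 1..16; with probability
    ``ortholog_ambiguity_rate`` a spurious lower-support mapping to a random
    other gene is added (skipped when the true support is already 1).
    """
    rng = np.random.default_rng(config.rng_seed + 2) if rng is None else rng
    ids = sorted(network.nodes())
    rows = []
    for g in ids:
        support = int(rng.integers(1, 17))
        rows.append((g, SPECIES_B_PREFIX + g, support))
        if support > 1 and rng.random() < config.ortholog_ambiguity_rate:
            other = ids[int(rng.integers(len(ids)))]
            while other == g:
                other = ids[int(rng.integers(len(ids)))]
            rows.append((other, SPECIES_B_PREFIX + g, int(rng.integers(1, support))))
    return pd.DataFrame(rows, columns=["species_a_id", "species_b_id", "n_databases"])


def generate_ontology(
    network: nx.Graph,
    config: SyntheticConfig,
    module_genes: set | None = None,
    rng: np.random.Generator | None = None,
    n_branches: int = 4,
) -> tuple[PhenotypeOntology, "AnnotationSet", set]:
    """Rooted term DAG plus annotations enriched for the module in one branch.

    The root has ``n_branches`` children; remaining terms are attached under
    them round-robin (each new term gets one random parent within its branch,
    so branches are trees and the whole structure a single-rooted DAG).  The
    first branch is the designated trait branch: module genes are annotated
    into it at ``annotation_enrichment`` times the background rate.  Returns
    (ontology, propagated annotations, trait-branch term ids).
    """
    from .ontology import AnnotationSet  # noqa: F401  (return type)

    rng = np.random.default_rng(config.rng_seed + 3) if rng is None else rng
    if module_genes is None:
        module_genes = network.graph.get("module_genes", set())
    n_terms = config.n_terms
    terms = {f"T{i:03d}": f"phenotype {i}" for i in range(n_terms)}
    root = "T000"
    terms[root] = "organism phenotype (root)"
    n_branches = min(n_branches, n_terms - 1)
    parents: dict = {root: frozenset()}
    branch_of: dict = {}
    branch_roots = []
    for i in range(1, n_branches + 1):
        tid = f"T{i:03d}"
        parents[tid] = frozenset({root})
        branch_of[tid] = i - 1
        branch_roots.append(tid)
    for i in range(n_branches + 1, n_terms):
        tid = f"T{i:03d}"
        b = (i - n_branches - 1) % n_branches
        candidates = sorted(t for t, bb in branch_of.items() if bb == b)
        parent = candidates[int(rng.integers(len(candidates)))]
        parents[tid] = frozenset({parent})
        branch_of[tid] = b
    ontology = PhenotypeOntology(terms=terms, parents=parents, root=root)
    trait_terms = {branch_roots[0]} | {t for t, b in branch_of.items() if b == 0}

    ids = sorted(network.nodes())
    non_root_terms = sorted(set(terms) - {root})
    trait_leaf_pool = sorted(trait_terms)
    p_trait_bg = config.base_annotation_rate
    p_trait_mod = min(1.0, config.base_annotation_rate * config.annotation_enrichment)
    direct: set = set()
    phenotyped: set = set()
    for g in ids:
        if rng.random() >= config.phenotyped_fraction:
            continue
        phenotyped.add(g)
        # sparse background annotations keep branch membership unsaturated
        for _ in range(config.background_annotations_per_gene):
            direct.add((g, non_root_terms[int(rng.integers(len(non_root_terms)))]))
        p_trait = p_trait_mod if g in module_genes else p_trait_bg
        if rng.random() < p_trait:
            direct.add((g, trait_leaf_pool[int(rng.integers(len(trait_leaf_pool)))]))
    annotations = propagate_annotations(ontology, direct, phenotyped_genes=phenotyped)
    return ontology, annotations, trait_terms


def generate_all(config: SyntheticConfig):
    """Network, truth, ortholog map and ontology from one configuration."""
    network = generate_network(config)
    truth = generate_seed_sets(network, config)
    truth.ortholog_map = generate_ortholog_map(network, config)
    ontology, annotations, trait_terms = generate_ontology(
        network, config, module_genes=truth.module_genes
    )
    truth.annotations = annotations.direct
    truth.trait_terms = trait_terms
    return network, truth, ontology, annotations
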