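"""Multiscale persistent community detection and containment hierarchies.

A subnetwork is partitioned by seeded Louvain modularity optimization at a
geometric grid of resolution parameters.  Candidate communities that recur
across resolutions (pairwise Jaccard above a cutoff) are collapsed into one
persistent community whose persistence is the number of distinct resolutions
that found it.  Persistent communities are then nested by the containment
index CI(v, w) = |s(v) ∩ s(w)| / |s(w)|: an edge runs from the larger
community v to the smaller w whenever CI(v, w) exceeds a threshold sigma,
and transitively implied edges are removed.  The result — the "systems map"
— is a rooted DAG of communities at all scales.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

ROOT_ID = "C-root"


class HierarchyError(ValueError):
    pass


@dataclass
class Community:
    id: str
    genes: frozenset
    resolutions_found: list = field(default_factory=list)

    @property
    def persistence(self) -> int:
        return len(set(self.resolutions_found))

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class CommunityHierarchy:
    communities: list  # Community, root first
    edges: list  # (parent_id, child_id, containment)
    root: str

    def by_id(self) -> dict:
        return {c.id: c for c in self.communities}

    def children(self, cid: str) -> list:
        return [child for parent, child, _ in self.edges if parent == cid]

    def leaves(self) -> list:
        parents = {p for p, _, _ in self.edges}
        return [c for c in self.communities if c.id not in parents and c.id != self.root]

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for c in self.communities:
            g.add_node(c.id, size=c.size, persistence=c.persistence)
        for p, ch, ci in self.edges:
            g.add_edge(p, ch, containment=ci)
        return g

    def membership_table(self) -> pd.DataFrame:
        rows = [
            {"community_id": c.id, "gene": g}
            for c in self.communities
            for g in sorted(c.genes)
        ]
        return pd.DataFrame(rows, columns=["community_id", "gene"])


def resolution_grid(r_min: float = 0.1, max_resolution: float = 10.0, n_steps: int = 20) -> np.ndarray:
    if not 0 < r_min < max_resolution:
        raise HierarchyError("need 0 < r_min < max_resolution")
    return np.geomspace(r_min, max_resolution, n_steps)


def _best_partition(graph: nx.Graph, resolution: float, rng: np.random.Generator, restarts: int = 3):
    """Best-of-restarts Louvain partition at one resolution (seeded)."""
    best, best_q = None, -np.inf
    for _ in range(restarts):
        seed = int(rng.integers(0, 2**31 - 1))
        part = nx.community.louvain_communities(graph, resolution=resolution, seed=seed)
        q = nx.community.modularity(graph, part, resolution=resolution)
        if q > best_q:
            best, best_q = part, q
    return best


def _jaccard(a: frozenset, b: frozenset) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / (len(a) + len(b) - inter)


def detect_multiscale(
    subnetwork: nx.Graph,
    max_resolution: float = 10.0,
    n_steps: int = 20,
    r_min: float = 0.1,
    jaccard_min: float = 0.75,
    min_persistence: int = 5,
    rng_seed: int | np.random.Generator = 0,
    restrict_to_lcc: bool = True,
    min_size: int = 2,
) -> list:
    """Persistent communities of a subnetwork across modularity resolutions.

    Partitions at each resolution of a geometric grid are pooled; candidates
    from different resolutions with pairwise Jaccard >= ``jaccard_min`` are
    merged (single linkage) into one community represented by the most
    frequent member set (ties broken by lexicographically smallest gene
    list).  Communities found at fewer than ``min_persistence`` distinct
    resolutions are dropped.  Deterministic under ``rng_seed``.
    """
    if subnetwork.number_of_nodes() == 0:
        raise HierarchyError("empty subnetwork")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    graph = subnetwork
    if restrict_to_lcc and not nx.is_connected(graph):
        lcc = max(nx.connected_components(graph), key=lambda c: (len(c), sorted(c)[0]))
        graph = graph.subgraph(lcc).copy()
    grid = resolution_grid(r_min, max_resolution, n_steps)
    candidates = []  # (frozenset, resolution)
    for r in grid:
        for part in _best_partition(graph, float(r), rng):
            if len(part) >= min_size:
                candidates.append((frozenset(part), float(r)))
    if not candidates:
        return []
    # single-linkage clustering of candidates at Jaccard >= jaccard_min
    parent = list(range(len(candidates)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(candidates)), 2):
        if _jaccard(candidates[i][0], candidates[j][0]) >= jaccard_min:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    groups: dict = {}
    for i in range(len(candidates)):
        groups.setdefault(find(i), []).append(i)

    communities = []
    for members in groups.values():
        sets = [candidates[i][0] for i in members]
        resolutions = sorted({candidates[i][1] for i in members})
        if len(resolutions) < min_persistence:
            continue
        counts: dict = {}
        for s in sets:
            counts[s] = counts.get(s, 0) + 1
        top = max(counts.values())
        representative = min(
            (s for s, c in counts.items() if c == top), key=lambda s: sorted(s)
        )
        communities.append((representative, resolutions))
    # deterministic ids: large to small, then lexicographic members
    communities.sort(key=lambda cr: (-len(cr[0]), sorted(cr[0])))
    return [
        Community(id=f"C{i:04d}", genes=genes, resolutions_found=list(res))
        for i, (genes, res) in enumerate(communities)
    ]


def containment_index(v: Community | frozenset, w: Community | frozenset) -> float:
    """CI(v, w) = |s(v) ∩ s(w)| / |s(w)|: the fraction of w inside v."""
    sv = v.genes if isinstance(v, Community) else frozenset(v)
    sw = w.genes if isinstance(w, Community) else frozenset(w)
    if not sw:
        raise HierarchyError("containment undefined for an empty community")
    return len(sv & sw) / len(sw)


def _merge_equal_size_pairs(communities: list, sigma: float) -> list:
    """Union equal-size communities with mutual containment above sigma."""
    merged = [Community(c.id, c.genes, list(c.resolutions_found)) for c in communities]
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(merged)), 2):
            a, b = merged[i], merged[j]
            if a.size == b.size and containment_index(a, b) > sigma and containment_index(b, a) > sigma:
                union = a.genes | b.genes
                merged[i] = Community(
                    min(a.id, b.id), frozenset(union),
                    sorted(set(a.resolutions_found) | set(b.resolutions_found)),
                )
                del merged[j]
                changed = True
                break
    return merged


def build_hierarchy(communities: list, sigma: float = 0.75, all_genes: set | None = None) -> CommunityHierarchy:
    """Nest communities by containment index into a rooted, reduced DAG.

    An edge v -> w is added for every ordered pair with CI(v, w) > sigma
    (strict) and |v| > |w|; equal-size mutually-contained pairs are merged
    first, so the size ordering guarantees acyclicity.  Transitively implied
    edges are removed.  A root covering every gene is added when no single
    detected community already covers all parentless communities.
    """
    if not communities:
        raise HierarchyError("no communities to organize")
    comms = _merge_equal_size_pairs(communities, sigma)
    g = nx.DiGraph()
    by_id = {c.id: c for c in comms}
    g.add_nodes_from(by_id)
    ci_of: dict = {}
    for v, w in itertools.permutations(comms, 2):
        if v.size > w.size:
            ci = containment_index(v, w)
            if ci > sigma:
                g.add_edge(v.id, w.id)
                ci_of[(v.id, w.id)] = ci
    reduced = nx.transitive_reduction(g)
    parentless = [cid for cid in reduced.nodes if reduced.in_degree(cid) == 0]
    root_genes = set(all_genes) if all_genes is not None else set().union(*(c.genes for c in comms))
    if len(parentless) == 1 and by_id[parentless[0]].genes == frozenset(root_genes):
        root = parentless[0]
    else:
        root = ROOT_ID
        root_comm = Community(id=root, genes=frozenset(root_genes), resolutions_found=[])
        by_id[root] = root_comm
        for cid in parentless:
            reduced.add_edge(root, cid)
            ci_of[(root, cid)] = containment_index(root_comm, by_id[cid])
    edges = [
        (p, c, ci_of.get((p, c), containment_index(by_id[p], by_id[c])))
        for p, c in sorted(reduced.edges())
    ]
    ordered = [by_id[root]] + [c for c in comms if c.id != root]
    return CommunityHierarchy(communities=ordered, edges=edges, root=root)


def filter_communities(h: CommunityHierarchy, min_size: int) -> CommunityHierarchy:
    """Drop communities below ``min_size``; re-attach orphans upward.

    A removed community's children are re-parented to their nearest retained
    ancestor (ultimately the root, which is never removed).
    """
    by_id = h.by_id()
    keep = {c.id for c in h.communities if c.size >= min_size or c.id == h.root}
    parent_of: dict = {}
    for p, c, _ in h.edges:
        parent_of.setdefault(c, []).append(p)

    def retained_ancestors(cid: str) -> set:
        out = set()
        frontier = list(parent_of.get(cid, []))
        while frontier:
            p = frontier.pop()
            if p in keep:
                out.add(p)
            else:
                frontier.extend(parent_of.get(p, []))
        return out

    g = nx.DiGraph()
    g.add_nodes_from(keep)
    for c in keep:
        if c == h.root:
            continue
        for p in retained_ancestors(c):
            g.add_edge(p, c)
    reduced = nx.transitive_reduction(g)
    for c in keep:
        if c != h.root and reduced.in_degree(c) == 0:
            reduced.add_edge(h.root, c)
    edges = [
        (p, c, containment_index(by_id[p], by_id[c])) for p, c in sorted(reduced.edges())
    ]
    communities = [by_id[h.root]] + [c for c in h.communities if c.id in keep and c.id != h.root]
    return CommunityHierarchy(communities=communities, edges=edges, root=h.root)


def check_locus_independence(
    community: Community | set,
    seed_records: pd.DataFrame,
    max_dist_bp: int = 250_000,
) -> tuple[bool, list]:
    """Flag communities whose seed genes may represent a single GWAS locus.

    Looks for pairs of seed genes inside the community lying on the same
    chromosome with a gap between their spans of at most ``max_dist_bp``.
    Informational only — nothing is filtered.  Returns (flagged, pairs).
    """
    genes = community.genes if isinstance(community, Community) else set(community)
    recs = seed_records[seed_records["gene_id"].isin(genes)]
    missing = genes & set(seed_records.get("gene_id", [])) - set(recs["gene_id"])
    if missing:
        import warnings

        warnings.warn(f"genes without coordinates skipped: {sorted(missing)}", stacklevel=2)
    offenders = []
    for _, chrom_tab in recs.groupby("chrom"):
        rows = chrom_tab.sort_values(["start", "gene_id"]).itertuples(index=False)
        rows = list(rows)
        for r1, r2 in itertools.combinations(rows, 2):
            gap = max(0, max(r1.start, r2.start) - min(r1.end, r2.end))
            if gap <= max_dist_bp:
                offenders.append((r1.gene_id, r2.gene_id, int(gap)))
    return bool(offenders), sorted(offenders)
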