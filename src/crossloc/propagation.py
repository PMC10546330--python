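"""Random walk with restart network propagation and network proximity scores.

Heat is spread from a set of seed genes over an undirected molecular
interaction network.  With ``W`` the column-normalized adjacency matrix and
``alpha`` the dissipation (restart) constant, the stationary heat vector is
the closed form

    F = (I - alpha * W)^{-1} (1 - alpha) * Y0

where ``Y0`` is the 0/1 indicator of the seed genes.  Because ``W`` is
column-stochastic on graphs without isolated nodes, total heat is conserved:
``sum(F)`` equals the number of in-network seeds.

The network proximity score (NPS) of a gene is the z-score of its observed
log-heat against a null ensemble of random seed sets matched to the observed
set's size and degree profile (genes binned by degree, at least 10 genes per
bin).  Large seed sets are handled by repeated weighted subsampling and a
per-gene consensus percentile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu


class PropagationError(ValueError):
    """Raised for unusable propagation inputs (e.g. no seed in the network)."""


def column_normalize(graph: nx.Graph, nodelist: list | None = None) -> sp.csc_matrix:
    """Column-normalized adjacency matrix W with W[i, j] = A[i, j] / degree(j).

    Columns of isolated nodes are all-zero; heat placed on such a node leaks
    out of the system, so callers are warned.
    """
    if nodelist is None:
        nodelist = sorted(graph.nodes())
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodelist, dtype=float, format="csc")
    if adj.diagonal().any():
        raise PropagationError("network must be simple (self-loops present)")
    deg = np.asarray(adj.sum(axis=0)).ravel()
    isolated = deg == 0
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} isolated node(s): their columns are zero and "
            "heat placed on them dissipates entirely",
            stacklevel=2,
        )
    inv_deg = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    return (adj @ sp.diags(inv_deg)).tocsc()


@dataclass
class HeatVector:
    """Stationary heat per gene for one seed set."""

    values: pd.Series  # gene -> heat, >= 0
    seed_set_id: str
    alpha: float
    in_network_seeds: list = field(default_factory=list)

    @property
    def total(self) -> float:
        return float(self.values.sum())


class Propagator:
    """Pre-factorized RWR solver for one network and one alpha.

    Factorizing ``I - alpha*W`` once (sparse LU) makes the thousands of null
    propagations behind an NPS table cheap: each is a single triangular solve.
    """

    def __init__(self, graph: nx.Graph, alpha: float = 0.5):
        if not 0 < alpha < 1:
            raise PropagationError(f"alpha must be in (0, 1), got {alpha}")
        self.alpha = float(alpha)
        self.nodes = sorted(graph.nodes())
        self.index = pd.Index(self.nodes, name="gene")
        self._pos = {g: i for i, g in enumerate(self.nodes)}
        self.w = column_normalize(graph, nodelist=self.nodes)
        n = len(self.nodes)
        self.degrees = np.asarray(
            nx.to_scipy_sparse_array(graph, nodelist=self.nodes).sum(axis=0)
        ).ravel()
        system = (sp.identity(n, format="csc") - self.alpha * self.w).tocsc()
        self._lu = splu(system)

    def heat(self, seed_genes, seed_set_id: str = "seeds") -> HeatVector:
        """Solve (I - alpha W) F = (1 - alpha) Y0 for the given seeds."""
        in_net = [g for g in seed_genes if g in self._pos]
        dropped = len(list(seed_genes)) - len(in_net)
        if dropped:
            warnings.warn(f"{dropped} seed gene(s) not in the network; ignored", stacklevel=2)
        if not in_net:
            raise PropagationError("no seed gene is present in the network")
        y0 = np.zeros(len(self.nodes))
        y0[[self._pos[g] for g in in_net]] = 1.0
        f = self._lu.solve((1.0 - self.alpha) * y0)
        f[np.abs(f) < 1e-300] = 0.0
        f = np.maximum(f, 0.0)  # LU round-off can produce -1e-25 on far nodes
        return HeatVector(pd.Series(f, index=self.index), seed_set_id, self.alpha, in_net)

    def heat_matrix(self, seed_sets: list[list]) -> np.ndarray:
        """Heats for many seed sets at once; rows are seed sets."""
        n = len(self.nodes)
        y = np.zeros((n, len(seed_sets)))
        for j, seeds in enumerate(seed_sets):
            y[[self._pos[g] for g in seeds], j] = 1.0
        f = self._lu.solve((1.0 - self.alpha) * y)
        return np.maximum(f, 0.0).T


def propagate(graph: nx.Graph, seed_genes, alpha: float = 0.5) -> HeatVector:
    """One-shot convenience wrapper around :class:`Propagator`."""
    return Propagator(graph, alpha=alpha).heat(seed_genes)


def degree_bins(degrees: np.ndarray, min_bin: int = 10) -> np.ndarray:
    """Partition genes into degree bins of at least ``min_bin`` genes.

    Genes are sorted by degree ascending and filled greedily; genes of equal
    degree are never split across a bin boundary when avoidable, and a short
    trailing bin is merged into its predecessor.  Returns a bin id per gene
    (aligned with the input order).
    """
    n = len(degrees)
    if n < min_bin:
        raise PropagationError(f"cannot build degree bins: {n} genes < min_bin={min_bin}")
    order = np.argsort(degrees, kind="stable")
    bin_of = np.empty(n, dtype=int)
    current, count, b = [], 0, 0
    sorted_deg = degrees[order]
    for i in range(n):
        current.append(order[i])
        count += 1
        boundary = i == n - 1 or sorted_deg[i + 1] != sorted_deg[i]
        if count >= min_bin and boundary:
            bin_of[current] = b
            b += 1
            current, count = [], 0
    if current:  # trailing short bin -> merge into predecessor
        if b == 0:
            raise PropagationError("degree sequence cannot fill a single bin")
        bin_of[current] = b - 1
    return bin_of


@dataclass
class NullHeatEnsemble:
    """Heats of degree-matched random seed sets (rows) per gene (columns)."""

    heats: np.ndarray  # shape (n_null, n_genes)
    index: pd.Index
    bin_of: np.ndarray
    alpha: float
    seed_set_size: int

    @property
    def n_null(self) -> int:
        return self.heats.shape[0]


def build_null_ensemble(
    propagator: Propagator,
    seed_genes,
    n_null: int = 1000,
    min_bin: int = 10,
    rng_seed: int | np.random.Generator = 0,
) -> NullHeatEnsemble:
    """Propagate ``n_null`` random seed sets matched in size and degree profile.

    Each null set replaces every observed seed by a uniform draw, without
    replacement, from the seed's degree bin.
    """
    if n_null < 2:
        raise PropagationError("n_null must be >= 2 for a standard deviation")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    in_net = [g for g in seed_genes if g in propagator._pos]
    if not in_net:
        raise PropagationError("no seed gene is present in the network")
    bin_of = degree_bins(propagator.degrees, min_bin=min_bin)
    seed_idx = np.array([propagator._pos[g] for g in in_net])
    # how many seeds each bin must supply
    need = np.bincount(bin_of[seed_idx], minlength=bin_of.max() + 1)
    members = [np.flatnonzero(bin_of == b) for b in range(bin_of.max() + 1)]
    for b, k in enumerate(need):
        if k > len(members[b]):
            raise PropagationError(
                f"degree bin {b} has {len(members[b])} genes but must supply {k} seeds"
            )
    null_sets = []
    nodes = propagator.nodes
    for _ in range(n_null):
        picks = np.concatenate(
            [rng.choice(members[b], size=k, replace=False) for b, k in enumerate(need) if k]
        )
        null_sets.append([nodes[i] for i in picks])
    heats = propagator.heat_matrix(null_sets)
    return NullHeatEnsemble(heats, propagator.index, bin_of, propagator.alpha, len(in_net))


@dataclass
class NPSTable:
    """Per-gene network proximity z-scores for one species."""

    table: pd.DataFrame  # columns: nps, is_seed, flagged
    species: str
    n_null: int
    alpha: float

    @property
    def nps(self) -> pd.Series:
        return self.table["nps"]

    @property
    def is_seed(self) -> pd.Series:
        return self.table["is_seed"]


def compute_nps(
    observed: HeatVector,
    null: NullHeatEnsemble,
    species: str = "",
    seed_genes=None,
) -> NPSTable:
    """z-score of observed log-heat against the null ensemble, per gene.

    Natural log throughout.  Genes with zero heat in the observation or in any
    null draw, or with zero null spread, get NaN and are flagged; they cannot
    be placed on the log scale and are excluded from downstream thresholding.
    """
    if not np.isclose(observed.alpha, null.alpha):
        raise PropagationError("observed and null alphas differ")
    if not observed.values.index.equals(null.index):
        raise PropagationError("observed and null gene universes differ")
    f_obs = observed.values.to_numpy()
    ok = (f_obs > 0) & (null.heats > 0).all(axis=0)
    nps = np.full(len(f_obs), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_null = np.log(null.heats[:, ok])
        mu = log_null.mean(axis=0)
        sd = log_null.std(axis=0, ddof=1)
        z = (np.log(f_obs[ok]) - mu) / sd
    z[sd == 0] = np.nan
    nps[ok] = z
    seeds = set(seed_genes if seed_genes is not None else observed.in_network_seeds)
    table = pd.DataFrame(
        {
            "nps": nps,
            "is_seed": [g in seeds for g in null.index],
            "flagged": ~np.isfinite(nps),
        },
        index=null.index,
    )
    return NPSTable(table, species, null.n_null, null.alpha)


def score_seed_set(
    graph_or_propagator,
    seed_genes,
    alpha: float = 0.5,
    n_null: int = 1000,
    min_bin: int = 10,
    rng_seed: int | np.random.Generator = 0,
    species: str = "",
) -> NPSTable:
    """Full observed-vs-null NPS computation for one seed set."""
    prop = (
        graph_or_propagator
        if isinstance(graph_or_propagator, Propagator)
        else Propagator(graph_or_propagator, alpha=alpha)
    )
    obs = prop.heat(seed_genes, seed_set_id=species or "seeds")
    null = build_null_ensemble(prop, seed_genes, n_null=n_null, min_bin=min_bin, rng_seed=rng_seed)
    return compute_nps(obs, null, species=species)


def consensus_nps(
    graph_or_propagator,
    records: pd.DataFrame,
    max_seeds: int = 500,
    n_reps: int = 100,
    percentile: float = 75,
    alpha: float = 0.5,
    n_null: int = 1000,
    min_bin: int = 10,
    rng_seed: int | np.random.Generator = 0,
    species: str = "",
) -> NPSTable:
    """NPS for a seed table, subsampling when it exceeds ``max_seeds``.

    ``records`` must carry a ``gene_id`` column and a ``p`` column.  When the
    table has at most ``max_seeds`` genes this is a single NPS run.  Otherwise
    ``max_seeds`` genes are drawn without replacement with probability
    proportional to -log10(p), ``n_reps`` times, and the per-gene consensus is
    the requested percentile (linear interpolation) across repetitions.
    """
    prop = (
        graph_or_propagator
        if isinstance(graph_or_propagator, Propagator)
        else Propagator(graph_or_propagator, alpha=alpha)
    )
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    genes = records["gene_id"].to_numpy()
    if len(genes) <= max_seeds:
        return score_seed_set(
            prop, list(genes), n_null=n_null, min_bin=min_bin, rng_seed=rng, species=species
        )
    weights = -np.log10(records["p"].to_numpy(dtype=float))
    if np.any(weights <= 0) or not np.all(np.isfinite(weights)):
        raise PropagationError("subsampling weights (-log10 p) must be positive and finite")
    probs = weights / weights.sum()
    reps = np.full((n_reps, len(prop.nodes)), np.nan)
    all_sampled: set = set()
    for r in range(n_reps):
        sub = rng.choice(genes, size=max_seeds, replace=False, p=probs)
        tab = score_seed_set(
            prop, list(sub), n_null=n_null, min_bin=min_bin, rng_seed=rng, species=species
        )
        reps[r] = tab.nps.to_numpy()
        all_sampled.update(sub)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN gene columns
        consensus = np.nanpercentile(reps, percentile, axis=0)
    table = pd.DataFrame(
        {
            "nps": consensus,
            "is_seed": [g in all_sampled or g in set(genes) for g in prop.nodes],
            "flagged": ~np.isfinite(consensus),
        },
        index=prop.index,
    )
    return NPSTable(table, species, n_null, prop.alpha)
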