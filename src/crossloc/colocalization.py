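"""Cross-species co-localization: combined scores, subnetworks, permutation test.

Two species' NPS tables are combined gene-wise as a product (NPS_ab); the
conserved subnetwork collects genes proximal to both species' seeds, the
species-specific subnetworks collect genes proximal to exactly one, and the
expanded subnetwork is their union superset.  Significance of conserved
co-localization is assessed by permuting one species' NPS labels across
genes — separately for genes that were seeds in both species, whose scores
are expected high a priori — and z-testing the observed subnetwork size and
mean combined score against the permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .propagation import NPSTable


class ColocalizationError(ValueError):
    pass


@dataclass
class CombinedNPS:
    """Gene-wise joined scores of two species, on their shared gene universe."""

    table: pd.DataFrame  # columns nps_a, nps_b, nps_ab, dual_seed
    species_a: str = "a"
    species_b: str = "b"

    @property
    def finite(self) -> pd.DataFrame:
        return self.table[np.isfinite(self.table["nps_ab"])]


def combine(nps_a: NPSTable, nps_b: NPSTable) -> CombinedNPS:
    """Elementwise product of two species' NPS tables (NaN-propagating)."""
    shared = nps_a.table.index.intersection(nps_b.table.index)
    if len(shared) == 0:
        raise ColocalizationError("NPS tables share no genes")
    if len(shared) < len(nps_a.table) or len(shared) < len(nps_b.table):
        warnings.warn(
            f"gene universes differ; intersecting to {len(shared)} shared genes",
            stacklevel=2,
        )
    a = nps_a.table.loc[shared]
    b = nps_b.table.loc[shared]
    table = pd.DataFrame(
        {
            "nps_a": a["nps"],
            "nps_b": b["nps"],
            "nps_ab": a["nps"] * b["nps"],
            "dual_seed": a["is_seed"] & b["is_seed"],
        },
        index=shared,
    )
    return CombinedNPS(table, nps_a.species or "a", nps_b.species or "b")


@dataclass
class SubnetworkResult:
    kind: str  # conserved | species_a_specific | species_b_specific | expanded
    genes: set
    thresholds: dict
    induced_edges: list = field(default_factory=list)


def _attach_edges(result: SubnetworkResult, network: nx.Graph | None) -> SubnetworkResult:
    if network is not None:
        sub = network.subgraph(result.genes)
        result.induced_edges = sorted(tuple(sorted(e)) for e in sub.edges())
    return result


def conserved_mask(nps_a, nps_b, t_ab: float = 3.0, t_a: float = 1.0, t_b: float = 1.0):
    """Strict-inequality membership predicate for the conserved subnetwork."""
    with np.errstate(invalid="ignore"):
        return (nps_a * nps_b > t_ab) & (nps_a > t_a) & (nps_b > t_b)


def a_specific_mask(nps_a, nps_b, t_same: float = 1.5, t_other: float = 0.0, t_comb: float = -4.0):
    """Species-a-specific: high in a, below the b mean, strongly anti-combined."""
    with np.errstate(invalid="ignore"):
        return (nps_a > t_same) & (nps_b < t_other) & (nps_a * (nps_b - 1) < t_comb)


def b_specific_mask(nps_a, nps_b, t_same: float = 1.0, t_other: float = 0.5, t_comb: float = -2.0):
    with np.errstate(invalid="ignore"):
        return (nps_b > t_same) & (nps_a < t_other) & (nps_b * (nps_a - 1) < t_comb)


def expanded_mask(nps_a, nps_b, t_a: float = 1.5, t_b: float = 1.0):
    with np.errstate(invalid="ignore"):
        return (nps_a > t_a) | (nps_b > t_b)


def select_conserved(
    c: CombinedNPS,
    t_ab: float = 3.0,
    t_a: float = 1.0,
    t_b: float = 1.0,
    network: nx.Graph | None = None,
) -> SubnetworkResult:
    t = c.finite  # genes with a NaN score cannot enter any subnetwork
    mask = conserved_mask(t["nps_a"], t["nps_b"], t_ab, t_a, t_b)
    genes = set(t.index[mask])
    res = SubnetworkResult("conserved", genes, {"t_ab": t_ab, "t_a": t_a, "t_b": t_b})
    return _attach_edges(res, network)


def select_species_specific(
    c: CombinedNPS,
    which: str,
    t_same: float | None = None,
    t_other: float | None = None,
    t_comb: float | None = None,
    network: nx.Graph | None = None,
) -> SubnetworkResult:
    """Genes proximal only to species ``which`` ("a" or "b")'s seeds.

    Defaults mirror the asymmetric cutoffs used for the human (a) and rat (b)
    analyses: a-specific requires nps_a > 1.5, nps_b < 0 and
    nps_a*(nps_b-1) < -4; b-specific requires nps_b > 1, nps_a < 0.5 and
    nps_b*(nps_a-1) < -2.  All three cutoffs per side are configurable.
    """
    t = c.finite
    na, nb = t["nps_a"], t["nps_b"]
    if which == "a":
        args = {
            "t_same": 1.5 if t_same is None else t_same,
            "t_other": 0.0 if t_other is None else t_other,
            "t_comb": -4.0 if t_comb is None else t_comb,
        }
        mask = a_specific_mask(na, nb, **args)
        kind = "species_a_specific"
    elif which == "b":
        args = {
            "t_same": 1.0 if t_same is None else t_same,
            "t_other": 0.5 if t_other is None else t_other,
            "t_comb": -2.0 if t_comb is None else t_comb,
        }
        mask = b_specific_mask(na, nb, **args)
        kind = "species_b_specific"
    else:
        raise ColocalizationError(f"which must be 'a' or 'b', got {which!r}")
    genes = set(t.index[mask])
    return _attach_edges(SubnetworkResult(kind, genes, args), network)


def select_expanded(
    c: CombinedNPS,
    t_a: float = 1.5,
    t_b: float = 1.0,
    network: nx.Graph | None = None,
) -> SubnetworkResult:
    t = c.finite
    mask = expanded_mask(t["nps_a"], t["nps_b"], t_a, t_b)
    genes = set(t.index[mask])
    return _attach_edges(SubnetworkResult("expanded", genes, {"t_a": t_a, "t_b": t_b}), network)


@dataclass
class PermutationReport:
    observed_size: int
    observed_mean_nps_ab: float
    null_sizes: np.ndarray
    null_means: np.ndarray
    z_size: float
    p_size: float
    z_mean: float
    p_mean: float
    p_size_empirical: float
    p_mean_empirical: float
    obs_exp_ratio: float
    ratio_ci95: tuple
    n_perm: int

    def to_dict(self) -> dict:
        return {
            "observed_size": int(self.observed_size),
            "observed_mean_nps_ab": float(self.observed_mean_nps_ab),
            "z_size": float(self.z_size),
            "p_size": float(self.p_size),
            "z_mean": float(self.z_mean),
            "p_mean": float(self.p_mean),
            "p_size_empirical": float(self.p_size_empirical),
            "p_mean_empirical": float(self.p_mean_empirical),
            "obs_exp_ratio": float(self.obs_exp_ratio),
            "ratio_ci95": [float(x) for x in self.ratio_ci95],
            "n_perm": int(self.n_perm),
        }


def _z_and_p(observed: float, null: np.ndarray) -> tuple[float, float]:
    mu, sd = null.mean(), null.std(ddof=1)
    if sd == 0:
        return float("nan"), float("nan")
    z = (observed - mu) / sd
    return float(z), float(norm.sf(z))


def permutation_test(
    c: CombinedNPS,
    selector=conserved_mask,
    n_perm: int = 10_000,
    rng_seed: int | np.random.Generator = 0,
    chunk: int = 1000,
) -> PermutationReport:
    """Label-permutation significance of subnetwork size and mean combined NPS.

    Each permutation shuffles species-b scores across genes within two strata
    (dual-seed genes among themselves, everything else among itself), then
    recomputes the selector's gene count and the mean combined score over all
    genes with finite scores.  Normal-tail (z-test) p-values are the primary
    report; empirical permutation p-values are included for robustness.
    """
    if n_perm < 100:
        raise ColocalizationError("n_perm must be >= 100")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    t = c.finite  # NaN genes cannot enter any subnetwork
    a = t["nps_a"].to_numpy()
    b = t["nps_b"].to_numpy()
    dual = t["dual_seed"].to_numpy()
    observed_size = int(selector(a, b).sum())
    observed_mean = float((a * b).mean())

    null_sizes = np.empty(n_perm)
    null_means = np.empty(n_perm)
    idx_dual = np.flatnonzero(dual)
    idx_rest = np.flatnonzero(~dual)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm_b = np.tile(b, (m, 1))
        for stratum in (idx_dual, idx_rest):
            if len(stratum) > 1:
                cols = rng.permuted(np.tile(stratum, (m, 1)), axis=1)
                perm_b[:, stratum] = np.take(b, cols)
        null_sizes[done : done + m] = selector(a[None, :], perm_b).sum(axis=1)
        null_means[done : done + m] = (a[None, :] * perm_b).mean(axis=1)
        done += m

    z_size, p_size = _z_and_p(observed_size, null_sizes)
    z_mean, p_mean = _z_and_p(observed_mean, null_means)
    p_size_emp = float((1 + (null_sizes >= observed_size).sum()) / (n_perm + 1))
    p_mean_emp = float((1 + (null_means >= observed_mean).sum()) / (n_perm + 1))
    exp_size = null_sizes.mean()
    ratio = observed_size / exp_size if exp_size > 0 else float("inf")
    with np.errstate(divide="ignore"):
        per_draw = np.where(null_sizes > 0, observed_size / null_sizes, np.inf)
    ci = (float(np.percentile(per_draw, 2.5)), float(np.percentile(per_draw, 97.5)))
    return PermutationReport(
        observed_size,
        observed_mean,
        null_sizes,
        null_means,
        z_size,
        p_size,
        z_mean,
        p_mean,
        p_size_emp,
        p_mean_emp,
        ratio,
        ci,
        n_perm,
    )
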