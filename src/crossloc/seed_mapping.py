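"""From GWAS summary statistics to species seed-gene sets.

Covers the windowed SNP-to-gene assignment used for species without
LD-aware gene-level statistics (each gene inherits the lowest p-value of any
variant within +/- window of its span), significance thresholding into seed
sets weighted by -log10 p, many-to-one ortholog resolution with a
database-support filter, and the hypergeometric test for raw seed overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "p", "lead_snp"]


class SeedMappingError(ValueError):
    pass


@dataclass
class SeedGeneSet:
    species: str
    genes: set
    weights: dict  # gene -> -log10(raw p)
    threshold_used: float

    def __post_init__(self):
        if not self.genes:
            raise SeedMappingError("seed set is empty after filtering")


@dataclass
class OrthologMap:
    pairs: pd.DataFrame  # columns species_a_id, species_b_id, n_databases
    resolved: dict = field(default_factory=dict)  # species_b_id -> species_a_id

    def translate(self, genes_b) -> set:
        return {self.resolved[g] for g in genes_b if g in self.resolved}


def _collapse_duplicate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    # variable genomic ranges for one gene id: take smallest start, greatest end
    return (
        genes.groupby(["gene_id", "chrom"], as_index=False)
        .agg(start=("start", "min"), end=("end", "max"))
    )


def map_snps_to_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = 10_000,
    exclude_chroms: set | None = None,
) -> pd.DataFrame:
    """Assign each gene the minimum SNP p-value within its windowed span.

    Coordinates are 1-based inclusive; a SNP at position ``pos`` is assigned
    to a gene iff ``start - window_bp <= pos <= end + window_bp`` on the same
    chromosome.  One SNP may be assigned to several genes.  Genes with no SNP
    in window are omitted.  Returns a gene-level table with columns
    ``gene_id, chrom, start, end, p, lead_snp``.
    """
    if window_bp < 0:
        raise SeedMappingError(f"window_bp must be non-negative, got {window_bp}")
    if snps.empty:
        warnings.warn("empty SNP table: no gene-level p-values produced", stacklevel=2)
        return pd.DataFrame(columns=GENE_COLUMNS)
    genes = _collapse_duplicate_genes(genes)
    if exclude_chroms:
        genes = genes[~genes["chrom"].isin(exclude_chroms)]
        snps = snps[~snps["chrom"].isin(exclude_chroms)]
    out = []
    for chrom, gtab in genes.groupby("chrom", sort=True):
        stab = snps[snps["chrom"] == chrom]
        if stab.empty:
            continue
        pos = stab["pos"].to_numpy()
        pval = stab["p"].to_numpy(dtype=float)
        # deterministic lead SNP on p ties: smallest position wins
        order = np.lexsort((pos, pval))
        pos, pval = pos[order], pval[order]
        for row in gtab.itertuples(index=False):
            lo, hi = row.start - window_bp, row.end + window_bp
            inside = (pos >= lo) & (pos <= hi)
            if not inside.any():
                continue
            k = int(np.flatnonzero(inside)[0])  # first hit = lowest p, then lowest pos
            out.append((row.gene_id, chrom, row.start, row.end, pval[k], int(pos[k])))
    result = pd.DataFrame(out, columns=GENE_COLUMNS)
    return result.sort_values("gene_id", ignore_index=True)


def define_seed_set(
    records: pd.DataFrame,
    threshold: float,
    correction: str = "none",
    species: str = "",
) -> SeedGeneSet:
    """Threshold gene-level p-values into a weighted seed-gene set.

    ``correction='bonferroni'`` multiplies each p by the number of tested
    genes in the table before comparing with ``threshold``.  Weights are
    always -log10 of the raw p.
    """
    if not 0 < threshold < 1:
        raise SeedMappingError(f"threshold must be in (0, 1), got {threshold}")
    if correction not in ("none", "bonferroni"):
        raise SeedMappingError(f"unknown correction {correction!r}")
    p = records["p"].to_numpy(dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise SeedMappingError("p-values must lie in (0, 1]")
    effective = np.minimum(p * len(records), 1.0) if correction == "bonferroni" else p
    keep = effective < threshold
    kept = records.loc[keep]
    genes = set(kept["gene_id"])
    if not genes:
        raise SeedMappingError(
            f"no gene passes threshold {threshold} ({correction}); propagation is undefined"
        )
    weights = {g: float(-np.log10(pv)) for g, pv in zip(kept["gene_id"], kept["p"])}
    return SeedGeneSet(species=species, genes=genes, weights=weights, threshold_used=threshold)


def resolve_orthologs(pairs: pd.DataFrame, min_databases: int = 3) -> OrthologMap:
    """Resolve a many-to-many ortholog table to a function ``id_b -> id_a``.

    Rows supported by fewer than ``min_databases`` databases are dropped;
    among a source gene's remaining candidates the highest-support target is
    chosen; exact support ties make the source ambiguous and it is dropped.
    """
    if (pairs["n_databases"] < 1).any():
        raise SeedMappingError("n_databases must be >= 1 for every pair")
    ok = pairs[pairs["n_databases"] >= min_databases]
    resolved: dict = {}
    for src, cand in ok.groupby("species_b_id"):
        best = cand["n_databases"].max()
        winners = cand.loc[cand["n_databases"] == best, "species_a_id"].unique()
        if len(winners) == 1:
            resolved[src] = winners[0]
    return OrthologMap(pairs=pairs.copy(), resolved=resolved)


def seed_overlap_test(seeds_a: set, seeds_b: set, universe_size: int) -> tuple[int, float]:
    """Upper-tail hypergeometric test of raw seed-gene overlap.

    Population ``universe_size``, ``|A|`` successes, ``|B|`` draws;
    p = P(X >= observed overlap).  Also useful for reporting alongside the
    observed/expected overlap ratio ``overlap / (|A||B|/N)``.
    """
    if universe_size < len(seeds_a) or universe_size < len(seeds_b):
        raise SeedMappingError("universe smaller than a seed set")
    overlap = len(seeds_a & seeds_b)
    p = float(hypergeom.sf(overlap - 1, universe_size, len(seeds_a), len(seeds_b)))
    return overlap, min(p, 1.0)
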