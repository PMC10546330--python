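"""Over-representation statistics for communities and subnetworks.

Fisher / hypergeometric enrichment with Benjamini-Hochberg correction,
phenotype validation rates, the phenotype-normalized positive predictive
value PPV = |community ∩ phenotype| / |phenotype|, and the top-down
PPV-guided traversal of a phenotype ontology that reports, per community,
the most specific phenotype terms it is enriched for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom
from statsmodels.stats.multitest import multipletests

from .ontology import AnnotationSet, PhenotypeOntology


class EnrichmentError(ValueError):
    pass


@dataclass
class EnrichmentRecord:
    unit_id: str
    term_id: str
    a: int  # unit ∩ term
    b: int  # unit \ term
    c: int  # term \ unit
    d: int  # neither
    odds_ratio: float
    p: float
    q: float = float("nan")
    ppv: float = float("nan")

    @property
    def term_size(self) -> int:
        return self.a + self.c

    @property
    def overlap(self) -> int:
        return self.a


def fisher_enrichment(
    unit_genes: set, term_genes: set, universe: set, unit_id: str = "", term_id: str = ""
) -> EnrichmentRecord:
    """One-sided (greater) Fisher exact test on the 2x2 membership table.

    The odds ratio is the sample odds ratio ad/bc: +inf when bc = 0 with
    ad > 0, NaN when both products vanish.
    """
    if not universe:
        raise EnrichmentError("empty universe")
    unit = unit_genes & universe
    term = term_genes & universe
    a = len(unit & term)
    b = len(unit - term)
    c = len(term - unit)
    d = len(universe) - a - b - c
    if a * d == 0 and b * c == 0:
        odds = float("nan")
    elif b * c == 0:
        odds = float("inf")
    else:
        odds = (a * d) / (b * c)
    _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
    return EnrichmentRecord(unit_id, term_id, a, b, c, d, odds, float(p))


def hypergeom_enrichment(unit_genes: set, class_genes: set, universe: set) -> float:
    """Upper-tail hypergeometric p for the unit/class overlap in ``universe``."""
    if not universe:
        raise EnrichmentError("empty universe")
    unit = unit_genes & universe
    cls = class_genes & universe
    k = len(unit & cls)
    return float(hypergeom.sf(k - 1, len(universe), len(cls), len(unit)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise EnrichmentError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def ppv(community_genes: set, phenotype_genes: set) -> float:
    """Fraction of the phenotype's genes captured by the community.

    Note the denominator: this statistic is normalized by the phenotype gene
    set, so it rewards communities that cover much of a phenotype rather
    than communities composed mostly of phenotype genes.
    """
    if not phenotype_genes:
        raise EnrichmentError("empty phenotype gene set")
    return len(community_genes & phenotype_genes) / len(phenotype_genes)


def validation_rate(
    unit_genes: set, annotations: AnnotationSet, relevant_terms: set
) -> float:
    """Fraction of a unit's phenotyped genes hitting any trait-relevant term.

    Numerator: unit genes with at least one propagated annotation to a
    relevant term.  Denominator: unit genes with any phenotype record at all.
    NaN when no unit gene is phenotyped.
    """
    if not relevant_terms:
        raise EnrichmentError("relevant_terms must be nonempty")
    phenotyped = unit_genes & annotations.phenotyped_genes
    if not phenotyped:
        return float("nan")
    relevant_genes: set = set()
    for t in relevant_terms:
        relevant_genes |= annotations.genes_for(t)
    return len(phenotyped & relevant_genes) / len(phenotyped)


def traverse_phenotypes(
    community_genes: set,
    ontology: PhenotypeOntology,
    annotations: AnnotationSet,
    universe: set,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Top-down PPV-guided search for the community's specific phenotypes.

    Starting at the root, each expanded parent's children are scored: a child
    is kept when its PPV strictly exceeds the parent's and its BH-adjusted
    Fisher p (corrected within that parent's child set) is below ``fdr``;
    only kept children are expanded further.  Children without annotated
    genes are skipped.  Returns the kept terms with their 2x2 counts, odds
    ratio, p, q and PPV.
    """
    term_genes = annotations.term_gene_map()
    rows = []
    visited: set = set()
    frontier = [(ontology.root, ppv(community_genes, term_genes[ontology.root]))] if (
        ontology.root in term_genes and term_genes[ontology.root]
    ) else []
    while frontier:
        parent, parent_ppv = frontier.pop(0)
        if parent in visited:
            continue
        visited.add(parent)
        kids = [t for t in ontology.children_of(parent) if term_genes.get(t)]
        if not kids:
            continue
        recs = []
        for t in kids:
            rec = fisher_enrichment(community_genes, term_genes[t], universe, term_id=t)
            rec.ppv = ppv(community_genes, term_genes[t])
            recs.append(rec)
        q = bh_adjust([r.p for r in recs])
        for rec, qv in zip(recs, q):
            rec.q = float(qv)
            if rec.ppv > parent_ppv and rec.q < fdr:
                rows.append(
                    {
                        "term_id": rec.term_id,
                        "parent_id": parent,
                        "a": rec.a,
                        "b": rec.b,
                        "c": rec.c,
                        "d": rec.d,
                        "odds_ratio": rec.odds_ratio,
                        "p": rec.p,
                        "q": rec.q,
                        "ppv": rec.ppv,
                        "parent_ppv": parent_ppv,
                    }
                )
                frontier.append((rec.term_id, rec.ppv))
    return pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "parent_id",
            "a",
            "b",
            "c",
            "d",
            "odds_ratio",
            "p",
            "q",
            "ppv",
            "parent_ppv",
        ],
    )


def filter_term_enrichments(
    records: pd.DataFrame,
    min_unit_genes: int = 5,
    min_overlap: int = 3,
    term_size_range: tuple = (50, 1000),
    q_max: float = 1e-3,
) -> pd.DataFrame:
    """Annotation-reporting filter for community term enrichments.

    Keeps records whose unit has at least ``min_unit_genes`` genes, at least
    ``min_overlap`` of them on the term, a term size inside the inclusive
    ``term_size_range``, and an FDR-corrected q strictly below ``q_max``.
    Expects columns ``unit_size, overlap, term_size, q``.
    """
    lo, hi = term_size_range
    keep = (
        (records["unit_size"] >= min_unit_genes)
        & (records["overlap"] >= min_overlap)
        & (records["term_size"] >= lo)
        & (records["term_size"] <= hi)
        & (records["q"] < q_max)
    )
    return records.loc[keep].reset_index(drop=True)


def community_composition_enrichment(
    communities: dict,
    class_sets: dict,
    universe: set,
) -> pd.DataFrame:
    """Hypergeometric composition tests of communities against gene classes.

    For every (community, class) pair: upper-tail hypergeometric p of the
    overlap in ``universe``; BH correction across all pairs.  Used to ask
    which communities of an expanded systems map are dominated by conserved
    or by species-specific genes.
    """
    rows = []
    for cid in sorted(communities):
        for cls in sorted(class_sets):
            unit = communities[cid] & universe
            cgenes = class_sets[cls] & universe
            p = hypergeom_enrichment(unit, cgenes, universe)
            rows.append(
                {
                    "unit_id": cid,
                    "class": cls,
                    "unit_size": len(unit),
                    "class_size": len(cgenes),
                    "overlap": len(unit & cgenes),
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out
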