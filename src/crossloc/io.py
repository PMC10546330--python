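"""Readers and writers for the pipeline's plain-text formats.

Edge lists (2-column TSV and SIF), GMT gene sets, gene-level summary tables,
ortholog tables, OBO-lite ontology TSVs, annotation TSVs and NPS tables.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .ontology import PhenotypeOntology
from .propagation import NPSTable


def write_edge_list(graph: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0]:
                g.add_edge(parts[0], parts[1])
    return g


def write_sif(graph: nx.Graph, path, interaction: str = "pp") -> None:
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{u}\t{interaction}\t{v}\n")


def read_sif(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                g.add_edge(parts[0], parts[2])
    return g


def write_gmt(gene_sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_gmt(path) -> dict:
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = set(parts[2:])
    return out


def write_gene_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_snp_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ortholog_table(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_ortholog_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_nps(table: NPSTable, path) -> None:
    out = table.table.copy()
    out.insert(0, "gene", out.index)
    out["n_null"] = table.n_null
    out.to_csv(path, sep="\t", index=False)


def read_nps(path, species: str = "", alpha: float = 0.5) -> NPSTable:
    df = pd.read_csv(path, sep="\t").set_index("gene")
    n_null = int(df["n_null"].iloc[0]) if "n_null" in df else 0
    table = df[["nps", "is_seed"]].copy()
    table["flagged"] = ~table["nps"].apply(pd.notna) if "flagged" not in df else df["flagged"]
    return NPSTable(table, species, n_null, alpha)


def write_ontology(ontology: PhenotypeOntology, path) -> None:
    """OBO-lite TSV: term_id, parent_id ('' for the root), name; one row per
    (term, parent) pair so multi-parent terms span several rows."""
    with open(path, "w") as fh:
        fh.write("term_id\tparent_id\tname\n")
        for term in sorted(ontology.terms):
            parents = sorted(ontology.parents.get(term, ())) or [""]
            for p in parents:
                fh.write(f"{term}\t{p}\t{ontology.terms[term]}\n")


def read_ontology(path) -> PhenotypeOntology:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    terms: dict = {}
    parents: dict = {}
    for row in df.itertuples(index=False):
        terms[row.term_id] = row.name
        parents.setdefault(row.term_id, set())
        if row.parent_id:
            parents[row.term_id].add(row.parent_id)
    parents = {t: frozenset(ps) for t, ps in parents.items()}
    root = [t for t, ps in parents.items() if not ps][0]
    return PhenotypeOntology(terms=terms, parents=parents, root=root)


def write_annotations(pairs, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tterm_id\n")
        for gene, term in sorted(pairs):
            fh.write(f"{gene}\t{term}\n")


def read_annotations(path) -> set:
    df = pd.read_csv(path, sep="\t")
    return {(row.gene, row.term_id) for row in df.itertuples(index=False)}


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
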