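"""Phenotype ontology DAG and gene annotations.

A lightweight rooted DAG of phenotype terms (id -> parents) with gene
annotations; annotations are propagated up the hierarchy so that a gene
annotated to a term is counted for every ancestor term, which is how
phenotype databases are conventionally queried.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class OntologyError(ValueError):
    pass


@dataclass(frozen=True)
class PhenotypeOntology:
    terms: dict  # id -> name
    parents: dict  # id -> frozenset of parent ids ({} for the root)
    root: str

    def __post_init__(self):
        roots = [t for t in self.terms if not self.parents.get(t)]
        if len(roots) != 1 or roots[0] != self.root:
            raise OntologyError(f"ontology must have the single root {self.root!r}, found {roots}")
        for t, ps in self.parents.items():
            unknown = set(ps) - set(self.terms)
            if unknown:
                raise OntologyError(f"term {t} has unknown parents {sorted(unknown)}")
        self._check_acyclic()

    def _check_acyclic(self):
        state: dict = {}

        def visit(t, stack):
            if t in stack:
                raise OntologyError(f"cycle through term {t}")
            if state.get(t):
                return
            for p in self.parents.get(t, ()):
                visit(p, stack | {t})
            state[t] = True

        for t in self.terms:
            visit(t, frozenset())

    def ancestors(self, term: str) -> frozenset:
        """All ancestors of ``term``, excluding the term itself (memoized)."""
        memo = self.__dict__.setdefault("_ancestor_memo", {})
        if term not in memo:
            out: set = set()
            for p in self.parents.get(term, ()):
                out.add(p)
                out |= self.ancestors(p)
            memo[term] = frozenset(out)
        return memo[term]

    def children_of(self, term: str) -> list:
        return sorted(t for t, ps in self.parents.items() if term in ps)

    def descendants(self, term: str) -> frozenset:
        out: set = set()
        frontier = [term]
        while frontier:
            t = frontier.pop()
            for ch in self.children_of(t):
                if ch not in out:
                    out.add(ch)
                    frontier.append(ch)
        return frozenset(out)


@dataclass
class AnnotationSet:
    """Direct and ancestry-closed gene->term annotations."""

    direct: set  # {(gene, term)}
    propagated: set  # closed under ancestry
    phenotyped_genes: set = field(default_factory=set)

    def genes_for(self, term: str) -> set:
        return {g for g, t in self.propagated if t == term}

    def term_gene_map(self) -> dict:
        out: dict = {}
        for g, t in self.propagated:
            out.setdefault(t, set()).add(g)
        return out


def propagate_annotations(
    ontology: PhenotypeOntology,
    direct_pairs,
    phenotyped_genes: set | None = None,
) -> AnnotationSet:
    """Close gene->term annotations under the ontology's ancestor relation.

    Idempotent: propagating an already-propagated set changes nothing.  Genes
    annotated to unknown terms raise, listing the offenders.
    """
    direct = set(direct_pairs)
    unknown = sorted({t for _, t in direct if t not in ontology.terms})
    if unknown:
        raise OntologyError(f"annotations reference unknown terms: {unknown}")
    propagated = set(direct)
    for gene, term in direct:
        for anc in ontology.ancestors(term):
            propagated.add((gene, anc))
    phenotyped = set(phenotyped_genes) if phenotyped_genes is not None else {g for g, _ in direct}
    return AnnotationSet(direct=direct, propagated=propagated, phenotyped_genes=phenotyped)
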