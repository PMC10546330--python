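"""Ontology propagation, exact tests, BH, PPV traversal, filter rules."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from crossloc.enrichment import (
    EnrichmentError,
    bh_adjust,
    community_composition_enrichment,
    filter_term_enrichments,
    fisher_enrichment,
    hypergeom_enrichment,
    ppv,
    traverse_phenotypes,
    validation_rate,
)
from crossloc.ontology import OntologyError, PhenotypeOntology, propagate_annotations
from crossloc.seed_mapping import seed_overlap_test


@pytest.fixture()
def chain_ontology():
    return PhenotypeOntology(
        terms={"root": "r", "p": "p", "t": "t"},
        parents={"root": frozenset(), "p": frozenset({"root"}), "t": frozenset({"p"})},
        root="root",
    )


@pytest.fixture()
def diamond_ontology():
    return PhenotypeOntology(
        terms={"g": "grand", "m1": "m1", "m2": "m2", "leaf": "leaf"},
        parents={
            "g": frozenset(),
            "m1": frozenset({"g"}),
            "m2": frozenset({"g"}),
            "leaf": frozenset({"m1", "m2"}),
        },
        root="g",
    )


class TestOntology:
    def test_leaf_annotation_propagates_to_all_ancestors(self, chain_ontology):
        ann = propagate_annotations(chain_ontology, {("gene1", "t")})
        assert ann.propagated == {("gene1", "t"), ("gene1", "p"), ("gene1", "root")}

    def test_root_annotation_adds_nothing(self, chain_ontology):
        ann = propagate_annotations(chain_ontology, {("gene1", "root")})
        assert ann.propagated == {("gene1", "root")}

    def test_diamond_counts_grandparent_once(self, diamond_ontology):
        ann = propagate_annotations(diamond_ontology, {("gene1", "leaf")})
        assert ann.propagated == {
            ("gene1", "leaf"),
            ("gene1", "m1"),
            ("gene1", "m2"),
            ("gene1", "g"),
        }

    def test_propagation_is_idempotent(self, diamond_ontology):
        once = propagate_annotations(diamond_ontology, {("gene1", "leaf"), ("gene2", "m1")})
        twice = propagate_annotations(diamond_ontology, once.propagated)
        assert twice.propagated == once.propagated

    def test_unknown_term_raises_with_offender(self, chain_ontology):
        with pytest.raises(OntologyError, match="ghost"):
            propagate_annotations(chain_ontology, {("gene1", "ghost")})

    def test_multiple_roots_rejected(self):
        with pytest.raises(OntologyError):
            PhenotypeOntology(
                terms={"a": "", "b": ""},
                parents={"a": frozenset(), "b": frozenset()},
                root="a",
            )

    def test_cycle_rejected(self):
        with pytest.raises(OntologyError, match="cycle"):
            PhenotypeOntology(
                terms={"r": "", "a": "", "b": ""},
                parents={"r": frozenset(), "a": frozenset({"b", "r"}), "b": frozenset({"a"})},
                root="r",
            )


def exact_fisher_greater(a, b, c, d):
    """Independent oracle: hypergeometric tail with exact rational arithmetic."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = math.comb(n, col1)
    tail = Fraction(0)
    for k in range(a, min(row1, col1) + 1):
        if col1 - k <= c + d:
            tail += Fraction(math.comb(row1, k) * math.comb(n - row1, col1 - k), denom)
    return float(tail)


class TestFisher:
    def test_odds_ratio_is_ad_over_bc(self):
        universe = set(range(100))
        unit = set(range(10))  # a=8, b=2
        term = set(range(8)) | set(range(10, 20))  # c=10, d=80
        rec = fisher_enrichment(unit, term, universe)
        assert (rec.a, rec.b, rec.c, rec.d) == (8, 2, 10, 80)
        assert rec.odds_ratio == pytest.approx(32.0)

    def test_p_matches_exact_enumeration_for_small_tables(self):
        for a, b, c, d in itertools.product(range(6), repeat=4):
            if a + b + c + d == 0:
                continue
            universe = set(range(a + b + c + d))
            unit = set(range(a + b))
            term = set(range(a)) | set(range(a + b, a + b + c))
            rec = fisher_enrichment(unit, term, universe)
            assert rec.p == pytest.approx(exact_fisher_greater(a, b, c, d), abs=1e-10)

    def test_no_overlap_gives_or_zero_and_p_near_one(self):
        universe = set(range(50))
        rec = fisher_enrichment(set(range(5)), set(range(10, 15)), universe)
        assert rec.a == 0 and rec.odds_ratio == 0.0
        assert rec.p > 0.5

    def test_infinite_and_undefined_odds_ratios(self):
        universe = set(range(10))
        rec = fisher_enrichment(set(range(5)), set(range(5)), universe)
        assert rec.odds_ratio == float("inf")
        rec2 = fisher_enrichment(set(), set(), universe)
        assert math.isnan(rec2.odds_ratio)

    def test_empty_universe_rejected(self):
        with pytest.raises(EnrichmentError):
            fisher_enrichment({"a"}, {"a"}, set())


class TestHypergeom:
    def test_equals_seed_overlap_test(self):
        universe = set(range(30))
        unit, cls = set(range(8)), set(range(4, 16))
        p1 = hypergeom_enrichment(unit, cls, universe)
        _, p2 = seed_overlap_test(cls, unit, 30)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_known_enumeration_value(self):
        p = hypergeom_enrichment(set(range(4)), set(range(5)), set(range(10)))
        assert p == pytest.approx(5 / 210, rel=1e-12)

    def test_zero_overlap_close_to_one(self):
        p = hypergeom_enrichment({0, 1}, {5, 6}, set(range(40)))
        assert p == pytest.approx(1.0, abs=0.2)


class TestBH:
    def test_textbook_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate_inputs(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_naive_definition_on_random_vectors(self, rng):
        for m in (1, 2, 7, 50, 200):
            p = rng.random(m)
            q = bh_adjust(p)
            order = np.argsort(p, kind="stable")
            naive = np.empty(m)
            for i in range(m):
                vals = [
                    m * p[order[j]] / (j + 1)
                    for j in range(m)
                    if p[order[j]] >= p[order[i]] or j >= np.where(order == order[i])[0][0]
                ]
                # naive: q_i = min over ranks j >= rank(i) of m p_(j) / j
                rank_i = int(np.where(order == order[i])[0][0])
                naive[order[i]] = min(
                    min(m * p[order[j]] / (j + 1) for j in range(rank_i, m)), 1.0
                )
            assert np.allclose(q, naive, atol=1e-12)

    def test_monotone_in_p(self, rng):
        p = rng.random(40)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(EnrichmentError):
            bh_adjust([0.5, 1.5])


class TestPPVAndValidation:
    def test_ppv_is_phenotype_normalized(self):
        assert ppv(set(range(3)), set(range(30))) == pytest.approx(0.1)
        assert ppv(set(range(50)), set(range(10))) == 1.0
        assert ppv({1}, {2}) == 0.0
        with pytest.raises(EnrichmentError):
            ppv({1}, set())

    def test_validation_rate_counts_phenotyped_denominator(self, chain_ontology):
        direct = {(f"g{i}", "t") for i in range(4)} | {(f"g{i}", "p") for i in range(4, 10)}
        ann = propagate_annotations(chain_ontology, direct)
        rate = validation_rate({f"g{i}" for i in range(10)}, ann, {"t"})
        assert rate == pytest.approx(0.4)

    def test_relevant_root_saturates_rate(self, chain_ontology):
        direct = {("g1", "t"), ("g2", "p")}
        ann = propagate_annotations(chain_ontology, direct)
        assert validation_rate({"g1", "g2"}, ann, {"root"}) == 1.0

    def test_no_phenotyped_genes_is_nan(self, chain_ontology):
        ann = propagate_annotations(chain_ontology, {("other", "t")})
        assert math.isnan(validation_rate({"g1"}, ann, {"t"}))


class TestTraversal:
    def _fixture(self, seed=0, enriched=True):
        """Two-level ontology; module genes concentrated in branch b1."""
        rng = np.random.default_rng(seed)
        terms = {"root": "r", "b1": "", "b2": "", "b3": "", "l1": "", "l2": ""}
        parents = {
            "root": frozenset(),
            "b1": frozenset({"root"}),
            "b2": frozenset({"root"}),
            "b3": frozenset({"root"}),
            "l1": frozenset({"b1"}),
            "l2": frozenset({"b1"}),
        }
        onto = PhenotypeOntology(terms, parents, "root")
        genes = [f"g{i}" for i in range(400)]
        module = set(genes[:60])
        direct = set()
        for i, g in enumerate(genes):
            u = rng.random()
            # deterministic parity split keeps the sibling branches exactly null
            direct.add((g, ["b2", "b3"][i % 2]))
            if g in module and enriched:
                if u < 0.8:
                    direct.add((g, ["l1", "l2"][int(rng.integers(2))]))
            elif u < 0.1:
                direct.add((g, ["l1", "l2"][int(rng.integers(2))]))
        ann = propagate_annotations(onto, direct)
        return onto, ann, module, set(genes)

    def test_enriched_branch_kept_and_expanded(self):
        onto, ann, module, universe = self._fixture(seed=1)
        out = traverse_phenotypes(module, onto, ann, universe)
        kept = set(out["term_id"])
        assert "b1" in kept
        assert kept & {"l1", "l2"}  # descended into the enriched branch

    def test_sibling_branches_not_kept(self):
        onto, ann, module, universe = self._fixture(seed=2)
        out = traverse_phenotypes(module, onto, ann, universe)
        assert not set(out["term_id"]) & {"b2", "b3"}

    def test_equal_ppv_child_dropped(self):
        onto = PhenotypeOntology(
            {"root": "", "c": ""},
            {"root": frozenset(), "c": frozenset({"root"})},
            "root",
        )
        # child term annotates exactly the genes of the root term: equal PPV
        direct = {(f"g{i}", "c") for i in range(10)}
        ann = propagate_annotations(onto, direct)
        out = traverse_phenotypes({"g0", "g1"}, onto, ann, {f"g{i}" for i in range(10)})
        assert out.empty  # PPV_c == PPV_root -> strict inequality drops it

    def test_no_enrichment_keeps_nothing(self):
        onto, ann, module, universe = self._fixture(seed=3, enriched=False)
        out = traverse_phenotypes(module, onto, ann, universe)
        assert not set(out["term_id"]) & {"b2", "b3"}


class TestFilters:
    def _records(self, **overrides):
        base = {"unit_size": 10, "overlap": 5, "term_size": 100, "q": 1e-4}
        base.update(overrides)
        return pd.DataFrame([base])

    def test_small_unit_dropped(self):
        assert filter_term_enrichments(self._records(unit_size=4)).empty
        assert len(filter_term_enrichments(self._records(unit_size=5))) == 1

    def test_term_size_range_inclusive(self):
        assert filter_term_enrichments(self._records(term_size=49)).empty
        assert len(filter_term_enrichments(self._records(term_size=50))) == 1
        assert len(filter_term_enrichments(self._records(term_size=1000))) == 1
        assert filter_term_enrichments(self._records(term_size=1001)).empty

    def test_q_threshold_is_strict(self):
        assert filter_term_enrichments(self._records(q=1e-3)).empty
        assert len(filter_term_enrichments(self._records(q=0.999e-3))) == 1

    def test_min_overlap(self):
        assert filter_term_enrichments(self._records(overlap=2)).empty


class TestComposition:
    def test_composition_table_shape_and_bh(self):
        universe = set(range(100))
        communities = {"c1": set(range(20)), "c2": set(range(50, 70))}
        classes = {"conserved": set(range(25)), "specific": set(range(60, 90))}
        out = community_composition_enrichment(communities, classes, universe)
        assert len(out) == 4
        assert (out["q"] >= out["p"] - 1e-12).all()
        best = out.sort_values("p").iloc[0]
        assert (best["unit_id"], best["class"]) in {("c1", "conserved"), ("c2", "specific")}
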