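"""Random-walk-with-restart propagation and NPS scoring."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from crossloc.propagation import (
    NullHeatEnsemble,
    PropagationError,
    Propagator,
    build_null_ensemble,
    column_normalize,
    compute_nps,
    consensus_nps,
    degree_bins,
    propagate,
    score_seed_set,
)

from conftest import random_connected_graph


class TestColumnNormalize:
    def test_path_graph_swaps_unit_heat(self, path_graph):
        w = column_normalize(path_graph).toarray()
        assert np.allclose(w, [[0, 1], [1, 0]])

    def test_triangle_splits_heat_in_half(self):
        w = column_normalize(nx.complete_graph(3)).toarray()
        assert np.allclose(w, [[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])

    def test_star_center_divides_leaves_concentrate(self):
        g = nx.Graph([("c", "l1"), ("c", "l2")])
        w = column_normalize(g, nodelist=["c", "l1", "l2"]).toarray()
        assert np.allclose(w[:, 0], [0, 0.5, 0.5])  # center's column
        assert np.allclose(w[:, 1], [1, 0, 0])
        assert np.allclose(w[:, 2], [1, 0, 0])

    def test_columns_sum_to_one(self):
        g = random_connected_graph(60, 0.08, seed=3)
        w = column_normalize(g)
        assert np.allclose(np.asarray(w.sum(axis=0)).ravel(), 1.0)

    def test_isolated_node_warns(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("loner")
        with pytest.warns(UserWarning, match="isolated"):
            column_normalize(g)


class TestPropagate:
    def test_two_node_closed_form(self, path_graph):
        f = propagate(path_graph, ["A"], alpha=0.5).values
        assert f["A"] == pytest.approx(2 / 3, abs=1e-12)
        assert f["B"] == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_dense_inverse_oracle(self):
        g = random_connected_graph(40, 0.1, seed=5)
        nodes = sorted(g.nodes())
        seeds = nodes[:5]
        w = column_normalize(g, nodelist=nodes).toarray()
        y0 = np.array([1.0 if n in seeds else 0.0 for n in nodes])
        expected = np.linalg.inv(np.eye(len(nodes)) - 0.5 * w) @ (0.5 * y0)
        f = propagate(g, seeds, alpha=0.5).values
        assert np.allclose(f.to_numpy(), expected, atol=1e-10)

    def test_all_seeds_on_regular_graph_gives_unit_heat(self):
        g = nx.circulant_graph(12, [1, 2])  # 4-regular, connected
        f = propagate(g, list(g.nodes()), alpha=0.5).values
        assert np.allclose(f.to_numpy(), 1.0, atol=1e-10)

    def test_component_without_seed_stays_cold(self):
        g = nx.Graph([("a", "b"), ("x", "y")])
        f = propagate(g, ["a"]).values
        assert f["x"] == 0.0 and f["y"] == 0.0
        assert f["a"] > 0 and f["b"] > 0

    def test_heat_conservation(self):
        for seed in (1, 2, 3):
            g = random_connected_graph(80, 0.06, seed=seed)
            seeds = sorted(g.nodes())[: 5 + seed]
            f = propagate(g, seeds)
            assert f.total == pytest.approx(len(seeds), abs=1e-8)

    def test_power_series_equivalence(self):
        alpha = 0.5
        n_terms = int(np.ceil(np.log(1e-9) / np.log(alpha)))
        g = random_connected_graph(50, 0.1, seed=9)
        nodes = sorted(g.nodes())
        seeds = nodes[:4]
        w = column_normalize(g, nodelist=nodes).toarray()
        y0 = np.array([1.0 if n in seeds else 0.0 for n in nodes])
        term, series = y0.copy(), y0.copy()
        for _ in range(n_terms):
            term = alpha * (w @ term)
            series += term
        f = propagate(g, seeds, alpha=alpha).values.to_numpy()
        assert np.max(np.abs(f - (1 - alpha) * series)) < 1e-6

    def test_adding_a_seed_never_cools_any_gene(self):
        g = random_connected_graph(50, 0.08, seed=13)
        nodes = sorted(g.nodes())
        prop = Propagator(g)
        f1 = prop.heat(nodes[:4]).values.to_numpy()
        f2 = prop.heat(nodes[:5]).values.to_numpy()
        assert np.all(f2 - f1 >= -1e-12)

    def test_missing_seeds_warn_and_absent_everywhere_errors(self, path_graph):
        with pytest.warns(UserWarning, match="not in the network"):
            propagate(path_graph, ["A", "ghost"])
        with pytest.raises(PropagationError, match="no seed"):
            propagate(path_graph, ["ghost"])

    def test_alpha_bounds(self, path_graph):
        with pytest.raises(PropagationError, match="alpha"):
            propagate(path_graph, ["A"], alpha=1.0)


class TestDegreeBins:
    def test_min_bin_respected(self):
        g = random_connected_graph(100, 0.07, seed=2)
        prop = Propagator(g)
        bins = degree_bins(prop.degrees, min_bin=10)
        sizes = np.bincount(bins)
        assert (sizes >= 10).all()

    def test_equal_degrees_not_split(self):
        degrees = np.array([1] * 12 + [2] * 12 + [3] * 12)
        bins = degree_bins(degrees, min_bin=10)
        for d in (1, 2, 3):
            assert len(set(bins[degrees == d])) == 1

    def test_tiny_network_rejected(self):
        with pytest.raises(PropagationError):
            degree_bins(np.array([1, 2, 3]), min_bin=10)


class TestNullEnsemble:
    def test_null_sets_match_size_and_degree(self):
        g = random_connected_graph(300, 0.03, seed=4)
        prop = Propagator(g)
        seeds = sorted(g.nodes())[:20]
        null = build_null_ensemble(prop, seeds, n_null=200, rng_seed=7)
        assert null.heats.shape == (200, len(prop.nodes))
        # each null propagation conserves the seed count => same set size
        assert np.allclose(null.heats.sum(axis=1), len(seeds), atol=1e-8)

    def test_null_mean_degree_tracks_observed(self):
        g = random_connected_graph(300, 0.03, seed=4)
        prop = Propagator(g)
        rng = np.random.default_rng(1)
        seeds = list(rng.choice(prop.nodes, size=25, replace=False))
        obs_mean = np.mean([g.degree(s) for s in seeds])
        bins = degree_bins(prop.degrees)
        pos = {n: i for i, n in enumerate(prop.nodes)}
        need = np.bincount(bins[[pos[s] for s in seeds]], minlength=bins.max() + 1)
        members = [np.flatnonzero(bins == b) for b in range(bins.max() + 1)]
        means = []
        for _ in range(1000):
            picks = np.concatenate(
                [rng.choice(members[b], size=k, replace=False) for b, k in enumerate(need) if k]
            )
            means.append(prop.degrees[picks].mean())
        means = np.asarray(means)
        assert abs(obs_mean - means.mean()) < 4 * means.std()

    def test_determinism(self):
        g = random_connected_graph(100, 0.06, seed=8)
        prop = Propagator(g)
        seeds = sorted(g.nodes())[:10]
        e1 = build_null_ensemble(prop, seeds, n_null=20, rng_seed=3)
        e2 = build_null_ensemble(prop, seeds, n_null=20, rng_seed=3)
        assert np.array_equal(e1.heats, e2.heats)


class TestComputeNPS:
    def _toy(self, n_null=50, seed=6):
        g = random_connected_graph(50, 0.1, seed=seed)
        prop = Propagator(g)
        seeds = sorted(g.nodes())[:5]
        obs = prop.heat(seeds)
        null = build_null_ensemble(prop, seeds, n_null=n_null, rng_seed=2)
        return obs, null

    def test_matches_independent_reimplementation(self):
        obs, null = self._toy()
        table = compute_nps(obs, null).table
        # independent oracle: per-gene z from raw log-heats, written separately
        for i, gene in enumerate(null.index):
            heats = null.heats[:, i]
            f = obs.values.iloc[i]
            if f > 0 and (heats > 0).all():
                logs = np.log(heats)
                expect = (np.log(f) - logs.mean()) / logs.std(ddof=1)
                assert table["nps"].iloc[i] == pytest.approx(expect, abs=1e-10)
            else:
                assert np.isnan(table["nps"].iloc[i])

    def test_z_of_null_mean_is_zero_and_one_sd_is_one(self):
        obs, null = self._toy()
        i = 0
        logs = np.log(null.heats[:, i])
        hacked = obs.values.copy()
        hacked.iloc[i] = np.exp(logs.mean())
        obs.values = hacked
        t = compute_nps(obs, null).table
        assert t["nps"].iloc[i] == pytest.approx(0.0, abs=1e-10)
        hacked.iloc[i] = np.exp(logs.mean() + logs.std(ddof=1))
        t = compute_nps(obs, null).table
        assert t["nps"].iloc[i] == pytest.approx(1.0, abs=1e-10)

    def test_mismatched_alpha_rejected(self):
        obs, null = self._toy()
        null.alpha = 0.3
        with pytest.raises(PropagationError, match="alpha"):
            compute_nps(obs, null)


class TestConsensusNPS:
    def test_small_seed_table_bypasses_subsampling(self):
        g = random_connected_graph(120, 0.05, seed=10)
        prop = Propagator(g)
        genes = sorted(g.nodes())[:15]
        records = pd.DataFrame({"gene_id": genes, "p": 1e-5})
        direct = score_seed_set(prop, genes, n_null=50, rng_seed=4)
        via = consensus_nps(prop, records, max_seeds=500, n_null=50, rng_seed=4)
        pd.testing.assert_series_equal(direct.nps, via.nps)

    def test_percentile_convention_linear_interpolation(self):
        assert np.percentile(np.arange(1, 101), 75) == pytest.approx(75.25)

    def test_uniform_weights_match_uniform_subsampling_oracle(self):
        g = random_connected_graph(150, 0.05, seed=12)
        prop = Propagator(g)
        genes = sorted(g.nodes())[:40]
        records = pd.DataFrame({"gene_id": genes, "p": 1e-3})  # all-equal weights
        cons = consensus_nps(
            prop, records, max_seeds=20, n_reps=30, n_null=50, rng_seed=5
        ).nps
        # oracle: explicit uniform subsampling, separate code path
        rng = np.random.default_rng(99)
        reps = []
        for _ in range(30):
            sub = list(rng.choice(genes, size=20, replace=False))
            reps.append(score_seed_set(prop, sub, n_null=50, rng_seed=rng).nps.to_numpy())
        oracle = np.nanpercentile(np.vstack(reps), 75, axis=0)
        both = np.isfinite(cons.to_numpy()) & np.isfinite(oracle)
        assert both.mean() > 0.9
        diff = cons.to_numpy()[both] - oracle[both]
        assert np.abs(np.median(diff)) < 0.5  # Monte-Carlo agreement, not identity

    def test_nonpositive_weights_rejected(self):
        g = random_connected_graph(60, 0.1, seed=1)
        genes = sorted(g.nodes())[:30]
        records = pd.DataFrame({"gene_id": genes, "p": 1.0})  # -log10(1) = 0
        with pytest.raises(PropagationError, match="weights"):
            consensus_nps(g, records, max_seeds=10, n_reps=2, n_null=10)
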