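"""Graph measures against hand values, brute-force oracles, and networkx."""

import numpy as np
import networkx as nx
import pytest

import oracles
from conftest import random_weighted_graph
from tbiconn import (
    WeightedNetwork,
    betweenness_centrality,
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    local_efficiency,
    measure_table,
    nodal_efficiency,
    node_strength,
    normalize_measures,
    shortest_paths,
)
from tbiconn.measures import length_matrix
from tbiconn.stats import anova_oneway


def triangle(w=1.0):
    m = np.full((3, 3), w)
    np.fill_diagonal(m, 0)
    return m


def chain(weights):
    n = len(weights) + 1
    m = np.zeros((n, n))
    for i, w in enumerate(weights):
        m[i, i + 1] = m[i + 1, i] = w
    return m


class TestHandValues:
    def test_strength_triangle(self):
        assert np.allclose(node_strength(triangle()), [2, 2, 2])

    def test_strength_partial_graph(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 2
        m[0, 2] = m[2, 0] = 3
        assert np.allclose(node_strength(m), [5, 2, 3])

    def test_chain_distance_adds(self):
        d = shortest_paths(chain([1, 1]))
        assert d[0, 2] == pytest.approx(2.0)

    def test_inverse_weight_length_convention(self):
        d = shortest_paths(chain([2]))
        assert d[0, 1] == pytest.approx(0.5)

    def test_global_efficiency_complete_unit_graph(self):
        assert global_efficiency(triangle()) == pytest.approx(1.0)

    def test_global_efficiency_edgeless(self):
        assert global_efficiency(np.zeros((4, 4))) == 0.0

    def test_cpl_complete_unit_graph(self):
        assert characteristic_path_length(triangle()) == pytest.approx(1.0)

    def test_cpl_three_edge_chain(self):
        # distances per direction: 1,1,2 between consecutive/skip pairs
        assert characteristic_path_length(chain([1, 1])) == pytest.approx(4 / 3)

    def test_cpl_undefined_without_edges(self):
        with pytest.raises(ValueError, match="no reachable pair"):
            characteristic_path_length(np.zeros((3, 3)))

    def test_clustering_triangle_is_one(self):
        assert np.allclose(clustering_coefficient(triangle()), [1, 1, 1])

    def test_clustering_star_is_zero(self):
        star = np.zeros((5, 5))
        star[0, 1:] = star[1:, 0] = 1
        assert np.allclose(clustering_coefficient(star), 0)

    def test_local_efficiency_triangle(self):
        assert np.allclose(local_efficiency(triangle()), [1, 1, 1])

    def test_local_efficiency_chain_midpoint(self):
        assert local_efficiency(chain([1, 1]))[1] == 0.0

    def test_betweenness_chain(self):
        assert np.allclose(betweenness_centrality(chain([1, 1])), [0, 1, 0])

    def test_betweenness_star_center(self):
        star = np.zeros((5, 5))
        star[0, 1:] = star[1:, 0] = 1
        bc = betweenness_centrality(star)
        assert bc[0] == pytest.approx(6.0)  # C(4,2) leaf pairs
        assert np.allclose(bc[1:], 0)


class TestOracleEquivalence:
    """All measures agree with naive brute-force implementations on small graphs."""

    @pytest.mark.parametrize("seed", range(8))
    def test_all_measures_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            w = random_weighted_graph(rng)
            wl = w.tolist()
            assert np.allclose(node_strength(w), oracles.strength(wl), atol=1e-10)
            assert np.allclose(
                shortest_paths(w), oracles.floyd_warshall(wl), atol=1e-10
            )
            assert global_efficiency(w) == pytest.approx(
                oracles.global_efficiency(wl), abs=1e-10
            )
            assert np.allclose(
                nodal_efficiency(w), oracles.nodal_efficiency(wl), atol=1e-10
            )
            assert np.allclose(
                clustering_coefficient(w), oracles.clustering(wl), atol=1e-10
            )
            assert np.allclose(
                local_efficiency(w), oracles.local_efficiency(wl), atol=1e-10
            )
            assert np.allclose(
                betweenness_centrality(w), oracles.betweenness(wl), atol=1e-10
            )
            finite = np.isfinite(shortest_paths(w)) & ~np.eye(len(w), dtype=bool)
            if finite.any():
                assert characteristic_path_length(w) == pytest.approx(
                    oracles.characteristic_path_length(wl), abs=1e-10
                )

    @pytest.mark.parametrize("seed", range(4))
    def test_betweenness_matches_networkx(self, seed):
        rng = np.random.default_rng(100 + seed)
        w = random_weighted_graph(rng, n=10)
        lengths = length_matrix(w)
        g = nx.Graph()
        g.add_nodes_from(range(10))
        for i in range(10):
            for j in range(i + 1, 10):
                if w[i, j] > 0:
                    g.add_edge(i, j, length=lengths[i, j])
        ref = nx.betweenness_centrality(g, weight="length", normalized=False)
        bc = betweenness_centrality(w)
        assert np.allclose(bc, [ref[i] for i in range(10)], atol=1e-9)


class TestInvariants:
    def test_permutation_equivariance(self):
        rng = np.random.default_rng(12)
        w = random_weighted_graph(rng, n=7)
        perm = rng.permutation(7)
        wp = w[np.ix_(perm, perm)]
        assert np.allclose(node_strength(wp), node_strength(w)[perm])
        assert np.allclose(
            betweenness_centrality(wp), betweenness_centrality(w)[perm], atol=1e-9
        )
        assert np.allclose(
            clustering_coefficient(wp), clustering_coefficient(w)[perm]
        )
        assert global_efficiency(wp) == pytest.approx(global_efficiency(w))
        assert characteristic_path_length(wp) == pytest.approx(
            characteristic_path_length(w)
        )

    def test_uniform_scaling(self):
        rng = np.random.default_rng(13)
        w = random_weighted_graph(rng, n=7)
        c = 3.7
        assert np.allclose(node_strength(c * w), c * node_strength(w))
        # max-scaled clustering and path-based betweenness are scale-free
        assert np.allclose(
            clustering_coefficient(c * w), clustering_coefficient(w)
        )
        assert np.allclose(
            betweenness_centrality(c * w), betweenness_centrality(w), atol=1e-9
        )

    def test_adding_edge_never_decreases_efficiency(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            w = random_weighted_graph(rng, n=6, density=0.4)
            absent = np.argwhere(np.triu(w == 0, k=1))
            if len(absent) == 0:
                continue
            i, j = absent[rng.integers(len(absent))]
            before = global_efficiency(w)
            w2 = w.copy()
            w2[i, j] = w2[j, i] = rng.random() + 0.1
            assert global_efficiency(w2) >= before - 1e-12


class TestMeasureTable:
    def _nets(self, k=3, seed=20):
        rng = np.random.default_rng(seed)
        w = random_weighted_graph(rng, n=6) + 0.01  # ensure connected-ish
        np.fill_diagonal(w, 0)
        net = WeightedNetwork(weights=w / np.triu(w, 1).sum(), total_fibers=1000.0)
        return [(f"s{i}", net) for i in range(k)]

    def test_identical_networks_give_identical_rows(self):
        table = measure_table(self._nets())
        pivots = [
            g.drop(columns="subject_id").reset_index(drop=True)
            for _, g in table.groupby("subject_id")
        ]
        for other in pivots[1:]:
            assert pivots[0].equals(other)

    def test_row_count(self):
        table = measure_table(self._nets(k=3))
        # 5 global + 6 nodal measures x 6 nodes, per subject
        assert len(table) == 3 * (5 + 6 * 6)

    def test_round_trip_through_csv(self, tmp_path):
        table = measure_table(self._nets())
        path = tmp_path / "measures.csv"
        table.to_csv(path, index=False)
        back = __import__("pandas").read_csv(path, keep_default_na=False)
        assert np.allclose(back["value"], table["value"])
        assert list(back["measure"]) == list(table["measure"])

    def test_label_mismatch_rejected(self):
        (sid, net), *_ = self._nets()
        other = WeightedNetwork(
            weights=net.weights, node_labels=[f"x{i}" for i in range(6)]
        )
        with pytest.raises(ValueError, match="parcellation"):
            measure_table([("a", net), ("b", other)])


class TestNormalizeMeasures:
    def test_midpoint_scales_to_half(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "subject_id": ["a", "b", "c"],
                "scope": ["global"] * 3,
                "node_label": [""] * 3,
                "measure": ["strength"] * 3,
                "value": [2.0, 4.0, 3.0],
            }
        )
        out = normalize_measures(table)
        assert list(out["value"]) == [0.0, 1.0, 0.5]

    def test_idempotent(self):
        table = measure_table(
            [
                (f"s{i}", WeightedNetwork(weights=random_weighted_graph(np.random.default_rng(i), n=5)))
                for i in range(3)
            ]
        )
        once = normalize_measures(table)
        twice = normalize_measures(once)
        assert np.allclose(once["value"], twice["value"])

    def test_anova_f_invariant_under_scaling(self):
        rng = np.random.default_rng(2)
        raw = [rng.normal(10, 2, 8), rng.normal(11, 2, 8), rng.normal(9, 2, 8)]
        pooled = np.concatenate(raw)
        lo, hi = pooled.min(), pooled.max()
        scaled = [(g - lo) / (hi - lo) for g in raw]
        assert anova_oneway(raw).F == pytest.approx(anova_oneway(scaled).F)

    def test_constant_measure_warns(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "scope": ["global"] * 2,
                "node_label": [""] * 2,
                "measure": ["strength"] * 2,
                "value": [1.0, 1.0],
            }
        )
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_measures(table)
        assert list(out["value"]) == [0.0, 0.0]
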