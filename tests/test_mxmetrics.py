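"""Single-layer and multiplex clustering / participation metrics."""

from __future__ import annotations

import numpy as np
import pytest

from mxbrain.errors import LayerCountError
from mxbrain.mxmetrics import (
    mcc_network,
    mcc_node,
    mcc_two_layer_triads,
    mpc_network,
    participation,
    weighted_clustering,
)
from mxbrain.netbuild import Layer

from _oracles import (
    brute_mcc1,
    brute_mcc2,
    brute_participation,
    brute_weighted_clustering,
    random_multiplex,
)
from conftest import layers_from_weights


def layer_from(w):
    w = np.asarray(w, dtype=float)
    return Layer(weighted=w, binary=(w > 0).astype(int), label="L", cost=0.0)


def sym(n, edges):
    w = np.zeros((n, n))
    for i, j, v in edges:
        w[i, j] = w[j, i] = v
    return w


class TestWeightedClustering:
    def test_unit_triangle_is_fully_clustered(self):
        w = sym(3, [(0, 1, 1), (1, 2, 1), (0, 2, 1)])
        assert np.allclose(weighted_clustering(layer_from(w)).values, 1.0)

    def test_star_center_has_no_triangles(self):
        w = sym(4, [(0, 1, 1), (0, 2, 1), (0, 3, 1)])
        c = weighted_clustering(layer_from(w)).values
        assert c[0] == 0.0
        assert np.all(c[1:] == 0.0)  # leaves have degree 1

    def test_weighted_triangle_matches_triad_enumeration(self):
        w = sym(3, [(0, 1, 1), (1, 2, 1), (0, 2, 0.5)])
        layer = layer_from(w)
        got = weighted_clustering(layer).values
        expected = brute_weighted_clustering(layer.weighted, layer.binary)
        assert np.allclose(got, expected, atol=1e-14)
        # closed form: each node has k=2, numerator 2*(1*1*0.5)^(1/3)
        assert got[0] == pytest.approx(0.5 ** (1 / 3), abs=1e-12)

    def test_random_layers_match_oracle(self, rng):
        for _ in range(10):
            lw, lb = random_multiplex(rng, 7, 1)
            layer = layer_from(lw[0])
            assert np.allclose(
                weighted_clustering(layer).values,
                brute_weighted_clustering(lw[0], lb[0]),
                atol=1e-12,
            )


class TestMultiplexClustering:
    def test_triangle_closing_through_second_layer_reaches_one(self):
        # layer 1: edges 0-1, 0-2 centred at node 0; layer 2: edge 1-2
        l1 = sym(3, [(0, 1, 1), (0, 2, 1)])
        l2 = sym(3, [(1, 2, 1)])
        c = mcc_node(layers_from_weights([l1, l2])).values
        assert c[0] == pytest.approx(1.0, abs=1e-12)

    def test_triangle_confined_to_one_layer_scores_zero(self):
        tri = sym(3, [(0, 1, 1), (1, 2, 1), (0, 2, 1)])
        empty = np.zeros((3, 3))
        c = mcc_node(layers_from_weights([tri, empty])).values
        assert np.all(c == 0.0)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(8):
            n = int(rng.integers(4, 9))
            m = int(rng.integers(2, 5))
            lw, lb = random_multiplex(rng, n, m)
            net = layers_from_weights(lw)
            assert np.allclose(mcc_node(net).values, brute_mcc1(lw, lb), atol=1e-12)

    def test_single_layer_is_rejected(self):
        with pytest.raises(Exception):
            layers_from_weights([sym(3, [(0, 1, 1)])])

    def test_identical_layers_reduce_to_single_layer_clustering(self, rng):
        lw, _ = random_multiplex(rng, 8, 1)
        single = weighted_clustering(layer_from(lw[0])).values
        multi = mcc_node(layers_from_weights([lw[0], lw[0].copy(), lw[0].copy()])).values
        assert np.allclose(multi, single, atol=1e-12)

    def test_node_relabeling_equivariance(self, rng):
        lw, _ = random_multiplex(rng, 6, 3)
        perm = rng.permutation(6)
        permuted = [w[np.ix_(perm, perm)] for w in lw]
        a = mcc_node(layers_from_weights(lw)).values
        b = mcc_node(layers_from_weights(permuted)).values
        assert np.allclose(a[perm], b, atol=1e-12)


class TestThreeLayerTriads:
    def test_two_layers_rejected(self):
        net = layers_from_weights([sym(3, [(0, 1, 1)]), sym(3, [(1, 2, 1)])])
        with pytest.raises(LayerCountError):
            mcc_two_layer_triads(net)

    def test_one_edge_per_layer_triangle_scores_positive(self):
        l1 = sym(3, [(0, 1, 1)])
        l2 = sym(3, [(1, 2, 1)])
        l3 = sym(3, [(0, 2, 1)])
        c = mcc_two_layer_triads(layers_from_weights([l1, l2, l3])).values
        assert np.all(c > 0)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(6):
            n = int(rng.integers(4, 7))
            lw, _ = random_multiplex(rng, n, 3)
            net = layers_from_weights(lw)
            assert np.allclose(mcc_two_layer_triads(net).values, brute_mcc2(lw), atol=1e-12)


class TestParticipation:
    def test_equal_degrees_give_full_participation(self):
        w = sym(4, [(0, 1, 1), (2, 3, 0.5)])
        net = layers_from_weights([w, w.copy()])
        p, nlp, o = participation(net)
        assert np.allclose(p.values, 1.0)
        assert np.allclose(nlp.values.sum(axis=0), 1.0)

    def test_single_layer_concentration_scores_zero(self):
        w = sym(3, [(0, 1, 1), (1, 2, 1), (0, 2, 1)])
        net = layers_from_weights([w, np.zeros((3, 3))])
        p, _, o = participation(net)
        assert np.all(p.values == 0.0)
        assert np.all(o.values == 2)

    def test_two_layer_degrees_two_and_one(self):
        # degrees (2, 1): P = 2 * (1 - (4/9 + 1/9)) = 8/9
        l1 = sym(3, [(0, 1, 1), (0, 2, 1)])
        l2 = sym(3, [(0, 1, 1)])
        p = participation(layers_from_weights([l1, l2]))[0].values
        assert p[0] == pytest.approx(8 / 9, abs=1e-12)

    def test_zero_overlap_node_is_zero_with_zero_nlp(self):
        w = sym(4, [(0, 1, 1)])
        p, nlp, o = participation(layers_from_weights([w, w.copy()]))
        assert o.values[2] == 0 and p.values[2] == 0.0
        assert np.all(nlp.values[:, 2] == 0.0)

    def test_matches_direct_definition(self, rng):
        for _ in range(8):
            lw, lb = random_multiplex(rng, 8, 4)
            got = participation(layers_from_weights(lw))[0].values
            assert np.allclose(got, brute_participation(lb), atol=1e-12)


class TestNetworkAverages:
    def test_network_values_are_node_means(self, rng):
        lw, _ = random_multiplex(rng, 8, 3)
        net = layers_from_weights(lw)
        t = mcc_node(net)
        assert mcc_network(t) == pytest.approx(float(np.mean(t.values)))
        p = participation(net)[0]
        assert mpc_network(p) == pytest.approx(float(np.mean(p.values)))
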