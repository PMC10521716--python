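import dataclasses

import numpy as np
import pytest
import scipy.sparse as sp

from sgcp.sgcn import (
    EncoderConfig,
    GCNEncoder,
    SGCNEncoder,
    SpatialConvParams,
    encode,
    gcn_encode,
    make_encoder,
    spatial_aggregate,
    spatial_conv_multi,
)

from conftest import graph_from_edges


def loop_aggregate(H, P, A, U, b):
    """Triple-loop scalar oracle for the geometric aggregation."""
    n, d = H.shape
    out = np.zeros((n, d))
    for i in range(n):
        for j in range(n):
            if A[i, j]:
                gate = np.maximum(U.T @ (P[j] - P[i]) + b, 0.0)
                for c in range(d):
                    out[i, c] += gate[c] * H[j, c]
    return out


def random_instance(rng, n, d):
    H = rng.normal(size=(n, d))
    P = rng.normal(size=(n, 3))
    A = np.triu((rng.random((n, n)) < 0.3).astype(int), 1)
    A = A + A.T
    U = rng.normal(size=(3, d))
    b = rng.normal(size=d)
    return H, P, A, U, b


class TestSpatialAggregate:
    def test_zero_parameters_annihilate(self):
        rng = np.random.default_rng(0)
        H, P, A, _, _ = random_instance(rng, 6, 4)
        out = spatial_aggregate(H, P, sp.csr_matrix(A), np.zeros((3, 4)), np.zeros(4))
        assert np.allclose(out, 0.0)

    def test_unit_bias_gives_neighbour_sum(self):
        rng = np.random.default_rng(1)
        H, P, A, _, _ = random_instance(rng, 6, 4)
        out = spatial_aggregate(H, P, sp.csr_matrix(A), np.zeros((3, 4)), np.ones(4))
        assert np.allclose(out, A @ H)

    def test_three_node_path_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        H = rng.normal(size=(3, 2))
        P = rng.normal(size=(3, 3))
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        U, b = rng.normal(size=(3, 2)), rng.normal(size=2)
        out = spatial_aggregate(H, P, sp.csr_matrix(A), U, b)
        assert np.allclose(out, loop_aggregate(H, P, A, U, b), atol=1e-6)

    def test_matches_loop_oracle_on_random_instances(self):
        # vectorised implementation vs independent scalar triple loop
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(2, 31))
            d = int(rng.integers(1, 9))
            H, P, A, U, b = random_instance(rng, n, d)
            out = spatial_aggregate(H, P, sp.csr_matrix(A), U, b)
            assert np.max(np.abs(out - loop_aggregate(H, P, A, U, b))) < 1e-6

    def test_isolated_node_maps_to_zero(self):
        rng = np.random.default_rng(4)
        H = rng.normal(size=(3, 2))
        P = rng.normal(size=(3, 3))
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = A[1, 0] = 1
        out = spatial_aggregate(H, P, sp.csr_matrix(A), rng.normal(size=(3, 2)), np.ones(2))
        assert np.allclose(out[2], 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spatial_aggregate(
                np.zeros((3, 2)), np.zeros((3, 3)), sp.csr_matrix((3, 3)),
                np.zeros((3, 5)), np.zeros(5),
            )


class TestSpatialConvMulti:
    def test_single_filter_reduces_to_aggregate(self):
        rng = np.random.default_rng(5)
        H, P, A, U, b = random_instance(rng, 8, 3)
        params = SpatialConvParams(filters=[(U, b)])
        assert np.allclose(
            spatial_conv_multi(H, P, sp.csr_matrix(A), params),
            spatial_aggregate(H, P, sp.csr_matrix(A), U, b),
        )

    def test_zero_second_filter_zeroes_second_half(self):
        rng = np.random.default_rng(6)
        H, P, A, U, b = random_instance(rng, 8, 3)
        params = SpatialConvParams(filters=[(U, b), (np.zeros((3, 3)), np.zeros(3))])
        out = spatial_conv_multi(H, P, sp.csr_matrix(A), params)
        assert np.allclose(out[:, 3:], 0.0)

    def test_equals_stacked_aggregates(self):
        rng = np.random.default_rng(7)
        H, P, A, _, _ = random_instance(rng, 10, 2)
        filters = [(rng.normal(size=(3, 2)), rng.normal(size=2)) for _ in range(3)]
        out = spatial_conv_multi(H, P, sp.csr_matrix(A), SpatialConvParams(filters))
        ref = np.concatenate(
            [spatial_aggregate(H, P, sp.csr_matrix(A), U, b) for U, b in filters], axis=1
        )
        assert np.allclose(out, ref)

    def test_inconsistent_filter_shapes_rejected(self):
        with pytest.raises(ValueError):
            SpatialConvParams(
                filters=[(np.zeros((3, 2)), np.zeros(2)), (np.zeros((3, 4)), np.zeros(4))]
            )


class TestEncoders:
    def test_translation_invariance(self, random_graph):
        cfg = EncoderConfig(seed=1)
        h1 = encode(random_graph, cfg)
        shifted = dataclasses.replace(random_graph)
        shifted.coords = random_graph.coords + np.array([10.0, -4.0, 2.0])
        h2 = encode(shifted, cfg)
        assert np.max(np.abs(h1 - h2)) < 1e-6

    @pytest.mark.parametrize("enc_fn", [encode, gcn_encode])
    def test_permutation_equivariance(self, random_graph, enc_fn):
        cfg = EncoderConfig(seed=2)
        h = enc_fn(random_graph, cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(random_graph.n_nodes)
        permuted = graph_from_edges(random_graph.n_nodes, [], n_feat=6)
        dense = random_graph.adjacency.toarray()[np.ix_(perm, perm)]
        permuted.adjacency = sp.csr_matrix(dense)
        permuted.features = random_graph.features[perm]
        permuted.coords = random_graph.coords[perm]
        hp = enc_fn(permuted, cfg)
        assert np.max(np.abs(hp - h[perm])) < 1e-8

    def test_locality_beyond_receptive_field(self):
        # path 0-1-2-3-4: with 2 layers, node 0 cannot see node 4's features
        g = graph_from_edges(5, [(i, i + 1) for i in range(4)], n_feat=3, seed=8)
        cfg = EncoderConfig(n_layers=2, filters=4, feature_transform=None, seed=9)
        h = encode(g, cfg)
        g2 = graph_from_edges(5, [(i, i + 1) for i in range(4)], n_feat=3, seed=8)
        g2.features = g.features.copy()
        g2.features[4] = g2.features[4] + 100
        g2.coords = g.coords
        h2 = encode(g2, cfg)
        assert np.allclose(h[0], h2[0])
        assert not np.allclose(h, h2)

    def test_one_layer_unit_bias_reduces_to_neighbour_sum(self, random_graph):
        cfg = EncoderConfig(
            n_layers=1, filters=1, mixing=False, feature_transform=None, seed=0
        )
        enc = SGCNEncoder(cfg, random_graph.n_features)
        d = random_graph.n_features
        enc.params["l0.U0"] = np.zeros((3, d))
        enc.params["l0.b0"] = np.ones(d)
        h = enc.embed(random_graph)
        A = random_graph.adjacency.toarray()
        assert np.allclose(h, A @ random_graph.features)

    def test_forward_matches_functional_multi(self, random_graph):
        cfg = EncoderConfig(
            n_layers=1, filters=3, mixing=False, feature_transform=None, seed=5
        )
        enc = SGCNEncoder(cfg, random_graph.n_features)
        h = enc.embed(random_graph)
        ref = spatial_conv_multi(
            random_graph.features.astype(float),
            random_graph.coords,
            random_graph.adjacency,
            enc.layer_params(0),
        )
        assert np.allclose(h, ref, atol=1e-10)

    def test_gcn_single_node_is_linear_map(self):
        g = graph_from_edges(1, [], n_feat=4, seed=0)
        cfg = EncoderConfig(type="gcn", n_layers=1, feature_transform=None, seed=1)
        enc = GCNEncoder(cfg, 4)
        h = enc.embed(g)
        # A_hat = 1 for a single self-looped node; last layer is linear
        ref = g.features.astype(float) @ enc.params["l0.W"] + enc.params["l0.c"]
        assert np.allclose(h, ref)

    def test_gcn_identical_isolated_nodes_identical_embeddings(self):
        g = graph_from_edges(2, [], n_feat=3, seed=0)
        g.features = np.ones((2, 3))
        h = gcn_encode(g, EncoderConfig(seed=4))
        assert np.allclose(h[0], h[1])

    def test_gcn_matches_dense_oracle(self):
        g = graph_from_edges(4, [(0, 1), (1, 2), (2, 3)], n_feat=3, seed=10)
        cfg = EncoderConfig(type="gcn", n_layers=1, feature_transform=None, seed=2)
        enc = GCNEncoder(cfg, 3)
        A = g.adjacency.toarray() + np.eye(4)
        dinv = 1.0 / np.sqrt(A.sum(axis=1))
        A_hat = np.diag(dinv) @ A @ np.diag(dinv)
        ref = A_hat @ g.features.astype(float) @ enc.params["l0.W"] + enc.params["l0.c"]
        assert np.max(np.abs(enc.embed(g) - ref)) < 1e-6

    def test_dimension_chain_checked_at_construction(self):
        cfg = EncoderConfig()
        enc = make_encoder(cfg, 6)
        g = graph_from_edges(4, [(0, 1)], n_feat=3)
        with pytest.raises(ValueError, match="features"):
            enc.embed(g)


class TestGradients:
    @pytest.mark.parametrize("enc_type", ["sgcn", "gcn"])
    def test_parameter_gradients_match_finite_differences(self, enc_type):
        rng = np.random.default_rng(0)
        g = graph_from_edges(7, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (0, 6)],
                             n_feat=3, seed=11)
        cfg = EncoderConfig(
            type=enc_type, n_layers=2, filters=2, hidden_dim=4, output_dim=3,
            feature_transform=None, seed=7,
        )
        enc = make_encoder(cfg, 3)
        gt = enc.prepare(g)
        W = rng.normal(size=(7, enc.output_dim))  # random linear readout

        def objective():
            h, _ = enc.forward(gt, want_cache=False)
            return float((h * W).sum())

        h, cache = enc.forward(gt)
        grads = enc.backward(gt, cache, W)
        eps = 1e-6
        for name in grads:
            flat = enc.params[name].ravel()
            idx = rng.integers(0, flat.size, size=min(4, flat.size))
            for i in idx:
                old = flat[i]
                flat[i] = old + eps
                f_plus = objective()
                flat[i] = old - eps
                f_minus = objective()
                flat[i] = old
                fd = (f_plus - f_minus) / (2 * eps)
                assert grads[name].ravel()[i] == pytest.approx(fd, abs=1e-4, rel=1e-4)
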