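import dataclasses
import math

import numpy as np
import pytest

from sgcp.augment import AugmentationConfig
from sgcp.contrastive import (
    ContrastiveConfig,
    ProjectionHead,
    _loss_and_grad,
    contrastive_loss,
    cosine_similarity,
    embed_nodes,
    train_stage1,
)
from sgcp.sgcn import EncoderConfig
from sgcp.synthetic import make_region

from conftest import graph_from_edges


def scalar_infonce(Z1, Z2, tau):
    """Independent term-by-term scalar implementation of the multiview loss."""

    def cos(a, b):
        return float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))

    n = len(Z1)

    def ell(A, B, i):
        # anchor A[i]; positive B[i]; negatives: all B[k], k != i and A[k], k != i
        num = math.exp(cos(A[i], B[i]) / tau)
        den = num
        for k in range(n):
            if k != i:
                den += math.exp(cos(A[i], B[k]) / tau)
                den += math.exp(cos(A[i], A[k]) / tau)
        return -math.log(num / den)

    total = sum(ell(Z1, Z2, i) + ell(Z2, Z1, i) for i in range(n))
    return total / (2 * n)


class TestCosine:
    def test_identical_vectors(self):
        assert cosine_similarity([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cosine_similarity([1.0, 0.0], [0.0, 5.0]) == pytest.approx(0.0)

    def test_worked_example(self):
        v = cosine_similarity([1, 2, 3], [-1, 0, 1])
        assert v == pytest.approx(2 / (math.sqrt(14) * math.sqrt(2)), abs=1e-5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([1, 2], [1, 2, 3])

    def test_zero_vector_defined_as_zero(self):
        assert cosine_similarity([0.0, 0.0], [1.0, 2.0]) == 0.0


class TestContrastiveLoss:
    def test_single_identical_pair_is_zero(self):
        z = np.array([[1.0, 2.0]])
        assert contrastive_loss(z, z, tau=0.5) == pytest.approx(0.0, abs=1e-12)

    def test_matches_scalar_oracle_n2(self):
        Z = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert contrastive_loss(Z, Z, 0.5) == pytest.approx(
            scalar_infonce(Z, Z, 0.5), abs=1e-8
        )

    def test_matches_scalar_oracle_random(self):
        rng = np.random.default_rng(21)
        Z1 = rng.normal(size=(4, 3))
        Z2 = rng.normal(size=(4, 3))
        assert contrastive_loss(Z1, Z2, 0.5) == pytest.approx(
            scalar_infonce(Z1, Z2, 0.5), abs=1e-8
        )

    def test_nonnegative_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(1, 8))
            d = int(rng.integers(2, 5))
            assert contrastive_loss(rng.normal(size=(n, d)), rng.normal(size=(n, d)),
                                    tau=0.5) >= 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        Z1, Z2 = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        perm = rng.permutation(6)
        assert contrastive_loss(Z1[perm], Z2[perm], 0.5) == pytest.approx(
            contrastive_loss(Z1, Z2, 0.5), abs=1e-10
        )

    def test_symmetric_under_view_swap(self):
        rng = np.random.default_rng(10)
        Z1, Z2 = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        assert contrastive_loss(Z1, Z2, 0.7) == pytest.approx(
            contrastive_loss(Z2, Z1, 0.7), abs=1e-10
        )

    def test_alignment_decreases_anchor_loss(self):
        # moving the positive pair together (negatives fixed) lowers the loss
        rng = np.random.default_rng(11)
        Z2 = rng.normal(size=(4, 3))
        base = rng.normal(size=(4, 3))
        far, near = base.copy(), base.copy()
        far[0] = -Z2[0] + 0.1 * rng.normal(size=3)
        near[0] = Z2[0]
        assert contrastive_loss(near, Z2, 0.5) < contrastive_loss(far, Z2, 0.5)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            contrastive_loss(np.ones((2, 2)), np.ones((2, 2)), tau=0.0)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(12)
        Z1, Z2 = rng.normal(size=(3, 2)), rng.normal(size=(3, 2))
        _, dZ1, dZ2 = _loss_and_grad(Z1, Z2, 0.5)
        eps = 1e-6
        for Z, dZ in ((Z1, dZ1), (Z2, dZ2)):
            for i in range(3):
                for j in range(2):
                    old = Z[i, j]
                    Z[i, j] = old + eps
                    f_plus = contrastive_loss(Z1, Z2, 0.5)
                    Z[i, j] = old - eps
                    f_minus = contrastive_loss(Z1, Z2, 0.5)
                    Z[i, j] = old
                    fd = (f_plus - f_minus) / (2 * eps)
                    assert dZ[i, j] == pytest.approx(fd, abs=1e-4)

    def test_float32_path_consistent(self):
        rng = np.random.default_rng(13)
        Z1, Z2 = rng.normal(size=(10, 4)), rng.normal(size=(10, 4))
        l64, _, _ = _loss_and_grad(Z1, Z2, 0.5, dtype=np.float64)
        l32, _, _ = _loss_and_grad(Z1, Z2, 0.5, dtype=np.float32)
        assert l32 == pytest.approx(l64, rel=1e-5)


class TestProjectionHead:
    def test_must_reduce_dimension(self):
        with pytest.raises(ValueError):
            ProjectionHead(4, 4)

    def test_default_halves_dimension(self):
        head = ProjectionHead(32)
        assert head.d_out == 16

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(14)
        head = ProjectionHead(4, 2, seed=0)
        H = rng.normal(size=(5, 4))
        W = rng.normal(size=(5, 2))
        Z, cache = head.forward(H)
        grads, dH = head.backward(cache, W)
        eps = 1e-6
        for name in grads:
            flat = head.params[name].ravel()
            for i in range(min(3, flat.size)):
                old = flat[i]
                flat[i] = old + eps
                f_plus = float((head.forward(H, want_cache=False)[0] * W).sum())
                flat[i] = old - eps
                f_minus = float((head.forward(H, want_cache=False)[0] * W).sum())
                flat[i] = old
                assert grads[name].ravel()[i] == pytest.approx(
                    (f_plus - f_minus) / (2 * eps), abs=1e-5, rel=1e-5
                )


class TestTrainStage1:
    def _config(self, epochs=30, seed=0):
        return ContrastiveConfig(epochs=epochs, seed=seed)

    def _encoder_config(self):
        return EncoderConfig(hidden_dim=16, output_dim=16, seed=1)

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            ContrastiveConfig(epochs=0)

    def test_loss_decreases(self, small_region):
        res = train_stage1(small_region, self._encoder_config(), self._config())
        assert res.loss_trace[-1] < res.loss_trace[0]

    def test_same_seed_identical_traces(self, small_region):
        r1 = train_stage1(small_region, self._encoder_config(), self._config(epochs=5))
        r2 = train_stage1(small_region, self._encoder_config(), self._config(epochs=5))
        assert np.array_equal(r1.loss_trace, r2.loss_trace)

    def test_different_seeds_differ(self, small_region):
        r1 = train_stage1(small_region, self._encoder_config(), self._config(epochs=5))
        r2 = train_stage1(
            small_region, self._encoder_config(), self._config(epochs=5, seed=9)
        )
        assert not np.array_equal(r1.loss_trace, r2.loss_trace)

    def test_embed_nodes_deterministic(self, small_region):
        res = train_stage1(small_region, self._encoder_config(), self._config(epochs=3))
        h1 = embed_nodes(small_region, res)
        h2 = embed_nodes(small_region, res)
        assert np.array_equal(h1, h2)

    def test_isolated_node_embeds_to_constant_without_mixing(self):
        g = graph_from_edges(4, [(0, 1)], n_feat=3, seed=2)
        cfg = EncoderConfig(n_layers=1, filters=1, mixing=False, seed=0)
        res = train_stage1(
            g,
            cfg,
            ContrastiveConfig(
                epochs=2,
                augment1=AugmentationConfig(p_e=0.0, p_f=0.0),
                augment2=AugmentationConfig(p_e=0.0, p_f=0.0),
            ),
            head=ProjectionHead(3, 2, seed=0, dtype=np.float32),
        )
        h = embed_nodes(g, res)
        assert np.allclose(h[2], 0.0) and np.allclose(h[3], 0.0)

    def test_embeddings_transfer_better_than_raw_profiles(self, small_config):
        # linear probe trained on one region, tested on the other: frozen
        # embeddings must transfer across regions better than the raw
        # connectivity profiles (whose fingerprint columns are region-specific
        # and therefore saturate within-region but not across)
        from sklearn.linear_model import LogisticRegression

        import sgcp
        from sgcp.synthetic import make_dataset

        regions = make_dataset(small_config, n_regions=2)
        enc = EncoderConfig(hidden_dim=16, output_dim=16, seed=1)
        res = train_stage1(regions, enc, ContrastiveConfig(epochs=120, seed=0))
        hs = [np.asarray(embed_nodes(g, res), np.float64) for g in regions]
        raws = [sgcp.transform_features(g.features) for g in regions]
        ys = [g.labels for g in regions]

        def cross_acc(Xs):
            accs = []
            for tr, te in ((0, 1), (1, 0)):
                clf = LogisticRegression(max_iter=2000).fit(Xs[tr], ys[tr])
                accs.append(clf.score(Xs[te], ys[te]))
            return float(np.mean(accs))

        assert cross_acc(hs) > cross_acc(raws)

    def test_nonfinite_loss_aborts_with_diagnostic(self, small_region):
        cfg = ContrastiveConfig(epochs=3, tau=1e-12)
        with pytest.raises(FloatingPointError, match="tau"):
            train_stage1(small_region, self._encoder_config(), cfg)
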