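import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from debatch._autograd import Tensor
from debatch.losses import (
    LossWeights,
    aggregate,
    classifier_loss,
    grouping_term,
    grouping_term_distance,
    reconstruction_loss,
    variation_loss,
)


class TestReconstructionLoss:
    def test_identity_is_zero(self):
        x = np.random.default_rng(0).normal(size=(3, 4))
        assert reconstruction_loss(x, x) == 0.0

    def test_hand_computed(self):
        assert reconstruction_loss(np.array([[0.0, 0.0]]), np.array([[1.0, 1.0]])) == 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        x, xh = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        perm = rng.permutation(5)
        assert reconstruction_loss(x, xh) == pytest.approx(
            reconstruction_loss(x[perm], xh[perm])
        )

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 2)), np.zeros((2, 3)))

    def test_mae(self):
        assert reconstruction_loss(
            np.array([[0.0, 0.0]]), np.array([[2.0, -2.0]]), kind="mae"
        ) == 2.0

    def test_tensor_path_matches_numpy(self):
        rng = np.random.default_rng(2)
        x, xh = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        t = reconstruction_loss(Tensor(x), Tensor(xh, requires_grad=True))
        assert t.item() == pytest.approx(reconstruction_loss(x, xh))


def _blob(rng, center, n, scale=0.05):
    return np.asarray(center) + rng.normal(0, scale, (n, 2))


class TestGroupingTerm:
    def test_perfect_coclustering_is_zero(self):
        rng = np.random.default_rng(3)
        X = np.vstack(
            [
                _blob(rng, [0, 0], 6),
                _blob(rng, [50, 0], 6),
                _blob(rng, [0, 50], 12),
            ]
        )
        groups = np.array(["A"] * 6 + ["B"] * 6 + [""] * 12, dtype=object)
        assert grouping_term(X, groups, random_state=0) == 0.0

    def test_fully_split_is_one(self):
        rng = np.random.default_rng(4)
        # the 2-member group straddles two far-apart clusters
        X = np.vstack(
            [
                _blob(rng, [0, 0], 1),
                _blob(rng, [80, 80], 1),
                _blob(rng, [0, 0], 8),
                _blob(rng, [80, 80], 8),
            ]
        )
        groups = np.array(["G", "G"] + [""] * 16, dtype=object)
        assert grouping_term(X, groups, min_cluster_size=4, random_state=0) == 1.0

    def test_three_one_split_is_half(self):
        rng = np.random.default_rng(5)
        # group of 4 split 3 + 1 across two clusters: 1 - 3/6 = 0.5
        X = np.vstack(
            [
                _blob(rng, [0, 0], 3),
                _blob(rng, [80, 80], 1),
                _blob(rng, [0, 0], 8),
                _blob(rng, [80, 80], 8),
            ]
        )
        groups = np.array(["G"] * 4 + [""] * 16, dtype=object)
        assert grouping_term(X, groups, min_cluster_size=4, random_state=0) == 0.5

    def test_no_reference_pairs_warns_zero(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        groups = np.array([""] * 10, dtype=object)
        with pytest.warns(UserWarning):
            assert grouping_term(X, groups) == 0.0

    def test_range(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 3))
        groups = np.array((["A"] * 5 + ["B"] * 5 + [""] * 20), dtype=object)
        r = grouping_term(X, groups, random_state=1)
        assert 0.0 <= r <= 1.0


class TestGroupingTermDistance:
    def test_coincident_replicates_zero(self):
        rng = np.random.default_rng(0)
        X = np.vstack([np.zeros((4, 3)), rng.normal(size=(10, 3))])
        groups = np.array(["G"] * 4 + [""] * 10, dtype=object)
        assert grouping_term_distance(X, groups) == pytest.approx(0.0)

    def test_scattered_replicates_near_one(self):
        # replicates drawn from the same distribution as everything else
        rng = np.random.default_rng(1)
        vals = []
        for seed in range(30):
            X = np.random.default_rng(seed).normal(size=(40, 5))
            groups = np.array(["G"] * 8 + [""] * 32, dtype=object)
            vals.append(grouping_term_distance(X, groups))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 4))
        groups = np.array(["G"] * 4 + [""] * 16, dtype=object)
        assert grouping_term_distance(X, groups) == pytest.approx(
            grouping_term_distance(1000.0 * X, groups)
        )

    def test_tensor_gradient_flows(self):
        rng = np.random.default_rng(3)
        X = Tensor(rng.normal(size=(10, 3)), requires_grad=True)
        groups = np.array(["G"] * 4 + [""] * 6, dtype=object)
        out = grouping_term_distance(X, groups)
        out.backward()
        assert np.abs(X.grad).sum() > 0


class TestClassifierLoss:
    def test_uniform_is_log_b(self):
        for n_batches in (2, 3, 7):
            logits = np.zeros((5, n_batches))
            labels = np.arange(5) % n_batches
            assert classifier_loss(logits, labels) == pytest.approx(np.log(n_batches))

    def test_perfect_prediction_near_zero(self):
        logits = np.full((4, 3), -1e3)
        labels = np.array([0, 1, 2, 0])
        logits[np.arange(4), labels] = 1e3
        assert classifier_loss(logits, labels) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_two_batch(self):
        # both rows predict their true class with probability 0.9 -> -ln(0.9)
        logits = np.log(np.array([[0.9, 0.1], [0.1, 0.9]]))
        assert classifier_loss(logits, np.array([0, 1])) == pytest.approx(-np.log(0.9))

    def test_single_batch_errors(self):
        with pytest.raises(ValueError):
            classifier_loss(np.zeros((3, 2)), np.array([1, 1, 1]))


def variation_loss_oracle(x, groups, batches):
    """Brute-force loop over (group, batch, feature) triples."""
    vcs = []
    for g in sorted(set(g for g in groups if g)):
        for b in sorted(set(batches)):
            idx = [i for i in range(len(groups)) if groups[i] == g and batches[i] == b]
            if len(idx) < 2:
                continue
            block = np.asarray(x)[idx]
            for j in range(block.shape[1]):
                col = block[:, j]
                vcs.append(col.std(ddof=1) / col.mean())
    return float(np.mean(vcs))


class TestVariationLoss:
    def test_identical_replicates_zero(self):
        x = np.tile([1e5, 2e5, 3e5], (4, 1))
        groups = np.array(["G"] * 4, dtype=object)
        batches = np.array(["B1", "B1", "B2", "B2"], dtype=object)
        assert variation_loss(x, groups, batches) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_123(self):
        x = np.array([[1.0], [2.0], [3.0]])
        groups = np.array(["G"] * 3, dtype=object)
        batches = np.array(["B1"] * 3, dtype=object)
        assert variation_loss(x, groups, batches) == pytest.approx(0.5)

    def test_nonreference_sample_ignored(self):
        x = np.array([[1.0], [2.0], [3.0], [1e9]])
        groups = np.array(["G", "G", "G", ""], dtype=object)
        batches = np.array(["B1"] * 4, dtype=object)
        assert variation_loss(x, groups, batches) == pytest.approx(0.5)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        x = 10 ** rng.uniform(3, 6, size=(12, 5))
        groups = np.array(["A"] * 4 + ["B"] * 4 + [""] * 4, dtype=object)
        batches = np.array(list("XXYY") * 3, dtype=object)
        assert variation_loss(x, groups, batches) == pytest.approx(
            variation_loss_oracle(x, groups, batches)
        )

    def test_tensor_path_matches_numpy(self):
        rng = np.random.default_rng(8)
        x = 10 ** rng.uniform(3, 6, size=(6, 4))
        groups = np.array(["A"] * 6, dtype=object)
        batches = np.array(["X", "X", "X", "Y", "Y", "Y"], dtype=object)
        t = variation_loss(Tensor(x, requires_grad=True), groups, batches)
        assert t.item() == pytest.approx(variation_loss(x, groups, batches))
        t.backward()

    def test_no_evaluable_cells_errors(self):
        x = np.ones((2, 2))
        groups = np.array(["", ""], dtype=object)
        batches = np.array(["B1", "B2"], dtype=object)
        with pytest.raises(ValueError):
            variation_loss(x, groups, batches)


class TestAggregate:
    def test_ablation_identity(self):
        w = LossWeights(2.0, 0.0, 0.0)
        assert aggregate(0.5, 0.25, 10.0, 10.0, w) == pytest.approx(2.0 * 0.75)

    def test_all_zero_weights(self):
        assert aggregate(1.0, 1.0, 1.0, 1.0, LossWeights(0, 0, 0)) == 0.0

    def test_adversarial_sign(self):
        w = LossWeights(1.0, 2.0, 1.0)
        low = aggregate(1.0, 0.0, 1.0, 1.0, w)
        high = aggregate(1.0, 0.0, 5.0, 1.0, w)
        assert high < low

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(0, 10),
        st.floats(0, 10),
        st.floats(0, 1),
        st.floats(0, 10),
        st.floats(0, 10),
        st.floats(0, 5),
    )
    def test_linear_in_each_lambda(self, lg, ld, rg, l_d, l_v, recon):
        base = aggregate(recon, rg, l_d, l_v, LossWeights(lg, ld, 1.0))
        doubled = aggregate(recon, rg, l_d, l_v, LossWeights(2 * lg, ld, 1.0))
        assert doubled - base == pytest.approx(lg * (recon + rg), rel=1e-9, abs=1e-9)

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            LossWeights(-1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            LossWeights(float("nan"), 0.0, 0.0)
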