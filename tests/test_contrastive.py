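"""Unit and property tests for the contrastive loss family."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asymcl.contrastive import (
    ContrastiveConfig,
    FeatureBatch,
    asymmetric_contrastive_loss,
    asymmetric_focal_contrastive_loss,
    contrastive_loss,
    contrastive_loss_value_and_grad,
    cosine_similarity_matrix,
    focal_contrastive_loss,
    l2_normalize,
    l2_normalize_backward,
    pair_probabilities,
    positive_negative_partition,
)

from conftest import random_batch
from reference import ref_losses, ref_pair_prob

# frozen from the literal scalar oracle (scratch independent evaluation)
FIXTURE_CL = 0.6265233750364456
FIXTURE_FCL = 0.1684980870038282
FIXTURE_ACL_ETA1 = 1.9461939306328366
FIXTURE_AFCL_ETA1_G2 = 1.3649866706133256


class TestL2Normalize:
    def test_scales_rows_to_unit_norm(self):
        out = l2_normalize(np.array([[3.0, 4.0], [1.0, 0.0]]))
        np.testing.assert_allclose(out, [[0.6, 0.8], [1.0, 0.0]])

    def test_preserves_direction_and_norms(self, rng):
        X = rng.standard_normal((5, 8))
        out = l2_normalize(X)
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-6)
        cos = np.sum(out * X, axis=1) / np.linalg.norm(X, axis=1)
        np.testing.assert_allclose(cos, 1.0, atol=1e-12)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            l2_normalize(np.array([[0.0, 0.0], [1.0, 0.0]]))


class TestFeatureBatch:
    def test_rejects_unnormalized_rows(self):
        with pytest.raises(ValueError, match="unit-norm"):
            FeatureBatch(np.array([[2.0, 0.0], [0.0, 1.0]]), np.array([0, 1]))

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError, match="at least 2"):
            FeatureBatch(np.array([[1.0, 0.0]]), np.array([0]))

    def test_from_raw_normalizes(self, rng):
        b = FeatureBatch.from_raw(rng.standard_normal((4, 3)), np.zeros(4, int))
        np.testing.assert_allclose(np.linalg.norm(b.embeddings, axis=1), 1.0)


class TestCosineSimilarity:
    def test_identical_antipodal_orthogonal(self):
        Z = np.array([[1.0, 0.0], [1.0, 0.0], [-1.0, 0.0], [0.0, 1.0]])
        S = cosine_similarity_matrix(FeatureBatch(Z, np.zeros(4, int)))
        assert S[0, 1] == pytest.approx(1.0)
        assert S[0, 2] == pytest.approx(-1.0)
        assert S[0, 3] == pytest.approx(0.0)

    def test_symmetric_bounded_unit_diagonal(self, rng):
        b = random_batch(rng, n=10, d=6)
        S = cosine_similarity_matrix(b)
        np.testing.assert_allclose(S, S.T, atol=1e-12)
        assert np.all(S >= -1.0) and np.all(S <= 1.0)
        np.testing.assert_allclose(np.diag(S), 1.0, atol=1e-9)


class TestPairProbabilities:
    def test_two_samples_give_certainty(self, rng):
        b = random_batch(rng, n=2, d=5)
        pp = pair_probabilities(b, tau=0.3)
        assert pp.probs[0, 1] == pytest.approx(1.0)
        assert pp.probs[1, 0] == pytest.approx(1.0)

    def test_three_sample_values(self, three_sample_batch):
        pp = pair_probabilities(three_sample_batch, tau=1.0)
        e = np.e
        assert pp.probs[0, 1] == pytest.approx(e / (e + 1), rel=1e-12)
        assert pp.probs[0, 2] == pytest.approx(1 / (e + 1), rel=1e-12)

    def test_matches_scalar_reference(self, rng):
        b = random_batch(rng, n=7, d=4)
        pp = pair_probabilities(b, tau=0.2)
        Z = b.embeddings.tolist()
        for i in range(7):
            for j in range(7):
                if i != j:
                    assert pp.probs[i, j] == pytest.approx(
                        ref_pair_prob(Z, 0.2, i, j), rel=1e-10
                    )

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        n=st.integers(2, 32),
        d=st.integers(2, 128),
        tau=st.floats(0.05, 2.0),
        seed=st.integers(0, 10_000),
    )
    def test_rows_are_stochastic(self, n, d, tau, seed):
        b = random_batch(np.random.default_rng(seed), n=n, d=d)
        P = pair_probabilities(b, tau).probs
        off = np.where(np.eye(n, dtype=bool), 0.0, P)
        np.testing.assert_allclose(off.sum(axis=1), 1.0, atol=1e-6)
        mask = ~np.eye(n, dtype=bool)
        # strictly positive always; the upper bound is strict in exact
        # arithmetic but reaches 1.0 in floats for a singleton row (n=2)
        assert np.all(P[mask] > 0.0) and np.all(P[mask] <= 1.0)
        if n > 2 and tau >= 0.2:
            assert np.all(P[mask] < 1.0)

    def test_temperature_sharpens_toward_nearest_neighbor(self):
        Z = l2_normalize(
            np.array([[1.0, 0.05], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.2]])
        )
        b = FeatureBatch(Z, np.zeros(4, int))
        probs = [pair_probabilities(b, tau).probs[0, 1] for tau in (1.0, 0.1, 0.01)]
        assert probs[0] < probs[1] < probs[2]
        assert probs[2] > 1.0 - 1e-6

    def test_rejects_bad_tau(self, three_sample_batch):
        with pytest.raises(ValueError):
            pair_probabilities(three_sample_batch, tau=0.0)


class TestPartition:
    def test_mixed_labels(self):
        parts = positive_negative_partition(np.array([0, 0, 1]))
        np.testing.assert_array_equal(parts[0][0], [1])
        np.testing.assert_array_equal(parts[0][1], [2])
        np.testing.assert_array_equal(parts[2][0], [])
        np.testing.assert_array_equal(parts[2][1], [0, 1])

    @pytest.mark.parametrize(
        "labels, all_pos_empty, all_neg_empty",
        [(np.zeros(5, int), False, True), (np.arange(5), True, False)],
    )
    def test_degenerate_labelings(self, labels, all_pos_empty, all_neg_empty):
        parts = positive_negative_partition(labels)
        assert all((len(P) == 0) == all_pos_empty for P, _ in parts)
        assert all((len(N) == 0) == all_neg_empty for _, N in parts)

    def test_partitions_the_candidate_set(self, rng):
        y = rng.integers(0, 3, 9)
        for i, (P, N) in enumerate(positive_negative_partition(y)):
            union = np.sort(np.concatenate([P, N]))
            np.testing.assert_array_equal(union, np.delete(np.arange(9), i))
            assert not np.intersect1d(P, N).size
            assert i not in union


class TestLossFixtures:
    """Frozen expected values from the independent scalar oracle."""

    def test_worked_three_sample_values(self, three_sample_batch):
        b = three_sample_batch
        assert contrastive_loss(b, 1.0, "sum") == pytest.approx(FIXTURE_CL, rel=1e-10)
        assert focal_contrastive_loss(b, 1.0, "sum") == pytest.approx(
            FIXTURE_FCL, rel=1e-10
        )
        assert asymmetric_contrastive_loss(b, 1.0, 1.0, "sum") == pytest.approx(
            FIXTURE_ACL_ETA1, rel=1e-10
        )
        assert asymmetric_focal_contrastive_loss(
            b, 1.0, 1.0, 2.0, "sum"
        ) == pytest.approx(FIXTURE_AFCL_ETA1_G2, rel=1e-10)

    def test_identical_pair_has_zero_loss(self):
        Z = np.array([[1.0, 0.0], [1.0, 0.0]])
        b = FeatureBatch(Z, np.array([0, 0]))
        assert contrastive_loss(b, 0.5, "sum") == pytest.approx(0.0, abs=1e-12)
        assert focal_contrastive_loss(b, 0.5, "sum") == pytest.approx(0.0, abs=1e-12)

    def test_mean_reduction_divides_by_batch_size(self, three_sample_batch):
        s = contrastive_loss(three_sample_batch, 1.0, "sum")
        m = contrastive_loss(three_sample_batch, 1.0, "mean")
        assert m == pytest.approx(s / 3, rel=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(30))
    def test_all_variants_match_double_loop(self, trial):
        rng = np.random.default_rng(1000 + trial)
        b = random_batch(rng, n_classes=int(rng.integers(1, 4)))
        tau = float(rng.uniform(0.05, 2.0))
        eta = float(rng.uniform(0.0, 10.0))
        gamma = float(rng.uniform(0.0, 5.0))
        ref = ref_losses(b.embeddings.tolist(), b.labels.tolist(), tau, eta, gamma)
        got = (
            contrastive_loss(b, tau, "sum"),
            focal_contrastive_loss(b, tau, "sum"),
            asymmetric_contrastive_loss(b, tau, eta, "sum"),
            asymmetric_focal_contrastive_loss(b, tau, eta, gamma, "sum"),
        )
        for g, r in zip(got, ref):
            assert g == pytest.approx(r, rel=1e-5, abs=1e-9)


class TestReductionLattice:
    @pytest.mark.parametrize("trial", range(10))
    def test_special_cases_collapse_exactly(self, trial):
        rng = np.random.default_rng(2000 + trial)
        b = random_batch(rng)
        tau = float(rng.uniform(0.05, 1.0))
        eta = float(rng.uniform(0.0, 5.0))
        cl = contrastive_loss(b, tau, "sum")
        assert asymmetric_contrastive_loss(b, tau, 0.0, "sum") == pytest.approx(
            cl, abs=1e-7
        )
        assert asymmetric_focal_contrastive_loss(
            b, tau, eta, 0.0, "sum"
        ) == pytest.approx(asymmetric_contrastive_loss(b, tau, eta, "sum"), abs=1e-7)
        assert asymmetric_focal_contrastive_loss(
            b, tau, 0.0, 1.0, "sum"
        ) == pytest.approx(focal_contrastive_loss(b, tau, "sum"), abs=1e-7)
        assert asymmetric_focal_contrastive_loss(
            b, tau, 0.0, 0.0, "sum"
        ) == pytest.approx(cl, abs=1e-7)


class TestLossProperties:
    @pytest.mark.parametrize("trial", range(10))
    def test_nonnegative_and_permutation_invariant(self, trial):
        rng = np.random.default_rng(3000 + trial)
        b = random_batch(rng)
        tau, eta, gamma = 0.3, float(rng.uniform(0, 5)), float(rng.uniform(0, 5))
        perm = rng.permutation(b.n)
        bp = FeatureBatch(b.embeddings[perm], b.labels[perm])
        for fn, args in [
            (contrastive_loss, (tau,)),
            (focal_contrastive_loss, (tau,)),
            (asymmetric_contrastive_loss, (tau, eta)),
            (asymmetric_focal_contrastive_loss, (tau, eta, gamma)),
        ]:
            v = fn(b, *args, "sum")
            assert v >= 0.0
            assert fn(bp, *args, "sum") == pytest.approx(v, abs=1e-6)

    def test_focal_bounded_by_plain_contrastive(self, rng):
        for _ in range(10):
            b = random_batch(rng)
            assert focal_contrastive_loss(b, 0.2, "sum") <= contrastive_loss(
                b, 0.2, "sum"
            ) + 1e-12

    def test_all_same_class_reduces_acl_to_cl(self, rng):
        b = random_batch(rng, n=6, n_classes=1)
        assert asymmetric_contrastive_loss(b, 0.5, 7.0, "sum") == pytest.approx(
            contrastive_loss(b, 0.5, "sum"), rel=1e-12
        )

    def test_all_distinct_classes_warns_and_is_zero(self):
        Z = l2_normalize(np.random.default_rng(5).standard_normal((4, 3)))
        b = FeatureBatch(Z, np.arange(4))
        with pytest.warns(RuntimeWarning, match="no anchor"):
            assert contrastive_loss(b, 0.5, "sum") == 0.0

    def test_anchor_without_positives_keeps_negative_term(self, three_sample_batch):
        # anchor 3 has no positives; its eta-weighted negative term must
        # still appear: ACL(eta) - CL is strictly increasing in eta
        b = three_sample_batch
        cl = contrastive_loss(b, 1.0, "sum")
        deltas = [
            asymmetric_contrastive_loss(b, 1.0, eta, "sum") - cl for eta in (1, 2, 4)
        ]
        assert deltas[0] > 0 and deltas[1] > deltas[0] and deltas[2] > deltas[1]


class TestGradients:
    @pytest.mark.parametrize(
        "eta, gamma", [(0.0, 0.0), (0.0, 1.0), (3.0, 0.0), (3.0, 4.0), (1.5, 0.7)]
    )
    def test_matches_central_finite_differences(self, eta, gamma):
        rng = np.random.default_rng(int(eta * 10 + gamma * 100))
        V = rng.standard_normal((6, 4))
        y = rng.integers(0, 2, 6)

        def f(Vf):
            b = FeatureBatch(l2_normalize(Vf), y)
            return contrastive_loss_value_and_grad(
                b, 0.5, eta, gamma, "sum", warn_no_positives=False
            )[0]

        Z = l2_normalize(V)
        _, gZ = contrastive_loss_value_and_grad(
            FeatureBatch(Z, y), 0.5, eta, gamma, "sum", warn_no_positives=False
        )
        gV = l2_normalize_backward(V, gZ)
        h = 1e-6
        fd = np.zeros_like(V)
        for i in range(V.shape[0]):
            for j in range(V.shape[1]):
                Vp, Vm = V.copy(), V.copy()
                Vp[i, j] += h
                Vm[i, j] -= h
                fd[i, j] = (f(Vp) - f(Vm)) / (2 * h)
        assert np.abs(fd - gV).max() <= 1e-4 * max(1.0, np.abs(fd).max())


class TestContrastiveConfig:
    def test_variant_resolution(self):
        assert ContrastiveConfig("cl", eta=9, gamma=9).effective_eta == 0.0
        assert ContrastiveConfig("cl", eta=9, gamma=9).effective_gamma == 0.0
        assert ContrastiveConfig("fcl").effective_gamma == 1.0
        assert ContrastiveConfig("acl", eta=5, gamma=9).effective_gamma == 0.0
        cfg = ContrastiveConfig("afcl", eta=5, gamma=7)
        assert (cfg.effective_eta, cfg.effective_gamma) == (5, 7)

    def test_default_temperature(self):
        assert ContrastiveConfig().tau == 0.07

    @pytest.mark.parametrize(
        "kwargs",
        [{"variant": "xx"}, {"tau": 0.0}, {"eta": -1}, {"gamma": -1}, {"reduction": "x"}],
    )
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ContrastiveConfig(**kwargs)

    def test_value_matches_functions(self, three_sample_batch):
        cfg = ContrastiveConfig("afcl", tau=1.0, eta=1.0, gamma=2.0, reduction="sum")
        assert cfg.value(three_sample_batch) == pytest.approx(
            FIXTURE_AFCL_ETA1_G2, rel=1e-10
        )
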