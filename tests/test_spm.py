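import numpy as np
import pytest

from spmlmi import (
    InteractionNetwork,
    PerturbationSample,
    SimilarityNetwork,
    build_bilayer,
    first_order_perturb,
    predict,
    rank_candidates,
    sample_perturbation,
)
from spmlmi.spm import layer_link_pairs, sample_from_layers

from _oracles import brute_force_perturb, naive_perturb


def _random_symmetric(n, rng, density=1.0):
    M = rng.standard_normal((n, n))
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 0.0)
    if density < 1.0:
        mask = rng.random((n, n)) < density
        mask = np.triu(mask, 1)
        mask = mask | mask.T
        M *= mask
    return M


def _toy_bilayer(rng, n_lnc=6, n_mi=4):
    ls = _random_symmetric(n_lnc, rng)
    ms = _random_symmetric(n_mi, rng)
    lm = (rng.random((n_lnc, n_mi)) < 0.5).astype(float)
    lm[0, 0] = 1.0
    lsn = SimilarityNetwork([f"L{i}" for i in range(n_lnc)], np.clip(ls, -1, 1))
    msn = SimilarityNetwork([f"M{i}" for i in range(n_mi)], np.clip(ms, -1, 1))
    lmn = InteractionNetwork(lsn.node_ids, msn.node_ids, lm)
    return build_bilayer(lsn, msn, lmn)


class TestSamplePerturbation:
    def test_conservation_exact(self, small_bilayer):
        ps = sample_perturbation(small_bilayer, 0.1, rng=0)
        np.testing.assert_array_equal(ps.A_R + ps.dA, small_bilayer.A)

    def test_disjoint_supports(self, small_bilayer):
        ps = sample_perturbation(small_bilayer, 0.1, rng=1)
        off = ~np.eye(small_bilayer.N, dtype=bool)
        assert not np.any((ps.A_R != 0.0) & (ps.dA != 0.0) & off)

    def test_per_layer_counts_are_rounded_fractions(self, small_bilayer):
        layers = layer_link_pairs(small_bilayer)
        ps = sample_perturbation(small_bilayer, 0.1, rng=2)
        removed = set(ps.removed_edges)
        n = small_bilayer.n_lnc
        for name, pairs in layers.items():
            got = sum(
                1 for (i, j) in removed
                if (name == "LS" and j < n)
                or (name == "MS" and i >= n)
                or (name == "LM" and i < n <= j)
            )
            assert got == int(round(0.1 * len(pairs)))

    def test_hundred_link_layer_removes_exactly_ten(self):
        # a single layer of exactly 100 links at fraction 0.10
        rng = np.random.default_rng(0)
        n = 30
        iu, ju = np.triu_indices(n, 1)
        pick = rng.choice(len(iu), size=100, replace=False)
        A = np.zeros((n, n))
        A[iu[pick], ju[pick]] = 1.0
        A = A + A.T
        pairs = np.column_stack((iu[pick], ju[pick]))
        ps = sample_from_layers(A, {"only": pairs}, 0.1, rng)
        assert len(ps.removed_edges) == 10

    def test_tiny_fraction_warns_and_removes_one(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        pairs = np.array([[0, 1], [2, 3]])
        with pytest.warns(UserWarning, match="removing 1"):
            ps = sample_from_layers(A, {"L": pairs}, 0.01, rng=0)
        assert len(ps.removed_edges) == 1

    def test_fraction_out_of_range_errors(self, small_bilayer):
        with pytest.raises(ValueError, match="fraction"):
            sample_perturbation(small_bilayer, 1.0, rng=0)
        with pytest.raises(ValueError, match="fraction"):
            sample_perturbation(small_bilayer, 0.0, rng=0)

    def test_seeded_draws_match_generator_enumeration(self):
        # 5-node toy: replay the generator's draws independently
        A = np.zeros((5, 5))
        edges = [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4), (1, 4)]
        for i, j in edges:
            A[i, j] = A[j, i] = 1.0
        pairs = np.array(edges)
        ps = sample_from_layers(A, {"L": pairs}, 0.5, rng=np.random.default_rng(42))
        oracle = np.random.default_rng(42)
        take = np.sort(oracle.choice(len(edges), size=3, replace=False))
        expected = [tuple(pairs[k]) for k in take]
        assert ps.removed_edges == expected

    def test_same_seed_bit_identical(self, small_bilayer):
        a = sample_perturbation(small_bilayer, 0.1, rng=9)
        b = sample_perturbation(small_bilayer, 0.1, rng=9)
        assert a.removed_edges == b.removed_edges
        np.testing.assert_array_equal(a.A_R, b.A_R)

    def test_pooled_mode_single_stratum(self, small_bilayer):
        layers = layer_link_pairs(small_bilayer)
        total = sum(len(p) for p in layers.values())
        ps = sample_perturbation(small_bilayer, 0.1, rng=3, per_layer=False)
        assert len(ps.removed_edges) == int(round(0.1 * total))


class TestFirstOrderPerturb:
    def test_zero_perturbation_reconstructs_identically(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            A = _random_symmetric(12, rng)
            ps = PerturbationSample(A_R=A, dA=np.zeros_like(A), removed_edges=[], fraction=0.0)
            tilde = first_order_perturb(ps)
            rel = np.linalg.norm(tilde - A, 2) / np.linalg.norm(A, 2)
            assert rel < 1e-8

    def test_three_node_path_matches_oracle(self):
        A = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        dA = np.zeros((3, 3))
        dA[1, 2] = dA[2, 1] = 1.0
        ps = PerturbationSample(A_R=A - dA, dA=dA, removed_edges=[(1, 2)], fraction=0.5)
        tilde = first_order_perturb(ps)
        oracle = brute_force_perturb(A - dA, dA)
        np.testing.assert_allclose(tilde, oracle, atol=1e-10)

    def test_random_weighted_matrices_match_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            A = _random_symmetric(10, rng, density=0.6)
            dA = _random_symmetric(10, rng, density=0.2) * 0.3
            ps = PerturbationSample(A_R=A, dA=dA, removed_edges=[(0, 1)], fraction=0.1)
            np.testing.assert_allclose(
                first_order_perturb(ps), brute_force_perturb(A, dA), atol=1e-10
            )

    def test_degenerate_spectrum_subspace_handling(self):
        # two disjoint edges: eigenvalues (-1, -1, 1, 1), fully degenerate pairs
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 1.0
        dA = np.zeros((4, 4))
        dA[0, 2] = dA[2, 0] = 1.0
        ps = PerturbationSample(A_R=A, dA=dA, removed_edges=[(0, 2)], fraction=0.1)
        tilde = first_order_perturb(ps, degenerate_handling="subspace")
        oracle = brute_force_perturb(A, dA)
        np.testing.assert_allclose(tilde, oracle, atol=1e-10)
        assert np.allclose(tilde, tilde.T, atol=1e-12)

    def test_naive_mode_matches_naive_oracle(self):
        rng = np.random.default_rng(21)
        A = _random_symmetric(8, rng)
        dA = _random_symmetric(8, rng) * 0.1
        ps = PerturbationSample(A_R=A, dA=dA, removed_edges=[(0, 1)], fraction=0.1)
        np.testing.assert_allclose(
            first_order_perturb(ps, degenerate_handling="naive"),
            naive_perturb(A, dA),
            atol=1e-10,
        )

    def test_eigenvalue_error_shrinks_quadratically(self):
        rng = np.random.default_rng(3)
        A = _random_symmetric(14, rng)
        dA = _random_symmetric(14, rng)

        def eig_err(eps):
            ps = PerturbationSample(A_R=A, dA=eps * dA, removed_edges=[(0, 1)], fraction=0.1)
            approx = np.sort(np.linalg.eigvalsh(first_order_perturb(ps)))
            exact = np.sort(np.linalg.eigvalsh(A + eps * dA))
            return np.abs(approx - exact).max()

        ratio = eig_err(0.1) / eig_err(0.01)
        assert 30.0 < ratio < 300.0  # ~100x per 10x drop in epsilon

    def test_asymmetric_input_rejected(self):
        A = np.arange(9.0).reshape(3, 3)
        ps = PerturbationSample(A_R=A, dA=np.zeros((3, 3)), removed_edges=[], fraction=0.1)
        with pytest.raises(ValueError, match="symmetric"):
            first_order_perturb(ps)


class TestPredict:
    def test_t1_equals_single_perturbation_with_derived_seed(self):
        rng = np.random.default_rng(0)
        bn = _toy_bilayer(rng)
        sm = predict(bn, t=1, fraction=0.2, rng=np.random.default_rng(5))
        replay = np.random.default_rng(5)
        child = int(replay.integers(0, 2**31, size=1)[0])
        ps = sample_perturbation(bn, 0.2, np.random.default_rng(child))
        np.testing.assert_array_equal(sm.scores, first_order_perturb(ps))

    def test_t3_is_mean_of_three_reconstructions(self):
        rng = np.random.default_rng(1)
        bn = _toy_bilayer(rng)
        sm = predict(bn, t=3, fraction=0.2, rng=np.random.default_rng(8))
        replay = np.random.default_rng(8)
        mats = []
        for child in replay.integers(0, 2**31, size=3):
            ps = sample_perturbation(bn, 0.2, np.random.default_rng(int(child)))
            mats.append(first_order_perturb(ps))
        np.testing.assert_allclose(sm.scores, np.mean(mats, axis=0), atol=1e-12)

    def test_scores_symmetric(self, small_bilayer):
        sm = predict(small_bilayer, t=2, rng=0)
        assert np.abs(sm.scores - sm.scores.T).max() < 1e-10

    def test_same_seed_bit_identical(self, small_bilayer):
        a = predict(small_bilayer, t=2, rng=4)
        b = predict(small_bilayer, t=2, rng=4)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_invalid_t_rejected(self, small_bilayer):
        with pytest.raises(ValueError, match="t must be"):
            predict(small_bilayer, t=0, rng=0)


class TestRankCandidates:
    def test_strict_descending_order(self, small_bilayer):
        sm = predict(small_bilayer, t=2, rng=0)
        ranked = rank_candidates(small_bilayer, sm)
        scores = [s for _, _, s in ranked]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_tie_break_by_index_is_deterministic(self):
        rng = np.random.default_rng(2)
        bn = _toy_bilayer(rng)
        from spmlmi import ScoreMatrix

        sm = ScoreMatrix(scores=np.zeros((bn.N, bn.N)), t=1, fraction=0.1)
        ranked = rank_candidates(bn, sm)
        pairs = [(l, m) for l, m, _ in ranked]
        assert pairs == sorted(pairs, key=lambda p: (bn.lnc_ids.index(p[0]), bn.mi_ids.index(p[1])))
        assert ranked == rank_candidates(bn, sm)

    def test_planted_removed_pair_ranks_first(self):
        # group of co-expressed lncRNAs all bound to M0; drop one such link:
        # the spectral scores must put it back on top of the candidate list
        n_lnc, n_mi = 8, 4
        ls = np.zeros((n_lnc, n_lnc))
        ls[:4, :4] = 0.95
        ls[4:, 4:] = 0.95
        np.fill_diagonal(ls, 0.0)
        ms = np.zeros((n_mi, n_mi))
        lm = np.zeros((n_lnc, n_mi))
        lm[:4, 0] = 1.0  # group A binds M0
        lm[4:, 1] = 1.0  # group B binds M1
        lm[3, 0] = 0.0  # hide one group-A link
        lsn = SimilarityNetwork([f"L{i}" for i in range(n_lnc)], ls)
        msn = SimilarityNetwork([f"M{i}" for i in range(n_mi)], ms)
        lmn = InteractionNetwork(lsn.node_ids, msn.node_ids, lm)
        bn = build_bilayer(lsn, msn, lmn)
        sm = predict(bn, t=8, fraction=0.15, rng=0)
        top = rank_candidates(bn, sm)[0]
        assert (top[0], top[1]) == ("L3", "M0")

    def test_query_restriction_and_unknown_id(self, small_bilayer):
        sm = predict(small_bilayer, t=2, rng=0)
        lnc = small_bilayer.lnc_ids[0]
        ranked = rank_candidates(small_bilayer, sm, query=lnc)
        assert ranked and all(l == lnc for l, _, _ in ranked)
        mi = small_bilayer.mi_ids[0]
        ranked_mi = rank_candidates(small_bilayer, sm, query=mi)
        assert ranked_mi and all(m == mi for _, m, _ in ranked_mi)
        with pytest.raises(ValueError, match="not in network"):
            rank_candidates(small_bilayer, sm, query="nope")
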