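import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import NMF as SKNMF

from ssctrn import metrics, nmf, simulate


def _df(arr, prefix="g"):
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"t{j}" for j in range(arr.shape[1])],
    )


class TestBuildFcMatrix:
    def test_constant_gene_zero_row(self):
        tc = pd.DataFrame({"base": [8.0, 5.0], "t1": [8.0, 6.0], "t2": [8.0, 7.0]},
                          index=["a", "b"])
        fc = nmf.build_fc_matrix(tc, "base")
        assert np.allclose(fc.loc["a"], 0.0)
        assert np.allclose(fc.loc["b"], [1.0, 2.0])

    def test_simple_subtraction(self):
        tc = pd.DataFrame({"base": [8.0], "t1": [9.5]}, index=["a"])
        assert nmf.build_fc_matrix(tc, "base").loc["a", "t1"] == pytest.approx(1.5)

    def test_shift_cancellation(self):
        tc = pd.DataFrame({"base": [8.0, 5.0], "t1": [9.0, 4.0]}, index=["a", "b"])
        fc1 = nmf.build_fc_matrix(tc, "base")
        fc2 = nmf.build_fc_matrix(tc + 3.0, "base")
        pd.testing.assert_frame_equal(fc1, fc2)

    def test_missing_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            nmf.build_fc_matrix(pd.DataFrame({"t1": [1.0]}), "base")


class TestHarmonizeLines:
    def test_identical_matrices_fixed_point(self):
        rng = np.random.default_rng(0)
        m = _df(rng.normal(0, 1, (30, 5)))
        out = nmf.harmonize_lines([m, m.copy(), m.copy()])
        for i in range(3):
            block = out[[c for c in out.columns if c.startswith(f"line{i+1}:")]]
            assert np.allclose(block.to_numpy(), m.to_numpy())

    def test_pooled_sorted_values_identical_across_lines(self):
        rng = np.random.default_rng(1)
        mats = [_df(rng.normal(i, 1 + i, (40, 6))) for i in range(3)]
        out = nmf.harmonize_lines(mats)
        blocks = [
            np.sort(out[[c for c in out.columns if c.startswith(f"line{i+1}:")]]
                    .to_numpy().ravel())
            for i in range(3)
        ]
        assert np.allclose(blocks[0], blocks[1])
        assert np.allclose(blocks[0], blocks[2])

    def test_scaling_one_line_preserves_rank_structure(self):
        # quantile normalization is rank-driven: scaling one line changes the
        # shared reference distribution but never the within-line ranks, so
        # the two outputs agree up to a common monotone transform
        rng = np.random.default_rng(2)
        mats = [_df(rng.normal(0, 1, (25, 4))) for _ in range(2)]
        scaled = [mats[0] * 2.0, mats[1]]
        out1 = nmf.harmonize_lines(mats).to_numpy()
        out2 = nmf.harmonize_lines(scaled).to_numpy()
        half = out1.shape[1] // 2
        for block1, block2 in [(out1[:, :half], out2[:, :half]),
                               (out1[:, half:], out2[:, half:])]:
            assert (block1.ravel().argsort() == block2.ravel().argsort()).all()
        # and the unscaled line's harmonized sorted values shift identically
        assert np.allclose(np.sort(out1[:, half:].ravel()),
                           np.sort(out1[:, :half].ravel()))

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        mats = [_df(rng.normal(0, 1, (25, 4))) for _ in range(2)]
        once = nmf.harmonize_lines(mats)
        halves = np.split(once.to_numpy(), 2, axis=1)
        again = nmf.harmonize_lines(
            [pd.DataFrame(h, index=once.index, columns=mats[0].columns) for h in halves]
        )
        assert np.allclose(once.to_numpy(), again.to_numpy())

    def test_empty_intersection_rejected(self):
        m1 = _df(np.zeros((3, 2)), prefix="a")
        m2 = _df(np.zeros((3, 2)), prefix="b")
        with pytest.raises(ValueError, match="intersection"):
            nmf.harmonize_lines([m1, m2])


class TestNMFFactorize:
    def test_rank_one_exact(self):
        u = np.array([1.0, 2.0, 3.0])
        v = np.array([0.5, 1.0, 2.0, 4.0])
        model = nmf.nmf_factorize(_df(np.outer(u, v)), k=1, seed=0, max_iter=2000, tol=0)
        assert model.reconstruction_error < 1e-8

    def test_error_non_increasing(self):
        rng = np.random.default_rng(4)
        model = nmf.nmf_factorize(_df(rng.random((20, 8))), k=3, seed=1, max_iter=200)
        trace = np.array(model.error_trace)
        assert (np.diff(trace) <= 1e-10).all()

    def test_planted_factorization_recovered(self):
        rng = np.random.default_rng(5)
        W = rng.random((3, 2))
        H = rng.random((2, 4))
        model = nmf.nmf_factorize(_df(W @ H), k=2, seed=2, max_iter=5000, tol=0)
        assert model.reconstruction_error < 1e-6

    def test_nonnegativity_preserved(self):
        rng = np.random.default_rng(6)
        model = nmf.nmf_factorize(_df(rng.random((15, 6))), k=3, seed=0)
        assert (model.W >= 0).all() and (model.H >= 0).all()

    def test_rank_exceeding_dimensions_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            nmf.nmf_factorize(_df(np.ones((3, 4))), k=5)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            nmf.nmf_factorize(_df(np.array([[1.0, -1.0]])), k=1)

    def test_seed_determinism(self):
        rng = np.random.default_rng(7)
        X = _df(rng.random((20, 8)))
        m1 = nmf.nmf_factorize(X, k=3, seed=9)
        m2 = nmf.nmf_factorize(X, k=3, seed=9)
        assert (m1.W == m2.W).all() and (m1.H == m2.H).all()

    def test_error_comparable_to_sklearn_mu(self):
        # independent cross-check: sklearn's multiplicative-update solver on
        # the same matrix should reach a similar Frobenius error
        rng = np.random.default_rng(8)
        X = rng.random((40, 12))
        ours = nmf.nmf_factorize(_df(X), k=4, seed=0, max_iter=1000, tol=1e-10)
        sk = SKNMF(n_components=4, solver="mu", init="random", random_state=0,
                   max_iter=1000, tol=1e-10).fit(X)
        sk_err = np.linalg.norm(X - sk.transform(X) @ sk.components_)
        assert ours.reconstruction_error <= 1.1 * sk_err


class TestMembership:
    def test_exchangeable_rows_nothing_significant(self):
        X = _df(np.tile(np.linspace(0.1, 1.0, 8), (30, 1)))
        model = nmf.nmf_factorize(X, k=2, seed=0)
        clusters, pvals = nmf.assign_membership(model, X, n_perm=49, alpha=0.05, seed=0)
        n_members = sum(len(m) for m in clusters.values())
        # exchangeable null: expect ~alpha false memberships per cluster
        assert n_members <= 0.15 * 30 * 2

    def test_planted_block_recovered(self):
        rng = np.random.default_rng(9)
        X = rng.random((200, 20)) * 0.2
        X[:50, :3] += 5.0  # block loading on a dedicated factor, SNR >> 1
        X = _df(X)
        model = nmf.nmf_factorize(X, k=3, seed=1)
        clusters, pvals = nmf.assign_membership(
            model, X, n_perm=199, alpha=0.05, seed=1, n_iter_refit=100
        )
        block = {f"g{i}" for i in range(50)}
        best = max(clusters.values(), key=lambda m: len(block & set(m)))
        assert len(block & set(best)) >= 48  # >= 95% of the planted block

    def test_too_few_permutations_rejected(self):
        X = _df(np.random.default_rng(0).random((10, 4)))
        model = nmf.nmf_factorize(X, k=2, seed=0)
        with pytest.raises(ValueError, match="n_perm"):
            nmf.assign_membership(model, X, n_perm=10)

    def test_null_pvalues_roughly_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(10)
        X = _df(rng.random((300, 8)))
        model = nmf.nmf_factorize(X, k=2, seed=0)
        _, pvals = nmf.assign_membership(model, X, n_perm=199, alpha=0.05, seed=0)
        # discrete uniform on {1/200..1}: KS against U(0,1) should not reject hard
        stat, p = kstest(pvals.to_numpy().ravel(), "uniform")
        assert p > 0.01


class TestSelectSignatures:
    def _mats(self, rows, n_lines=3):
        return [
            _df(np.array(rows, dtype=float)) for _ in range(n_lines)
        ]

    def test_low_fold_change_gene_excluded(self):
        # peaks at 0.5 < log2(1.5) ~ 0.585 -> fails the filter
        mats = self._mats([[0.1, 0.3, 0.5]])
        sets = nmf.select_signatures({1: ["g0"]}, mats, fc_min=1.5)
        assert sets.differentiation == [] and sets.pluripotency == []

    def test_strong_down_gene_in_pluripotency_set(self):
        mats = self._mats([[-0.5, -1.0, -2.0]])
        sets = nmf.select_signatures({1: ["g0"]}, mats, fc_min=1.5)
        assert sets.pluripotency == ["g0"]

    def test_direction_must_be_consistent_across_lines(self):
        up = _df(np.array([[0.5, 1.0, 2.0]]))
        down = _df(np.array([[-0.5, -1.0, -2.0]]))
        sets = nmf.select_signatures({1: ["g0"]}, [up, down], fc_min=1.5)
        assert sets.pluripotency == [] and sets.differentiation == []

    def test_sets_disjoint_invariant(self):
        rng = np.random.default_rng(11)
        mats, truth = simulate.simulate_timecourses(
            200, 3, 10, simulate.SignatureSpec(0.2, 0.2, 2.0), 0.3, seed=3
        )
        sets, _, _ = nmf.extract_signatures(mats, k=10, seed=3)
        assert not (set(sets.pluripotency) & set(sets.differentiation))

    def test_planted_signatures_recovered(self):
        # 100 planted up + 100 planted down among 1000 genes
        mats, truth = simulate.simulate_timecourses(
            1000, 3, 10, simulate.SignatureSpec(0.1, 0.1, 2.0), 0.3, seed=7
        )
        sets, _, _ = nmf.extract_signatures(mats, k=40, seed=7)
        for recovered, which in [
            (sets.pluripotency, "pluripotency"),
            (sets.differentiation, "differentiation"),
        ]:
            precision, recall = metrics.precision_recall(
                recovered, truth.signature_genes(which)
            )
            assert precision >= 0.9 and recall >= 0.9
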