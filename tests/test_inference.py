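"""The five edge-scoring engines and their shared primitives."""

import numpy as np
import pandas as pd
import pytest

from modnet.inference import (
    RegulatorModuleMatrix,
    aracne_scores,
    build_regulator_module_matrix,
    clr_scores,
    dpi_prune,
    genie3_scores,
    mi_matrix,
    mutual_information,
    partial_correlations,
    pcor_scores,
    rank_normalize,
    shrinkage_intensity,
    tigress_scores,
)


def mi_oracle(x, y, bins):
    """Independent plug-in MI: explicit loops over an equal-width grid."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)

    def cut(v):
        lo, hi = v.min(), v.max()
        if hi == lo:
            return np.zeros(n, dtype=int)
        idx = np.floor((v - lo) / (hi - lo) * bins).astype(int)
        return np.minimum(idx, bins - 1)

    ix, iy = cut(x), cut(y)
    total = 0.0
    for a in range(bins):
        for b in range(bins):
            pab = np.mean((ix == a) & (iy == b))
            if pab > 0:
                pa, pb = np.mean(ix == a), np.mean(iy == b)
                total += pab * np.log(pab / (pa * pb))
    return total


def small_matrix(rng, n_reg=6, n_mod=3, n_cond=20):
    data = rng.normal(size=(n_reg + n_mod, n_cond))
    idx = [f"tf{i}" for i in range(n_reg)] + [str(m + 1) for m in range(n_mod)]
    df = pd.DataFrame(data, index=idx)
    return RegulatorModuleMatrix(df, regulators=idx[:n_reg], modules=idx[n_reg:])


class TestBuildMatrix:
    def test_shapes_and_candidate_count(self):
        rng = np.random.default_rng(0)
        tf = pd.DataFrame(rng.normal(size=(2, 5)), index=["tfA", "tfB"])
        mm = pd.DataFrame(rng.normal(size=(3, 5)), index=[1, 2, 3])
        M = build_regulator_module_matrix(tf, mm)
        assert M.data.shape == (5, 5)
        assert M.n_candidate_edges == 6

    def test_constant_regulator_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        tf = pd.DataFrame(
            np.vstack([np.ones(5), rng.normal(size=5)]), index=["flat", "ok"]
        )
        mm = pd.DataFrame(rng.normal(size=(2, 5)), index=[1, 2])
        with pytest.warns(UserWarning, match="flat"):
            M = build_regulator_module_matrix(tf, mm)
        assert M.regulators == ["ok"]

    def test_column_mismatch_rejected(self):
        tf = pd.DataFrame(np.zeros((1, 4)), index=["t"], columns=list("abcd"))
        mm = pd.DataFrame(np.zeros((1, 4)), index=[1], columns=list("abce"))
        with pytest.raises(ValueError, match="columns"):
            build_regulator_module_matrix(tf, mm)

    def test_de_tf_filter(self):
        rng = np.random.default_rng(2)
        tf = pd.DataFrame(rng.normal(size=(3, 5)), index=["t1", "t2", "t3"])
        mm = pd.DataFrame(rng.normal(size=(1, 5)), index=[1])
        M = build_regulator_module_matrix(tf, mm, de_tfs={"t1", "t3"})
        assert M.regulators == ["t1", "t3"]


class TestMutualInformation:
    def test_four_point_hand_value(self):
        # {(1,1),(1,1),(2,2),(2,2)} with B=2: joint diag(1/2, 1/2) -> ln 2
        mi = mutual_information([1, 1, 2, 2], [1, 1, 2, 2], bins=2)
        assert mi == pytest.approx(np.log(2), abs=1e-12)

    def test_identity_equal_occupancy(self):
        B = 4
        x = np.repeat(np.arange(B, dtype=float), 5)
        assert mutual_information(x, x, bins=B) == pytest.approx(np.log(B), abs=1e-12)

    def test_null_mean_small_at_pipeline_bin_count(self):
        rng = np.random.default_rng(3)
        mis = [
            mutual_information(rng.uniform(size=2000), rng.uniform(size=2000), bins=5)
            for _ in range(100)
        ]
        assert np.mean(mis) <= 0.05

    def test_default_bins_show_plugin_bias(self):
        # plug-in bias under independence is ~ (B-1)^2 / (2n) nats
        rng = np.random.default_rng(4)
        n = 2000
        B = int(np.ceil(np.sqrt(n)))
        mis = [
            mutual_information(rng.uniform(size=n), rng.uniform(size=n))
            for _ in range(30)
        ]
        expected_bias = (B - 1) ** 2 / (2 * n)
        assert 0.5 * expected_bias < np.mean(mis) < 1.5 * expected_bias

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(8, 60))
            x, y = rng.normal(size=n), rng.normal(size=n)
            B = int(rng.integers(2, 6))
            assert mutual_information(x, y, bins=B) == pytest.approx(
                mi_oracle(x, y, B), abs=1e-10
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([1, 2, 3, 4], [1, 2, 3])

    def test_rank_discretization_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=40), rng.normal(size=40)
        a = mutual_information(x, y, bins=5, strategy="frequency")
        b = mutual_information(np.exp(x), y**3, bins=5, strategy="frequency")
        assert a == pytest.approx(b, abs=1e-12)


class TestAracne:
    def test_markov_chain_dpi_pruning(self):
        pruned_ok = 0
        runs = 30
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=2000)
            y = x + rng.normal(0, 0.5, 2000)
            z = y + rng.normal(0, 0.5, 2000)
            df = pd.DataFrame([x, y, z], index=["x", "y", "z"])
            mi = mi_matrix(df, bins=10)
            keep = dpi_prune(mi, epsilon=0.0)
            names = list(df.index)
            i, j, k = names.index("x"), names.index("y"), names.index("z")
            if (not keep[i, k]) and keep[i, j] and keep[j, k]:
                pruned_ok += 1
        assert pruned_ok >= int(0.95 * runs)

    def test_dpi_matches_triplet_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            W = rng.uniform(size=(n, n))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0)
            eps = float(rng.uniform(0, 0.2))
            keep = dpi_prune(W, epsilon=eps)
            oracle = np.ones((n, n), dtype=bool)
            np.fill_diagonal(oracle, False)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    for k in range(n):
                        if k in (i, j):
                            continue
                        if W[i, j] < min(W[i, k], W[j, k]) * (1 - eps):
                            oracle[i, j] = False
            assert (keep == oracle).all()

    def test_independent_rows_score_near_zero(self):
        rng = np.random.default_rng(8)
        M = small_matrix(rng, n_reg=3, n_mod=2, n_cond=200)
        sm = aracne_scores(M, bins=5)
        assert sm.scores.to_numpy().max() < 0.25

    def test_injected_mi_matrix_pruning(self):
        # hand-set MI: x-y strong, y-z strong, x-z weakest -> x-z pruned
        W = pd.DataFrame(
            [[0.0, 1.0, 0.2], [1.0, 0.0, 0.9], [0.2, 0.9, 0.0]],
            index=["x", "y", "1"],
            columns=["x", "y", "1"],
        )
        M = RegulatorModuleMatrix(
            pd.DataFrame(np.random.default_rng(0).normal(size=(3, 10)), index=["x", "y", "1"]),
            regulators=["x", "y"],
            modules=["1"],
        )
        sm = aracne_scores(M, dpi_epsilon=0.0, mi=W)
        assert sm.scores.loc["x", "1"] == 0.0  # pruned
        assert sm.scores.loc["y", "1"] == pytest.approx(0.9)


class TestClr:
    def test_constant_mi_background_scores_zero(self):
        W = pd.DataFrame(np.full((4, 4), 0.3) - 0.3 * np.eye(4))
        W.index = W.columns = ["a", "b", "1", "2"]
        M = RegulatorModuleMatrix(
            pd.DataFrame(np.zeros((4, 5)), index=W.index),
            regulators=["a", "b"],
            modules=["1", "2"],
        )
        sm = clr_scores(M, mi=W)
        assert np.allclose(sm.scores, 0.0)

    def test_outlier_pair_dominates(self):
        rng = np.random.default_rng(9)
        n = 6
        W = rng.uniform(0.1, 0.2, size=(n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        W[0, n - 1] = W[n - 1, 0] = 2.0
        idx = [f"tf{i}" for i in range(n - 2)] + ["1", "2"]
        Wdf = pd.DataFrame(W, index=idx, columns=idx)
        M = RegulatorModuleMatrix(
            pd.DataFrame(np.zeros((n, 5)), index=idx),
            regulators=idx[: n - 2],
            modules=idx[n - 2 :],
        )
        sm = clr_scores(M, mi=Wdf)
        assert sm.scores.loc["tf0", "2"] == sm.scores.to_numpy().max()

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(10)
        n = 6
        W = rng.uniform(size=(n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        idx = [f"tf{i}" for i in range(4)] + ["1", "2"]
        Wdf = pd.DataFrame(W, index=idx, columns=idx)
        M = RegulatorModuleMatrix(
            pd.DataFrame(np.zeros((n, 5)), index=idx), regulators=idx[:4], modules=idx[4:]
        )
        sm = clr_scores(M, mi=Wdf)
        for i, r in enumerate(idx[:4]):
            for j, m in enumerate(idx[4:], start=4):
                off_i = [W[i, t] for t in range(n) if t != i]
                off_j = [W[j, t] for t in range(n) if t != j]
                zi = max(0.0, (W[i, j] - np.mean(off_i)) / np.std(off_i))
                zj = max(0.0, (W[i, j] - np.mean(off_j)) / np.std(off_j))
                assert sm.scores.loc[r, m] == pytest.approx(
                    np.hypot(zi, zj), abs=1e-10
                )


class TestGenie3:
    def test_copied_tf_gets_top_importance(self):
        tops = 0
        runs = 15
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 20))  # 20 noise TFs x 20 conditions
            idx = [f"tf{i}" for i in range(20)] + ["1"]
            data = pd.DataFrame(np.vstack([X, X[0]]), index=idx)  # module = copy of tf0
            M = RegulatorModuleMatrix(data, regulators=idx[:20], modules=["1"])
            sm = genie3_scores(M, n_trees=200, seed=seed)
            tops += sm.scores["1"].idxmax() == "tf0"
        assert tops >= runs - 1

    def test_importances_sum_to_one(self):
        rng = np.random.default_rng(20)
        M = small_matrix(rng, n_reg=8, n_mod=3)
        sm = genie3_scores(M, n_trees=100, seed=0)
        sums = sm.scores.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_noise_target_importance_roughly_uniform(self):
        rng = np.random.default_rng(21)
        maxes = []
        for seed in range(10):
            M = small_matrix(np.random.default_rng(seed), n_reg=20, n_mod=1, n_cond=30)
            sm = genie3_scores(M, n_trees=100, seed=seed)
            maxes.append(sm.scores.to_numpy().max())
        assert np.mean(maxes) <= 5 / 20


class TestTigress:
    def test_single_true_driver_dominates(self):
        # the random reweighting deliberately drops even a perfect driver in
        # some resamples, so an unambiguous design (many conditions, short
        # path) is needed for a high selection frequency
        freqs_true, freqs_decoy = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(15, 40))  # 15 regulators x 40 conditions
            y = 2.0 * X[0] + rng.normal(0, 0.1, 40)
            idx = [f"tf{i}" for i in range(15)] + ["1"]
            data = pd.DataFrame(np.vstack([X, y]), index=idx)
            M = RegulatorModuleMatrix(data, regulators=idx[:15], modules=["1"])
            sm = tigress_scores(M, n_resamples=100, L_steps=2, seed=seed)
            freqs_true.append(sm.scores.loc["tf0", "1"])
            freqs_decoy.append(sm.scores.drop("tf0")["1"].max())
        assert np.mean(freqs_true) >= 0.8
        assert np.mean(freqs_decoy) <= 0.3

    def test_scores_are_frequencies(self):
        rng = np.random.default_rng(30)
        M = small_matrix(rng, n_reg=5, n_mod=2)
        sm = tigress_scores(M, n_resamples=50, seed=0)
        s = sm.scores.to_numpy()
        assert ((s >= 0) & (s <= 1)).all()

    def test_too_few_conditions_rejected(self):
        rng = np.random.default_rng(31)
        M = small_matrix(rng, n_cond=5)
        with pytest.raises(ValueError, match="conditions"):
            tigress_scores(M)

    def test_lars_entry_order_on_orthogonal_design(self):
        # orthogonal predictors: LARS admits them by |correlation| rank
        from sklearn.linear_model import Lars

        n = 16
        Q, _ = np.linalg.qr(np.random.default_rng(32).normal(size=(n, 3)))
        y = 3.0 * Q[:, 2] + 2.0 * Q[:, 0] + 1.0 * Q[:, 1]
        orders = []
        for steps in (1, 2, 3):
            model = Lars(n_nonzero_coefs=steps, fit_intercept=False).fit(Q, y)
            orders.append(set(np.flatnonzero(model.coef_)))
        assert orders[0] == {2}
        assert orders[1] == {2, 0}
        assert orders[2] == {2, 0, 1}


class TestPcor:
    def test_three_variable_closed_form(self):
        # r_xy=0.6, r_xz=0.5, r_yz=0.5 -> pcor_xy = 0.35/0.75
        R = np.array([[1.0, 0.6, 0.5], [0.6, 1.0, 0.5], [0.5, 0.5, 1.0]])
        L = np.linalg.cholesky(R)
        rng = np.random.default_rng(40)
        # construct data with EXACT sample correlation R
        raw = rng.normal(size=(3, 2000))
        raw -= raw.mean(axis=1, keepdims=True)
        cov = raw @ raw.T / (raw.shape[1] - 1)
        white = np.linalg.inv(np.linalg.cholesky(cov)) @ raw
        data = L @ white
        pc = partial_correlations(data, lam=0.0)
        expected = (0.6 - 0.25) / np.sqrt((1 - 0.25) * (1 - 0.25))
        assert pc[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_lambda_one_zeroes_offdiagonal(self):
        rng = np.random.default_rng(41)
        data = rng.normal(size=(5, 30))
        pc = partial_correlations(data, lam=1.0)
        off = pc[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-12)

    def test_independent_variables_vanish_with_n(self):
        rng = np.random.default_rng(42)
        data = rng.normal(size=(5, 5000))
        pc = partial_correlations(data, lam=0.0)
        assert np.abs(pc[~np.eye(5, dtype=bool)]).max() < 0.1

    def test_lambda_zero_matches_inverse_correlation_oracle(self):
        rng = np.random.default_rng(43)
        for _ in range(20):
            p, n = int(rng.integers(3, 7)), 60
            data = rng.normal(size=(p, n))
            pc = partial_correlations(data, lam=0.0)
            R = np.corrcoef(data)
            om = np.linalg.inv(R)
            oracle = -om / np.sqrt(np.outer(np.diag(om), np.diag(om)))
            np.fill_diagonal(oracle, 1.0)
            assert np.allclose(pc, oracle, atol=1e-10)

    def test_analytic_shrinkage_in_unit_interval_and_scores(self):
        rng = np.random.default_rng(44)
        M = small_matrix(rng, n_reg=8, n_mod=4, n_cond=10)
        lam = shrinkage_intensity(M.data.to_numpy())
        assert 0.0 <= lam <= 1.0
        sm = pcor_scores(M)
        assert (sm.scores.to_numpy() >= 0).all()


class TestEngineInvariances:
    def test_row_order_invariance(self):
        rng = np.random.default_rng(50)
        M = small_matrix(rng, n_reg=5, n_mod=3, n_cond=15)
        perm = rng.permutation(5)
        regs_perm = [M.regulators[i] for i in perm]
        M2 = RegulatorModuleMatrix(
            M.data.loc[regs_perm + M.modules], regulators=regs_perm, modules=M.modules
        )
        for fn in (lambda m: pcor_scores(m), lambda m: clr_scores(m)):
            a = fn(M).scores
            b = fn(M2).scores
            pd.testing.assert_frame_equal(a.sort_index(), b.sort_index(), atol=1e-10)

    def test_rank_normalize_range_and_order(self):
        rng = np.random.default_rng(51)
        M = small_matrix(rng)
        sm = pcor_scores(M, lam=0.2)
        rn = rank_normalize(sm)
        flat_raw = sm.scores.to_numpy().ravel()
        flat_rn = rn.scores.to_numpy().ravel()
        assert flat_rn.min() == 0.0 and flat_rn.max() == 1.0
        assert (np.argsort(flat_raw) == np.argsort(flat_rn)).all()
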