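import numpy as np
import pytest

import nmfkit.algorithms
from nmfkit import (
    ConfigurationError,
    NMFModel,
    StoppingRule,
    connectivity,
    consensus_invariance,
    evar,
    fit,
    fit_snmfr,
    make_synthetic,
    max_iterations,
    multifit,
    objective,
    seed_random,
    spawn_run_seeds,
    sparseness,
    stationarity,
    update_brunet,
    update_lee,
    update_nsnmf,
    update_offset,
)
from nmfkit.model_core import predict_clusters

UPDATES = {
    "lee": (update_lee, "euclidean", {}),
    "brunet": (update_brunet, "KL", {}),
    "nsnmf": (update_nsnmf, "KL", {"theta": 0.5}),
    "offset": (update_offset, "KL", {"offset": True}),
}


def _start_model(rng, n, p, r, kw):
    W = rng.random((n, r)) + 0.05
    H = rng.random((r, p)) + 0.05
    if kw.get("offset"):
        return NMFModel(W, H, offset=rng.random(n) + 0.05)
    if "theta" in kw:
        return NMFModel(W, H, theta=kw["theta"])
    return NMFModel(W, H)


class TestUpdateSteps:
    def test_lee_hand_iteration(self):
        m = NMFModel(np.array([[2.0]]), np.array([[1.0]]))
        out = update_lee(m, np.array([[4.0]]))
        np.testing.assert_allclose(out.H, [[2.0]], rtol=1e-12)
        np.testing.assert_allclose(out.W, [[2.0]], rtol=1e-12)

    def test_brunet_hand_iteration(self):
        m = NMFModel(np.array([[2.0]]), np.array([[1.0]]))
        out = update_brunet(m, np.array([[4.0]]))
        np.testing.assert_allclose(out.H, [[2.0]], rtol=1e-12)
        np.testing.assert_allclose(out.W, [[2.0]], rtol=1e-12)
        assert objective(out, np.array([[4.0]]), "KL") == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("name", ["lee", "brunet"])
    def test_fixed_point_at_perfect_reconstruction(self, name, rng):
        upd = UPDATES[name][0]
        W = rng.random((6, 2)) + 0.1
        H = rng.random((2, 5)) + 0.1
        m = NMFModel(W, H)
        out = upd(m, W @ H)
        np.testing.assert_allclose(out.W, W, rtol=1e-10)
        np.testing.assert_allclose(out.H, H, rtol=1e-10)

    def test_nsnmf_theta_zero_matches_brunet(self, rng):
        X = rng.random((8, 6))
        W, H = rng.random((8, 2)) + 0.1, rng.random((2, 6)) + 0.1
        a = update_nsnmf(NMFModel(W, H, theta=0.0), X)
        b = update_brunet(NMFModel(W, H), X)
        np.testing.assert_allclose(a.W, b.W, rtol=1e-12)
        np.testing.assert_allclose(a.H, b.H, rtol=1e-12)

    def test_offset_zero_and_frozen_matches_brunet(self, rng):
        X = rng.random((8, 6)) + 0.1
        W, H = rng.random((8, 2)) + 0.1, rng.random((2, 6)) + 0.1
        a = update_offset(NMFModel(W, H, offset=np.zeros(8)), X)
        b = update_brunet(NMFModel(W, H), X)
        np.testing.assert_allclose(a.W, b.W, rtol=1e-10)
        np.testing.assert_allclose(a.H, b.H, rtol=1e-10)
        assert np.all(a.offset == 0)  # multiplicative update keeps zeros at zero

    def test_offset_update_recovers_constant_row_with_frozen_factors(self):
        # the full model cannot identify the offset (H may absorb any part of
        # a constant row), so the update formula is checked with W, H held at
        # the generating values: the offset must converge to the added row
        d = make_synthetic(n=40, p=15, r=3, group_sizes=[5, 5, 5],
                           noise_sd=0.0, rng_seed=2)
        c = 0.5
        X = d.X.values + c
        b = np.full(40, 0.05)
        for _ in range(500):
            est = d.W0 @ d.H0 + b[:, None] + 2.0**-52
            b = b * (X / est).sum(axis=1) / 15
        assert np.abs(b - c).max() / c < 0.1

    @pytest.mark.parametrize("name", list(UPDATES))
    def test_objective_non_increasing_and_nonnegative(self, name, rng):
        upd, metric, kw = UPDATES[name]
        for _ in range(3):
            X = rng.random((10, 6)) + 0.01
            m = _start_model(rng, 10, 6, 2, kw)
            prev = objective(m, X, metric)
            for _ in range(100):
                m = upd(m, X)
                cur = objective(m, X, metric)
                assert cur <= prev * (1 + 1e-10) + 1e-12
                prev = cur
            assert m.W.min() >= 0 and m.H.min() >= 0
            if m.offset is not None:
                assert m.offset.min() >= 0

    def test_nsnmf_high_theta_gives_sparser_basis(self):
        # smoothing exists to push sparsity into the factors
        wins = 0
        for seed in range(10):
            d = make_synthetic(n=40, p=16, r=2, group_sizes=[8, 8],
                               noise_sd=0.1, rng_seed=seed)
            res = {}
            for theta in (0.0, 0.9):
                m = seed_random(d.X, 2, rng_seed=seed + 100)
                m = NMFModel(m.W, m.H, theta=theta)
                for _ in range(500):
                    m = update_nsnmf(m, d.X)
                res[theta] = np.mean([sparseness(m.W[:, j]) for j in range(2)])
            wins += res[0.9] >= res[0.0]
        assert wins >= 6

    def test_update_requires_matching_variant(self):
        plain = NMFModel(np.ones((2, 1)), np.ones((1, 2)))
        with pytest.raises(ConfigurationError):
            update_nsnmf(plain, np.ones((2, 2)))
        with pytest.raises(ConfigurationError):
            update_offset(plain, np.ones((2, 2)))
        smoothed = NMFModel(np.ones((2, 1)), np.ones((1, 2)), theta=0.5)
        with pytest.raises(ConfigurationError):
            update_lee(smoothed, np.ones((2, 2)))


class TestSNMFR:
    def test_exact_recovery_without_sparsity_penalty(self, rng):
        W0 = rng.random((30, 3))
        W0[np.arange(30), np.arange(30) % 3] += 1.0  # block boost
        H0 = rng.random((3, 20))
        H0[np.arange(3).repeat(7)[:20], np.arange(20)] += 1.0
        X = W0 @ H0
        res = fit_snmfr(X, 3, beta=0.0, rng_seed=0,
                        stop=stationarity(tol=1e-10, max_iter=500, check_interval=1))
        assert evar(X, res.model) >= 0.999

    def test_large_beta_increases_H_column_sparseness(self, small_data):
        init = seed_random(small_data.X, 3, rng_seed=9)
        sparsities = {}
        for beta in (0.01, 100.0):
            res = fit_snmfr(small_data.X, 3, beta=beta, init=init.copy())
            H = res.model.H
            sparsities[beta] = np.mean(
                [sparseness(H[:, j]) for j in range(H.shape[1])]
            )
        assert sparsities[100.0] > sparsities[0.01]

    def test_rank_one_identical_columns_gives_constant_H_ratio(self):
        X = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4))
        res = fit_snmfr(X, 1, rng_seed=1)
        h = res.model.H.ravel()
        assert np.ptp(h) / h.mean() < 1e-6


class TestFitInterface:
    def test_max_iter_runs_exact_count(self, small_data):
        res = fit(small_data.X, 3, method="brunet", rng_seed=0,
                  stop=max_iterations(50))
        assert res.n_iterations == 50

    def test_consensus_invariance_terminates_after_stable_window(self, small_data):
        res = fit(small_data.X, 3, method="brunet", rng_seed=0,
                  stop=consensus_invariance(window=40, check_interval=10))
        assert res.n_iterations < 2000
        assert res.n_iterations >= 50  # 40-iteration stable window + settling

    def test_reproducible_bit_identical(self, small_data):
        a = fit(small_data.X, 3, method="lee", rng_seed=4)
        b = fit(small_data.X, 3, method="lee", rng_seed=4)
        assert a.model.W.tobytes() == b.model.W.tobytes()
        assert a.objective_track == b.objective_track

    def test_track_is_non_increasing_and_final_matches(self, small_data):
        res = fit(small_data.X, 3, method="brunet", rng_seed=1)
        objs = [o for _, o in res.objective_track]
        assert all(b <= a * (1 + 1e-10) for a, b in zip(objs, objs[1:]))
        assert res.final_objective == objs[-1]

    def test_unknown_method_rejected(self, small_data):
        with pytest.raises(ConfigurationError):
            fit(small_data.X, 3, method="pca")

    def test_excessive_rank_warns(self):
        X = np.ones((4, 3)) + np.eye(4, 3)
        with pytest.warns(UserWarning, match="rank"):
            fit(X, 5, method="lee", rng_seed=0, stop=max_iterations(5))

    def test_metric_assignment_per_method(self, small_data):
        assert fit(small_data.X, 2, method="lee", rng_seed=0,
                   stop=max_iterations(5)).metric == "euclidean"
        assert fit(small_data.X, 2, method="brunet", rng_seed=0,
                   stop=max_iterations(5)).metric == "KL"


class TestMultifit:
    def test_single_run_consensus_is_connectivity(self, small_data):
        mf = multifit(small_data.X, 3, nrun=1, master_seed=0)
        conn = connectivity(predict_clusters(mf.best.model))
        np.testing.assert_array_equal(mf.consensus, conn)

    def test_consensus_is_average_of_connectivities(self):
        # two runs assigning (1,1,2) and (1,2,2)
        c1 = connectivity([1, 1, 2])
        c2 = connectivity([1, 2, 2])
        expected = np.array([[1, 0.5, 0], [0.5, 1, 0.5], [0, 0.5, 1]])
        np.testing.assert_allclose((c1 + c2) / 2, expected)

    def test_best_index_minimizes_objective(self, small_data):
        mf = multifit(small_data.X, 3, nrun=5, master_seed=3)
        objs = [f.final_objective for f in mf.fits]
        assert mf.best_index == int(np.argmin(objs))

    def test_seed_derivation_order_independent(self):
        assert spawn_run_seeds(42, 5) == spawn_run_seeds(42, 5)
        assert spawn_run_seeds(42, 5)[:3] == spawn_run_seeds(42, 3)

    def test_serial_equals_parallel(self, small_data):
        a = multifit(small_data.X, 3, nrun=4, master_seed=5, n_jobs=1)
        b = multifit(small_data.X, 3, nrun=4, master_seed=5, n_jobs=2)
        np.testing.assert_array_equal(a.consensus, b.consensus)
        assert a.best_index == b.best_index

    def test_failed_runs_excluded_with_warning(self, small_data, monkeypatch):
        real_fit = nmfkit.algorithms.fit
        seeds = spawn_run_seeds(7, 3)

        def flaky(X, r, **kwargs):
            if kwargs.get("rng_seed") == seeds[1]:
                raise RuntimeError("synthetic failure")
            return real_fit(X, r, **kwargs)

        monkeypatch.setattr(nmfkit.algorithms, "fit", flaky)
        with pytest.warns(UserWarning, match="failed"):
            mf = multifit(small_data.X, 3, nrun=3, master_seed=7)
        assert mf.nrun == 2

    def test_perfect_consensus_on_separated_data(self):
        d = make_synthetic(rng_seed=1)  # default well-separated 3-group data
        mf = multifit(d.X, 3, nrun=20, master_seed=1)
        assert set(np.unique(mf.consensus)) <= {0.0, 1.0}
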