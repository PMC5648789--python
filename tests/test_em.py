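"""EM inference: initializer, ascent property, M-step optimality,
chunked E-step, BIC selection, correction and PVE decomposition."""

import warnings

import numpy as np
import pytest
from scipy import linalg, optimize

from scpls import (
    ExpressionPair,
    ScplsParams,
    SimConfig,
    correct,
    em_step_naive,
    fit_chunks,
    fit_naive,
    initialize,
    marginal_loglik,
    posterior_moments,
    pve_decompose,
    select_model,
    simulate_continuous,
    simulate_dataset,
)
from scpls.model import VARIANCE_FLOOR

from conftest import make_random_params, sample_from_model


def direct_max_loglik(data, kz, ku, starts):
    """Independent oracle: maximize the marginal likelihood directly
    with L-BFGS on (B, log psi) using analytic gradients of the
    Gaussian log-likelihood (no EM machinery involved)."""
    n, q, p = data.n, data.q, data.p
    d, k = q + p, kz + ku
    S = data.W.T @ data.W / n
    mask = np.ones((d, k))
    mask[:q, kz:] = 0.0

    def negloglik_grad(theta):
        B = theta[: d * k].reshape(d, k) * mask
        psi = np.exp(theta[d * k:])
        Sigma = B @ B.T + np.diag(psi)
        Si = linalg.inv(Sigma)
        _, logdet = np.linalg.slogdet(Sigma)
        nll = 0.5 * n * (logdet + np.trace(Si @ S) + d * np.log(2 * np.pi))
        G = Si - Si @ S @ Si
        return nll, np.concatenate([(n * (G @ B) * mask).ravel(),
                                    0.5 * n * np.diag(G) * psi])

    best = -np.inf
    for p0 in starts:
        theta0 = np.concatenate([p0.B.ravel(),
                                 np.log(np.maximum(p0.psi, VARIANCE_FLOOR))])
        res = optimize.minimize(
            negloglik_grad, theta0, jac=True, method="L-BFGS-B",
            bounds=[(None, None)] * (d * k)
                   + [(np.log(VARIANCE_FLOOR), None)] * d,
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9})
        best = max(best, -res.fun)
    return best


def expected_complete_loglik(B, psi, W, Ev, sum_Evv):
    """Expected complete-data log-likelihood as a function of the
    loadings, for fixed posterior moments (terms free of B included but
    constant)."""
    PiB = B / psi[:, None]
    quad = -0.5 * np.einsum("ab,ab->", PiB @ sum_Evv, B)
    cross = np.einsum("ik,ik->", W @ PiB, Ev)
    return quad + cross


class TestInitialize:
    def test_exact_low_rank_recovers_column_space(self):
        # noiseless rank-kz X: the initialized control loadings span
        # X's column space (principal angles ~ 0)
        rng = np.random.default_rng(5)
        kz = 2
        Z = rng.standard_normal((40, kz))
        Lx = rng.standard_normal((6, kz))
        X = Z @ Lx.T
        Y = rng.standard_normal((40, 8))
        data = ExpressionPair(X, Y).centered()
        params = initialize(data, kz=kz, ku=1)
        angles = linalg.subspace_angles(linalg.orth(params.Lambda_x),
                                        linalg.orth(data.X.T))
        assert np.max(angles) < 1e-6

    def test_ku_zero_skips_residual_step(self):
        params = initialize(sample_from_model(make_random_params(1), 30,
                                              seed=2), kz=1, ku=0)
        assert params.Lambda_u.shape == (20, 0)
        assert params.ku == 0

    def test_kz_exceeding_rank_bound_raises(self):
        data = sample_from_model(make_random_params(1, q=3, p=5), 30, seed=2)
        with pytest.raises(ValueError, match="rank bound"):
            initialize(data, kz=4, ku=1)

    def test_initial_loglik_finite_and_first_step_improves(self):
        truth, pair = simulate_dataset(SimConfig(
            n_cells=100, q_controls=10, p_targets=60, n_de=12, seed=3))
        params = initialize(pair, kz=2, ku=2)
        ll0 = marginal_loglik(params, pair)
        assert np.isfinite(ll0)
        ll1 = marginal_loglik(em_step_naive(params, pair), pair)
        assert ll1 > ll0


class TestEmStep:
    def test_no_factor_model_updates_psi_to_sample_variance(self):
        data = sample_from_model(make_random_params(4, kz=1, ku=1), 50,
                                 seed=5)
        params = ScplsParams(np.zeros((5, 0)), np.zeros((20, 0)),
                             np.zeros((20, 0)), np.ones(5), np.ones(20))
        new = em_step_naive(params, data)
        np.testing.assert_allclose(new.psi_x, (data.X ** 2).mean(axis=0),
                                   rtol=1e-12)
        np.testing.assert_allclose(new.psi_y, (data.Y ** 2).mean(axis=0),
                                   rtol=1e-12)

    def test_mstep_zeroes_gradient_of_expected_loglik(self, small_instance):
        # after the update, finite-difference gradients of the expected
        # complete-data log-likelihood w.r.t. every loading entry vanish
        true_params, data = small_instance
        params = initialize(data, kz=1, ku=1)
        for _ in range(3):
            mom = posterior_moments(params, data)
            sum_Evv = mom.sum_Evv()
            new = em_step_naive(params, data)
            q, kz, ku = params.q, params.kz, params.ku

            def q_of_loadings(flat, psi=params.psi, W=data.W,
                              Ev=mom.Ev, sum_Evv=sum_Evv, q=q, kz=kz):
                Lx = flat[: q * kz].reshape(q, kz)
                rest = flat[q * kz:].reshape(data.p, kz + ku)
                B = np.vstack([
                    np.hstack([Lx, np.zeros((q, ku))]), rest])
                return expected_complete_loglik(B, psi, W, Ev, sum_Evv)

            flat0 = np.concatenate([
                new.Lambda_x.ravel(),
                np.hstack([new.Lambda_y, new.Lambda_u]).ravel()])
            h = 1e-2  # Q is exactly quadratic; central differences exact
            grad = np.empty_like(flat0)
            for i in range(flat0.size):
                fp, fm = flat0.copy(), flat0.copy()
                fp[i] += h
                fm[i] -= h
                grad[i] = (q_of_loadings(fp) - q_of_loadings(fm)) / (2 * h)
            assert np.abs(grad).max() < 1e-6
            params = new

    def test_loglik_nondecreasing_over_consecutive_steps(self,
                                                         small_instance):
        _, data = small_instance
        params = initialize(data, kz=1, ku=1)
        lls = [marginal_loglik(params, data)]
        for _ in range(10):
            params = em_step_naive(params, data)
            lls.append(marginal_loglik(params, data))
        assert np.all(np.diff(lls) >= -1e-8)


class TestFit:
    def test_null_data_recovery(self):
        # independent-noise data: fitted loadings are small and the
        # log-likelihood is close to the independent-Gaussian optimum
        rng = np.random.default_rng(9)
        data = ExpressionPair(rng.standard_normal((120, 5)),
                              rng.standard_normal((120, 20))).centered()
        res = fit_naive(data, kz=1, ku=1, tol=1e-6)
        indep = sum(
            -0.5 * 120 * (np.log(2 * np.pi * (col ** 2).mean()) + 1)
            for col in data.W.T)
        # free factor loadings can only overfit by about a log-unit
        # per extra loading parameter
        assert 0 <= res.loglik - indep < (5 + 20 + 20) + 5
        assert (res.params.Lambda_y ** 2).sum(axis=1).mean() < 0.15

    @pytest.mark.parametrize("seed", range(3))
    def test_final_loglik_matches_direct_optimizer(self, seed):
        params = make_random_params(seed + 40)
        data = sample_from_model(params, 60, seed=seed + 400)
        res = fit_naive(data, kz=1, ku=1, tol=1e-8, max_iter=5000)
        opt = direct_max_loglik(data, 1, 1,
                                [res.params, initialize(data, 1, 1)])
        assert opt - res.loglik < 0.1

    def test_nonconvergence_flagged(self, small_instance):
        _, data = small_instance
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = fit_naive(data, kz=1, ku=1, tol=1e-12, max_iter=2)
        assert not res.converged

    def test_pve_recovery_on_simulated_data(self):
        truth, pair = simulate_dataset(SimConfig(
            n_cells=300, q_controls=30, p_targets=300, n_de=60, seed=17))
        res = fit_naive(pair, kz=2, ku=5, seed=17)
        r = np.corrcoef(truth.true_pve_confounding(),
                        res.pve_confounding)[0, 1]
        assert r ** 2 > 0.7

    def test_summary_mentions_dimensions(self, small_instance):
        _, data = small_instance
        res = fit_naive(data, kz=1, ku=1)
        text = res.summary()
        assert "kz = 1" in text and "ku = 1" in text
        assert f"{res.bic:.4f}" in text


class TestChunks:
    def test_single_chunk_reproduces_naive_exactly(self, small_instance):
        _, data = small_instance
        a = fit_naive(data, 1, 1, seed=0)
        b = fit_chunks(data, 1, 1, chunk_size=data.p, seed=0)
        np.testing.assert_array_equal(a.loglik_trace, b.loglik_trace)
        np.testing.assert_array_equal(a.corrected_Y, b.corrected_Y)

    def test_chunked_correction_tracks_naive(self):
        truth, pair = simulate_dataset(SimConfig(
            n_cells=150, q_controls=20, p_targets=200, n_de=40, seed=23))
        naive = fit_naive(pair, 2, 3, seed=23)
        chunked = fit_chunks(pair, 2, 3, chunk_size=100, seed=23)
        cors = [np.corrcoef(naive.corrected_Y[:, j],
                            chunked.corrected_Y[:, j])[0, 1]
                for j in range(pair.p)]
        # at this reduced problem size (2 chunks of 100 genes, q=20)
        # the moment averaging is noisier than at full scale
        assert np.median(cors) > 0.9

    def test_estep_solve_dimension_scales_with_chunks(self):
        # chunked E-step solves are (q + chunk) dimensional instead of
        # (q + p): bookkeeping check on the partition
        from scpls.em import _make_chunks

        rng = np.random.default_rng(0)
        chunks = _make_chunks(1000, 250, rng)
        assert len(chunks) == 4
        assert sorted(np.concatenate(chunks)) == list(range(1000))
        sizes = {len(c) for c in chunks}
        assert sizes == {250}

    def test_tiny_chunk_warns(self, small_instance):
        _, data = small_instance
        with pytest.warns(RuntimeWarning, match="ill-conditioned"):
            fit_chunks(data, 1, 2, chunk_size=2, max_iter=3, tol=1e-12)


class TestSelect:
    def test_null_data_selects_smallest_model(self):
        rng = np.random.default_rng(31)
        data = ExpressionPair(rng.standard_normal((80, 5)),
                              rng.standard_normal((80, 12))).centered()
        res = select_model(data, kz_grid=(0, 1, 2), ku_grid=(0, 1),
                           tol=1e-6)
        assert (res.kz, res.ku) == (0, 0)

    def test_bic_internally_consistent(self, small_instance):
        _, data = small_instance
        res = select_model(data, kz_grid=(1,), ku_grid=(1, 2))
        m = res.params.n_free_parameters()
        assert res.bic == pytest.approx(-2 * res.loglik + m * np.log(data.n))
        assert set(res.bic_grid.columns) >= {"kz", "ku", "bic"}

    def test_modal_selected_kz_matches_truth(self):
        # data carry kz=2 confounders plus a rank-1 DE signature, so the
        # u-grid must offer a slot beyond the 5 true biological factors
        picks = []
        for seed in range(3):
            truth, pair = simulate_dataset(SimConfig(
                n_cells=400, seed=seed))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = select_model(pair, kz_grid=(1, 2, 3), ku_grid=(5, 6),
                                   tol=1e-3, max_iter=150, seed=seed)
            picks.append(res.kz)
        assert np.bincount(picks).argmax() == 2


class TestCorrectAndPve:
    def test_zero_confounding_loadings_leave_data_unchanged(self,
                                                            small_instance):
        _, data = small_instance
        params = ScplsParams(np.zeros((5, 1)), np.zeros((20, 1)),
                             np.ones((20, 1)), np.ones(5), np.ones(20))
        np.testing.assert_array_equal(correct(data, params), data.Y)

    def test_kz_zero_is_identity(self, small_instance):
        _, data = small_instance
        params = ScplsParams(np.zeros((5, 0)), np.zeros((20, 0)),
                             np.ones((20, 2)), np.ones(5), np.ones(20))
        np.testing.assert_array_equal(correct(data, params), data.Y)

    def test_correction_moves_towards_clean_signal(self):
        # on ground-truth continuous data the corrected matrix is closer
        # to the confounding-free component than the uncorrected one
        cfg = SimConfig(n_cells=200, q_controls=30, p_targets=300,
                        n_de=60, seed=41)
        truth = simulate_continuous(cfg)
        pair = ExpressionPair(truth.W_controls, truth.W_targets).centered()
        res = fit_naive(pair, cfg.kz, cfg.ku, seed=41)
        s = truth.labels - 0.5
        clean = np.outer(s, truth.beta) + truth.U @ truth.Lambda_u.T
        clean -= clean.mean(axis=0)
        mse_unc = ((pair.Y - clean) ** 2).mean()
        mse_cor = ((res.corrected_Y - clean) ** 2).mean()
        assert mse_cor < mse_unc

    def test_pve_trivial_rows(self):
        params = ScplsParams(
            np.ones((2, 1)),
            np.array([[0.0], [1.0]]),
            np.array([[0.0], [0.0]]),
            np.ones(2), np.ones(2))
        conf, bio = pve_decompose(params)
        assert conf[0] == 0.0
        assert conf[1] == pytest.approx(0.5)
        np.testing.assert_array_equal(bio, 0.0)

    def test_pve_matches_large_sample_variance_share(self):
        # one gene simulated at 10^5 cells: the empirical share of the
        # confounding component matches the model decomposition
        params = ScplsParams([[0.6]], [[0.8]], [[0.5]], [1.0], [1.0])
        rng = np.random.default_rng(77)
        n = 100_000
        z = rng.standard_normal(n)
        u = rng.standard_normal(n)
        y = 0.8 * z + 0.5 * u + rng.standard_normal(n)
        conf, bio = pve_decompose(params)
        emp_conf = np.var(0.8 * z) / np.var(y)
        assert conf[0] == pytest.approx(emp_conf, abs=0.02)
        assert conf[0] + bio[0] <= 1.0
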