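"""Maximum-likelihood fitting: strength, joint, pooled, non-parametric, smoothing."""

import numpy as np
import pytest

import interpot as ip
from interpot.fitting import nonparametric_objective


@pytest.fixture(scope="module")
def ctx_q(small_context):
    return small_context["q"]


class TestFitStrength:
    def test_null_recovery(self, ctx_q, rng):
        D = ip.sample_distances(ctx_q, None, 2000, seed=rng)
        fit = ip.fit_strength(D, ctx_q, "plummer", 2.0, 0.0)
        assert abs(fit.epsilon) <= 3 * fit.stderr

    def test_step_equals_closed_form(self, ctx_q, rng):
        for _ in range(5):
            D = ip.sample_distances(ctx_q, ip.Potential("step", 1.2, 1.0, 0.0), 400, seed=rng)
            res = ip.analyze_coloc(D, ctx_q, t=0.0)
            fit = ip.fit_strength(D, ctx_q, "step", 1.0, 0.0)
            assert fit.epsilon == pytest.approx(res.epsilon_hat.value, abs=1e-4)

    def test_plummer_recovery(self, benchmark_context, rng):
        q = benchmark_context["q"]
        truth = ip.Potential("plummer", 1.0, 1.0, 0.0)
        D = ip.sample_distances(q, truth, 1000, seed=rng)
        fit = ip.fit_strength(D, q, "plummer", 1.0, 0.0)
        assert abs(fit.epsilon - 1.0) <= 3 * fit.stderr

    def test_reported_loglik_is_reproducible(self, ctx_q, rng):
        D = ip.sample_distances(ctx_q, None, 300, seed=rng)
        fit = ip.fit_strength(D, ctx_q, "hermquist", 2.0, 0.0)
        ll = ip.log_likelihood(D, ctx_q, ip.Potential("hermquist", fit.epsilon, 2.0, 0.0))
        assert ll == pytest.approx(fit.loglik, abs=1e-9)


class TestFitCell:
    def test_joint_recovery(self, ctx_q, rng):
        truth = ip.Potential("hermquist", 2.0, 4.0, 0.0)
        D = ip.sample_distances(ctx_q, truth, 2000, seed=rng)
        fit = ip.fit_cell(D, ctx_q, "hermquist")
        assert abs(fit.epsilon - 2.0) <= 3 * fit.stderr_epsilon
        assert abs(fit.sigma - 4.0) <= 3 * fit.stderr_sigma

    def test_profile_likelihood_peaks_at_truth(self, ctx_q, rng):
        truth = ip.Potential("hermquist", 2.0, 4.0, 0.0)
        D = ip.sample_distances(ctx_q, truth, 3000, seed=rng)
        sig_grid = np.linspace(1.0, 10.0, 19)
        profile = [ip.fit_strength(D, ctx_q, "hermquist", s, 0.0).loglik for s in sig_grid]
        assert abs(sig_grid[int(np.argmax(profile))] - 4.0) <= 1.5

    def test_null_data_gives_small_likelihood_gain(self, ctx_q, rng):
        # 2*(l_fit - l_null) should be modest when there is nothing to find
        gains = []
        for _ in range(20):
            D = ip.sample_distances(ctx_q, None, 300, seed=rng)
            fit = ip.fit_cell(D, ctx_q, "plummer")
            l0 = ip.log_likelihood(D, ctx_q, ip.Potential("plummer", 0.0, 1.0, 0.0))
            gains.append(2 * (fit.loglik - l0))
        # 99th percentile of a half-mixture chi2_2 is ~ 9; allow slack for MC
        assert np.quantile(gains, 0.9) < 9.0

    def test_small_sample_warns(self, ctx_q):
        D = ip.DistanceSample([0.5, 1.0, -0.5, 2.0, 3.0])
        with pytest.warns(UserWarning, match="N=5"):
            ip.fit_cell(D, ctx_q, "plummer")


@pytest.fixture(scope="module")
def batch(small_context):
    q = small_context["q"]
    rng = np.random.default_rng(77)
    cells = []
    eps_true = {}
    for k in range(10):
        eps = float(1.0 + 2.0 * rng.random())
        D = ip.sample_distances(q, ip.Potential("hermquist", eps, 4.0, 0.0), 500,
                                seed=rng, cell_id=f"c{k}")
        cells.append(ip.CellData(f"c{k}", D, q, {}))
        eps_true[f"c{k}"] = eps
    return cells, eps_true


class TestFitPooled:
    def test_single_cell_collapses_to_fit_cell(self, small_context, rng):
        q = small_context["q"]
        D = ip.sample_distances(q, ip.Potential("hermquist", 2.0, 4.0, 0.0), 1500, seed=rng)
        cell = ip.CellData("c", D, q, {})
        pooled = ip.fit_pooled([cell], "hermquist")
        single = ip.fit_cell(D, q, "hermquist")
        assert pooled.sigma_star == pytest.approx(single.sigma, rel=0.05)
        assert pooled.pooled_loglik == pytest.approx(single.loglik, abs=0.05)

    def test_shared_scale_recovery(self, batch):
        cells, eps_true = batch
        pooled = ip.fit_pooled(cells, "hermquist")
        assert pooled.convergence == "converged"
        assert pooled.n_params == 11
        assert pooled.sigma_star == pytest.approx(4.0, abs=1.0)
        for cid, eps in pooled.epsilons.items():
            se = ip.fit_strength(cells[int(cid[1:])].D, cells[0].q, "hermquist",
                                 pooled.sigma_star, 0.0).stderr
            assert abs(eps - eps_true[cid]) <= 4 * se + 0.3

    def test_pooled_loglik_consistency_and_nesting(self, batch):
        cells, _ = batch
        pooled = ip.fit_pooled(cells, "hermquist")
        # reported pooled loglik equals the sum of re-evaluated per-cell logliks
        total = sum(
            ip.log_likelihood(c.D, c.q,
                              ip.Potential("hermquist", pooled.epsilons[c.cell_id],
                                           pooled.sigma_star, 0.0))
            for c in cells
        )
        assert total == pytest.approx(pooled.pooled_loglik, abs=1e-6)
        # nesting: the common-scale optimum cannot beat per-cell 2-parameter maxima
        free = sum(ip.fit_cell(c.D, c.q, "hermquist").loglik for c in cells)
        assert pooled.pooled_loglik <= free + 1e-6

    def test_model_ranking_prefers_true_family(self, batch):
        cells, _ = batch
        logliks = {fam: ip.fit_pooled(cells, fam).pooled_loglik
                   for fam in ("step", "plummer", "hermquist")}
        assert max(logliks, key=logliks.get) == "hermquist"
        assert logliks["hermquist"] > logliks["step"]


class TestFitNonparametric:
    def test_null_shrinks_to_zero(self, small_context):
        q = small_context["q"]
        rng = np.random.default_rng(31)
        max_w = []
        for _ in range(8):
            cells = [ip.CellData("c", ip.sample_distances(q, None, 600, seed=rng), q, {})]
            fit = ip.fit_nonparametric(cells)
            max_w.append(np.max(np.abs(fit.weights)))
        # under the null the fitted weights stay small compared to a real
        # interaction depth (|phi(0)| = 3 in the recovery test below); the
        # residual scatter includes the weakly-identified overall level,
        # which only the smoothness prior pins down
        assert np.median(max_w) < 1.0
        assert np.quantile(max_w, 0.95) < 2.0
        # a fresh null refit is not an outlier among null refits
        assert max_w[-1] <= np.quantile(max_w, 0.95) or max_w[-1] < 1.0

    def test_tracks_known_truth_within_replicate_band(self, small_context):
        q = small_context["q"]
        truth = ip.Potential("hermquist", 3.0, 4.0, 0.0)
        rng = np.random.default_rng(32)
        fits = []
        for _ in range(10):
            cells = [ip.CellData(f"c{j}", ip.sample_distances(q, truth, 500, seed=rng), q, {})
                     for j in range(4)]
            fits.append(ip.fit_nonparametric(cells).weights)
        W = np.array(fits)
        sp = ip.NonparametricPotential.default_grid().support_points
        data_range = (sp >= -5) & (sp <= 20)  # range covered by the sampled distances
        lo = W.min(axis=0) - 0.5
        hi = W.max(axis=0) + 0.5
        truth_w = truth(sp)
        assert np.all(truth_w[data_range] >= lo[data_range])
        assert np.all(truth_w[data_range] <= hi[data_range])

    def test_objective_beats_multistart_quasi_newton_oracle(self, small_context):
        # oracle: restarted numerical-gradient BFGS on the same objective
        from scipy import optimize

        q = small_context["q"]
        truth = ip.Potential("hermquist", 2.0, 4.0, 0.0)
        rng = np.random.default_rng(33)
        cells = [ip.CellData("c", ip.sample_distances(q, truth, 400, seed=rng), q, {})]
        fit = ip.fit_nonparametric(cells)
        obj_fit = nonparametric_objective(cells, fit)
        sp = fit.support_points
        best = -np.inf
        for start_scale in (0.0, 0.5):
            x0 = rng.normal(0, start_scale, len(sp) - 1)

            def neg(wf):
                pot = ip.NonparametricPotential(sp, np.concatenate([wf, [0.0]]))
                return -nonparametric_objective(cells, pot)

            res = optimize.minimize(neg, x0=x0, method="BFGS",
                                    options={"maxiter": 500})
            best = max(best, -res.fun)
        assert obj_fit >= best - 1e-3

    def test_penalty_scales_inverse_square_smoothness(self, small_context):
        q = small_context["q"]
        rng = np.random.default_rng(34)
        cells = [ip.CellData("c", ip.sample_distances(q, None, 200, seed=rng), q, {})]
        w = np.zeros(21)
        w[2:6] = -1.0
        pot = ip.NonparametricPotential.default_grid(weights=w)
        objs = [nonparametric_objective(cells, pot, s=s) for s in (1.0, 2.0, 4.0, 8.0)]
        assert np.all(np.diff(objs) > 0)  # looser penalty -> higher objective


class TestKernelSmooth:
    def test_constant_signal(self):
        x = np.linspace(0, 40, 15)
        y = np.full(15, 2.5)
        xq, mean, sd = ip.kernel_smooth(x, y, bandwidth=5.0)
        np.testing.assert_allclose(mean, 2.5, atol=1e-12)
        np.testing.assert_allclose(sd, 0.0, atol=1e-9)

    def test_huge_bandwidth_gives_global_mean(self, rng):
        x = rng.uniform(0, 40, 30)
        y = rng.normal(1.0, 0.5, 30)
        xq, mean, sd = ip.kernel_smooth(x, y, bandwidth=1e6)
        np.testing.assert_allclose(mean, y.mean(), rtol=1e-6)

    def test_tracks_trend(self, rng):
        x = np.linspace(0, 46, 80)
        y = 0.1 * x + rng.normal(0, 0.05, 80)
        xq, mean, sd = ip.kernel_smooth(x, y, bandwidth=5.0)
        mid = (xq > 10) & (xq < 36)
        np.testing.assert_allclose(mean[mid], 0.1 * xq[mid], atol=0.15)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="two points"):
            ip.kernel_smooth([1.0], [2.0], bandwidth=5.0)
        with pytest.raises(ValueError, match="bandwidth"):
            ip.kernel_smooth([1.0, 2.0], [1.0, 2.0], bandwidth=0.0)
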