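import numpy as np
import pytest
from scipy import stats

import uncertime as ut
from uncertime.gplvm import (
    DEFAULT_JITTER,
    _logpost_and_grad,
    hpd_interval,
    kernel_matrix,
    predictive_density,
    summarize_posterior,
)


def random_state(rng, n=6, p=2):
    return ut.GPLVMState(
        t=rng.uniform(0.05, 0.95, size=n),
        lam=rng.uniform(0.5, 5.0, size=p),
        sigma_sq=rng.uniform(0.05, 1.0, size=p),
        gamma=rng.uniform(1.0, 10.0),
    )


class TestKernel:
    def test_closed_form_two_points(self):
        K = kernel_matrix(np.array([0.0, 1.0]), 1.0, jitter=0.0)
        e1 = np.exp(-1.0)
        np.testing.assert_allclose(K, [[1.0, e1], [e1, 1.0]], rtol=1e-12)

    def test_lambda_zero_gives_ones(self):
        K = kernel_matrix(np.array([0.1, 0.4, 0.9]), 0.0, jitter=0.0)
        np.testing.assert_array_equal(K, np.ones((3, 3)))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_positive_semidefinite(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.uniform(0, 1, size=8)
        lam = rng.uniform(0, 50)
        jitter = 1e-6
        K = kernel_matrix(t, lam, jitter=jitter)
        eigs = np.linalg.eigvalsh(K)
        assert eigs.min() >= -1e-10 + jitter

    def test_non_finite_pseudotimes_error(self):
        with pytest.raises(ut.gplvm.NumericalError):
            kernel_matrix(np.array([0.1, np.nan]), 1.0)


class TestLogMarginal:
    def test_single_point_closed_form(self):
        # N=1, sigma^2=1: x ~ N(0, 2), density at 0 is -0.5*log(4*pi)
        lp = ut.log_marginal([0.3], [1.0], [1.0], np.array([[0.0]]), jitter=0.0)
        np.testing.assert_allclose(lp, -0.5 * np.log(4 * np.pi), rtol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_mvn_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(3, 10), 2
        t = rng.uniform(0, 1, size=n)
        lam = rng.uniform(0.2, 8.0, size=p)
        sig = rng.uniform(0.05, 1.5, size=p)
        X = rng.normal(size=(n, p))
        lp = ut.log_marginal(t, lam, sig, X, jitter=0.0)
        oracle = sum(
            stats.multivariate_normal.logpdf(
                X[:, j], mean=np.zeros(n), cov=kernel_matrix(t, lam[j]) + sig[j] * np.eye(n)
            )
            for j in range(p)
        )
        np.testing.assert_allclose(lp, oracle, atol=1e-8)

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(9)
        n = 7
        t = rng.uniform(0, 1, size=n)
        X = rng.normal(size=(n, 2))
        lam, sig = [1.5, 0.7], [0.3, 0.4]
        perm = rng.permutation(n)
        lp1 = ut.log_marginal(t, lam, sig, X, jitter=0.0)
        lp2 = ut.log_marginal(t[perm], lam, sig, X[perm], jitter=0.0)
        np.testing.assert_allclose(lp1, lp2, atol=1e-9)


class TestLogJoint:
    def test_matches_term_by_term_density_oracle(self):
        rng = np.random.default_rng(4)
        state = random_state(rng)
        X = rng.normal(size=(6, 2))
        h = ut.GPLVMHyperparams(gamma_alpha=30, gamma_beta=5, alpha=1, beta=1, mu_t=0.5, sigma_t_sq=1.0)
        sd = np.sqrt(h.sigma_t_sq)
        a, b = (0 - h.mu_t) / sd, (1 - h.mu_t) / sd
        oracle_prior = (
            stats.gamma.logpdf(state.gamma, a=h.gamma_alpha, scale=1 / h.gamma_beta)
            + stats.expon.logpdf(state.lam, scale=1 / state.gamma).sum()
            + stats.invgamma.logpdf(state.sigma_sq, a=h.alpha, scale=h.beta).sum()
            + stats.truncnorm.logpdf(state.t, a, b, loc=h.mu_t, scale=sd).sum()
        )
        expected = oracle_prior + ut.log_marginal(state.t, state.lam, state.sigma_sq, X)
        np.testing.assert_allclose(ut.log_joint(state, X, h), expected, atol=1e-8)

    def test_reversal_symmetry_at_central_prior(self):
        rng = np.random.default_rng(5)
        h = ut.GPLVMHyperparams(mu_t=0.5)
        for _ in range(5):
            state = random_state(rng)
            X = rng.normal(size=(6, 2))
            flipped = ut.GPLVMState(1.0 - state.t, state.lam, state.sigma_sq, state.gamma)
            np.testing.assert_allclose(
                ut.log_joint(state, X, h), ut.log_joint(flipped, X, h), atol=1e-8
            )

    def test_boundary_and_out_of_support_minus_inf(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(4, 2))
        h = ut.GPLVMHyperparams()
        good = random_state(rng, n=4)
        t_bad = good.t.copy()
        t_bad[0] = 1.0
        assert ut.log_joint(ut.GPLVMState(t_bad, good.lam, good.sigma_sq, good.gamma), X, h) == -np.inf
        assert (
            ut.log_joint(ut.GPLVMState(good.t, -good.lam, good.sigma_sq, good.gamma), X, h)
            == -np.inf
        )


def test_unconstrained_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    N, P = 7, 2
    Xc = rng.normal(size=(N, P))
    h = ut.GPLVMHyperparams()
    z = rng.normal(size=N + 2 * P + 1) * 0.5
    lp, g = _logpost_and_grad(z, Xc, h, DEFAULT_JITTER)
    num = np.zeros_like(z)
    eps = 1e-6
    for i in range(len(z)):
        zp, zm = z.copy(), z.copy()
        zp[i] += eps
        zm[i] -= eps
        num[i] = (
            _logpost_and_grad(zp, Xc, h, DEFAULT_JITTER)[0]
            - _logpost_and_grad(zm, Xc, h, DEFAULT_JITTER)[0]
        ) / (2 * eps)
    np.testing.assert_allclose(g, num, rtol=1e-4, atol=1e-5)


class TestHPD:
    def test_point_mass_zero_width(self):
        lo, hi = hpd_interval(np.full(30, 2.5), 0.95)
        assert (lo, hi) == (2.5, 2.5)

    def test_width_nondecreasing_in_mass(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=500)
        widths = []
        for mass in (0.5, 0.75, 0.9, 0.95, 0.99):
            lo, hi = hpd_interval(s, mass)
            widths.append(hi - lo)
        assert all(w2 >= w1 for w1, w2 in zip(widths, widths[1:]))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(10), 0.95)

    def test_normal_interval_matches_theory(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=20_000)
        lo, hi = hpd_interval(s, 0.95)
        assert abs((hi - lo) - 2 * 1.959964) < 0.08


class TestOrientation:
    def test_idempotent(self, posterior_low_noise, low_noise_ds):
        anchor = low_noise_ds.truth_pseudotimes
        once = ut.orient_and_map(posterior_low_noise, anchor)
        twice = ut.orient_and_map(once, anchor)
        np.testing.assert_array_equal(once.t, twice.t)

    def test_negated_anchor_flips_every_draw(self, posterior_low_noise, low_noise_ds):
        anchor = low_noise_ds.truth_pseudotimes
        plus = ut.orient_and_map(posterior_low_noise, anchor)
        minus = ut.orient_and_map(posterior_low_noise, -anchor)
        np.testing.assert_allclose(plus.t, 1.0 - minus.t, atol=1e-12)

    def test_constant_anchor_rejected(self, posterior_low_noise):
        with pytest.raises(ValueError, match="orientation"):
            ut.orient_and_map(posterior_low_noise, np.ones(posterior_low_noise.n_cells))

    def test_cell_id_anchor_puts_cell_early(self, oriented_posterior, low_noise_ds):
        early_cell = oriented_posterior.cell_ids[int(np.argmin(low_noise_ds.truth_pseudotimes))]
        re = ut.orient_and_map(oriented_posterior, early_cell)
        idx = re.cell_ids.index(early_cell)
        assert np.median(re.t[:, idx]) <= 0.5

    def test_map_is_argmax_log_posterior(self, oriented_posterior):
        assert oriented_posterior.map_index == int(np.argmax(oriented_posterior.log_posterior))


class TestSampler:
    def test_draws_stay_in_support(self, posterior_low_noise):
        post = posterior_low_noise
        assert post.t.min() >= 0.0
        assert post.t.max() < 1.0
        assert np.all(post.lam > 0)
        assert np.all(post.sigma_sq > 0)
        assert np.all(post.gamma > 0)
        assert np.all(np.isfinite(post.log_posterior))

    def test_seeded_determinism(self, low_noise_ds):
        Xs = ut.standardize(low_noise_ds.embedding)
        settings = ut.MCMCSettings(chains=1, warmup=60, samples=30, seed=42)
        a = ut.sample_posterior(Xs, settings=settings)
        b = ut.sample_posterior(Xs, settings=settings)
        np.testing.assert_array_equal(a.t, b.t)
        np.testing.assert_array_equal(a.log_posterior, b.log_posterior)

    def test_random_walk_fallback_in_support(self, low_noise_ds):
        Xs = ut.standardize(low_noise_ds.embedding)
        settings = ut.MCMCSettings(chains=1, warmup=200, samples=50, seed=3, method="rw")
        post = ut.sample_posterior(Xs, settings=settings)
        assert post.t.min() >= 0.0 and post.t.max() < 1.0

    def test_shrinkage_reduces_trajectory_wiggliness(self, low_noise_ds):
        # stronger shrinkage on the length-scale prior => smaller lambda
        Xs = ut.standardize(low_noise_ds.embedding)
        settings = ut.MCMCSettings(chains=1, warmup=300, samples=200, seed=9)
        high = ut.sample_posterior(Xs, ut.GPLVMHyperparams(gamma_alpha=30, gamma_beta=5), settings)
        low = ut.sample_posterior(Xs, ut.GPLVMHyperparams(gamma_alpha=3, gamma_beta=1), settings)
        assert high.lam.sum(axis=1).mean() < low.lam.sum(axis=1).mean()


class TestPredictiveDensity:
    def test_nonnegative_everywhere(self, posterior_high_noise):
        ds, post = posterior_high_noise
        Xs = ut.standardize(ds.embedding)
        grid = np.random.default_rng(0).uniform(-3, 3, size=(50, 2))
        dens = predictive_density(post, Xs, grid, n_draws=5, n_tstar=5)
        assert np.all(dens >= 0)

    def test_conditional_density_peaks_near_the_cell(self, oriented_posterior, low_noise_ds):
        Xs = ut.standardize(low_noise_ds.embedding)
        post = oriented_posterior
        i = int(np.argmin(np.abs(post.t_mean() - 0.5)))
        t_i = float(post.t_mean()[i])
        x_i = Xs.coords[i]
        far = x_i + 3.0 * Xs.coords.std(axis=0)
        dens = predictive_density(post, Xs, np.vstack([x_i, far]), t_star=t_i, n_draws=10)
        assert dens[0] > dens[1]

    def test_noise_increases_conditional_overlap(
        self, oriented_posterior, low_noise_ds, posterior_high_noise
    ):
        # Bhattacharyya coefficient between p(x*|t*=0.5) and p(x*|t*=0.7)
        def overlap(post, X):
            Xs = ut.standardize(X)
            g = np.linspace(-2.5, 2.5, 25)
            gx, gy = np.meshgrid(g, g)
            grid = np.column_stack([gx.ravel(), gy.ravel()])
            p = predictive_density(post, Xs, grid, t_star=0.5, n_draws=10)
            q = predictive_density(post, Xs, grid, t_star=0.7, n_draws=10)
            p, q = p / p.sum(), q / q.sum()
            return np.sum(np.sqrt(p * q))

        ds_noisy, post_noisy = posterior_high_noise
        bc_low = overlap(oriented_posterior, low_noise_ds.embedding)
        bc_high = overlap(post_noisy, ds_noisy.embedding)
        assert bc_low < bc_high


def test_summarize_posterior_table(oriented_posterior):
    df = summarize_posterior(oriented_posterior)
    assert list(df.columns) == [
        "cell", "t_mean", "t_map", "hpd75_lo", "hpd75_hi", "hpd95_lo", "hpd95_hi",
    ]
    assert len(df) == oriented_posterior.n_cells
    assert (df["hpd95_hi"] - df["hpd95_lo"] >= df["hpd75_hi"] - df["hpd75_lo"] - 1e-12).all()
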