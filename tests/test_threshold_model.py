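import numpy as np
import pytest
from scipy import sparse, stats

import ordmisfit as om
from ordmisfit import _gibbs
from ordmisfit.threshold_model import ChainSettings, PriorSpec, run_chain


class TestCategoryProbability:
    def test_symmetry_at_zero(self):
        assert om.category_probability(0.0, (0.0, 1.0), 0) == pytest.approx(0.5)

    def test_standard_normal_cdf_values(self):
        probs = om.category_probability(0.0, (0.0, 1.0))
        assert probs[1] == pytest.approx(0.34134, abs=1e-5)
        assert probs[2] == pytest.approx(0.15866, abs=1e-5)

    def test_sums_to_one_and_upper_limit(self):
        for eta in (-3.0, 0.3, 2.0):
            assert om.category_probability(eta, (0.0, 1.0)).sum() == pytest.approx(1.0)
        assert om.category_probability(50.0, (0.0, 1.0), 2) == pytest.approx(1.0)


class TestNdtri:
    def test_matches_scipy_across_range(self):
        from scipy.special import ndtri

        p = np.concatenate(
            [np.geomspace(1e-12, 0.4, 200), 1 - np.geomspace(1e-12, 0.4, 200)]
        )
        ours = np.array([_gibbs._ndtri(v) for v in p])
        assert np.abs(ours - ndtri(p)).max() < 1e-9


class TestTruncatedNormal:
    def test_bounds_respected(self):
        draws = _gibbs.truncnorm_draws(1, 0.0, 1.0, -np.inf, 0.0, 5000)
        assert (draws <= 0).all()
        draws = _gibbs.truncnorm_draws(2, 0.0, 1.0, 0.0, 1.0, 5000)
        assert ((draws > 0) & (draws <= 1)).all()

    def test_half_normal_mean(self):
        """Lower-truncated standard normal at 0: mean -sqrt(2/pi) ~ -0.7979."""
        draws = _gibbs.truncnorm_draws(3, 0.0, 1.0, -np.inf, 0.0, 100_000)
        assert draws.mean() == pytest.approx(-np.sqrt(2 / np.pi), abs=0.01)

    def test_extreme_truncation_stays_finite(self):
        draws = _gibbs.truncnorm_draws(4, -30.0, 1.0, 5.0, 6.0, 100)
        assert np.isfinite(draws).all()
        assert ((draws >= 5.0) & (draws <= 6.0)).all()

    def test_python_reference_sampler(self, rng):
        for _ in range(200):
            val = om.sample_liability(1, 0.3, (0.0, 1.0), rng)
            assert 0.0 < val <= 1.0
        low = om.sample_liability(0, -1.0, (0.0, 1.0), rng)
        assert low <= 0.0


class TestGeneticVariance:
    def test_no_data_limit_recovers_prior(self, rng):
        """With u = 0 the conditional is the scaled inverse chi-squared prior."""
        prior = PriorSpec(nu=4.0, s2=0.05)
        a_inv = sparse.eye(3, format="csr")
        draws = np.array(
            [om.sample_genetic_variance(np.zeros(3), a_inv, prior, rng)
             for _ in range(20_000)]
        )
        # u'A^-1 u = 0 with q = 3: draws = nu s2 / chi2_{q + nu}
        ref = prior.nu * prior.s2 / rng.chisquare(3 + prior.nu, 20_000)
        assert draws.mean() == pytest.approx(ref.mean(), rel=0.05)
        assert stats.ks_2samp(draws, ref).pvalue > 1e-3

    def test_single_animal_mean_formula(self, rng):
        """q=1, A=I, u=1: E = (1 + nu s2) / (q + nu - 2)."""
        prior = PriorSpec(nu=6.0, s2=0.05)
        a_inv = sparse.eye(1, format="csr")
        draws = np.array(
            [om.sample_genetic_variance(np.ones(1), a_inv, prior, rng)
             for _ in range(40_000)]
        )
        expected = (1.0 + prior.nu * prior.s2) / (1 + prior.nu - 2)
        assert draws.mean() == pytest.approx(expected, rel=0.03)

    def test_positivity(self, rng):
        prior = PriorSpec()
        a_inv = sparse.eye(5, format="csr")
        assert all(
            om.sample_genetic_variance(rng.normal(size=5), a_inv, prior, rng) > 0
            for _ in range(100)
        )


class TestThresholdSampler:
    def test_support_between_bracketing_liabilities(self, rng):
        l = np.array([-0.5, 0.2, 0.9, 1.1, 2.0])
        r = np.array([0, 1, 1, 2, 2])
        for _ in range(100):
            t1 = om.sample_threshold(l, r, rng, m=1, t=(0.0, 1.0))
            assert 0.9 < t1 < 1.1

    def test_empty_top_class_falls_back_to_upper_bound(self, rng):
        l = np.array([-0.5, 0.2, 0.9])
        r = np.array([0, 1, 1])
        draws = [
            om.sample_threshold(l, r, rng, m=1, t=(0.0, 1.0), t_upper=4.0)
            for _ in range(500)
        ]
        assert all(0.9 < t < 4.0 for t in draws)
        assert max(draws) > 2.0  # actually uses the widened interval

    def test_single_record_per_class(self, rng):
        t1 = om.sample_threshold(
            np.array([0.4, 1.3]), np.array([1, 2]), rng, m=1, t=(0.0, 1.0)
        )
        assert 0.4 < t1 < 1.3

    def test_inverted_interval_raises(self, rng):
        with pytest.raises(ValueError):
            om.sample_threshold(
                np.array([1.5, 0.5]), np.array([1, 2]), rng, m=1, t=(0.0, 1.0)
            )


class TestSpecs:
    def test_prior_validation(self):
        with pytest.raises(ValueError):
            PriorSpec(beta_min=1, beta_max=-1)
        with pytest.raises(ValueError):
            PriorSpec(nu=-1)

    def test_settings_defaults(self):
        s = ChainSettings(n_iter=10_000)
        assert s.burnin == 5_000
        assert s.n_retained == 500
        assert s.misclass_warmup == 1000
        with pytest.raises(ValueError):
            ChainSettings(n_iter=100, burnin=200)


def _toy_problem(n=30, q=40, seed=0):
    ped = om.simulate_pedigree(q, 8, seed=seed)
    rng = np.random.default_rng(seed)
    animal = np.arange(q - n, q, dtype=np.int64)
    eff_idx = (np.arange(n) % 2).reshape(-1, 1).astype(np.int64)
    y = rng.integers(0, 3, n).astype(np.int64)
    return ped, y, eff_idx, animal


class TestRunChain:
    def test_bitwise_reproducible(self):
        ped, y, eff_idx, animal = _toy_problem()
        settings = ChainSettings(n_iter=100, burnin=50, thin=1)
        outs = [
            run_chain(y, eff_idx, animal, 2, ped, PriorSpec(), settings, seed=5)
            for _ in range(2)
        ]
        assert (outs[0].sigma_u2_samples == outs[1].sigma_u2_samples).all()
        assert (outs[0].u_mean == outs[1].u_mean).all()

    def test_identity_pi_keeps_layer_inert(self):
        """With P fixed at identity no record can switch class."""
        ped, y, eff_idx, animal = _toy_problem()
        settings = ChainSettings(n_iter=200, burnin=100, thin=1, misclass_warmup=0)
        out = run_chain(
            y, eff_idx, animal, 2, ped, PriorSpec(), settings,
            misclass_enabled=True, pi_fixed=np.eye(3), seed=3,
        )
        assert (out.misclass_prob == 0).all()
        assert (out.gamma_mean == np.diag(np.bincount(y, minlength=3))).all()

    def test_invalid_classes_rejected(self):
        ped, y, eff_idx, animal = _toy_problem()
        y[0] = 7
        with pytest.raises(ValueError):
            run_chain(y, eff_idx, animal, 2, ped, PriorSpec(), ChainSettings(n_iter=10, burnin=5))

    def test_liability_class_consistency_of_final_state(self):
        ped, y, eff_idx, animal = _toy_problem()
        settings = ChainSettings(n_iter=150, burnin=100, thin=1, misclass_warmup=0)
        out = run_chain(
            y, eff_idx, animal, 2, ped, PriorSpec(), settings,
            misclass_enabled=True, seed=11,
        )
        st = out.state
        thr = st["thr"]
        edges = np.concatenate(([-np.inf], thr, [np.inf]))
        for i, (li, ri) in enumerate(zip(st["l"], st["r"])):
            assert edges[ri] < li <= edges[ri + 1]
        assert thr[0] == 0.0 and (np.diff(thr) > 0).all()


class TestJointDistribution:
    """Geweke-style successive-conditional check of the compiled kernel.

    Cycling (parameters | data) via the kernel and (data | parameters) via
    the generative model must leave the prior invariant; biased or
    inconsistent full conditionals show up as drift in the marginal moments.
    """

    @pytest.mark.parametrize("misclass", [False, True])
    def test_prior_moments_preserved(self, misclass):
        ped = om.simulate_pedigree(25, 5, seed=2)
        n = 20
        animal = np.arange(5, 25, dtype=np.int64)
        eff_idx = (np.arange(n) % 2).reshape(-1, 1).astype(np.int64)
        prior = PriorSpec(beta_min=-2, beta_max=2, nu=5, s2=0.05)
        settings = ChainSettings(n_iter=1, burnin=0, thin=1, t_upper=4.0,
                                 misclass_warmup=0)
        rng = np.random.default_rng(0)
        y = rng.integers(0, 3, n).astype(np.int64)
        state = None
        kept = []
        ncyc, skip = 12_000, 1_000
        for c in range(ncyc):
            out = run_chain(
                y, eff_idx, animal, 2, ped, prior, settings,
                misclass_enabled=misclass, n_categories=3,
                seed=1_000 + c, state=state,
            )
            state = out.state
            eta = state["u"][animal] + state["beta"][eff_idx[:, 0]]
            if misclass:
                # r ~ theta(eta, t), y | r ~ pi row, l | r truncated normal
                edges = np.concatenate(([-np.inf], state["thr"], [np.inf]))
                theta = np.diff(stats.norm.cdf(edges[None, :] - eta[:, None]), axis=1)
                r = (rng.random(n)[:, None] > theta.cumsum(axis=1)).sum(axis=1)
                probs = state["pi"][r]
                ynew = (rng.random(n)[:, None] > probs.cumsum(axis=1)).sum(axis=1)
                lo, hi = edges[r] - eta, edges[r + 1] - eta
                l = eta + stats.truncnorm.rvs(lo, hi, random_state=rng)
                state["r"][:] = r
            else:
                l = eta + rng.standard_normal(n)
                ynew = np.searchsorted(state["thr"], l, side="left")
                state["r"][:] = ynew
            y[:] = ynew
            state["l"][:] = l
            if c >= skip:
                kept.append(
                    (state["sigma_u2"][0], state["beta"][0], state["thr"][1],
                     state["pi"][0, 1], state["pi"][2, 1])
                )
        kept = np.array(kept)
        # sigma_u2 marginal = scaled inverse chi-squared prior
        ref = prior.nu * prior.s2 / np.random.default_rng(1).chisquare(
            prior.nu, 40_000
        )
        se = kept[:, 0].std() / np.sqrt(len(kept) / 20)  # crude ESS guard
        assert abs(kept[:, 0].mean() - ref.mean()) < 4 * se
        assert stats.ks_2samp(kept[::20, 0], ref).pvalue > 1e-4
        # beta marginal = U(-2, 2)
        assert abs(kept[:, 1].mean()) < 0.1
        assert kept[:, 1].var() == pytest.approx(4 / 3, rel=0.15)
        if misclass:
            # pi rows keep their Dirichlet prior means: 2.5/95 off-diagonal
            assert kept[:, 3].mean() == pytest.approx(2.5 / 95, rel=0.2)
            assert kept[:, 4].mean() == pytest.approx(2.5 / 95, rel=0.2)


class TestPythonScanReference:
    def test_u_update_scalar_mixed_model_equation(self, rng):
        """With A = I and one record per animal the conditional mean is
        (l_i - x_i beta) / (1 + lambda)."""
        n = 4
        l = np.array([0.4, -0.2, 1.0, 0.3])
        X = np.zeros((n, 1), dtype=int)
        animal = np.arange(n)
        a_inv = sparse.eye(n, format="csr")
        sigma_u2 = 0.5
        lam = 1.0 / sigma_u2
        # pin the single fixed-effect level at 0.1 via its prior bounds
        prior = PriorSpec(beta_min=0.1 - 1e-9, beta_max=0.1 + 1e-9)
        draws = []
        for _ in range(3000):
            beta = np.array([0.1])
            eta = beta[0] + np.zeros(n)
            ui = np.zeros(n)
            om.sample_location_effects(
                l, eta, beta, ui, X, animal, a_inv, sigma_u2, prior, rng,
            )
            draws.append(ui[2])
        expected = (l[2] - beta[0]) / (1 + lam)
        assert np.mean(draws) == pytest.approx(expected, abs=0.05)

    def test_shift_invariance_of_level_update(self, rng):
        """Adding +c to every liability shifts an intercept-like level by +c."""
        n = 60
        X = np.zeros((n, 1), dtype=int)
        animal = np.zeros(n, dtype=int)
        a_inv = sparse.eye(1, format="csr")
        base = rng.normal(size=n)
        means = []
        for c in (0.0, 1.5):
            l = base + c
            vals = []
            for _ in range(400):
                beta = np.array([0.0])
                eta = np.zeros(n)
                u = np.zeros(1)
                om.sample_location_effects(
                    l, eta, beta, u, X, animal, a_inv, 1e6, PriorSpec(), rng
                )
                vals.append(beta[0])
            means.append(np.mean(vals))
        assert means[1] - means[0] == pytest.approx(1.5, abs=0.1)
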