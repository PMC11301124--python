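import numpy as np
import pytest

from triarm import BayesianOutcomeModel, PosteriorDraws, rhat
from triarm.grid import GridCoverageWarning, grid_posterior
from triarm.inference import ConvergenceWarning


class TestRhat:
    def test_iid_chains_are_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((4, 1000))
        assert 0.999 < rhat(chains) < 1.01

    def test_divergent_chain_detected(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((4, 500))
        chains[3] += 10.0
        assert rhat(chains) > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            rhat(np.zeros((1, 100)))

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="10 draws"):
            rhat(np.zeros((4, 5)))

    def test_permutation_within_chains_stable_for_iid_draws(self):
        rng = np.random.default_rng(2)
        chains = rng.standard_normal((4, 800))
        r0 = rhat(chains)
        perm = np.stack([rng.permutation(c) for c in chains])
        assert abs(rhat(perm) - r0) < 0.01


class TestPosteriorDraws:
    def test_summary_and_long_export_shapes(self):
        rng = np.random.default_rng(3)
        draws = PosteriorDraws(("a", "b"), rng.standard_normal((4, 50, 2)))
        summ = draws.summary()
        assert list(summ.columns) == ["mean", "sd", "2.5%", "97.5%", "rhat"]
        assert list(summ.index) == ["a", "b"]
        long = draws.to_frame()
        assert len(long) == 4 * 50 * 2
        assert set(long.parameter) == {"a", "b"}


class TestFit:
    def test_same_seed_identical_draws(self, ref_dataset):
        model = BayesianOutcomeModel.from_dataset("postSTAI", ref_dataset)
        a = model.fit(chains=2, iterations=150, warmup=75, seed=5)
        b = model.fit(chains=2, iterations=150, warmup=75, seed=5)
        np.testing.assert_array_equal(a.draws.draws, b.draws.draws)

    def test_default_sampler_settings_recorded(self, spic_fit):
        md = spic_fit.draws.metadata
        assert md["chains"] == 4
        assert md["outcome"] == "postSPIC"

    def test_positive_parameters_respect_support(self, spic_fit):
        assert np.all(spic_fit.draws.get("sigma") > 0)
        assert np.all(spic_fit.draws.get("nu") > 1)

    def test_rhat_defined_for_every_parameter(self, spic_fit):
        assert set(spic_fit.rhat) == set(spic_fit.draws.param_names)

    def test_posterior_intervals_much_narrower_than_priors(self, spic_fit):
        """On trial-sized data the data dominate the weak priors for every
        identified parameter. The degrees-of-freedom parameter is excluded:
        with ~45 near-normal records nu is weakly identified and its
        posterior legitimately spans most of its prior."""
        pri = spic_fit.spec.priors
        coef_lo, coef_hi = pri.coef_interval()
        pos_lo, pos_hi = pri.positive_interval()
        for name in spic_fit.draws.param_names:
            if name == "nu":
                continue
            lo, hi = spic_fit.credible_interval(name)
            prior_width = (pos_hi - pos_lo) if name == "sigma" else (coef_hi - coef_lo)
            assert (hi - lo) < prior_width / 2

    def test_nonconvergent_fit_flagged_not_silent(self, ref_dataset):
        """A backend returning divergent chains must surface through the
        Rhat gate as a flagged result, never a silent success."""

        class DivergentBackend:
            name = "stub"

            def sample(self, log_prob, ndim, *, chains, iterations, warmup, seed,
                       init_center, init_scale):
                rng = np.random.default_rng(0)
                draws = rng.normal(size=(chains, 200, ndim)) * 0.01
                draws[-1] += 10.0  # one chain stuck far away
                draws += init_center
                return draws

        model = BayesianOutcomeModel.from_dataset("postSTAI", ref_dataset)
        with pytest.warns(ConvergenceWarning):
            res = model.fit(chains=4, iterations=100, seed=8, backend=DivergentBackend())
        assert not res.converged
        with pytest.raises(RuntimeError, match="Rhat"):
            res.raise_for_convergence()


def _reduced_logpost(model, sigma, log_prob_free):
    """Vectorized log posterior over (mu, beta) with everything else fixed."""

    def f(z):
        z = np.atleast_2d(z)
        out = np.empty(len(z))
        for i, (mu, beta) in enumerate(z):
            theta = np.array([mu, 0.0, 0.0, beta, 0.0, 0.0, sigma, 30.0])
            out[i] = model.logpost(theta)
        return out

    return f


class TestGridOracle:
    @pytest.fixture(scope="class")
    def small_model(self, ref_config):
        from triarm import generate_trial

        cfg = ref_config.with_n_per_arm({"control": 10, "multiple": 10, "single": 10})
        ds = generate_trial(cfg, seed=17)
        return BayesianOutcomeModel.from_dataset("postPRCA24", ds)

    @pytest.fixture(scope="class")
    def fixed(self, small_model):
        start = small_model.start_vector()
        return {
            "alpha_multiple": 0.0,
            "alpha_single": 0.0,
            "gamma_multiple": 0.0,
            "gamma_single": 0.0,
            "sigma": float(start[-2]),
            "nu": 30.0,
        }

    def _grids(self, small_model, n=81):
        start = small_model.start_vector()
        mu0, beta0 = start[0], start[3]
        return {
            "mu": np.linspace(mu0 - 60, mu0 + 60, n),
            "beta": np.linspace(beta0 - 0.9, beta0 + 0.9, n),
        }

    def test_grid_covers_mass_and_normalizes(self, small_model, fixed):
        gp = grid_posterior(small_model, self._grids(small_model), fixed)
        assert gp.covered
        x, d = gp.marginal("mu")
        assert np.trapezoid(d, x) == pytest.approx(1.0, rel=1e-6)

    def test_refining_grid_leaves_marginal_means_stable(self, small_model, fixed):
        coarse = grid_posterior(small_model, self._grids(small_model, 81), fixed)
        fine = grid_posterior(small_model, self._grids(small_model, 161), fixed)
        for name in ("mu", "beta"):
            assert abs(coarse.marginal_mean(name) - fine.marginal_mean(name)) < 1e-3 * max(
                1.0, abs(fine.marginal_mean(name))
            )

    def test_symmetric_data_gives_symmetric_posterior(self, ref_config):
        from triarm import generate_trial

        cfg = ref_config.with_n_per_arm({"control": 10, "multiple": 10, "single": 10})
        ds = generate_trial(cfg, seed=23)
        frame = ds.frame.copy()
        # symmetrize the STAI outcome about the scale midpoint of 20
        half = frame.postSTAI - 20.0
        frame.postSTAI = 20.0 + np.concatenate([half[:15], -half[:15]])
        from triarm.data import TrialDataset

        model = BayesianOutcomeModel.from_dataset("postSTAI", TrialDataset(frame))
        free = {"mu": np.linspace(-30 + 20, 30 + 20, 201)}
        fixed = {
            "alpha_multiple": 0.0,
            "alpha_single": 0.0,
            "beta_fam": 0.0,
            "sigma": float(np.std(frame.postSTAI, ddof=1)),
            "nu": 30.0,
        }
        gp = grid_posterior(model, free, fixed)
        step = free["mu"][1] - free["mu"][0]
        assert abs(gp.marginal_mean("mu") - 20.0) < step

    def test_undersized_grid_flagged(self, small_model, fixed):
        grids = self._grids(small_model)
        grids["mu"] = np.linspace(grids["mu"].mean() - 1, grids["mu"].mean() + 1, 21)
        with pytest.warns(GridCoverageWarning):
            gp = grid_posterior(small_model, grids, fixed)
        assert not gp.covered

    def test_mcmc_marginals_match_grid(self, small_model, fixed):
        """Ensemble MCMC on the same reduced 2-parameter posterior agrees
        with the brute-force grid within Monte Carlo error."""
        from triarm.inference import EmceeBackend

        gp = grid_posterior(small_model, self._grids(small_model, 121), fixed)
        logpost = _reduced_logpost(small_model, fixed["sigma"], None)
        start = small_model.start_vector()
        backend = EmceeBackend(walkers=16)
        draws = backend.sample(
            logpost,
            2,
            chains=4,
            iterations=800,
            warmup=400,
            seed=31,
            init_center=np.array([start[0], start[3]]),
            init_scale=np.array([1.0, 0.05]),
        )
        for j, name in enumerate(["mu", "beta"]):
            chain_means = draws[:, :, j].mean(axis=1)
            mcse = chain_means.std(ddof=1) / np.sqrt(len(chain_means))
            grid_err = np.diff(self._grids(small_model, 121)[name][:2])[0]
            tol = 2 * mcse + grid_err
            assert abs(draws[:, :, j].mean() - gp.marginal_mean(name)) < tol
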