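"""Bayesian mixing model: likelihood oracles, recovery and calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats as sps

from csiaa import (DomainError, EndMember, EndMemberSet, MixingModel,
                   MixingModelSpec, MixingResults, UndefinedResultError,
                   fit_mixing, mixing_loglik, summarize_contributions)
from csiaa.synthetic import simulate_mixture


def _endmembers(means, sds, tracers=("t",)):
    sources = []
    for i, (m, s) in enumerate(zip(means, sds)):
        m = np.atleast_1d(m)
        s = np.atleast_1d(s)
        sources.append(EndMember(f"src{i}", {t: (float(mi), float(si), None)
                                             for t, mi, si in zip(tracers, m, s)}))
    return EndMemberSet(tuple(sources))


class TestLoglik:
    def test_standard_normal_at_mode(self):
        ems = _endmembers([0.0, 5.0], [1.0, 1.0])
        model = MixingModel(np.array([[0.0]]), ems)
        # all weight on source 0, observation at its mean, unit variance
        assert model.loglik([1.0, 0.0]) == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_non_simplex_rejected(self):
        ems = _endmembers([0.0, 5.0], [1.0, 1.0])
        model = MixingModel(np.array([[1.0]]), ems)
        for bad in ([0.5, 0.6], [-0.1, 1.1], [0.5, 0.4]):
            with pytest.raises(DomainError):
                model.loglik(bad)

    def test_evidence_matches_independent_quadrature(self):
        """∫ exp(loglik) dp over the 2-source simplex vs a textbook-density oracle."""
        mu, sd = np.array([0.0, 4.0]), np.array([0.8, 1.2])
        obs = np.array([[1.1], [2.3], [0.4]])
        ems = _endmembers(mu, sd)
        model = MixingModel(obs, ems)

        def oracle_density(p1):
            mean = p1 * mu[0] + (1 - p1) * mu[1]
            var = p1 ** 2 * sd[0] ** 2 + (1 - p1) ** 2 * sd[1] ** 2
            return np.prod(sps.norm.pdf(obs.ravel(), mean, np.sqrt(var)))

        oracle, _ = integrate.quad(oracle_density, 0.0, 1.0, epsabs=1e-13, limit=200)
        grid = np.linspace(1e-9, 1 - 1e-9, 20001)
        ours = np.trapezoid([math.exp(model.loglik([p, 1 - p])) for p in grid], grid)
        assert ours == pytest.approx(oracle, rel=1e-6)

    def test_functional_wrapper(self):
        ems = _endmembers([0.0, 5.0], [1.0, 1.0])
        spec = MixingModelSpec(sources=ems)
        direct = MixingModel(np.array([[2.0]]), ems).loglik([0.5, 0.5])
        assert mixing_loglik(np.array([[2.0]]), [0.5, 0.5], spec) == pytest.approx(direct)


class TestFit:
    def test_observation_at_source_mean_dominates(self):
        ems = _endmembers([0.0, 10.0], [1.0, 1.0])  # 10σ separation
        fit = MixingModel(np.array([[0.0]]), ems).fit(
            seed=1, n_chains=2, n_iter=4000, n_burn=1000, thin=3)
        assert fit.summary()["mean"].iloc[0] > 0.9

    def test_identical_sources_recover_prior_mean(self):
        ems = _endmembers([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        obs = np.random.default_rng(4).normal(2.0, 0.6, size=(20, 1))
        fit = MixingModel(obs, ems).fit(seed=2, n_chains=2, n_iter=6000,
                                        n_burn=2000, thin=4)
        assert fit.draws.mean(axis=0) == pytest.approx([1 / 3] * 3, abs=0.05)

    def test_draws_on_simplex(self, two_source_endmembers):
        obs = simulate_mixture(two_source_endmembers, (0.6, 0.4), 20, rng=5)
        fit = MixingModel(obs, two_source_endmembers).fit(
            seed=3, n_chains=2, n_iter=2000, n_burn=500, thin=2)
        assert np.all(fit.draws >= 0)
        assert np.allclose(fit.draws.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.isfinite(fit.rhat))

    def test_reproducible_for_fixed_seed(self, two_source_endmembers):
        obs = simulate_mixture(two_source_endmembers, (0.5, 0.5), 10, rng=6)
        a = MixingModel(obs, two_source_endmembers).fit(
            seed=9, n_chains=1, n_iter=1000, n_burn=200, thin=2)
        b = MixingModel(obs, two_source_endmembers).fit(
            seed=9, n_chains=1, n_iter=1000, n_burn=200, thin=2)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_prior_only_recovers_dirichlet_moments(self):
        alpha = (2.0, 1.0, 1.0)
        ems = _endmembers([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        spec = MixingModelSpec(sources=ems, prior_alpha=alpha)
        fit = MixingModel(np.array([[0.0]]), spec=spec).fit(
            seed=7, n_chains=2, n_iter=15000, n_burn=3000, thin=4, prior_only=True)
        a0 = sum(alpha)
        expected_mean = np.array(alpha) / a0
        expected_var = expected_mean * (1 - expected_mean) / (a0 + 1)
        assert fit.draws.mean(0) == pytest.approx(expected_mean, abs=0.02)
        assert fit.draws.var(0) == pytest.approx(expected_var, abs=0.01)

    def test_label_permutation_equivariance(self):
        # two tracers keep the 3-source model identifiable
        mu = [[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]]
        sd = [[1.0, 1.0]] * 3
        tracers = ("t1", "t2")
        obs = simulate_mixture(_endmembers(mu, sd, tracers), (0.2, 0.5, 0.3), 40, rng=8)
        kwargs = dict(seed=12, n_chains=2, n_iter=6000, n_burn=2000, thin=3)
        forward = MixingModel(obs, _endmembers(mu, sd, tracers)).fit(**kwargs)
        perm = [2, 0, 1]
        permuted = MixingModel(obs, _endmembers([mu[i] for i in perm],
                                                [sd[i] for i in perm],
                                                tracers)).fit(**kwargs)
        assert permuted.draws.mean(0) == pytest.approx(
            forward.draws.mean(0)[perm], abs=0.03)

    def test_fit_mixing_wrapper_requires_seed(self, two_source_endmembers):
        spec = MixingModelSpec(sources=two_source_endmembers, n_iter=100, n_burn=10)
        with pytest.raises(ValueError, match="seed"):
            fit_mixing(np.array([[1.0]]), spec)


class TestSummaries:
    def _degenerate(self, draws, ems):
        model = MixingModel(np.array([[0.0, 0.0]]), ems, spec=MixingModelSpec())
        k = len(ems)
        return MixingResults(
            model=model, spec=MixingModelSpec(seed=0), chain_draws=draws,
            rhat=np.ones(k), ess=np.full(k, 400.0), acceptance=np.array([0.3]),
        )

    def test_degenerate_point_mass(self):
        ems = _endmembers([[0, 0], [1, 1], [2, 2], [3, 3]],
                          [[1, 1]] * 4, tracers=("t1", "t2"))
        draws = np.tile([1.0, 0.0, 0.0, 0.0], (1, 50, 1))
        res = self._degenerate(draws, ems)
        assert res.summary()["mean"].tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_flat_posterior_means_quarter_and_sum_to_one(self, rng):
        ems = _endmembers([[0, 0], [1, 1], [2, 2], [3, 3]],
                          [[1, 1]] * 4, tracers=("t1", "t2"))
        draws = rng.dirichlet(np.ones(4), size=4000)[None, :, :]
        res = self._degenerate(draws, ems)
        table = summarize_contributions(res, by="layer-5-20")
        assert table["mean"].to_numpy() == pytest.approx([0.25] * 4, abs=0.02)
        assert table["mean"].sum() == pytest.approx(1.0, abs=1e-6)
        assert (table["group"] == "layer-5-20").all()

    def test_empty_draws_undefined(self):
        ems = _endmembers([[0, 0], [1, 1]], [[1, 1]] * 2, tracers=("t1", "t2"))
        res = self._degenerate(np.empty((1, 0, 2)), ems)
        with pytest.raises(UndefinedResultError):
            res.summary()

    def test_truth_ranked_first_in_phytoplankton_dominated_mixture(self):
        """Four POM end-members with phytoplankton truth 0.6 → top-ranked source."""
        from csiaa.synthetic import default_endmembers

        ems = default_endmembers()
        idx = ems.source_names.index("phytoplankton")
        p = np.full(4, 0.4 / 3)
        p[idx] = 0.6
        obs = simulate_mixture(ems, p, 60, rng=21)
        fit = MixingModel(obs, ems).fit(seed=22, n_chains=2, n_iter=6000,
                                        n_burn=2000, thin=4)
        means = fit.summary().set_index("source")["mean"]
        assert means.idxmax() == "phytoplankton"


class TestCalibration:
    def test_simulation_based_calibration_ranks_uniform(self):
        """Rank of the true proportion in its posterior is uniform over replicates."""
        ems = _endmembers([0.0, 5.0], [1.0, 1.0])
        master = np.random.default_rng(314)
        n_draws = 200
        ranks = []
        for rep in range(200):
            p_true = master.dirichlet([1.0, 1.0])
            obs = simulate_mixture(ems, p_true, 8, rng=master)
            fit = MixingModel(obs, ems).fit(seed=int(master.integers(2**31)),
                                            n_chains=1, n_iter=1300, n_burn=500,
                                            thin=4)
            ranks.append(int(np.sum(fit.draws[:, 0] < p_true[0])))
        counts, _ = np.histogram(ranks, bins=10, range=(0, n_draws + 1))
        chi2, p = sps.chisquare(counts)
        assert p > 0.01
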