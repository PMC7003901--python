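import numpy as np
import pytest
from scipy import integrate, optimize

from spnma._engine import find_map, sample_posterior
from spnma._flatten import flatten_dataset
from spnma.data import NMADataset, StudyRecord
from spnma.inference import (
    MCMCConfig,
    SharedParameterNMA,
    SimpleORNMA,
    fit,
    rhat,
    summarize_effects,
)
from spnma.likelihoods import SHARED_DEFAULT_PRIOR

from conftest import make_arm


def two_arm_poisson_dataset(r1, r2, E=100.0):
    """Single format-3 trial, treatments 1 vs 2, one outcome: 2 parameters."""
    study = StudyRecord(
        "s", 3,
        [make_arm("s", 1, 1, {1: r1}, E=E), make_arm("s", 2, 2, {1: r2}, E=E)],
    )
    return NMADataset([study], n_treatments=2, n_outcomes=1)


class TestRhat:
    def test_identical_chains_give_one(self):
        x = np.random.default_rng(0).normal(size=1000)
        # zero between-chain variance: statistic is sqrt((n-1)/n), i.e. ~1
        assert rhat(np.stack([x, x])) == pytest.approx(1.0, abs=2e-3)
        assert rhat(np.stack([x, x])) <= 1.0

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)])
        assert rhat(chains) > 1.1

    def test_single_chain_is_an_error(self):
        with pytest.raises(ValueError):
            rhat(np.ones((1, 100)))

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(0, 1, size=(3, 500)) + np.array([[0.0], [0.3], [-0.2]])
        n = chains.shape[1]
        W = chains.var(axis=1, ddof=1).mean()
        B_over_n = chains.mean(axis=1).var(ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B_over_n) / W)
        assert rhat(chains) == pytest.approx(expected, rel=1e-12)


class TestMap:
    def test_matches_scipy_optimizer(self, mixed_format_dataset):
        flat = flatten_dataset(mixed_format_dataset, "shared", SHARED_DEFAULT_PRIOR)
        theta_map, cov = find_map(flat)
        res = optimize.minimize(
            lambda th: -flat.logpost(th),
            flat.init,
            jac=lambda th: -flat.grad_hess_logpost(th[None, None, :])[0][0, 0],
            method="BFGS",
            options={"gtol": 1e-10, "maxiter": 500},
        )
        assert np.allclose(theta_map[0], res.x, atol=1e-6)
        assert np.all(np.linalg.eigvalsh(cov[0]) > 0)


class TestSamplerAccuracy:
    def test_posterior_mean_matches_quadrature(self):
        """2-parameter posterior: exact mean by 2D quadrature as the oracle."""
        ds = two_arm_poisson_dataset(5, 4)
        flat = flatten_dataset(ds, "shared", SHARED_DEFAULT_PRIOR)

        def post(omega, h):
            return np.exp(flat.logpost(np.array([omega, h])) + 9.0)

        Z, _ = integrate.dblquad(post, -4, 4, -7, 1)
        Eh, _ = integrate.dblquad(lambda o, h: h * post(o, h), -4, 4, -7, 1)
        oracle_mean_h = Eh / Z
        res = sample_posterior(
            flat, n_chains=2, burn_in=500, samples=8000,
            rng=np.random.default_rng(3),
        )
        mc_se = res.sd[0, 1] / np.sqrt(1000)  # conservative ESS floor
        assert res.mean[0, 1] == pytest.approx(oracle_mean_h, abs=3 * mc_se)

    def test_two_kernels_agree(self, mixed_format_dataset):
        """Independence and random-walk kernels target the same posterior."""
        flat = flatten_dataset(mixed_format_dataset, "shared", SHARED_DEFAULT_PRIOR)
        res_ind = sample_posterior(
            flat, n_chains=2, burn_in=500, samples=6000,
            rng=np.random.default_rng(0), kernel="independence",
        )
        res_rwm = sample_posterior(
            flat, n_chains=2, burn_in=2000, samples=20000,
            rng=np.random.default_rng(1), kernel="rwm",
        )
        se = np.sqrt(res_ind.sd[0] ** 2 / 1000 + res_rwm.sd[0] ** 2 / 300)
        assert np.all(np.abs(res_ind.mean[0] - res_rwm.mean[0]) < 4 * se)


class TestFit:
    def test_no_effect_symmetry_with_huge_counts(self):
        ds = two_arm_poisson_dataset(10_000, 10_000, E=100_000.0)
        summary = fit(ds, model="shared", config=MCMCConfig(seed=4))
        row = summary.hr_table.iloc[0]
        assert abs(row["log_mean"]) < 0.05
        assert row["hr_q2.5"] < 1.0 < row["hr_q97.5"]
        assert summary.converged

    def test_reference_treatment_absent_from_table(self, mixed_format_dataset):
        summary = fit(mixed_format_dataset, model="shared", config=MCMCConfig(seed=5))
        effects = summary.table[summary.table["kind"] == "effect"]
        assert set(effects["treatment"]) == {2, 3}
        assert set(summary.hr_table["treatment"]) == {2, 3}
        assert summary.table["q2.5"].le(summary.table["q97.5"]).all()

    def test_simple_model_rejects_count_over_n(self):
        ds = two_arm_poisson_dataset(150, 10)
        with pytest.raises(ValueError, match="cannot describe"):
            fit(ds, model="simple", config=MCMCConfig(seed=6))

    def test_seed_reproducibility(self, mixed_format_dataset):
        a = fit(mixed_format_dataset, model="shared", config=MCMCConfig(seed=7))
        b = fit(mixed_format_dataset, model="shared", config=MCMCConfig(seed=7))
        assert np.array_equal(a.effect_draws, b.effect_draws)
        assert a.table.equals(b.table)


class TestSummarizeEffects:
    def test_degenerate_zero_draws(self):
        draws = np.zeros((2, 100, 1, 2))
        table, corr = summarize_effects(draws, treatments=[2])
        assert np.allclose(table["hr_mean"], 1.0)
        assert np.allclose(table["hr_q2.5"], 1.0)
        assert np.allclose(table["hr_q97.5"], 1.0)
        off_diag = corr[2].values[0, 1]
        assert np.isnan(off_diag)

    def test_lognormal_mean(self):
        rng = np.random.default_rng(8)
        draws = rng.normal(-0.105, 0.01, size=(2, 50_000, 1, 1))
        table, _ = summarize_effects(draws, treatments=[2])
        # lognormal mean: exp(mu + sigma^2/2)
        assert table["hr_mean"].iloc[0] == pytest.approx(
            np.exp(-0.105 + 0.5 * 0.01**2), rel=2e-4
        )

    def test_correlations_computed_per_treatment(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(2, 2000, 1, 1))
        noise = rng.normal(size=(2, 2000, 1, 1))
        draws = np.concatenate([base, 0.9 * base + 0.3 * noise], axis=3)
        _, corr = summarize_effects(draws, treatments=[2])
        assert corr[2].values[0, 1] > 0.8


class TestEstimators:
    def test_fit_sets_trailing_underscore_attributes(self, mixed_format_dataset):
        est = SharedParameterNMA(config=MCMCConfig(seed=10))
        assert est.fit(mixed_format_dataset) is est
        assert hasattr(est, "summary_") and hasattr(est, "hr_table_")
        assert est.summary_.model == "shared"

    def test_get_set_params(self):
        est = SimpleORNMA()
        cfg = MCMCConfig(seed=11)
        est.set_params(config=cfg)
        assert est.get_params()["config"] is cfg
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_seed_override(self, mixed_format_dataset):
        est = SimpleORNMA(config=MCMCConfig(seed=1))
        est.fit(mixed_format_dataset, seed=12)
        assert est.summary_.seed == 12
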