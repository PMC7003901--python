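import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spnma._flatten import flatten_dataset
from spnma.data import StudyRecord
from spnma.likelihoods import (
    ModelParams,
    PriorSpec,
    SHARED_DEFAULT_PRIOR,
    SHARED_VAGUE_PRIOR,
    SIMPLE_DEFAULT_PRIOR,
    linear_predictor,
    log_prior,
    loglik_format1,
    loglik_format2,
    loglik_format3,
    loglik_shared,
    loglik_simple,
)
from spnma.simulation import ScenarioSpec, simulate_dataset

from conftest import make_arm


def params_for(dataset, theta_fn):
    """Build ModelParams with baselines/effects filled by theta_fn(kind, i)."""
    base = np.full((len(dataset.studies), dataset.n_outcomes), np.nan)
    for i, study in enumerate(dataset.studies):
        for m in study.reported_outcomes:
            base[i, m - 1] = theta_fn("baseline", (i, m))
    eff = np.zeros((dataset.n_treatments, dataset.n_outcomes))
    for t in range(2, dataset.n_treatments + 1):
        for m in range(1, dataset.n_outcomes + 1):
            eff[t - 1, m - 1] = theta_fn("effect", (t, m))
    return ModelParams(base, eff)


class TestLinearPredictor:
    def setup_method(self):
        self.arm2 = make_arm("s", 2, 2, {1: 0}, E=100.0)

    def test_direct_substitution(self):
        params = ModelParams(np.array([[-2.0]]), np.array([[0.0], [-0.25]]))
        assert linear_predictor(params, 0, self.arm2, 1, 1) == pytest.approx(-2.25)

    def test_effects_cancel_on_baseline_arm(self):
        params = ModelParams(np.array([[-2.0]]), np.array([[0.0], [-0.25]]))
        arm = make_arm("s", 1, 2, {1: 0}, E=100.0)
        assert linear_predictor(params, 0, arm, 1, 2) == pytest.approx(-2.0)

    def test_consistency_equation_without_reference_arm(self):
        # trial comparing treatments 2 vs 3; effects are differences vs 1
        params = ModelParams(
            np.array([[-1.0]]), np.array([[0.0], [-0.25], [0.25]])
        )
        arm3 = make_arm("s", 2, 3, {1: 0}, E=100.0)
        assert linear_predictor(params, 0, arm3, 1, 2) == pytest.approx(-0.5)

    def test_unknown_indices_raise(self):
        params = ModelParams(np.array([[-1.0]]), np.array([[0.0], [0.1]]))
        with pytest.raises(IndexError):
            linear_predictor(params, 0, self.arm2, 3, 1)
        arm9 = make_arm("s", 2, 9, {1: 0}, E=100.0)
        with pytest.raises(IndexError):
            linear_predictor(params, 0, arm9, 1, 1)

    def test_reference_effects_must_be_zero(self):
        with pytest.raises(ValueError):
            ModelParams(np.array([[0.0]]), np.array([[0.3], [0.0]]))


class TestFormat1:
    def one_arm_study(self, counts):
        # two arms so the record validates; second arm checked separately
        return StudyRecord(
            "s", 1,
            [make_arm("s", 1, 1, counts, E=100.0),
             make_arm("s", 2, 2, {m: 0 for m in counts}, E=100.0)],
        )

    def test_matches_direct_factorial_pmfs(self):
        study = self.one_arm_study({1: 1, 2: 2})
        lam = np.array([[0.01, 0.02], [0.013, 0.017]])
        # independent oracle: factorial-formula Poisson and multinomial pmfs
        def log_pois(k, mu):
            return k * math.log(mu) - mu - math.log(math.factorial(k))
        def log_multi(ks, ps):
            R = sum(ks)
            coef = math.factorial(R) / np.prod([math.factorial(k) for k in ks])
            return math.log(coef) + sum(k * math.log(p) for k, p in zip(ks, ps))
        expected = 0.0
        for k in range(2):
            r = [study.arms[k].counts[1], study.arms[k].counts[2]]
            tot = lam[k].sum()
            if sum(r) > 0:
                expected += log_multi(r, lam[k] / tot)
            expected += log_pois(sum(r), 100.0 * tot)
        assert loglik_format1(study, lam) == pytest.approx(expected, abs=1e-10)
        # arm 1 alone: the worked three-event example
        first_arm_only = log_pois(3, 3.0) + log_multi([1, 2], [1 / 3, 2 / 3])
        assert first_arm_only == pytest.approx(-2.3069, abs=1e-4)

    def test_zero_counts_leave_only_poisson_zero_term(self):
        study = self.one_arm_study({1: 0, 2: 0})
        lam = np.array([[0.01, 0.02], [0.01, 0.02]])
        assert loglik_format1(study, lam) == pytest.approx(2 * -100.0 * 0.03)

    def test_factorizes_into_independent_poissons(self):
        # Poisson(R) x multinomial(split) is exactly prod Poisson(E*lambda_m):
        # the same counts scored by the format-3 block give the same value
        study1 = self.one_arm_study({1: 3, 2: 5})
        study3 = StudyRecord("s", 3, study1.arms)
        lam = np.array([[0.02, 0.055], [0.03, 0.041]])
        assert loglik_format1(study1, lam) == pytest.approx(
            loglik_format3(study3, lam), abs=1e-10
        )

    def test_nonpositive_hazard_rejected(self):
        study = self.one_arm_study({1: 1, 2: 0})
        with pytest.raises(ValueError, match="positive"):
            loglik_format1(study, np.array([[0.0, 0.1], [0.1, 0.1]]))


class TestFormat2:
    def study(self, counts_a=(10, 4), counts_b=(8, 3)):
        return StudyRecord(
            "s", 2,
            [make_arm("s", 1, 1, {1: counts_a[0], 2: counts_a[1]}, E=100.0),
             make_arm("s", 2, 2, {1: counts_b[0], 2: counts_b[1]}, E=100.0)],
        )

    def test_cloglog_cell_probability(self):
        # lambda=0.1, Tbar=1 -> p = 1 - e^-0.1 ~ 0.09516, binomial at r=10,n=100
        study = self.study()
        lam = np.full((2, 2), 0.1)
        got = loglik_format2(study, lam, mortality_outcome=None)
        p = 1.0 - math.exp(-0.1)
        assert p == pytest.approx(0.09516, abs=1e-5)
        expected = sum(
            stats.binom.logpmf(r, 100, p)
            for r in (10, 4, 8, 3)
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_all_survivors_term(self):
        study = self.study(counts_a=(0, 0), counts_b=(0, 0))
        lam = np.full((2, 2), 0.1)
        # each of four cells contributes 100*log(e^-0.1) = -10
        assert loglik_format2(study, lam, None) == pytest.approx(-40.0)

    def test_mortality_outcome_uses_poisson(self):
        study = self.study(counts_a=(10, 4), counts_b=(8, 4))
        lam = np.array([[0.1, 0.0366], [0.1, 0.0366]])
        got = loglik_format2(study, lam, mortality_outcome=2)
        p = 1.0 - math.exp(-0.1)
        expected = (
            stats.binom.logpmf(10, 100, p)
            + stats.binom.logpmf(8, 100, p)
            + stats.poisson.logpmf(4, 3.66) * 2
        )
        assert got == pytest.approx(expected, abs=1e-10)
        # oracle for the death cell: direct pmf formula
        direct = 4 * math.log(3.66) - 3.66 - math.log(math.factorial(4))
        assert stats.poisson.logpmf(4, 3.66) == pytest.approx(direct, abs=1e-12)


class TestFormat3:
    def test_direct_pmf_value(self):
        study = StudyRecord(
            "s", 3,
            [make_arm("s", 1, 1, {1: 3}, E=100.0), make_arm("s", 2, 2, {1: 0}, E=100.0)],
        )
        lam = np.array([[0.03], [0.03]])
        expected = math.log(3.0**3 * math.exp(-3.0) / 6.0) - 3.0
        assert loglik_format3(study, lam) == pytest.approx(expected, abs=1e-10)
        assert math.log(3.0**3 * math.exp(-3.0) / 6.0) == pytest.approx(-1.4959, abs=1e-4)

    @given(
        scale=st.floats(min_value=0.25, max_value=4.0),
        lam=st.floats(min_value=1e-3, max_value=0.5),
        r=st.integers(min_value=0, max_value=20),
    )
    @settings(max_examples=30, deadline=None)
    def test_poisson_mean_parameterization_invariance(self, scale, lam, r):
        """Scaling E by c and hazards by 1/c leaves the Poisson mean fixed."""
        base = StudyRecord(
            "s", 3,
            [make_arm("s", 1, 1, {1: r}, E=100.0), make_arm("s", 2, 2, {1: r}, E=100.0)],
        )
        scaled = StudyRecord(
            "s", 3,
            [make_arm("s", 1, 1, {1: r}, E=100.0 * scale),
             make_arm("s", 2, 2, {1: r}, E=100.0 * scale)],
        )
        lams = np.full((2, 1), lam)
        assert loglik_format3(base, lams) == pytest.approx(
            loglik_format3(scaled, lams / scale), rel=1e-12
        )


class TestSimpleModel:
    def test_even_odds_midpoint(self, mixed_format_dataset):
        ds = mixed_format_dataset
        params = params_for(ds, lambda kind, key: 0.0)
        got = loglik_simple(ds, params)
        expected = sum(
            stats.binom.logpmf(arm.counts[m], arm.n_randomized, 0.5)
            for s in ds.studies for arm in s.arms for m in s.reported_outcomes
        )
        assert got == pytest.approx(expected, abs=1e-10)

    def test_baseline_arm_depends_only_on_mu(self):
        study = StudyRecord(
            "s", 2,
            [make_arm("s", 1, 2, {1: 10}, E=100.0), make_arm("s", 2, 3, {1: 8}, E=100.0)],
        )
        from spnma.data import NMADataset

        ds = NMADataset([study], n_treatments=3, n_outcomes=1)
        p1 = params_for(ds, lambda k, key: -2.0 if k == "baseline" else 0.1)
        p2 = params_for(ds, lambda k, key: -2.0 if k == "baseline" else 0.1)
        # shift treatment-2 effect; the baseline arm's predictor shifts the
        # non-baseline arm only through the difference d_t - d_ref
        p2.effects[1, 0] += 0.3
        p2.effects[2, 0] += 0.3
        assert loglik_simple(ds, p1) == pytest.approx(loglik_simple(ds, p2), abs=1e-10)

    def test_count_exceeding_n_raises(self):
        study = StudyRecord(
            "s", 3,
            [make_arm("s", 1, 1, {1: 120}, E=100.0), make_arm("s", 2, 2, {1: 10}, E=100.0)],
        )
        from spnma.data import NMADataset

        ds = NMADataset([study], n_treatments=2, n_outcomes=1)
        params = params_for(ds, lambda k, key: 0.0)
        with pytest.raises(ValueError, match="cannot describe"):
            loglik_simple(ds, params)


class TestPriors:
    @pytest.mark.parametrize(
        "prior,sd",
        [
            (SHARED_DEFAULT_PRIOR, 1.4142),   # precision 0.5
            (SHARED_VAGUE_PRIOR, 4.4721),     # precision 0.05
            (SIMPLE_DEFAULT_PRIOR, 100.0),    # precision 1e-4
        ],
    )
    def test_precision_to_sd(self, prior, sd):
        assert prior.baseline_sd == pytest.approx(sd, abs=1e-3)

    def test_log_prior_excludes_reference_and_nan(self):
        base = np.array([[0.5, np.nan]])
        eff = np.array([[0.0, 0.0], [1.0, -1.0]])
        params = ModelParams(base, eff)
        got = log_prior(params, SHARED_DEFAULT_PRIOR)
        sd = SHARED_DEFAULT_PRIOR.baseline_sd
        expected = (
            stats.norm.logpdf(0.5, scale=sd)
            + stats.norm.logpdf(1.0, scale=sd)
            + stats.norm.logpdf(-1.0, scale=sd)
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_precision_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(0.0, 0.5)


class TestFlattenedAgreement:
    """The vectorized model must equal the pmf-based reference exactly."""

    @pytest.mark.parametrize("model", ["shared", "simple"])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_flat_equals_reference(self, model, seed, mixed_format_dataset):
        ds = mixed_format_dataset
        prior = SHARED_DEFAULT_PRIOR if model == "shared" else SIMPLE_DEFAULT_PRIOR
        flat = flatten_dataset(ds, model, prior)
        rng = np.random.default_rng(seed)
        theta = rng.normal(-1.5, 0.5, flat.n_params)
        lookup = {}
        for j, meta in enumerate(flat.param_meta):
            if meta["kind"] == "baseline":
                lookup[("baseline", (meta["study_index"], meta["outcome"]))] = theta[j]
            else:
                lookup[("effect", (meta["treatment"], meta["outcome"]))] = theta[j]
        params = params_for(ds, lambda k, key: lookup[(k, key)])
        if model == "shared":
            ref = loglik_shared(ds, params)
        else:
            ref = loglik_simple(ds, params)
        assert flat.loglik(theta) == pytest.approx(ref, abs=1e-9)
        assert flat.logpost(theta) == pytest.approx(
            ref + log_prior(params, prior), abs=1e-9
        )

    def test_finite_on_simulated_data(self):
        ds = simulate_dataset(
            ScenarioSpec(target_rates=(0.3, 0.1), n_sim=1), np.random.default_rng(5)
        )
        flat = flatten_dataset(ds, "shared", SHARED_DEFAULT_PRIOR)
        rng = np.random.default_rng(0)
        for _ in range(20):
            theta = rng.normal(-1.0, 1.5, flat.n_params)
            assert np.isfinite(flat.logpost(theta))
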