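"""Exact log-densities for the two NMA models.

Two fixed-effect consistency models over a connected treatment network:

* **simple odds-ratio model** — every count is treated as a number of
  patients with the event out of ``n`` randomized, ``r ~ Bin(p, n)`` with
  ``logit(p) = mu_im + d_{t,m} - d_{t1,m}``, regardless of the study's
  summary format;
* **shared-parameter hazard-ratio model** — a single per-arm hazard
  ``lambda_ikm`` with ``log lambda_ikm = omega_im + h_{t,m} - h_{t1,m}``
  feeds a different likelihood block per data format:

  - format 1 (first events, competing risks): the total event count
    ``R = sum_m r_m`` is Poisson(E·sum_m lambda_m) and the per-outcome split
    is Multinomial(lambda/sum lambda, R) — jointly this factorizes into
    independent Poisson(E·lambda_m) terms;
  - format 2 (patients with >= 1 event): ``r ~ Bin(p, n)`` with the
    complementary log-log link ``cloglog(p) = log T̄ + log lambda``; a
    designated mortality outcome, which can occur at most once per patient,
    uses Poisson(E·lambda) instead;
  - format 3 (total events, repeats included): ``r ~ Poisson(E·lambda)``.

Priors are zero-mean normals parameterized by *precision* (inverse
variance): precision 0.5 (sd ≈ 1.41) by default for both baselines and
effects of the shared model, 0.0001 (sd = 100) for the simple model, and a
vaguer 0.05 (sd ≈ 4.47) variant used to probe prior influence at rare event
rates.  Reference-treatment effects are constrained to zero and carry no
prior mass.

Functions here are the clear, study-at-a-time reference implementations used
by tests and small fits; :mod:`spnma._flatten` provides the equivalent
vectorized form the sampler runs on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

from .data import ArmRecord, NMADataset, StudyRecord, exposure

__all__ = [
    "ModelParams",
    "PriorSpec",
    "SHARED_DEFAULT_PRIOR",
    "SHARED_VAGUE_PRIOR",
    "SIMPLE_DEFAULT_PRIOR",
    "linear_predictor",
    "study_hazards",
    "loglik_format1",
    "loglik_format2",
    "loglik_format3",
    "loglik_shared",
    "loglik_simple",
    "log_prior",
]


@dataclass
class ModelParams:
    """Parameter point for either model.

    ``baselines[i, m-1]`` is the study-level nuisance parameter for study
    ``i`` (0-based position) and outcome ``m`` (omega for the shared model,
    mu for the simple model); entries for outcomes a study does not report
    may be NaN and are ignored.  ``effects[t-1, m-1]`` is the relative effect
    of treatment ``t`` versus treatment 1 (h = log hazard ratio, d = log odds
    ratio); the first row is the reference constraint and must be zero.
    """

    baselines: np.ndarray
    effects: np.ndarray

    def __post_init__(self):
        self.baselines = np.asarray(self.baselines, dtype=float)
        self.effects = np.asarray(self.effects, dtype=float)
        if not np.all(self.effects[0] == 0.0):
            raise ValueError("reference-treatment effects must be zero (h_1m = 0)")


@dataclass(frozen=True)
class PriorSpec:
    """Zero-mean normal priors, parameterized by precision (1/variance)."""

    baseline_precision: float
    effect_precision: float

    def __post_init__(self):
        if self.baseline_precision <= 0 or self.effect_precision <= 0:
            raise ValueError("precisions must be positive")

    @property
    def baseline_sd(self) -> float:
        return self.baseline_precision ** -0.5

    @property
    def effect_sd(self) -> float:
        return self.effect_precision ** -0.5


SHARED_DEFAULT_PRIOR = PriorSpec(0.5, 0.5)
SHARED_VAGUE_PRIOR = PriorSpec(0.05, 0.05)
SIMPLE_DEFAULT_PRIOR = PriorSpec(1e-4, 1e-4)


def linear_predictor(
    params: ModelParams,
    study_index: int,
    arm: ArmRecord,
    outcome: int,
    study_reference_treatment: int,
) -> float:
    """Consistency-equation linear predictor for one arm and outcome.

    Returns ``baseline[i,m] + effect[t_ik, m] - effect[t_i1, m]`` — the log
    hazard under the shared model or the log odds under the simple model.
    The subtraction of the study-baseline effect is what lets trials with no
    reference-treatment arm (for example a 2-vs-3 comparison) contribute.
    """
    n_treat, n_out = params.effects.shape
    if not (1 <= outcome <= n_out):
        raise IndexError(f"outcome {outcome} out of range 1..{n_out}")
    for t in (arm.treatment, study_reference_treatment):
        if not (1 <= t <= n_treat):
            raise IndexError(f"treatment {t} out of range 1..{n_treat}")
    m = outcome - 1
    return float(
        params.baselines[study_index, m]
        + params.effects[arm.treatment - 1, m]
        - params.effects[study_reference_treatment - 1, m]
    )


def study_hazards(
    params: ModelParams, study_index: int, study: StudyRecord
) -> np.ndarray:
    """Arm x reported-outcome hazard (or odds) matrix implied by the params.

    Columns follow ``sorted(study.reported_outcomes)``.
    """
    ref = study.baseline_treatment
    rows = []
    for arm in study.arms:
        rows.append(
            [
                np.exp(linear_predictor(params, study_index, arm, m, ref))
                for m in study.reported_outcomes
            ]
        )
    return np.asarray(rows)


def _check_hazards(hazards: np.ndarray, study: StudyRecord) -> np.ndarray:
    hazards = np.asarray(hazards, dtype=float)
    expected = (len(study.arms), len(study.reported_outcomes))
    if hazards.shape != expected:
        raise ValueError(f"hazards shape {hazards.shape} != arm x outcome {expected}")
    if np.any(hazards <= 0) or not np.all(np.isfinite(hazards)):
        raise ValueError("hazards must be strictly positive and finite")
    return hazards


def loglik_format1(study: StudyRecord, hazards: np.ndarray) -> float:
    """Competing-risks block: Poisson total + multinomial first-event split.

    ``hazards[k, j]`` is lambda for arm ``k`` and the j-th reported outcome.
    """
    if study.data_format != 1:
        raise ValueError(f"study {study.study_id!r} is not format 1")
    hazards = _check_hazards(hazards, study)
    total = 0.0
    for k, arm in enumerate(study.arms):
        r = np.array([arm.counts[m] for m in study.reported_outcomes])
        R = int(r.sum())
        lam = hazards[k]
        E = exposure(arm)
        rate = E * lam.sum()
        total += stats.poisson.logpmf(R, rate)
        if R > 0:
            total += stats.multinomial.logpmf(r, n=R, p=lam / lam.sum())
    return float(total)


def loglik_format2(
    study: StudyRecord,
    hazards: np.ndarray,
    mortality_outcome: int | None = None,
) -> float:
    """Patients-with-event block: binomial with cloglog link; Poisson death.

    ``p = 1 - exp(-lambda * T̄)`` is the probability of at least one event
    over the mean follow-up.  The mortality outcome, if designated, is a
    once-only event and keeps the Poisson(E·lambda) form.
    """
    if study.data_format != 2:
        raise ValueError(f"study {study.study_id!r} is not format 2")
    hazards = _check_hazards(hazards, study)
    total = 0.0
    for k, arm in enumerate(study.arms):
        tbar = exposure(arm) / arm.n_randomized
        for j, m in enumerate(study.reported_outcomes):
            r, lam = arm.counts[m], hazards[k, j]
            if m == mortality_outcome:
                total += stats.poisson.logpmf(r, exposure(arm) * lam)
            else:
                p = -np.expm1(-lam * tbar)
                total += stats.binom.logpmf(r, arm.n_randomized, p)
    return float(total)


def loglik_format3(study: StudyRecord, hazards: np.ndarray) -> float:
    """Total-events block: independent Poisson(E·lambda) per outcome."""
    if study.data_format != 3:
        raise ValueError(f"study {study.study_id!r} is not format 3")
    hazards = _check_hazards(hazards, study)
    total = 0.0
    for k, arm in enumerate(study.arms):
        for j, m in enumerate(study.reported_outcomes):
            total += stats.poisson.logpmf(arm.counts[m], exposure(arm) * hazards[k, j])
    return float(total)


def loglik_shared(
    dataset: NMADataset, params: ModelParams, mortality_outcome: int | None = None
) -> float:
    """Shared-parameter model log-likelihood over the whole evidence base."""
    if mortality_outcome is None:
        mortality_outcome = dataset.mortality_outcome
    total = 0.0
    for i, study in enumerate(dataset.studies):
        hazards = study_hazards(params, i, study)
        if study.data_format == 1:
            total += loglik_format1(study, hazards)
        elif study.data_format == 2:
            total += loglik_format2(study, hazards, mortality_outcome)
        else:
            total += loglik_format3(study, hazards)
    return total


def loglik_simple(dataset: NMADataset, params: ModelParams) -> float:
    """Simple model log-likelihood: binomial/logit, formats ignored.

    Raises on any count exceeding its denominator — possible for format-3
    data at high event rates, where the simple model is simply inapplicable;
    the condition is surfaced, never clipped.
    """
    total = 0.0
    for i, study in enumerate(dataset.studies):
        ref = study.baseline_treatment
        for arm in study.arms:
            for m in study.reported_outcomes:
                r = arm.counts[m]
                if r > arm.n_randomized:
                    raise ValueError(
                        f"study {study.study_id!r}, arm {arm.arm_index}, "
                        f"outcome {m}: count {r} > n = {arm.n_randomized}; "
                        "the simple binomial model cannot describe these data"
                    )
                p = expit(linear_predictor(params, i, arm, m, ref))
                total += stats.binom.logpmf(r, arm.n_randomized, p)
    return float(total)


def log_prior(params: ModelParams, prior: PriorSpec) -> float:
    """Sum of normal log-densities over baselines and non-reference effects.

    NaN baseline entries (outcomes a study never reports) and the zero
    reference row of ``effects`` contribute nothing.
    """
    base = params.baselines[np.isfinite(params.baselines)]
    eff = params.effects[1:].ravel()
    return float(
        stats.norm.logpdf(base, scale=prior.baseline_sd).sum()
        + stats.norm.logpdf(eff, scale=prior.effect_sd).sum()
    )
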