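"""Posterior sampling, convergence diagnostics and effect summarization.

Point estimates are posterior *means*; intervals are equal-tailed 95%
credible intervals (2.5/97.5 posterior quantiles).  Relative effects are
reported on the ratio scale as summaries of ``exp(draws)`` — the mean of the
exponentiated draws, never the exponential of the mean.  Convergence is
assessed per parameter with the Brooks-Gelman-Rubin potential scale
reduction statistic across chains; a fit with any statistic above the
threshold is flagged, never silently re-run.

The default chain protocol reflects the high statistical efficiency of the
independence-type sampler in :mod:`spnma._engine` (a few thousand
near-independent draws); :data:`BUGS_ANALYSIS_PRESET` and
:data:`BUGS_SIMULATION_PRESET` provide the long random-walk protocols
(2 chains, 60k/30k and 30k/10k burn-in/sampling iterations) matching how
such models have traditionally been run under generic Gibbs/Metropolis
software, for compatibility experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _engine
from ._flatten import flatten_dataset
from .data import NMADataset
from .likelihoods import (
    PriorSpec,
    SHARED_DEFAULT_PRIOR,
    SIMPLE_DEFAULT_PRIOR,
)

__all__ = [
    "MCMCConfig",
    "PosteriorSummary",
    "BUGS_ANALYSIS_PRESET",
    "BUGS_SIMULATION_PRESET",
    "fit",
    "rhat",
    "summarize_effects",
    "SharedParameterNMA",
    "SimpleORNMA",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Sampling protocol.  ``seed`` is mandatory: every run is reproducible."""

    seed: int
    n_chains: int = 2
    burn_in: int = 500
    samples: int = 4000
    rhat_threshold: float = 1.05
    kernel: str = "independence"
    proposal_df: float = 8.0
    proposal_scale: float = 1.0

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if self.burn_in <= 0 or self.samples <= 0:
            raise ValueError("burn_in and samples must be positive")


#: iteration counts of the traditional Gibbs-software protocol for full
#: data analyses (2 chains, 60k burn-in / 30k sampling) — random-walk kernel
BUGS_ANALYSIS_PRESET = dict(
    n_chains=2, burn_in=60_000, samples=30_000, kernel="rwm"
)
#: the lighter protocol used for simulation replicates (30k/10k)
BUGS_SIMULATION_PRESET = dict(
    n_chains=2, burn_in=30_000, samples=10_000, kernel="rwm"
)


@dataclass
class PosteriorSummary:
    """Per-parameter posterior table plus ratio-scale effect summaries.

    ``table`` has one row per model parameter (baselines and non-reference
    effects) with columns parameter, kind, study_id, treatment, outcome,
    mean, sd, q2.5, q97.5, rhat.  ``hr_table`` summarizes exp(effect draws)
    per (treatment, outcome) — hazard ratios for the shared model, odds
    ratios for the simple one.  ``effect_correlations`` maps each treatment
    to the outcome-by-outcome correlation matrix of its effect draws.
    """

    model: str
    table: pd.DataFrame
    hr_table: pd.DataFrame
    effect_correlations: dict[int, pd.DataFrame]
    converged: bool
    max_rhat: float
    accept_rate: float
    seed: int
    effect_draws: np.ndarray = field(repr=False, default=None)
    effect_treatments: list[int] = field(default_factory=list)
    n_outcomes: int = 0


def rhat(chain_draws) -> float:
    """Brooks-Gelman-Rubin potential scale reduction for one parameter.

    ``chain_draws`` is an (n_chains, n_iterations) array; at least two
    chains of equal length are required.  Values near 1 indicate that the
    between-chain variance is negligible relative to within-chain variance.
    """
    draws = np.asarray(chain_draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    n = draws.shape[1]
    mean_c = draws.mean(axis=1)[:, None]
    var_c = draws.var(axis=1, ddof=1)[:, None]
    return float(_engine._rhat_from_moments(mean_c, var_c, n)[0])


def summarize_effects(
    effect_draws: np.ndarray,
    treatments: list[int],
    outcomes: list[int] | None = None,
    reference_label: int | str = 1,
) -> tuple[pd.DataFrame, dict[int, pd.DataFrame]]:
    """Ratio-scale summaries and cross-outcome correlations of effect draws.

    ``effect_draws`` is (n_chains, n_draws, n_treatments-1, n_outcomes),
    holding log hazard (or odds) ratios versus the reference treatment.
    Returns the per-(treatment, outcome) table of exp-draw means and 95%
    credible intervals, and per-treatment correlation matrices across
    outcomes.  Constant draws make correlations undefined; they are reported
    as NaN (degenerate), never invented.
    """
    draws = np.asarray(effect_draws, dtype=float)
    C, S, T1, M = draws.shape
    outcomes = outcomes or list(range(1, M + 1))
    flat = draws.reshape(C * S, T1, M)
    ratio = np.exp(flat)
    rows = []
    for it, t in enumerate(treatments):
        for im, m in enumerate(outcomes):
            rows.append(
                {
                    "treatment": t,
                    "outcome": m,
                    "reference": reference_label,
                    "hr_mean": ratio[:, it, im].mean(),
                    "hr_q2.5": np.quantile(ratio[:, it, im], 0.025),
                    "hr_q97.5": np.quantile(ratio[:, it, im], 0.975),
                    "log_mean": flat[:, it, im].mean(),
                    "log_q2.5": np.quantile(flat[:, it, im], 0.025),
                    "log_q97.5": np.quantile(flat[:, it, im], 0.975),
                }
            )
    hr_table = pd.DataFrame(rows)
    correlations = {}
    for it, t in enumerate(treatments):
        sub = flat[:, it, :]
        sds = sub.std(axis=0)
        if np.any(sds == 0):
            corr = np.full((M, M), np.nan)
            np.fill_diagonal(corr, 1.0)
        else:
            corr = np.corrcoef(sub, rowvar=False).reshape(M, M)
        correlations[t] = pd.DataFrame(corr, index=outcomes, columns=outcomes)
    return hr_table, correlations


def fit(
    dataset: NMADataset,
    model: str = "shared",
    prior: PriorSpec | None = None,
    config: MCMCConfig | None = None,
) -> PosteriorSummary:
    """Sample the posterior of one model on one dataset and summarize it.

    ``model`` is ``"shared"`` (hazard-ratio, format-specific likelihood
    blocks) or ``"simple"`` (binomial/logit, formats ignored).
    """
    if config is None:
        raise ValueError("an MCMCConfig with an explicit seed is required")
    if prior is None:
        prior = SHARED_DEFAULT_PRIOR if model == "shared" else SIMPLE_DEFAULT_PRIOR
    dataset.validate()
    flat = flatten_dataset(dataset, model, prior)
    rng = np.random.default_rng(config.seed)
    res = _engine.sample_posterior(
        flat,
        n_chains=config.n_chains,
        burn_in=config.burn_in,
        samples=config.samples,
        rng=rng,
        keep_idx=None,
        kernel=config.kernel,
        proposal_df=config.proposal_df,
        proposal_scale=config.proposal_scale,
    )
    draws = res.draws[0].astype(float)  # (C, S, P)
    q = np.quantile(draws.reshape(-1, flat.n_params), [0.025, 0.975], axis=0)
    base_sym, eff_sym = ("omega", "h") if model == "shared" else ("mu", "d")
    rows = []
    for j, meta in enumerate(flat.param_meta):
        if meta["kind"] == "baseline":
            name = f"{base_sym}[{meta['study_id']},{meta['outcome']}]"
        else:
            name = f"{eff_sym}[{meta['treatment']},{meta['outcome']}]"
        rows.append(
            {
                "parameter": name,
                "kind": meta["kind"],
                "study_id": meta["study_id"],
                "treatment": meta["treatment"],
                "outcome": meta["outcome"],
                "mean": res.mean[0, j],
                "sd": res.sd[0, j],
                "q2.5": q[0, j],
                "q97.5": q[1, j],
                "rhat": res.rhat[0, j],
            }
        )
    table = pd.DataFrame(rows)

    treatments = list(range(2, dataset.n_treatments + 1))
    M = dataset.n_outcomes
    eff_cols = [flat.effect_index[(t, m)] for t in treatments for m in range(1, M + 1)]
    effect_draws = draws[:, :, eff_cols].reshape(
        config.n_chains, config.samples, len(treatments), M
    )
    outcome_ids = list(range(1, M + 1))
    hr_table, correlations = summarize_effects(effect_draws, treatments, outcome_ids)
    if dataset.outcome_labels:
        hr_table["outcome_label"] = hr_table["outcome"].map(
            lambda m: dataset.outcome_labels[m - 1]
        )
    max_rhat = float(np.nanmax(table["rhat"])) if len(table) else 1.0
    converged = max_rhat <= config.rhat_threshold
    if not converged:
        warnings.warn(
            f"{model} model fit flagged non-converged: max rhat {max_rhat:.3f} "
            f"> {config.rhat_threshold}",
            RuntimeWarning,
            stacklevel=2,
        )
    return PosteriorSummary(
        model=model,
        table=table,
        hr_table=hr_table,
        effect_correlations=correlations,
        converged=converged,
        max_rhat=max_rhat,
        accept_rate=float(res.accept_rate.mean()),
        seed=config.seed,
        effect_draws=effect_draws,
        effect_treatments=treatments,
        n_outcomes=M,
    )


class _BaseNMA:
    """Estimator-style wrapper: configure once, ``fit`` per dataset.

    Follows the fit-then-inspect idiom: fitted results live in trailing-
    underscore attributes (``summary_``, ``hr_table_``, ``converged_``).
    """

    _model: str

    def __init__(self, prior: PriorSpec | None = None, config: MCMCConfig | None = None):
        self.prior = prior
        self.config = config

    def get_params(self) -> dict:
        return {"prior": self.prior, "config": self.config}

    def set_params(self, **params) -> "_BaseNMA":
        for key, value in params.items():
            if key not in ("prior", "config"):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, dataset: NMADataset, seed: int | None = None) -> "_BaseNMA":
        config = self.config
        if config is None and seed is not None:
            config = MCMCConfig(seed=seed)
        elif config is not None and seed is not None:
            config = replace(config, seed=seed)
        self.summary_ = fit(dataset, model=self._model, prior=self.prior, config=config)
        self.hr_table_ = self.summary_.hr_table
        self.converged_ = self.summary_.converged
        self.effect_correlations_ = self.summary_.effect_correlations
        return self


class SharedParameterNMA(_BaseNMA):
    """Shared-parameter hazard-ratio NMA with format-specific likelihoods."""

    _model = "shared"


class SimpleORNMA(_BaseNMA):
    """Simple odds-ratio NMA: binomial/logit on every count, formats ignored."""

    _model = "simple"
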