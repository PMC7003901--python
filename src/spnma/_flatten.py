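"""Vectorized (design-matrix) form of the two NMA models.

Every likelihood contribution is a "cell": one (study, arm, outcome) triple
with a count ``r``, a denominator ``n``, an offset, and a one-row linear map
from the parameter vector to the cell's linear predictor eta.  Three
exponential-family forms cover both models:

====  =====================  ===============================  ===========
code  family                 log-likelihood kernel in eta     offset
====  =====================  ===============================  ===========
0     Poisson, log link      r*(eta+o) - e^(eta+o)            log E
1     binomial, cloglog      r*log p - (n-r)*e^(eta+o),       log T̄
                             p = 1 - exp(-e^(eta+o))
2     binomial, logit        r*eta - n*log(1+e^eta)           0
====  =====================  ===============================  ===========

The format-1 competing-risks block (Poisson total + multinomial first-event
split) factorizes exactly into independent Poisson cells, so code 0 covers
formats 1 and 3 and the format-2 mortality outcome.  Count-dependent
constants (log r!, binomial coefficients, the r*log E part of the Poisson
pmf) are precomputed so the flattened log-likelihood equals the reference
pmf-based one to machine precision.

Parameter order: all baselines (one per reported (study, outcome) pair, in
study-major order), then effects for treatments 2..T, outcome-major within
treatment.  Reference-treatment effects are not parameters at all.

Batch convention: a single dataset stores ``r``/``offset`` as (ncells,) and
``const`` as a scalar; a stacked batch of B replicates stores them as
(B, 1, ncells) / (B, 1) so they broadcast against parameter arrays of shape
(B, C, P) for C chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from .data import NMADataset, exposure
from .likelihoods import PriorSpec

POISSON, CLOGLOG, LOGIT = 0, 1, 2


@dataclass
class FlatModel:
    """Flattened model: data arrays plus the cells-by-parameters design map."""

    X: np.ndarray           # (ncells, P), shared across any batch
    family: np.ndarray      # (ncells,) int codes
    offset: np.ndarray      # (ncells,) or (B, 1, ncells)
    r: np.ndarray           # (ncells,) or (B, 1, ncells)
    n: np.ndarray           # (ncells,)
    prior_prec: np.ndarray  # (P,)
    const: np.ndarray       # scalar or (B, 1): count-dependent constants
    init: np.ndarray        # (P,) or (B, P): data-driven starting point
    param_meta: list = field(default_factory=list)   # one dict per parameter
    effect_index: dict = field(default_factory=dict)  # (treatment, outcome) -> col

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def loglik(self, theta: np.ndarray) -> np.ndarray:
        """Exact log-likelihood for theta of shape (..., P).

        Leading dims of theta must broadcast against those of ``r``.
        """
        eta = theta @ self.X.T
        return self._cell_ll(eta).sum(axis=-1) + self.const

    def logpost(self, theta: np.ndarray) -> np.ndarray:
        prior = -0.5 * (self.prior_prec * theta * theta).sum(axis=-1)
        prior += 0.5 * np.log(self.prior_prec / (2.0 * np.pi)).sum()
        return self.loglik(theta) + prior

    def _cell_ll(self, eta: np.ndarray) -> np.ndarray:
        r, n, fam = self.r, self.n, self.family
        z = eta + self.offset
        out = np.zeros(np.broadcast_shapes(eta.shape, np.shape(r)), dtype=float)
        pois = fam == POISSON
        if pois.any():
            zp = z[..., pois]
            out[..., pois] = np.asarray(r)[..., pois] * zp - np.exp(zp)
        clog = fam == CLOGLOG
        if clog.any():
            u = np.exp(z[..., clog])  # cumulative hazard over mean follow-up
            rc = np.asarray(r)[..., clog]
            out[..., clog] = rc * np.log(-np.expm1(-u)) - (n[clog] - rc) * u
        logit = fam == LOGIT
        if logit.any():
            el = eta[..., logit]
            out[..., logit] = (
                np.asarray(r)[..., logit] * el - n[logit] * np.logaddexp(0.0, el)
            )
        return out

    def _cell_grad_hess(self, eta: np.ndarray):
        """d(ll)/d(eta) and d2(ll)/d(eta)2 per cell, shaped like eta."""
        r = np.broadcast_to(self.r, eta.shape)
        n, fam = self.n, self.family
        g = np.empty_like(eta)
        w = np.empty_like(eta)
        z = eta + self.offset
        pois = fam == POISSON
        if pois.any():
            mu = np.exp(z[..., pois])
            g[..., pois] = r[..., pois] - mu
            w[..., pois] = -mu
        clog = fam == CLOGLOG
        if clog.any():
            u = np.exp(z[..., clog])
            emu = np.exp(-u)
            p = -np.expm1(-u)
            rc = r[..., clog]
            nc = n[clog]
            g[..., clog] = rc * u * emu / p - (nc - rc) * u
            dratio_du = emu * (1.0 - u) / p - u * emu * emu / (p * p)
            w[..., clog] = u * (rc * dratio_du - (nc - rc))
        logit = fam == LOGIT
        if logit.any():
            pl = expit(eta[..., logit])
            g[..., logit] = r[..., logit] - n[logit] * pl
            w[..., logit] = -n[logit] * pl * (1.0 - pl)
        return g, w

    def grad_hess_logpost(self, theta: np.ndarray):
        """Gradient (..., P) and Hessian (..., P, P) of the log-posterior.

        The log-posterior is strictly concave (all three families are
        log-concave in eta, the priors are Gaussian), so the Hessian is
        negative definite everywhere.
        """
        eta = theta @ self.X.T
        g, w = self._cell_grad_hess(eta)
        grad = g @ self.X - self.prior_prec * theta
        hess = np.einsum("...c,ci,cj->...ij", w, self.X, self.X)
        hess -= np.diag(self.prior_prec)
        return grad, hess


def flatten_dataset(dataset: NMADataset, model: str, prior: PriorSpec) -> FlatModel:
    """Build the flat representation of ``dataset`` for one model.

    ``model`` is ``"shared"`` (hazard-ratio, format-specific blocks) or
    ``"simple"`` (binomial/logit everywhere, formats deliberately ignored).
    """
    if model not in ("shared", "simple"):
        raise ValueError(f"unknown model {model!r}")

    param_meta: list[dict] = []
    baseline_cols: dict[tuple[str, int], int] = {}
    for i, study in enumerate(dataset.studies):
        for m in study.reported_outcomes:
            baseline_cols[(study.study_id, m)] = len(param_meta)
            param_meta.append(
                {"kind": "baseline", "study_id": study.study_id,
                 "study_index": i, "outcome": m, "treatment": None}
            )
    effect_index: dict[tuple[int, int], int] = {}
    for t in range(2, dataset.n_treatments + 1):
        for m in range(1, dataset.n_outcomes + 1):
            effect_index[(t, m)] = len(param_meta)
            param_meta.append(
                {"kind": "effect", "study_id": None,
                 "study_index": None, "outcome": m, "treatment": t}
            )
    P = len(param_meta)

    rows, fams, offs, rs, ns, consts = [], [], [], [], [], []
    events = np.zeros(P)  # per-baseline event / exposure totals for the init
    expos = np.zeros(P)
    for study in dataset.studies:
        ref = study.baseline_treatment
        for arm in study.arms:
            E = exposure(arm)
            if E <= 0:
                raise ValueError(
                    f"study {study.study_id!r}, arm {arm.arm_index}: "
                    "positive exposure required"
                )
            tbar = E / arm.n_randomized
            for m in study.reported_outcomes:
                r = arm.counts[m]
                x = np.zeros(P)
                b = baseline_cols[(study.study_id, m)]
                x[b] = 1.0
                if arm.treatment != 1:
                    x[effect_index[(arm.treatment, m)]] += 1.0
                if ref != 1:
                    x[effect_index[(ref, m)]] -= 1.0
                if model == "simple":
                    if r > arm.n_randomized:
                        raise ValueError(
                            f"study {study.study_id!r}, arm {arm.arm_index}, "
                            f"outcome {m}: count {r} > n = {arm.n_randomized}; "
                            "the simple binomial model cannot describe these data"
                        )
                    fam, off, const = LOGIT, 0.0, _log_choose(arm.n_randomized, r)
                elif study.data_format == 2 and m != dataset.mortality_outcome:
                    fam, off = CLOGLOG, np.log(tbar)
                    const = _log_choose(arm.n_randomized, r)
                else:
                    # formats 1 and 3, and format-2 mortality: Poisson(E*lambda);
                    # the kernel uses r*(eta+log E), so r*log E is already in it
                    fam, off, const = POISSON, np.log(E), -float(gammaln(r + 1.0))
                rows.append(x)
                fams.append(fam)
                offs.append(off)
                rs.append(float(r))
                ns.append(float(arm.n_randomized))
                consts.append(const)
                events[b] += r
                expos[b] += arm.n_randomized if model == "simple" else E

    prior_prec = np.array(
        [
            prior.baseline_precision if meta["kind"] == "baseline"
            else prior.effect_precision
            for meta in param_meta
        ]
    )

    # empirical crude-rate starting values (0.5-event continuity); effects 0
    init = np.zeros(P)
    for j, meta in enumerate(param_meta):
        if meta["kind"] == "baseline":
            if model == "simple":
                p = (events[j] + 0.5) / (expos[j] + 1.0)
                init[j] = np.log(p / (1.0 - p))
            else:
                init[j] = np.log((events[j] + 0.5) / expos[j])

    return FlatModel(
        X=np.asarray(rows),
        family=np.asarray(fams, dtype=np.int8),
        offset=np.asarray(offs),
        r=np.asarray(rs),
        n=np.asarray(ns),
        prior_prec=prior_prec,
        const=np.float64(sum(consts)),
        init=init,
        param_meta=param_meta,
        effect_index=effect_index,
    )


def stack_flat_models(models: list[FlatModel]) -> FlatModel:
    """Stack replicates sharing one design matrix into a batched FlatModel."""
    first = models[0]
    for fm in models[1:]:
        if fm.X.shape != first.X.shape or not np.array_equal(fm.X, first.X):
            raise ValueError("replicates do not share a design matrix")
    return FlatModel(
        X=first.X,
        family=first.family,
        offset=np.stack([np.asarray(fm.offset) for fm in models])[:, None, :],
        r=np.stack([np.asarray(fm.r) for fm in models])[:, None, :],
        n=first.n,
        prior_prec=first.prior_prec,
        const=np.array([float(fm.const) for fm in models])[:, None],
        init=np.stack([fm.init for fm in models]),
        param_meta=first.param_meta,
        effect_index=first.effect_index,
    )


def _log_choose(n, r):
    return float(gammaln(n + 1.0) - gammaln(r + 1.0) - gammaln(n - r + 1.0))
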