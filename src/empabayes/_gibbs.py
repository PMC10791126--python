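"""Blocked Gibbs sampler for hierarchical Gaussian regression with censoring.

The sampler targets the posterior of the model

    y*_n     = x_n' beta + z_n' b_{s(n)} + eps_n,   eps_n ~ N(0, sigma_{s(n)}^2)
    y_n      = y*_n clamped to [low, high] with known censoring indicators
    b_i      ~ MVN(0, diag(tau) C diag(tau)),       i = 1..S subjects
    beta_j   ~ N(0, beta_scale_j^2)
    tau_k    ~ HalfNormal(re_sd_scale)
    C        ~ LKJ(concentration)
    sigma_i  ~ HalfNormal(sigma_scale)

Interval-censored observations are handled by data augmentation: each
censored y* is redrawn from its truncated-normal full conditional, after
which every other update is exactly conjugate (beta, b) or a cheap
Metropolis-within-Gibbs step on an unbounded scale (log sigma, log tau,
correlation entries) with Robbins-Monro step-size adaptation during
warmup. Augmentation and the direct tail-probability likelihood define the
identical posterior; the latter is exposed in
:func:`empabayes.censored_model.censored_loglik` and drives the emcee
cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class GibbsSpec:
    """Design and prior information consumed by the sampler.

    X : (n, p) fixed-effect design; Z : (n, q) random-effect design;
    subject : (n,) integer subject index in 0..S-1; y, censored as data.
    ``censored`` holds 0 (interior), -1 (at the lower bound) or +1 (at
    the upper bound).
    """

    X: np.ndarray
    Z: np.ndarray
    subject: np.ndarray
    y: np.ndarray
    censored: np.ndarray
    low: float
    high: float
    beta_scale: np.ndarray  # (p,) prior SDs of the fixed effects
    re_sd_scale: float
    sigma_scale: float
    lkj_eta: float = 2.0


@dataclass
class GibbsDraws:
    """Raw per-chain output arrays, stacked as (chains, draws, ...)."""

    beta: np.ndarray        # (c, d, p)
    b: np.ndarray           # (c, d, S, q)
    tau: np.ndarray         # (c, d, q)
    corr: np.ndarray        # (c, d, q, q)
    sigma: np.ndarray       # (c, d, S)
    accept: dict[str, float] = field(default_factory=dict)


def _draw_censored(
    rng: np.random.Generator,
    mu: np.ndarray,
    sd: np.ndarray,
    bound: np.ndarray,
    side: np.ndarray,
) -> np.ndarray:
    """Truncated-normal draws of latent y* for censored observations.

    side=-1: y* lies below ``bound`` (observation clamped at the low end);
    side=+1: y* lies above ``bound``.
    """
    z = (bound - mu) / sd
    u = rng.uniform(size=mu.shape)
    p = ndtr(z)
    below = side < 0
    # Uniform on (0, Phi(z)) for the lower tail, (Phi(z), 1) for the upper.
    q = np.where(below, u * p, p + u * (1.0 - p))
    # Guard the extreme tails where Phi underflows.
    q = np.clip(q, 1e-300, 1.0 - 1e-16)
    draws = mu + sd * ndtri(q)
    return np.where(below, np.minimum(draws, bound), np.maximum(draws, bound))


def _lkj_logpdf(C: np.ndarray, eta: float) -> float:
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        return -np.inf
    return (eta - 1.0) * logdet


def _mvn_b_loglik(b: np.ndarray, tau: np.ndarray, C: np.ndarray) -> float:
    """Sum over subjects of log MVN(b_i; 0, diag(tau) C diag(tau))."""
    S, q = b.shape
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return -np.inf
    scaled = b / tau  # (S, q)
    sol = np.linalg.solve(L, scaled.T)  # (q, S)
    quad = float(np.sum(sol**2))
    logdet = 2.0 * float(np.sum(np.log(np.diag(L)))) + 2.0 * float(np.sum(np.log(tau)))
    return -0.5 * (S * q * _LOG_2PI + S * logdet + quad)


def _halfnormal_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    return np.where(x > 0, -0.5 * (x / scale) ** 2, -np.inf)


class _StepSize:
    """Robbins-Monro adaptation of a log step size toward a target rate."""

    def __init__(self, init: float, target: float):
        self.log_s = np.log(init)
        self.target = target
        self.t = 0

    def update(self, accepted: float) -> None:
        self.t += 1
        self.log_s += (accepted - self.target) / np.sqrt(self.t + 10.0)

    @property
    def value(self) -> float:
        return float(np.exp(self.log_s))


def _run_chain(
    spec: GibbsSpec,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
) -> GibbsDraws:
    X, Z, subj, y = spec.X, spec.Z, spec.subject, spec.y.astype(float).copy()
    cens = spec.censored
    n, p = X.shape
    q = Z.shape[1]
    S = int(subj.max()) + 1

    subj_rows = [np.flatnonzero(subj == i) for i in range(S)]
    ZtZ = [Z[r].T @ Z[r] for r in subj_rows]
    XtX = [X[r].T @ X[r] for r in subj_rows]
    XtZ = [X[r].T @ Z[r] for r in subj_rows]
    cens_idx = np.flatnonzero(cens != 0)
    cens_side = cens[cens_idx].astype(float)
    cens_bound = np.where(cens_side < 0, spec.low, spec.high)

    # Initial state: least-squares beta, unit-ish scales.
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    b = np.zeros((S, q))
    tau = np.full(q, max(spec.re_sd_scale / 4.0, 1e-3))
    C = np.eye(q)
    resid0 = y - X @ beta
    sse = np.bincount(subj, weights=resid0**2, minlength=S)
    cnt = np.bincount(subj, minlength=S).astype(float)
    sigma = np.sqrt(np.maximum(sse / np.maximum(cnt, 1.0), 1e-2))
    ystar = y.copy()

    prior_prec_beta = 1.0 / spec.beta_scale**2

    step_sigma = _StepSize(0.3, 0.44)
    step_tau = _StepSize(0.2, 0.23)
    step_corr = _StepSize(0.1, 0.23)
    acc = {"sigma": 0.0, "tau": 0.0, "corr": 0.0}

    out_beta = np.empty((n_draws, p))
    out_b = np.empty((n_draws, S, q))
    out_tau = np.empty((n_draws, q))
    out_corr = np.empty((n_draws, q, q))
    out_sigma = np.empty((n_draws, S))

    offdiag = [(i, j) for i in range(q) for j in range(i + 1, q)]

    total = n_warmup + n_draws
    for it in range(total):
        sigma_n = sigma[subj]
        mu = X @ beta + np.einsum("nq,nq->n", Z, b[subj])

        # --- latent y* for censored observations -------------------------
        if cens_idx.size:
            ystar[cens_idx] = _draw_censored(
                rng, mu[cens_idx], sigma_n[cens_idx], cens_bound, cens_side
            )

        # --- beta | y*, variances (random effects integrated out) --------
        # Collapsing b removes the fixed/random coupling that slows plain
        # Gibbs: per subject, V_i^{-1} = (I - Z_i M_i Z_i'/s^2)/s^2 with
        # M_i = (Sigma_b^{-1} + Z_i'Z_i/s^2)^{-1} (Woodbury; noise is
        # homoscedastic within subject).
        Dm = np.diag(tau)
        Sigma_b = Dm @ C @ Dm
        try:
            Sigma_b_inv = np.linalg.inv(Sigma_b)
        except np.linalg.LinAlgError:
            Sigma_b_inv = np.linalg.pinv(Sigma_b)
        A = np.diag(prior_prec_beta).astype(float)
        rhs = np.zeros(p)
        M_cache = []
        for i in range(S):
            rows = subj_rows[i]
            s2 = sigma[i] ** 2
            Mi = np.linalg.inv(Sigma_b_inv + ZtZ[i] / s2)
            M_cache.append(Mi)
            Xty = X[rows].T @ ystar[rows]
            Zty = Z[rows].T @ ystar[rows]
            A += (XtX[i] - XtZ[i] @ Mi @ XtZ[i].T / s2) / s2
            rhs += (Xty - XtZ[i] @ (Mi @ Zty) / s2) / s2
        La = np.linalg.cholesky(A)
        mean = np.linalg.solve(La.T, np.linalg.solve(La, rhs))
        beta = mean + np.linalg.solve(La.T, rng.standard_normal(p))

        # --- b_i | beta, rest (conjugate per subject) --------------------
        resid = ystar - X @ beta
        for i in range(S):
            rows = subj_rows[i]
            Mi = M_cache[i]  # posterior covariance of b_i
            rhs_i = Z[rows].T @ resid[rows] / sigma[i] ** 2
            Li = np.linalg.cholesky(Mi)
            b[i] = Mi @ rhs_i + Li @ rng.standard_normal(q)

        # --- sigma_i | rest (vectorized scalar MH on log sigma) ----------
        res = resid - np.einsum("nq,nq->n", Z, b[subj])
        sse = np.bincount(subj, weights=res**2, minlength=S)
        prop = sigma * np.exp(step_sigma.value * rng.standard_normal(S))
        ll_cur = -cnt * np.log(sigma) - 0.5 * sse / sigma**2
        ll_prop = -cnt * np.log(prop) - 0.5 * sse / prop**2
        # Half-normal prior plus the log-scale Jacobian.
        lp_cur = _halfnormal_logpdf(sigma, spec.sigma_scale) + np.log(sigma)
        lp_prop = _halfnormal_logpdf(prop, spec.sigma_scale) + np.log(prop)
        log_alpha = (ll_prop + lp_prop) - (ll_cur + lp_cur)
        accept = np.log(rng.uniform(size=S)) < log_alpha
        sigma = np.where(accept, prop, sigma)
        rate = float(np.mean(accept))
        acc["sigma"] += rate
        if it < n_warmup:
            step_sigma.update(rate)

        # --- tau | rest (joint MH on log tau) ----------------------------
        prop_tau = tau * np.exp(step_tau.value * rng.standard_normal(q))
        num = (
            _mvn_b_loglik(b, prop_tau, C)
            + float(np.sum(_halfnormal_logpdf(prop_tau, spec.re_sd_scale)))
            + float(np.sum(np.log(prop_tau)))
        )
        den = (
            _mvn_b_loglik(b, tau, C)
            + float(np.sum(_halfnormal_logpdf(tau, spec.re_sd_scale)))
            + float(np.sum(np.log(tau)))
        )
        a_tau = float(np.log(rng.uniform()) < num - den)
        if a_tau:
            tau = prop_tau
        acc["tau"] += a_tau
        if it < n_warmup:
            step_tau.update(a_tau)

        # --- C | rest (MH on the off-diagonal entries) -------------------
        if offdiag:
            prop_C = C.copy()
            for (i, j) in offdiag:
                prop_C[i, j] = prop_C[j, i] = C[i, j] + step_corr.value * rng.standard_normal()
            if np.all(np.abs(prop_C[tuple(zip(*offdiag))] ) < 1.0):
                num = _mvn_b_loglik(b, tau, prop_C) + _lkj_logpdf(prop_C, spec.lkj_eta)
                den = _mvn_b_loglik(b, tau, C) + _lkj_logpdf(C, spec.lkj_eta)
                a_c = float(np.isfinite(num) and np.log(rng.uniform()) < num - den)
            else:
                a_c = 0.0
            if a_c:
                C = prop_C
            acc["corr"] += a_c
            if it < n_warmup:
                step_corr.update(a_c)

        if it >= n_warmup:
            k = it - n_warmup
            out_beta[k] = beta
            out_b[k] = b
            out_tau[k] = tau
            out_corr[k] = C
            out_sigma[k] = sigma

    for key in acc:
        acc[key] /= total
    return GibbsDraws(
        beta=out_beta[None],
        b=out_b[None],
        tau=out_tau[None],
        corr=out_corr[None],
        sigma=out_sigma[None],
        accept=acc,
    )


def sample(
    spec: GibbsSpec,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    seed: int = 0,
) -> GibbsDraws:
    """Run independent chains and stack their draws."""
    if spec.X.shape[0] != spec.y.shape[0]:
        raise ValueError("X and y row counts differ")
    if n_chains < 1 or n_warmup < 0 or n_draws < 1:
        raise ValueError("need n_chains >= 1, n_warmup >= 0, n_draws >= 1")
    seqs = np.random.SeedSequence(seed).spawn(n_chains)
    chains = [
        _run_chain(spec, n_warmup, n_draws, np.random.default_rng(s)) for s in seqs
    ]
    accept = {
        k: float(np.mean([c.accept[k] for c in chains])) for k in chains[0].accept
    }
    return GibbsDraws(
        beta=np.concatenate([c.beta for c in chains]),
        b=np.concatenate([c.b for c in chains]),
        tau=np.concatenate([c.tau for c in chains]),
        corr=np.concatenate([c.corr for c in chains]),
        sigma=np.concatenate([c.sigma for c in chains]),
        accept=accept,
    )
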