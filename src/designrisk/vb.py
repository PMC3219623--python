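"""Variational-Laplace inversion of nonlinear Gaussian models.

The posterior over parameters is assumed Gaussian (fixed form) and the
posterior over the residual precision Gamma.  The scheme alternates:

* a regularized Gauss-Newton ascent on the variational free energy F with
  respect to the parameter posterior mean (step halving on rejected steps,
  so the accepted-iteration free-energy trace is non-decreasing);
* a closed-form Gamma update of the precision posterior given the current
  parameter moments.

F is a lower bound on the log model evidence (in nats); free-energy
differences between models approximate log Bayes factors and drive
Bayesian model selection via :func:`model_posterior`.

For a linear mapping with fixed (known) precision the scheme converges to
the exact Gaussian posterior and F equals the closed-form log marginal
likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.special import digamma, gammaln

from .models import NonlinearGaussianModel, finite_difference_jacobian

logger = logging.getLogger(__name__)

__all__ = ["InversionConfig", "InversionResult", "invert_vl", "model_posterior"]


@dataclass
class InversionConfig:
    """Tolerances and limits of the variational-Laplace scheme."""

    tol_free_energy: float = 1e-2   # nats; |dF| convergence threshold
    max_iterations: int = 64
    max_step_halvings: int = 8
    update_precision: bool = True   # False freezes the precision at its prior mean


@dataclass
class InversionResult:
    posterior_mean: np.ndarray
    posterior_cov: np.ndarray
    precision_posterior: tuple          # Gamma (shape, scale)
    free_energy: float                  # nats
    free_energy_trace: List[float]
    converged: bool
    n_iterations: int
    model_name: str = ""

    def expected_precision(self) -> float:
        a, s = self.precision_posterior
        return a * s

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "posterior_mean": self.posterior_mean.tolist(),
            "posterior_cov": self.posterior_cov.tolist(),
            "precision_posterior": {"shape": self.precision_posterior[0],
                                    "scale": self.precision_posterior[1]},
            "free_energy_nats": self.free_energy,
            "free_energy_trace": list(self.free_energy_trace),
            "converged": bool(self.converged),
            "n_iterations": self.n_iterations,
        }


def _gamma_kl(a: float, s: float, a0: float, s0: float) -> float:
    """KL( Gamma(a, s) || Gamma(a0, s0) ), shape/scale parameterization."""
    return float(
        gammaln(a0) - gammaln(a)
        + a0 * np.log(s0 / s)
        + (a - a0) * digamma(a)
        - a
        + a * s / s0
    )


def _free_energy(resid, JS_trace, m, S, eta, P0, logdet_P0, a, s, a0, s0, n,
                 fixed_precision: Optional[float]) -> float:
    """Variational free energy (nats) at the current posterior moments.

    resid: y - g(m); JS_trace: tr(J' J S) (expected curvature term);
    P0 = prior precision; (a, s) the Gamma posterior, (a0, s0) its prior.
    """
    if fixed_precision is not None:
        e_lam, e_loglam = fixed_precision, np.log(fixed_precision)
        kl_lam = 0.0
    else:
        e_lam = a * s
        e_loglam = digamma(a) + np.log(s)
        kl_lam = _gamma_kl(a, s, a0, s0)
    sse = float(resid @ resid) + JS_trace
    expected_loglik = 0.5 * n * (e_loglam - np.log(2 * np.pi)) - 0.5 * e_lam * sse
    p = m.size
    if p:
        d = m - eta
        sign, logdet_S = np.linalg.slogdet(S)
        kl_theta = 0.5 * (
            float(np.trace(P0 @ S)) + float(d @ P0 @ d) - p - logdet_S - logdet_P0
        )
    else:
        kl_theta = 0.0
    return float(expected_loglik - kl_theta - kl_lam)


def invert_vl(
    model: NonlinearGaussianModel,
    data,
    config: Optional[InversionConfig] = None,
    design=None,
) -> InversionResult:
    """Invert a nonlinear Gaussian model given data.

    ``data`` may be a 1-D vector or any object with a ``vector()`` method
    (e.g. a simulated :class:`~designrisk.dcm.Dataset`).  Residual noise is
    modelled as i.i.d. with a Gamma-distributed precision (the model's
    hyperprior); if the model declares no hyperprior, the precision is fixed
    from its scalar noise covariance.
    """
    cfg = config or InversionConfig()
    y = np.asarray(data.vector() if hasattr(data, "vector") else data, float).ravel()
    n = y.size
    if model.n_y is not None and n != model.n_y:
        raise ValueError(f"data length {n} != model n_y {model.n_y}")

    eta = model.prior_mean
    p = eta.size
    prior_cov = np.asarray(model.prior_cov, float)
    P0 = np.linalg.inv(prior_cov) if p else np.zeros((0, 0))
    logdet_P0 = -np.linalg.slogdet(prior_cov)[1] if p else 0.0

    fixed_precision = None
    if model.noise_precision_prior is None:
        sigma2 = float(np.atleast_2d(np.asarray(model.noise_cov, float)).ravel()[0]) \
            if np.asarray(model.noise_cov).ndim < 2 else float(np.asarray(model.noise_cov)[0, 0])
        fixed_precision = 1.0 / sigma2
        a0 = s0 = a = s = 0.0
    else:
        a0, s0 = model.noise_precision_prior
        a, s = float(a0), float(s0)

    def mapping(th):
        return model.evaluate(th, design)

    batch = (lambda ts: model.evaluate_batch(ts, design)) \
        if model.batch_mapping is not None else None

    m = eta.copy()
    g = mapping(m)
    J = finite_difference_jacobian(mapping, m, batch_fun=batch) if p else np.zeros((n, 0))
    e_lam = fixed_precision if fixed_precision is not None else a * s

    def posterior_cov(J, e_lam):
        if not p:
            return np.zeros((0, 0))
        P = e_lam * (J.T @ J) + P0
        return np.linalg.inv(0.5 * (P + P.T))

    S = posterior_cov(J, e_lam)
    resid = y - g
    JS_tr = float(np.trace(J.T @ J @ S)) if p else 0.0
    F = _free_energy(resid, JS_tr, m, S, eta, P0, logdet_P0, a, s, a0, s0, n,
                     fixed_precision)
    if not np.isfinite(F):
        raise FloatingPointError(
            f"non-finite free energy for model {model.name} at the prior mean"
        )
    trace = [F]
    converged = False
    it = 0
    for it in range(1, cfg.max_iterations + 1):
        # --- precision update (closed-form Gamma) ---
        if fixed_precision is None and cfg.update_precision:
            a = a0 + 0.5 * n
            s = 1.0 / (1.0 / s0 + 0.5 * (float(resid @ resid) + JS_tr))
            e_lam = a * s
        # --- Gauss-Newton step on the parameter mean ---
        accepted = False
        if p:
            S = posterior_cov(J, e_lam)
            grad = e_lam * (J.T @ resid) - P0 @ (m - eta)
            full_step = S @ grad
            step_scale = 1.0
            for _ in range(cfg.max_step_halvings + 1):
                m_new = m + step_scale * full_step
                try:
                    g_new = mapping(m_new)
                    J_new = finite_difference_jacobian(mapping, m_new,
                                                       batch_fun=batch)
                except (FloatingPointError, RuntimeError):
                    # step landed in a divergent region of parameter space
                    step_scale *= 0.5
                    continue
                with np.errstate(all="ignore"):
                    S_new = posterior_cov(J_new, e_lam)
                    resid_new = y - g_new
                    JS_new = float(np.trace(J_new.T @ J_new @ S_new))
                    F_new = _free_energy(resid_new, JS_new, m_new, S_new, eta,
                                         P0, logdet_P0, a, s, a0, s0, n,
                                         fixed_precision)
                if not np.isfinite(F_new):
                    # overflow near a divergent region: reject and shrink
                    step_scale *= 0.5
                    continue
                if F_new >= trace[-1] - 1e-9:
                    m, g, J, S, resid, JS_tr, F = (
                        m_new, g_new, J_new, S_new, resid_new, JS_new, F_new
                    )
                    accepted = True
                    break
                step_scale *= 0.5
        if not accepted:
            # re-evaluate F after the precision update alone
            S = posterior_cov(J, e_lam)
            JS_tr = float(np.trace(J.T @ J @ S)) if p else 0.0
            F = _free_energy(resid, JS_tr, m, S, eta, P0, logdet_P0, a, s, a0, s0,
                             n, fixed_precision)
        dF = F - trace[-1]
        trace.append(F)
        if abs(dF) < cfg.tol_free_energy:
            converged = True
            break
    if not converged:
        logger.warning("model %s: VB did not converge in %d iterations",
                       model.name, cfg.max_iterations)
    return InversionResult(
        posterior_mean=m,
        posterior_cov=S if p else np.zeros((0, 0)),
        precision_posterior=(a, s) if fixed_precision is None
        else (float("nan"), float("nan")),
        free_energy=float(trace[-1]),
        free_energy_trace=[float(x) for x in trace],
        converged=converged,
        n_iterations=it,
        model_name=model.name,
    )


def model_posterior(
    free_energies: Sequence[float],
    model_priors: Optional[Sequence[float]] = None,
) -> tuple:
    """Posterior model probabilities from free energies (softmax of
    F + log prior, max-subtracted for stability) and the selected index
    (argmax; ties broken by the lowest index)."""
    F = np.asarray(free_energies, float)
    if not np.all(np.isfinite(F)):
        raise ValueError("free energies must be finite")
    if model_priors is None:
        model_priors = np.full(F.size, 1.0 / F.size)
    priors = np.asarray(model_priors, float)
    logp = F + np.log(np.maximum(priors, 1e-300))
    logp = logp - logp.max()
    post = np.exp(logp)
    post = post / post.sum()
    return post, int(np.argmax(post))
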