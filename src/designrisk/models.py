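"""Nonlinear Gaussian generative models and Laplace approximation of their
prior predictive densities.

A generative model here is ``y = g(theta, u) + eps`` with a deterministic
observation mapping ``g``, a Gaussian prior ``theta ~ N(eta, Sigma_theta)``
and Gaussian residuals ``eps ~ N(0, Sigma_eps)``.  The residual precision may
alternatively carry a Gamma hyperprior, in which case the predictive density
is conditioned on the *expected* precision.

The first two moments of the prior predictive density ``p(y | m, u)`` are
obtained by a first-order Taylor expansion of ``g`` around the prior mean::

    mu = g(eta, u)
    Q  = J Sigma_theta J' + Sigma_eps

where ``J`` is the Jacobian of the mapping at the prior mean.  For an affine
mapping this is exact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianPredictive",
    "NonlinearGaussianModel",
    "ModelSet",
    "build_model_set",
    "laplace_predictive",
    "finite_difference_jacobian",
    "complex_step_jacobian",
]

_SYM_TOL = 1e-10


class ModelConfigurationError(ValueError):
    """Raised when a model or model set is internally inconsistent."""


class DegenerateModelError(RuntimeError):
    """Raised when a predictive covariance cannot be repaired to PD."""


def _as_cov(value, dim: int, name: str) -> np.ndarray:
    """Accept a scalar (variance * identity), a diagonal vector or a full matrix."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return float(arr) * np.eye(dim)
    if arr.ndim == 1:
        if arr.size != dim:
            raise ModelConfigurationError(
                f"{name}: diagonal of length {arr.size}, expected {dim}"
            )
        return np.diag(arr)
    if arr.shape != (dim, dim):
        raise ModelConfigurationError(f"{name}: shape {arr.shape}, expected ({dim}, {dim})")
    if not np.allclose(arr, arr.T, atol=_SYM_TOL):
        raise ModelConfigurationError(f"{name} is not symmetric within {_SYM_TOL}")
    return arr


@dataclass
class GaussianPredictive:
    """First two moments (mean, covariance) of a Gaussian density over data space."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = _as_cov(self.cov, self.mean.size, "predictive cov")
        if self.mean.size != self.cov.shape[0]:
            raise ModelConfigurationError("predictive mean/cov dimension mismatch")
        if not np.all(np.isfinite(self.mean)) or not np.all(np.isfinite(self.cov)):
            raise ModelConfigurationError("non-finite predictive moments")
        min_eig = float(np.linalg.eigvalsh(self.cov).min())
        if min_eig <= -1e-10:
            raise ModelConfigurationError(
                f"predictive covariance not PSD (min eigenvalue {min_eig:.3e})"
            )

    @property
    def dim(self) -> int:
        return self.mean.size

    def to_delimited(self, path) -> None:
        """Export moments as tab-delimited text (mean row, then covariance)."""
        with open(path, "w") as fh:
            fh.write("# gaussian predictive: first row mean, remaining rows cov\n")
            np.savetxt(fh, self.mean[None, :], delimiter="\t")
            np.savetxt(fh, self.cov, delimiter="\t")

    def entropy_bits(self) -> float:
        """Differential entropy in bits."""
        n = self.dim
        sign, logdet = np.linalg.slogdet(self.cov)
        if sign <= 0:
            raise DegenerateModelError("singular covariance in entropy")
        return 0.5 * (n * np.log(2.0 * np.pi * np.e) + logdet) / np.log(2.0)


@dataclass
class NonlinearGaussianModel:
    """A nonlinear Gaussian generative model ``y = g(theta, u) + eps``.

    Parameters
    ----------
    name
        Identifier used in error messages and reports.
    observation_mapping
        Deterministic map ``g(theta, design) -> y`` returning a 1-D array of
        length ``n_y`` (``design`` may be ignored by the mapping).
    prior_mean, prior_cov
        Moments of the Gaussian parameter prior.  ``prior_cov`` accepts a
        scalar (variance times identity), a diagonal or a full matrix.
    noise_cov
        Fixed residual covariance (scalar shorthand allowed), used when
        ``noise_mode='fixed'``.  May be None if a precision hyperprior is given.
    noise_precision_prior
        (shape, scale) of a Gamma hyperprior over the residual precision;
        its expectation ``shape * scale`` defines the noise level under
        ``noise_mode='expected-precision'``.
    batch_mapping
        Optional vectorized variant mapping a (p, k) matrix of parameter
        columns to an (n_y, k) matrix; used to accelerate Jacobians.
    """

    name: str
    observation_mapping: Callable[[np.ndarray, object], np.ndarray]
    prior_mean: np.ndarray
    prior_cov: object
    noise_cov: Optional[object] = None
    noise_precision_prior: Optional[tuple] = None
    n_y: Optional[int] = None
    batch_mapping: Optional[Callable[[np.ndarray, object], np.ndarray]] = None

    def __post_init__(self):
        self.prior_mean = np.atleast_1d(np.asarray(self.prior_mean, dtype=float))
        p = self.prior_mean.size
        self.prior_cov = _as_cov(self.prior_cov, p, f"{self.name}: prior_cov")
        if p and np.linalg.eigvalsh(self.prior_cov).min() < -_SYM_TOL:
            raise ModelConfigurationError(f"{self.name}: prior_cov not PSD")
        if self.noise_cov is None and self.noise_precision_prior is None:
            raise ModelConfigurationError(
                f"{self.name}: need noise_cov or noise_precision_prior"
            )
        if self.noise_precision_prior is not None:
            shape, scale = self.noise_precision_prior
            if shape <= 0 or scale <= 0:
                raise ModelConfigurationError(
                    f"{self.name}: Gamma hyperprior requires shape, scale > 0"
                )

    @property
    def n_params(self) -> int:
        return self.prior_mean.size

    def evaluate(self, theta: np.ndarray, design=None) -> np.ndarray:
        """Evaluate the observation mapping, validating output."""
        y = np.asarray(self.observation_mapping(np.asarray(theta, float), design), float)
        y = np.atleast_1d(y).ravel()
        if not np.all(np.isfinite(y)):
            bad = int(np.flatnonzero(~np.isfinite(y))[0])
            raise FloatingPointError(
                f"model {self.name}: non-finite mapping output at index {bad}"
            )
        if self.n_y is not None and y.size != self.n_y:
            raise ModelConfigurationError(
                f"model {self.name}: mapping returned {y.size} values, declared n_y={self.n_y}"
            )
        return y

    def evaluate_batch(self, thetas: np.ndarray, design=None) -> np.ndarray:
        """Evaluate the mapping on parameter columns; (p, k) -> (n_y, k)."""
        thetas = np.asarray(thetas, float)
        if self.batch_mapping is not None:
            out = np.asarray(self.batch_mapping(thetas, design), float)
            if not np.all(np.isfinite(out)):
                raise FloatingPointError(f"model {self.name}: non-finite batch output")
            return out
        return np.column_stack(
            [self.evaluate(thetas[:, j], design) for j in range(thetas.shape[1])]
        )

    def expected_noise_cov(self, n: int, noise_mode: str = "expected-precision") -> np.ndarray:
        """Residual covariance over an n-dimensional data space."""
        if noise_mode == "fixed":
            if self.noise_cov is None:
                raise ModelConfigurationError(f"{self.name}: no fixed noise_cov set")
            return _as_cov(self.noise_cov, n, f"{self.name}: noise_cov")
        if noise_mode == "expected-precision":
            if self.noise_precision_prior is None:
                if self.noise_cov is not None:
                    return _as_cov(self.noise_cov, n, f"{self.name}: noise_cov")
                raise ModelConfigurationError(f"{self.name}: no precision hyperprior set")
            shape, scale = self.noise_precision_prior
            return np.eye(n) / (shape * scale)
        raise ValueError(f"unknown noise_mode {noise_mode!r}")


@dataclass
class ModelSet:
    """An ordered comparison set of models with prior probabilities p(m)."""

    models: Sequence[NonlinearGaussianModel]
    model_priors: np.ndarray
    family_labels: Optional[Mapping[int, object]] = None

    def __post_init__(self):
        if len(self.models) < 2:
            raise ModelConfigurationError("a comparison set needs at least 2 models")
        self.model_priors = np.asarray(self.model_priors, dtype=float)
        if self.model_priors.size != len(self.models):
            raise ModelConfigurationError(
                f"{self.model_priors.size} priors for {len(self.models)} models"
            )
        if np.any(self.model_priors < 0):
            raise ModelConfigurationError("model priors must be nonnegative")
        if abs(self.model_priors.sum() - 1.0) > 1e-12:
            raise ModelConfigurationError(
                f"model priors sum to {self.model_priors.sum():.15g}, not 1"
            )
        if self.family_labels is not None:
            labels = dict(self.family_labels)
            if set(labels) != set(range(len(self.models))):
                raise ModelConfigurationError(
                    "family_labels must assign exactly one label per model index"
                )
            self.family_labels = labels

    def __len__(self) -> int:
        return len(self.models)

    @property
    def names(self):
        return [m.name for m in self.models]

    def families(self) -> dict:
        """Mapping family label -> list of member model indices."""
        if self.family_labels is None:
            raise ModelConfigurationError("model set carries no family labels")
        fams: dict = {}
        for i, lab in self.family_labels.items():
            fams.setdefault(lab, []).append(i)
        return {k: sorted(v) for k, v in fams.items()}

    def prior_entropy_bits(self) -> float:
        p = self.model_priors[self.model_priors > 0]
        return float(-(p * np.log2(p)).sum())


def build_model_set(
    specs: Sequence[NonlinearGaussianModel],
    priors: Optional[Sequence[float]] = None,
    families: Optional[Mapping[int, object]] = None,
) -> ModelSet:
    """Assemble a validated :class:`ModelSet`; uniform p(m) when none given."""
    if not specs:
        raise ModelConfigurationError("empty model list")
    if priors is None:
        priors = np.full(len(specs), 1.0 / len(specs))
    return ModelSet(models=list(specs), model_priors=np.asarray(priors, float),
                    family_labels=families)


def finite_difference_jacobian(
    fun: Callable[[np.ndarray], np.ndarray],
    theta0: np.ndarray,
    batch_fun: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Central finite-difference Jacobian with per-parameter step
    ``max(rel_step, rel_step * |theta_i|)``."""
    theta0 = np.asarray(theta0, float)
    p = theta0.size
    steps = np.maximum(rel_step, rel_step * np.abs(theta0))
    if batch_fun is not None and p > 0:
        thetas = np.repeat(theta0[:, None], 2 * p, axis=1)
        for i in range(p):
            thetas[i, 2 * i] += steps[i]
            thetas[i, 2 * i + 1] -= steps[i]
        ys = np.asarray(batch_fun(thetas), float)
        return (ys[:, 0::2] - ys[:, 1::2]) / (2.0 * steps[None, :])
    cols = []
    for i in range(p):
        tp = theta0.copy()
        tm = theta0.copy()
        tp[i] += steps[i]
        tm[i] -= steps[i]
        cols.append((np.asarray(fun(tp), float) - np.asarray(fun(tm), float))
                    / (2.0 * steps[i]))
    return np.column_stack(cols) if cols else np.zeros((np.asarray(fun(theta0)).size, 0))


def complex_step_jacobian(
    fun: Callable[[np.ndarray], np.ndarray],
    theta0: np.ndarray,
    step: float = 1e-20,
) -> np.ndarray:
    """Complex-step Jacobian (machine precision; requires an analytic mapping
    that propagates complex perturbations)."""
    theta0 = np.asarray(theta0, float)
    p = theta0.size
    cols = []
    for i in range(p):
        t = theta0.astype(complex)
        t[i] += 1j * step
        cols.append(np.imag(np.asarray(fun(t))) / step)
    return np.column_stack(cols) if cols else np.zeros((np.asarray(fun(theta0)).size, 0))


def repair_pd(cov: np.ndarray, name: str = "covariance") -> np.ndarray:
    """Symmetrize and, if needed, ridge-regularize a covariance to PD."""
    cov = 0.5 * (cov + cov.T)
    n = cov.shape[0]
    min_eig = float(np.linalg.eigvalsh(cov).min())
    if min_eig > 0:
        return cov
    ridge = max(1e-10 * np.trace(cov) / n, 1e-12)
    for _ in range(8):
        cand = cov + ridge * np.eye(n)
        if np.linalg.eigvalsh(cand).min() > 0:
            logger.warning("%s repaired to PD with ridge %.3e", name, ridge)
            warnings.warn(f"{name} repaired to positive-definiteness (ridge {ridge:.3e})",
                          RuntimeWarning, stacklevel=2)
            return cand
        ridge *= 10.0
    raise DegenerateModelError(f"{name} singular even after ridge repair")


def laplace_predictive(
    model: NonlinearGaussianModel,
    design=None,
    jacobian_method: str = "finite-difference",
    noise_mode: str = "expected-precision",
) -> GaussianPredictive:
    """First-order (Laplace) Gaussian approximation of a model's prior
    predictive density over data.

    ``mean = g(eta, u)``; ``cov = J Sigma_theta J' + Sigma_eps`` with J the
    Jacobian of the mapping at the prior mean.  Exact for affine mappings.
    """
    mu = model.evaluate(model.prior_mean, design)
    n = mu.size
    if jacobian_method == "finite-difference":
        J = finite_difference_jacobian(
            lambda th: model.evaluate(th, design),
            model.prior_mean,
            batch_fun=(lambda ts: model.evaluate_batch(ts, design))
            if model.batch_mapping is not None else None,
        )
    elif jacobian_method == "complex-step":
        J = complex_step_jacobian(
            lambda th: np.atleast_1d(model.observation_mapping(th, design)).ravel(),
            model.prior_mean,
        )
    else:
        raise ValueError(f"unknown jacobian_method {jacobian_method!r}")
    cov = J @ model.prior_cov @ J.T + model.expected_noise_cov(n, noise_mode)
    cov = repair_pd(cov, name=f"predictive covariance of {model.name}")
    return GaussianPredictive(mean=mu, cov=cov)
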