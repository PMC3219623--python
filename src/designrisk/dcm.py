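"""Deterministic bilinear dynamic causal model (DCM) for small networks.

The generative cascade is:

1. *Neural dynamics* — experimental inputs u(t) drive hidden neural states z
   through the bilinear evolution equation
   ``dz/dt = (A + sum_j u_j B_j + sum_r z_r D_r) z + C u`` with between-region
   coupling A (Hz), input-dependent modulations B_j, driving gains C and
   optional nonlinear gating D_r (off by default).
2. *Hemodynamics* — each region's neural activity feeds a balloon model:
   a vasodilatory signal s, normalized blood inflow f, venous volume v and
   deoxyhemoglobin content q.
3. *Observation* — a static nonlinear BOLD equation maps (v, q) to percent
   signal change, sampled every TR.

Each region therefore carries five hidden states (1 neural + 4 hemodynamic).
Integration is fixed-step RK4 on a microtime grid (dt <= 0.2 s) with
zero-order-hold inputs.  The integrator is batched over columns of parameter
vectors, which makes finite-difference Jacobians of the full forward mapping
a single integration pass; complex parameter vectors propagate analytically,
enabling complex-step derivatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "HemodynamicParams",
    "DCMSpec",
    "DesignSpec",
    "StatePath",
    "Dataset",
    "neural_flow",
    "hemodynamic_flow",
    "bold_observation",
    "integrate_dcm",
    "dcm_as_nonlinear_gaussian",
    "simulate_dataset",
]

STATES_PER_REGION = 5  # z, s, f, v, q


class InstabilityError(RuntimeError):
    """Raised when the integrated system diverges."""


@dataclass
class HemodynamicParams:
    """Balloon-model constants (per-region scalars), standard published
    defaults adopted as a convention.

    kappa : vasodilatory signal decay rate (1/s)
    gamma : flow autoregulation rate (1/s)
    tau   : mean transit time (s)
    alpha : vessel stiffness exponent
    E0    : resting oxygen extraction fraction
    V0    : resting venous volume fraction
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    E0: float = 0.32
    V0: float = 0.04

    @property
    def k1(self) -> float:
        return 7.0 * self.E0

    @property
    def k2(self) -> float:
        return 2.0

    @property
    def k3(self) -> float:
        return 2.0 * self.E0 - 0.2


@dataclass
class DesignSpec:
    """Experimental input time courses on a uniform microtime grid.

    ``u`` is (n_inputs, T) at step ``dt`` seconds; observations are sampled
    every ``tr`` seconds (an integer multiple of dt).  Scan k is taken at the
    end of its repetition interval, microtime index ``(k+1)*tr/dt - 1``.
    """

    u: np.ndarray
    dt: float
    tr: float
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        self.u = np.atleast_2d(np.asarray(self.u, float))
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("inputs contain non-finite values")
        ratio = self.tr / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(f"TR={self.tr} is not an integer multiple of dt={self.dt}")

    @property
    def n_inputs(self) -> int:
        return self.u.shape[0]

    @property
    def n_steps(self) -> int:
        return self.u.shape[1]

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    @property
    def steps_per_scan(self) -> int:
        return int(round(self.tr / self.dt))

    @property
    def scan_indices(self) -> np.ndarray:
        spc = self.steps_per_scan
        return np.arange(spc - 1, self.n_steps, spc)

    @property
    def n_scans(self) -> int:
        return self.scan_indices.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    def segment(self, scan_start: int, scan_stop: int) -> "DesignSpec":
        """Sub-design covering scans [scan_start, scan_stop)."""
        spc = self.steps_per_scan
        return DesignSpec(
            u=self.u[:, scan_start * spc: scan_stop * spc],
            dt=self.dt,
            tr=self.tr,
            annotations={**self.annotations, "segment": (scan_start, scan_stop)},
        )


@dataclass
class DCMSpec:
    """Structure and parameters of a bilinear DCM.

    ``free_parameters`` lists the estimated entries as tuples
    ``("A", i, j)``, ``("B", k, i, j)``, ``("C", i, j)`` or ``("D", r, i, j)``;
    all other entries stay fixed at their specified values.
    """

    A: np.ndarray
    B: Sequence[np.ndarray]
    C: np.ndarray
    D: Optional[Sequence[np.ndarray]] = None
    hemo: HemodynamicParams = field(default_factory=HemodynamicParams)
    free_parameters: Sequence[tuple] = field(default_factory=list)
    name: str = "dcm"

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, float))
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        self.B = [np.asarray(b, float) for b in self.B]
        self.C = np.atleast_2d(np.asarray(self.C, float))
        if self.C.shape[0] != n:
            raise ValueError("C must have one row per region")
        n_inputs = self.C.shape[1]
        if len(self.B) != n_inputs:
            raise ValueError(f"|B|={len(self.B)} but C has {n_inputs} input columns")
        for b in self.B:
            if b.shape != (n, n):
                raise ValueError("every B matrix must be n x n")
        if self.D is not None:
            self.D = [np.asarray(d, float) for d in self.D]
            if len(self.D) not in (0, n):
                raise ValueError("|D| must be 0 or n_regions")
            if len(self.D) == 0:
                self.D = None
        if np.any(np.diag(self.A) > 0):
            raise ValueError("A diagonal entries must be <= 0 (self-inhibition)")
        eigs = np.linalg.eigvals(self.A)
        if np.any(eigs.real >= 0):
            warnings.warn(
                f"{self.name}: linearized system unstable at rest "
                f"(max Re eig(A) = {eigs.real.max():.3f})", RuntimeWarning,
            )
        self.free_parameters = [tuple(t) for t in self.free_parameters]
        for t in self.free_parameters:
            self._check_slot(t)

    def _check_slot(self, t):
        n = self.n_regions
        if t[0] == "A" and len(t) == 3 and 0 <= t[1] < n and 0 <= t[2] < n:
            return
        if t[0] == "B" and len(t) == 4 and 0 <= t[1] < len(self.B):
            return
        if t[0] == "C" and len(t) == 3 and 0 <= t[2] < self.C.shape[1]:
            return
        if t[0] == "D" and len(t) == 4 and self.D is not None and 0 <= t[1] < n:
            return
        raise ValueError(f"invalid free parameter slot {t!r}")

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.C.shape[1]

    @property
    def n_free(self) -> int:
        return len(self.free_parameters)

    @property
    def n_states(self) -> int:
        return STATES_PER_REGION * self.n_regions

    def prior_mean_from_spec(self) -> np.ndarray:
        """Free-parameter values currently stored in the matrices."""
        out = []
        mats = {"A": self.A, "C": self.C}
        for t in self.free_parameters:
            if t[0] in mats:
                out.append(mats[t[0]][t[1], t[2]])
            elif t[0] == "B":
                out.append(self.B[t[1]][t[2], t[3]])
            else:
                out.append(self.D[t[1]][t[2], t[3]])
        return np.asarray(out, float)

    def _batched_matrices(self, thetas: np.ndarray):
        """Per-column effective (A, B, C, D) arrays; thetas is (p, k)."""
        k = thetas.shape[1]
        dtype = thetas.dtype
        A = np.repeat(self.A[None].astype(dtype), k, axis=0)
        B = np.repeat(np.stack(self.B)[None].astype(dtype), k, axis=0) if self.B else None
        C = np.repeat(self.C[None].astype(dtype), k, axis=0)
        D = (np.repeat(np.stack(self.D)[None].astype(dtype), k, axis=0)
             if self.D is not None else None)
        for row, t in enumerate(self.free_parameters):
            if t[0] == "A":
                A[:, t[1], t[2]] = thetas[row]
            elif t[0] == "B":
                B[:, t[1], t[2], t[3]] = thetas[row]
            elif t[0] == "C":
                C[:, t[1], t[2]] = thetas[row]
            else:
                D[:, t[1], t[2], t[3]] = thetas[row]
        return A, B, C, D


@dataclass
class StatePath:
    """Hidden-state trajectory: (5 * n_regions, T) array, rows grouped per
    region as (z, s, f, v, q)."""

    trajectory: np.ndarray
    times: np.ndarray
    n_regions: int

    def __post_init__(self):
        if self.trajectory.shape[0] != STATES_PER_REGION * self.n_regions:
            raise ValueError("expected five states per region")

    def region_states(self, r: int) -> np.ndarray:
        i = STATES_PER_REGION * r
        return self.trajectory[i: i + STATES_PER_REGION]

    @property
    def neural(self) -> np.ndarray:
        return self.trajectory[0::STATES_PER_REGION]

    @property
    def volume(self) -> np.ndarray:
        return self.trajectory[3::STATES_PER_REGION]

    @property
    def dhb(self) -> np.ndarray:
        return self.trajectory[4::STATES_PER_REGION]


@dataclass
class Dataset:
    """Simulated BOLD dataset: (n_regions, n_scans) percent signal change."""

    y: np.ndarray
    tr: float
    design: Optional[DesignSpec] = None
    noise_precision: Optional[float] = None
    seed: Optional[int] = None
    theta: Optional[np.ndarray] = None

    def __post_init__(self):
        self.y = np.atleast_2d(np.asarray(self.y, float))
        if not np.all(np.isfinite(self.y)):
            raise ValueError("dataset contains non-finite values")

    @property
    def n_regions(self) -> int:
        return self.y.shape[0]

    @property
    def n_scans(self) -> int:
        return self.y.shape[1]

    def vector(self) -> np.ndarray:
        """Region-major stacked data vector matching the DCM mapping."""
        return self.y.ravel()

    def segment(self, scan_start: int, scan_stop: int) -> "Dataset":
        return Dataset(
            y=self.y[:, scan_start:scan_stop],
            tr=self.tr,
            design=self.design.segment(scan_start, scan_stop) if self.design else None,
            noise_precision=self.noise_precision,
            seed=self.seed,
            theta=self.theta,
        )

    def save(self, path) -> None:
        """Write as tab-delimited text (one column per region, header with TR
        and seed) plus a `.json` provenance sidecar."""
        import json
        from pathlib import Path as _P

        path = _P(path)
        with open(path, "w") as fh:
            fh.write(f"# TR={self.tr} seed={self.seed} "
                     f"noise_precision={self.noise_precision}\n")
            fh.write("\t".join(f"region_{r + 1}" for r in range(self.n_regions))
                     + "\n")
            np.savetxt(fh, self.y.T, delimiter="\t")
        sidecar = {
            "tr": self.tr,
            "seed": self.seed,
            "noise_precision": self.noise_precision,
            "n_regions": self.n_regions,
            "n_scans": self.n_scans,
            "theta": self.theta.tolist() if self.theta is not None else None,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar,
                                                                      indent=2))

    @classmethod
    def load(cls, path) -> "Dataset":
        import json
        from pathlib import Path as _P

        path = _P(path)
        y = np.loadtxt(path, delimiter="\t", skiprows=2).T
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            y=np.atleast_2d(y),
            tr=meta["tr"],
            noise_precision=meta.get("noise_precision"),
            seed=meta.get("seed"),
            theta=np.asarray(meta["theta"], float)
            if meta.get("theta") is not None else None,
        )


def neural_flow(x_neural: np.ndarray, u: np.ndarray, spec: DCMSpec,
                theta: Optional[np.ndarray] = None) -> np.ndarray:
    """Rate of change of the neural states:
    ``(A + sum_j u_j B_j + sum_r x_r D_r) x + C u``."""
    x = np.asarray(x_neural, float)
    u = np.atleast_1d(np.asarray(u, float))
    if x.size != spec.n_regions or u.size != spec.n_inputs:
        raise ValueError("neural state / input dimension mismatch")
    thetas = (spec.prior_mean_from_spec() if theta is None else np.asarray(theta, float))
    A, B, C, D = spec._batched_matrices(thetas.reshape(-1, 1))
    M = A[0] + (np.tensordot(u, B[0], axes=1) if B is not None else 0.0)
    if D is not None:
        M = M + np.tensordot(x, D[0], axes=1)
    return M @ x + C[0] @ u


def hemodynamic_flow(hemo_states: np.ndarray, x_neural_region: float,
                     hemo: HemodynamicParams) -> np.ndarray:
    """Balloon-model cascade derivatives for one region.

    States are (s, f, v, q): vasodilatory signal, inflow, venous volume,
    deoxyhemoglobin.  The resting point (0, 1, 1, 1) with zero neural input
    is a fixed point by construction.
    """
    s, f, v, q = np.asarray(hemo_states, float)
    if v <= 0 or q <= 0:
        raise ValueError("volume and deoxyhemoglobin states must stay positive")
    fv = v ** (1.0 / hemo.alpha)
    E = 1.0 - (1.0 - hemo.E0) ** (1.0 / f)
    ds = x_neural_region - hemo.kappa * s - hemo.gamma * (f - 1.0)
    df = s
    dv = (f - fv) / hemo.tau
    dq = (f * E / hemo.E0 - fv * q / v) / hemo.tau
    return np.array([ds, df, dv, dq])


def bold_observation(hemo_states: np.ndarray, hemo: HemodynamicParams) -> float:
    """Static BOLD observation (percent signal change) from (s, f, v, q)."""
    _, _, v, q = np.asarray(hemo_states, float)
    return float(100.0 * hemo.V0 * (
        hemo.k1 * (1.0 - q) + hemo.k2 * (1.0 - q / v) + hemo.k3 * (1.0 - v)
    ))


def _rest_state(n_regions: int, k: int, dtype=float) -> tuple:
    z = np.zeros((n_regions, k), dtype)
    s = np.zeros((n_regions, k), dtype)
    f = np.ones((n_regions, k), dtype)
    v = np.ones((n_regions, k), dtype)
    q = np.ones((n_regions, k), dtype)
    return z, s, f, v, q


def _forward(spec: DCMSpec, design: DesignSpec, thetas: np.ndarray,
             keep_states: bool = False):
    """Batched RK4 integration from rest.

    ``thetas``: (p, k) parameter columns (possibly complex).  Returns
    ``(bold, states)`` with bold (n_regions, n_scans, k) and, if requested,
    states (5 n_regions, T, k).
    """
    thetas = np.asarray(thetas)
    if thetas.ndim == 1:
        thetas = thetas.reshape(-1, 1)
    if thetas.shape[0] != spec.n_free:
        raise ValueError(
            f"{spec.name}: {thetas.shape[0]} parameter rows for "
            f"{spec.n_free} free parameters"
        )
    k = thetas.shape[1] if thetas.shape[1] else 1
    if spec.n_free == 0:
        thetas = np.zeros((0, k))
    dtype = complex if np.iscomplexobj(thetas) else float
    A, B, C, D = spec._batched_matrices(thetas.astype(dtype))
    n, J = spec.n_regions, spec.n_inputs
    h = spec.hemo
    inv_alpha = 1.0 / h.alpha
    log1mE0 = np.log(1.0 - h.E0)
    dt = design.dt
    T = design.n_steps
    u = design.u
    z, s, f, v, q = _rest_state(n, k, dtype)
    scan_set = design.scan_indices
    bold = np.empty((n, scan_set.size, k), dtype)
    states = np.empty((STATES_PER_REGION * n, T, k), dtype) if keep_states else None
    scan_ptr = 0
    next_scan = scan_set[0] if scan_set.size else -1

    def deriv(z, s, f, v, q, u_t):
        M = A + np.einsum("j,kjab->kab", u_t, B) if B is not None else A
        if D is not None:
            M = M + np.einsum("rk,krab->kab", z, D)
        dz = np.einsum("kab,bk->ak", M, z) + np.einsum("kaj,j->ak", C, u_t)
        ds = z - h.kappa * s - h.gamma * (f - 1.0)
        df = s
        fv = np.exp(inv_alpha * np.log(v))
        E_ratio = (1.0 - np.exp(log1mE0 / f)) / h.E0
        dv = (f - fv) / h.tau
        dq = (f * E_ratio - fv * q / v) / h.tau
        return dz, ds, df, dv, dq

    with np.errstate(invalid="ignore", over="ignore"):
        for t in range(T):
            u_t = u[:, t]
            k1 = deriv(z, s, f, v, q, u_t)
            k2 = deriv(z + 0.5 * dt * k1[0], s + 0.5 * dt * k1[1],
                       f + 0.5 * dt * k1[2], v + 0.5 * dt * k1[3],
                       q + 0.5 * dt * k1[4], u_t)
            k3 = deriv(z + 0.5 * dt * k2[0], s + 0.5 * dt * k2[1],
                       f + 0.5 * dt * k2[2], v + 0.5 * dt * k2[3],
                       q + 0.5 * dt * k2[4], u_t)
            k4 = deriv(z + dt * k3[0], s + dt * k3[1], f + dt * k3[2],
                       v + dt * k3[3], q + dt * k3[4], u_t)
            z = z + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            s = s + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            f = f + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
            v = v + dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
            q = q + dt / 6.0 * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
            if t % 50 == 0 or t == T - 1:
                zr = z.real if dtype is complex else z
                if not np.all(np.isfinite(zr)) or np.abs(zr).max() > 1e6:
                    raise InstabilityError(
                        f"{spec.name}: trajectory diverged at t={t * dt:.1f}s "
                        f"for free parameters {list(spec.free_parameters)}"
                    )
            if keep_states:
                st = states[:, t, :]
                st[0::STATES_PER_REGION] = z
                st[1::STATES_PER_REGION] = s
                st[2::STATES_PER_REGION] = f
                st[3::STATES_PER_REGION] = v
                st[4::STATES_PER_REGION] = q
            if t == next_scan:
                bold[:, scan_ptr, :] = 100.0 * h.V0 * (
                    h.k1 * (1.0 - q) + h.k2 * (1.0 - q / v) + h.k3 * (1.0 - v)
                )
                scan_ptr += 1
                next_scan = scan_set[scan_ptr] if scan_ptr < scan_set.size else -1
    return bold, states


def integrate_dcm(spec: DCMSpec, design: DesignSpec,
                  theta: Optional[np.ndarray] = None) -> StatePath:
    """Deterministic hidden-state trajectory from rest under a design."""
    if design.dt > 0.2 + 1e-12:
        warnings.warn("dt > 0.2 s: integrator accuracy not guaranteed", RuntimeWarning)
    th = spec.prior_mean_from_spec() if theta is None else np.asarray(theta, float)
    _, states = _forward(spec, design, th.reshape(-1, 1), keep_states=True)
    return StatePath(trajectory=states[:, :, 0].real.astype(float),
                     times=design.times, n_regions=spec.n_regions)


def forward_bold(spec: DCMSpec, design: DesignSpec,
                 theta: Optional[np.ndarray] = None) -> np.ndarray:
    """Noise-free BOLD output (n_regions, n_scans) at scan times."""
    th = spec.prior_mean_from_spec() if theta is None else np.asarray(theta, float)
    bold, _ = _forward(spec, design, th.reshape(-1, 1))
    return bold[:, :, 0].real.astype(float)


def dcm_as_nonlinear_gaussian(
    spec: DCMSpec,
    design: Optional[DesignSpec] = None,
    prior_mean: Optional[np.ndarray] = None,
    prior_var: float = 1.0,
    prior_cov: Optional[np.ndarray] = None,
    noise_precision_prior: Tuple[float, float] = (1.0, 0.1),
    name: Optional[str] = None,
):
    """Compile a DCM into a nonlinear Gaussian generative model.

    The observation mapping sends the free-parameter vector theta to the
    region-major stacked BOLD time series at scan times.  Free parameters
    carry shrinkage i.i.d. Gaussian priors centered on the values stored in
    the spec matrices (variance ``prior_var`` by default).
    """
    from .models import NonlinearGaussianModel

    if prior_mean is None:
        prior_mean = spec.prior_mean_from_spec()
    prior_mean = np.asarray(prior_mean, float)

    def mapping(theta, d):
        d = d if d is not None else design
        if d is None:
            raise ValueError("a DesignSpec is required to evaluate a DCM mapping")
        if np.iscomplexobj(theta):
            bold, _ = _forward(spec, d, np.asarray(theta).reshape(-1, 1))
            return bold[:, :, 0].reshape(-1)
        return forward_bold(spec, d, theta).ravel()

    def batch_mapping(thetas, d):
        d = d if d is not None else design
        if d is None:
            raise ValueError("a DesignSpec is required to evaluate a DCM mapping")
        bold, _ = _forward(spec, d, thetas)
        k = bold.shape[2]
        return bold.real.reshape(-1, k)

    return NonlinearGaussianModel(
        name=name or spec.name,
        observation_mapping=mapping,
        batch_mapping=batch_mapping,
        prior_mean=prior_mean,
        prior_cov=prior_cov if prior_cov is not None else prior_var,
        noise_precision_prior=tuple(noise_precision_prior),
        n_y=(spec.n_regions * design.n_scans) if design is not None else None,
    )


def simulate_dataset(
    spec: DCMSpec,
    design: DesignSpec,
    theta: Optional[np.ndarray] = None,
    noise_precision: float = 1.0,
    seed: Optional[int] = None,
) -> Dataset:
    """Simulate a BOLD dataset: forward output plus i.i.d. Gaussian noise of
    the stated precision.  Fully reproducible given the seed."""
    if noise_precision <= 0:
        raise ValueError("noise_precision must be > 0")
    clean = forward_bold(spec, design, theta)
    rng = np.random.default_rng(seed)
    y = clean + rng.standard_normal(clean.shape) / np.sqrt(noise_precision)
    return Dataset(y=y, tr=design.tr, design=design,
                   noise_precision=noise_precision, seed=seed,
                   theta=np.asarray(theta, float) if theta is not None else None)
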