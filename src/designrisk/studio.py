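"""Design generators, scenario library, risk-vs-design curves, Monte-Carlo
validation of the error-rate bounds, and the data-splitting analysis.

The scenario library collects small two-region network-identification
problems: where a driving input enters, whether a connection is modulated,
whether a feedback connection exists, the 3x2 factorial set of models
compatible with a psycho-physiological interaction (PPI), TMS intervention
sites, and a bimanual finger-tapping comparison set.  Scenario defaults are
reconstructed working values, not verbatim experimental protocols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .dcm import DCMSpec, DesignSpec, dcm_as_nonlinear_gaussian
from .models import ModelSet, build_model_set
from .risk import family_risk, laplace_chernoff_risk, posterior_error_probability
from .vb import InversionConfig, invert_vl, model_posterior

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioSet",
    "MonteCarloResult",
    "make_blocked_design",
    "make_event_design",
    "make_correlated_pair_designs",
    "risk_curve",
    "monte_carlo_error_rate",
    "split_analysis",
    "scenario_library",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = (
    "input-entry-pair",
    "driving-input",
    "modulatory-input",
    "feedback",
    "ppi-3x2",
    "tms-site",
    "finger-tapping",
)


# --------------------------------------------------------------------------
# design generators
# --------------------------------------------------------------------------

def make_blocked_design(
    epoch_duration: float,
    session_length: float = 300.0,
    inter_block_interval: float = 32.0,
    jitter_sd: float = 0.0,
    seed: Optional[int] = None,
    n_inputs: int = 1,
    dt: float = 0.1,
    tr: float = 1.3,
    conditions: Optional[Sequence[Sequence[int]]] = None,
    extra_pulse_channel: Optional[dict] = None,
) -> DesignSpec:
    """Blocked on/off (square-wave) design.

    Block onsets are spaced by ``inter_block_interval`` on average, each
    jittered by a truncated Gaussian (sd ``jitter_sd`` seconds, truncated so
    epochs never overlap).  With several inputs, blocks cycle through the
    ``conditions`` (default: one condition per input, one-hot), keeping the
    repetition counts balanced.

    ``extra_pulse_channel`` adds a channel of brief pulse trains grouped in
    epochs (e.g. on-line TMS): dict with keys ``epoch`` (s, default 8),
    ``pulse_rate`` (Hz, default 5).
    """
    if epoch_duration <= 0 or epoch_duration >= session_length:
        raise ValueError("need 0 < epoch_duration < session_length")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if inter_block_interval < epoch_duration:
        raise ValueError(
            "infeasible packing: inter_block_interval shorter than the epoch"
        )
    rng = np.random.default_rng(seed)
    T = int(round(session_length / dt))
    if conditions is None:
        conditions = [tuple(1 if j == i else 0 for j in range(n_inputs))
                      for i in range(n_inputs)]
    n_blocks = int(np.floor(session_length / inter_block_interval))
    onsets = []
    labels = []
    max_shift = 0.5 * (inter_block_interval - epoch_duration)
    for b in range(n_blocks):
        base = b * inter_block_interval
        if jitter_sd > 0:
            shift = np.clip(rng.normal(0.0, jitter_sd), -max_shift, max_shift)
        else:
            shift = 0.0
        onset = base + max(0.0, max_shift) + shift  # center epochs in their slot
        onsets.append(onset)
        labels.append(conditions[b % len(conditions)])
    u = np.zeros((n_inputs, T))
    for onset, cond in zip(onsets, labels):
        i0 = int(round(onset / dt))
        i1 = min(int(round((onset + epoch_duration) / dt)), T)
        for j, on in enumerate(cond):
            if on:
                u[j, i0:i1] = 1.0
    ann = {
        "kind": "blocked",
        "epoch_duration": epoch_duration,
        "inter_block_interval": inter_block_interval,
        "jitter_sd": jitter_sd,
        "seed": seed,
        "onsets": [float(o) for o in onsets],
        "conditions": [tuple(c) for c in labels],
    }
    if extra_pulse_channel is not None:
        epoch = float(extra_pulse_channel.get("epoch", 8.0))
        rate = float(extra_pulse_channel.get("pulse_rate", 5.0))
        chan = np.zeros((1, T))
        period = max(int(round(1.0 / (rate * dt))), 1)
        # pulse epochs interleave with the stimulus blocks (on alternate
        # inter-block slots) so the TMS channel stays near-orthogonal to the
        # other experimental inputs
        for onset in onsets[::2]:
            i0 = int(round((onset + 0.5 * inter_block_interval) / dt))
            i1 = min(int(round((onset + 0.5 * inter_block_interval + epoch) / dt)), T)
            chan[0, i0:i1:period] = 1.0
        u = np.vstack([u, chan])
        ann["pulse_channel"] = {"epoch": epoch, "pulse_rate": rate}
    return DesignSpec(u=u, dt=dt, tr=tr, annotations=ann)


def make_event_design(
    trial_types: Sequence[str],
    n_per_type: Sequence[int],
    mean_iti: float = 2.0,
    seed: Optional[int] = None,
    dt: float = 0.1,
    tr: float = 1.3,
    stimulus_duration: float = 0.5,
    blocked: bool = False,
    block_size: int = 10,
) -> DesignSpec:
    """Event-related design: a randomized trial sequence with the requested
    per-type counts and mean inter-trial interval.

    Trial types named ``"null"`` contribute no input.  Each non-null type
    gets (or shares, via '+'-joined compound names such as ``"left+right"``)
    an input channel.  ``blocked=True`` groups ``block_size`` consecutive
    identical trials per block instead of fully randomizing.
    """
    n_per_type = [int(k) for k in n_per_type]
    if len(trial_types) != len(n_per_type) or any(k < 0 for k in n_per_type):
        raise ValueError("trial_types and n_per_type must match, counts >= 0")
    if mean_iti <= 0:
        raise ValueError("mean_iti must be > 0")
    rng = np.random.default_rng(seed)
    seq = [t for t, k in zip(trial_types, n_per_type) for _ in range(k)]
    if blocked:
        # group trials per type into blocks of identical consecutive trials
        blocks = []
        for t, k in zip(trial_types, n_per_type):
            blocks += [[t] * min(block_size, k - i)
                       for i in range(0, k, block_size)]
        order = rng.permutation(len(blocks))
        seq = [t for bi in order for t in blocks[bi]]
    else:
        seq = list(rng.permutation(seq))
    channels = sorted({c for t in trial_types if t != "null" for c in t.split("+")})
    n_events = len(seq)
    # inter-trial intervals jittered uniformly around the requested mean
    itis = mean_iti * rng.uniform(0.5, 1.5, size=max(n_events - 1, 0))
    onsets = np.concatenate([[0.0], np.cumsum(itis)])
    session_length = float(onsets[-1]) + 30.0  # tail for the hemodynamic decay
    T = int(round(session_length / dt))
    u = np.zeros((max(len(channels), 1), T))
    for onset, t in zip(onsets, seq):
        if t == "null":
            continue
        i0 = int(round(onset / dt))
        i1 = min(int(round((onset + stimulus_duration) / dt)), T)
        for c in t.split("+"):
            u[channels.index(c), i0:i1] = 1.0
    return DesignSpec(
        u=u, dt=dt, tr=tr,
        annotations={
            "kind": "event-related" if not blocked else "event-blocked",
            "sequence": seq, "mean_iti": mean_iti, "seed": seed,
            "channels": channels, "n_events": n_events,
            "empirical_mean_iti": float(np.diff(onsets).mean()) if n_events > 1 else None,
        },
    )


def make_correlated_pair_designs(
    correlation_levels: Sequence[float],
    epoch_duration: float = 16.0,
    session_length: float = 300.0,
    inter_block_interval: float = 32.0,
    dt: float = 0.1,
    tr: float = 1.3,
    seed: Optional[int] = None,
) -> List[DesignSpec]:
    """Pairs of on/off input sequences with controlled temporal correlation.

    The first input is a blocked sequence.  The second has one block per
    inter-block slot as well, but each block is either *coincident* with the
    first input's block, *anti-phase* (placed in the following off period,
    zero overlap), or partially overlapping (one block, the continuous
    knob).  For binary sequences with common on-fraction p and co-activation
    fraction p11, corr = (p11 - p^2) / (p (1 - p)); the number of coincident
    blocks and the partial overlap are solved from this identity, so the
    empirical correlation hits each requested level up to microtime
    rounding.  Which blocks coincide is chosen by the seed.
    """
    base = make_blocked_design(
        epoch_duration, session_length, inter_block_interval,
        jitter_sd=0.0, seed=seed, n_inputs=1, dt=dt, tr=tr,
    )
    u1 = base.u[0]
    T = u1.size
    onsets = np.asarray(base.annotations["onsets"])
    n_blocks = onsets.size
    L = epoch_duration
    p = n_blocks * L / session_length
    rng = np.random.default_rng(seed)

    designs = []
    for level in correlation_levels:
        if not (0.0 <= level < 1.0 + 1e-12):
            raise ValueError("correlation levels must lie in [0, 1)")
        # shared on-time (in blocks) required for this correlation level
        shared = session_length * (p * p + level * p * (1.0 - p)) / L
        if shared > n_blocks + 1e-9:
            raise ValueError(
                f"correlation {level} unattainable with epoch {epoch_duration}"
                f" and interval {inter_block_interval}"
            )
        k = int(np.floor(shared))
        x = shared - k  # partial overlap of one more block
        order = rng.permutation(n_blocks)
        u2 = np.zeros(T)
        iL = int(round(L / dt))
        for rank, b in enumerate(order):
            if rank < k:
                start = onsets[b]                      # coincident
            elif rank == k and x > 0:
                start = onsets[b] + (1.0 - x) * L      # partial overlap
            else:
                start = onsets[b] + L                  # anti-phase
            i0 = int(round(start / dt))
            i1 = min(i0 + iL, T)
            u2[i0:i1] = 1.0
        emp = float(np.corrcoef(u1, u2)[0, 1])
        if abs(emp - level) > 0.05:
            raise ValueError(
                f"correlation {level} unattainable: closest achieved {emp:.3f}"
            )
        designs.append(DesignSpec(
            u=np.vstack([u1, u2]), dt=dt, tr=tr,
            annotations={**base.annotations, "kind": "correlated-pair",
                         "target_correlation": float(level),
                         "empirical_correlation": emp,
                         "n_coincident_blocks": k,
                         "partial_overlap": float(x)},
        ))
    return designs


# --------------------------------------------------------------------------
# scenarios
# --------------------------------------------------------------------------

@dataclass
class ScenarioSet:
    """A named study setup: a model-set builder parameterized by the prior
    mean of the neural evolution parameters, a design family, and factor
    grids to sweep."""

    name: str
    build_model_set: Callable[[float], ModelSet]
    design_family: str = "blocked"
    epoch_grid: Sequence[float] = (2.0, 4.0, 8.0, 16.0, 24.0, 32.0)
    eta_grid: Sequence[float] = (0.2, 0.4, 0.6, 0.8)
    correlation_levels: Sequence[float] = ()
    partitions: Dict[str, Sequence] = field(default_factory=dict)
    design_kwargs: dict = field(default_factory=dict)
    n_inputs: int = 1

    def __post_init__(self):
        if not len(self.epoch_grid) or not len(self.eta_grid):
            raise ValueError("scenario grids must be non-empty")

    def make_design(self, epoch_duration: float, jitter_sd: float = 2.0,
                    seed: Optional[int] = None, **overrides) -> DesignSpec:
        kw = {**self.design_kwargs, **overrides}
        return make_blocked_design(
            epoch_duration=epoch_duration, jitter_sd=jitter_sd, seed=seed,
            n_inputs=self.n_inputs, **kw,
        )


def _two_region_spec(name, a21=0.0, a12=0.0, c=None, b=None, d=None,
                     free=None, self_coupling=(-1.0, -1.0)):
    """Helper: a two-region bilinear DCM with fixed -1 Hz self-connections
    (per-region overrides allowed, e.g. to compensate gating terms)."""
    sc = (self_coupling, self_coupling) if np.isscalar(self_coupling) else self_coupling
    A = np.array([[sc[0], a12], [a21, sc[1]]])
    n_inputs = np.asarray(c).shape[1] if c is not None else 1
    C = np.asarray(c, float) if c is not None else np.zeros((2, 1))
    B = [np.zeros((2, 2)) for _ in range(n_inputs)]
    if b:
        for (k, i, j), val in b.items():
            B[k][i, j] = val
    D = None
    if d:
        D = [np.zeros((2, 2)), np.zeros((2, 2))]
        for (r, i, j), val in d.items():
            D[r][i, j] = val
    return DCMSpec(A=A, B=B, C=C, D=D, free_parameters=free or [], name=name)


def _default_noise_prior():
    # weakly informative: unit shape, scale 0.1 (expected precision 0.1)
    return (1.0, 0.1)


def scenario_library(
    name: str,
    session_length: float = 300.0,
    tr: float = 1.3,
    dt: float = 0.1,
    prior_var: float = 1.0,
    noise_precision_prior: Optional[tuple] = None,
) -> ScenarioSet:
    """Fully specified, seeded scenarios for canonical network-identification
    questions (each model set is a function of the prior mean eta of the
    neural evolution parameters)."""
    if name not in SCENARIO_NAMES:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(SCENARIO_NAMES)}"
        )
    npp = noise_precision_prior or _default_noise_prior()
    common = dict(prior_var=prior_var, noise_precision_prior=npp)
    design_kwargs = dict(session_length=session_length, tr=tr, dt=dt)
    # balanced factorial block conditions for two-input designs: u1, u2, u1&u2
    factorial2 = dict(design_kwargs, conditions=[(1, 0), (0, 1), (1, 1)])

    def compile_set(specs, families=None):
        models = [dcm_as_nonlinear_gaussian(s, **common) for s in specs]
        return build_model_set(models, families=families)

    if name == "input-entry-pair":
        # two reciprocally connected regions; the models swap which of the
        # two inputs drives which region
        def build(eta):
            c1 = np.array([[1.0, 0.0], [0.0, 1.0]])
            c2 = np.array([[0.0, 1.0], [1.0, 0.0]])
            free = [("A", 0, 1), ("A", 1, 0), ("C", 0, 0), ("C", 1, 1)]
            m1 = _two_region_spec("m1-u1r1-u2r2", a21=eta, a12=eta, c=c1, free=free)
            free2 = [("A", 0, 1), ("A", 1, 0), ("C", 0, 1), ("C", 1, 0)]
            m2 = _two_region_spec("m2-u1r2-u2r1", a21=eta, a12=eta, c=c2, free=free2)
            return compile_set([m1, m2])
        return ScenarioSet(name=name, build_model_set=build, n_inputs=2,
                           design_kwargs=factorial2,
                           correlation_levels=(0.0, 0.4, 0.8))

    if name == "driving-input":
        def build(eta):
            free = [("A", 0, 1), ("A", 1, 0)]
            m1 = _two_region_spec("drv-r1", a21=eta, a12=eta,
                                  c=np.array([[1.0], [0.0]]),
                                  free=free + [("C", 0, 0)])
            m2 = _two_region_spec("drv-r2", a21=eta, a12=eta,
                                  c=np.array([[0.0], [1.0]]),
                                  free=free + [("C", 1, 0)])
            return compile_set([m1, m2])
        return ScenarioSet(name=name, build_model_set=build, n_inputs=1,
                           design_kwargs=design_kwargs)

    if name == "modulatory-input":
        # u1 drives region 1; the models differ in whether u2 modulates the
        # forward connection 1 -> 2
        def build(eta):
            c = np.array([[1.0, 0.0], [0.0, 0.0]])
            base_free = [("A", 1, 0), ("C", 0, 0)]
            m0 = _two_region_spec("mod-", a21=eta, c=c, free=base_free)
            m1 = _two_region_spec("mod+", a21=eta, c=c,
                                  b={(1, 1, 0): eta},
                                  free=base_free + [("B", 1, 1, 0)])
            return compile_set([m0, m1])
        return ScenarioSet(name=name, build_model_set=build, n_inputs=2,
                           design_kwargs=factorial2)

    if name == "feedback":
        def build(eta):
            c = np.array([[1.0], [0.0]])
            m0 = _two_region_spec("fbk-", a21=eta, c=c,
                                  free=[("A", 1, 0), ("C", 0, 0)])
            m1 = _two_region_spec("fbk+", a21=eta, a12=eta, c=c,
                                  free=[("A", 1, 0), ("A", 0, 1), ("C", 0, 0)])
            return compile_set([m0, m1])
        return ScenarioSet(name=name, build_model_set=build, n_inputs=1,
                           design_kwargs=design_kwargs)

    if name in ("ppi-3x2", "tms-site"):
        # 3x2 factorial PPI set (reconstructed classes):
        #   B  : psych. factor u_p modulates the 1->2 connection
        #   Bd : same, and u_p also drives region 2
        #   D  : region 1 gates the direct drive of u_p on region 2
        # x {no feedback, feedback 2->1}.  Inputs: u_s drives region 1,
        # u_p is the psychological factor; TMS adds a third pulse channel.
        tms = name == "tms-site"
        n_inputs = 3 if tms else 2

        def build(eta, tms_site=None):
            specs = []
            fams1 = {}
            fams2 = {}
            eta_tms = 0.1  # comparatively weak TMS effect
            for fb in (0, 1):
                for cls in ("B", "Bd", "D"):
                    c = np.zeros((2, n_inputs))
                    c[0, 0] = 1.0  # u_s drives region 1
                    b = {}
                    d = None
                    free = [("A", 1, 0), ("C", 0, 0)]
                    if cls in ("B", "Bd"):
                        b[(1, 1, 0)] = eta
                        free.append(("B", 1, 1, 0))
                    if cls == "Bd":
                        c[1, 1] = eta
                        free.append(("C", 1, 1))
                    sc = (-1.0, -1.0)
                    if cls == "D":
                        # region 1 gates the gain of region 2 (its response to
                        # the psych. drive); the baseline self-inhibition of
                        # region 2 is deepened to keep the operating point
                        # stable under the gating loop
                        c[1, 1] = eta
                        d = {(0, 1, 1): eta}
                        sc = (-1.0, -(1.0 + eta))
                        free += [("C", 1, 1), ("D", 0, 1, 1)]
                    a12 = eta if fb else 0.0
                    if fb:
                        free.append(("A", 0, 1))
                    if tms and tms_site is not None:
                        c[tms_site, 2] = eta_tms
                        free.append(("C", tms_site, 2))
                    spec = _two_region_spec(
                        f"ppi-{cls}{'-fb' if fb else ''}", a21=eta, a12=a12,
                        c=c, b=b, d=d, free=free, self_coupling=sc,
                    )
                    idx = len(specs)
                    specs.append(spec)
                    fams1[idx] = "1-modulates-psych->2" if cls == "D" \
                        else "psych-modulates-1->2"
                    fams2[idx] = "feedback" if fb else "no-feedback"
            ms = compile_set(specs, families=fams2)
            ms.partition_interpretation = fams1   # partition 1
            ms.partition_feedback = fams2         # partition 2
            return ms

        dk = dict(factorial2)
        if tms:
            # on-line TMS: brief pulses grouped in 8 s epochs on a third channel
            dk["extra_pulse_channel"] = {"epoch": 8.0, "pulse_rate": 5.0}
        return ScenarioSet(
            name=name, build_model_set=build, n_inputs=2,
            design_kwargs=dk,
            eta_grid=(0.1, 0.2, 0.3, 0.4),  # reconstructed grid, not verbatim
            partitions={"partition1": "interpretation", "partition2": "feedback"},
        )

    if name == "finger-tapping":
        # bimanual finger tapping: left/right pacing inputs, left and right
        # motor cortex regions.  F: contralateral drive + feedback; IF:
        # drives swapped; NF: F without feedback; NF2: both paces drive both.
        def build(eta):
            free_fb = [("A", 0, 1), ("A", 1, 0)]
            cF = np.array([[0.0, 1.0], [1.0, 0.0]]) * 1.0
            cIF = np.array([[1.0, 0.0], [0.0, 1.0]]) * 1.0
            cNF2 = np.array([[1.0, 1.0], [1.0, 1.0]]) * 1.0
            F = _two_region_spec("F", a21=eta, a12=eta, c=cF,
                                 free=free_fb + [("C", 0, 1), ("C", 1, 0)])
            IF = _two_region_spec("IF", a21=eta, a12=eta, c=cIF,
                                  free=free_fb + [("C", 0, 0), ("C", 1, 1)])
            NF = _two_region_spec("NF", c=cF, free=[("C", 0, 1), ("C", 1, 0)])
            NF2 = _two_region_spec("NF2", c=cNF2,
                                   free=[("C", 0, 0), ("C", 0, 1),
                                         ("C", 1, 0), ("C", 1, 1)])
            fams = {0: "family1", 1: "family2", 2: "family1", 3: "family2"}
            return compile_set([F, IF, NF, NF2], families=fams)
        return ScenarioSet(name=name, build_model_set=build, n_inputs=2,
                           design_kwargs=factorial2,
                           partitions={"plausibility": "family1-vs-family2"})

    raise AssertionError("unreachable")


# --------------------------------------------------------------------------
# sweeps, Monte-Carlo validation, splitting
# --------------------------------------------------------------------------

def risk_curve(
    scenario: ScenarioSet,
    n_jitter_draws: int = 4,
    seed: int = 0,
    jitter_sd: float = 2.0,
    partition: Optional[str] = None,
    epoch_grid: Optional[Sequence[float]] = None,
    eta_grid: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Mean +/- sd Laplace-Chernoff risk over jittered designs, per
    (epoch duration, eta) grid point.  Deterministic given the seed."""
    epochs = list(epoch_grid if epoch_grid is not None else scenario.epoch_grid)
    etas = list(eta_grid if eta_grid is not None else scenario.eta_grid)
    rng = np.random.default_rng(seed)
    rows = []
    for eta in etas:
        model_set = scenario.build_model_set(eta)
        if partition is not None:
            labels = getattr(model_set, f"partition_{partition}", None) \
                if not isinstance(partition, dict) else partition
            if labels is None:
                labels = model_set.family_labels
        for epoch in epochs:
            risks = []
            for _ in range(max(n_jitter_draws, 1)):
                dseed = int(rng.integers(0, 2**31 - 1))
                design = scenario.make_design(epoch, jitter_sd=jitter_sd, seed=dseed)
                try:
                    if partition is not None:
                        rep = family_risk(model_set, labels, design)
                    else:
                        rep = laplace_chernoff_risk(model_set, design)
                except Exception as exc:
                    raise RuntimeError(
                        f"risk failed at epoch={epoch}, eta={eta}: {exc}"
                    ) from exc
                risks.append(rep.laplace_chernoff_risk)
            rows.append({
                "epoch_duration": epoch, "eta": eta,
                "risk_mean": float(np.mean(risks)),
                "risk_sd": float(np.std(risks, ddof=1)) if len(risks) > 1 else 0.0,
                "n_draws": len(risks),
            })
    return pd.DataFrame(rows)


@dataclass
class MonteCarloResult:
    """Monte-Carlo estimate of the model selection error rate."""

    n_errors: int
    n_trials: int
    per_cell: pd.DataFrame
    seeds: List[int]
    n_failures: int = 0

    @property
    def error_rate(self) -> float:
        return self.n_errors / self.n_trials

    @property
    def sd(self) -> float:
        p = self.error_rate
        return float(np.sqrt(p * (1 - p) / self.n_trials))

    def to_dict(self) -> dict:
        return {
            "n_errors": self.n_errors,
            "n_trials": self.n_trials,
            "error_rate": self.error_rate,
            "sd": self.sd,
            "n_inversion_failures": self.n_failures,
        }


def monte_carlo_error_rate(
    build_model_set: Callable[[float], ModelSet],
    design: DesignSpec,
    coupling_levels: Sequence[float] = (0.4, 0.8),
    noise_precisions: Sequence[float] = (1.0, 4.0),
    n_noise_reps: int = 8,
    seed: int = 0,
    generating_models: Optional[Sequence[int]] = None,
    inversion_config: Optional[InversionConfig] = None,
    model_specs_for: Optional[Callable[[float], Sequence[DCMSpec]]] = None,
) -> MonteCarloResult:
    """Monte-Carlo estimate of the selection error rate for one design.

    Factorial cells: generating model x coupling level x noise precision x
    noise realization.  Each simulated dataset is inverted under every model
    in the set (variational Laplace, Gamma precision prior with unit shape
    and scale equal to the simulated precision, mirroring the bound
    derivation), the model with the highest free energy is selected, and
    mismatches with the generating model are counted.  Inversion failures
    are counted separately, never silently dropped.
    """
    cfg = inversion_config or InversionConfig()
    rng = np.random.default_rng(seed)
    rows = []
    n_errors = 0
    n_trials = 0
    n_failures = 0
    seeds_used: List[int] = []
    for eta in coupling_levels:
        model_set = build_model_set(eta)
        gen_idx = list(generating_models) if generating_models is not None \
            else list(range(len(model_set)))
        for prec in noise_precisions:
            # condition the bound and the inversion on the simulated precision
            inversion_models = [
                _with_noise_prior(m, (1.0, float(prec))) for m in model_set.models
            ]
            for g in gen_idx:
                cell_err = 0
                cell_n = 0
                for rep in range(n_noise_reps):
                    s = int(rng.integers(0, 2**31 - 1))
                    seeds_used.append(s)
                    gen_model = inversion_models[g]
                    clean = gen_model.evaluate(gen_model.prior_mean, design)
                    noise_rng = np.random.default_rng(s)
                    y = clean + noise_rng.standard_normal(clean.size) / np.sqrt(prec)
                    Fs = []
                    failed = False
                    for m in inversion_models:
                        try:
                            res = invert_vl(m, y, cfg, design=design)
                            Fs.append(res.free_energy)
                        except Exception:
                            logger.exception("inversion failed for %s", m.name)
                            failed = True
                            break
                    if failed:
                        n_failures += 1
                        continue
                    _, selected = model_posterior(Fs, model_set.model_priors)
                    err = int(selected != g)
                    cell_err += err
                    cell_n += 1
                n_errors += cell_err
                n_trials += cell_n
                rows.append({
                    "generating_model": model_set.names[g],
                    "coupling": eta,
                    "noise_precision": prec,
                    "n": cell_n,
                    "n_errors": cell_err,
                    "error_rate": cell_err / cell_n if cell_n else np.nan,
                })
    if n_trials == 0:
        raise RuntimeError("all inversions failed")
    return MonteCarloResult(
        n_errors=n_errors, n_trials=n_trials, per_cell=pd.DataFrame(rows),
        seeds=seeds_used, n_failures=n_failures,
    )


def _with_noise_prior(model, noise_precision_prior):
    from dataclasses import replace
    return replace(model, noise_precision_prior=noise_precision_prior)


def split_analysis(
    dataset,
    design: DesignSpec,
    model_set: ModelSet,
    families: Optional[dict] = None,
    n_splits: int = 1,
    inversion_config: Optional[InversionConfig] = None,
    true_index: Optional[int] = None,
) -> dict:
    """Split the data (and the stimulation sequence) into consecutive
    segments, analyze each independently, and average the posterior
    probability of the wrong selection.

    Each segment is inverted under every model; per-segment model (or
    family) posteriors are derived from the free energies.  When the true
    model or family is known, the average posterior probability assigned to
    the wrong alternative approximates the selection error rate.  The
    Laplace-Chernoff risk of a single segment's design is also reported.
    """
    cfg = inversion_config or InversionConfig()
    n_scans = dataset.n_scans
    seg_len = n_scans // n_splits
    if seg_len * n_splits != n_scans and abs(seg_len * n_splits - n_scans) > 1:
        raise ValueError(
            f"{n_splits} splits do not evenly divide {n_scans} scans"
        )
    if seg_len < 8:
        raise ValueError("segments too short for inversion")
    seg_results = []
    for k in range(n_splits):
        a, b = k * seg_len, (k + 1) * seg_len if k < n_splits - 1 else n_scans
        seg_data = dataset.segment(a, b)
        seg_design = design.segment(a, b)
        Fs = []
        for m in model_set.models:
            res = invert_vl(m, seg_data, cfg, design=seg_design)
            Fs.append(res.free_energy)
        post, selected = model_posterior(Fs, model_set.model_priors)
        entry = {"segment": k, "posteriors": post, "selected": selected}
        if families is not None:
            fam_labels = sorted(set(families.values()))
            fam_post = np.array([
                sum(post[i] for i, lab in families.items() if lab == f)
                for f in fam_labels
            ])
            entry["family_posteriors"] = fam_post
            entry["family_labels"] = fam_labels
            entry["selected_family"] = fam_labels[int(np.argmax(fam_post))]
        seg_results.append(entry)
    out = {"n_splits": n_splits, "segments": seg_results}
    seg_design0 = design.segment(0, seg_len)
    if families is not None:
        out["risk"] = family_risk(model_set, families, seg_design0)
    else:
        out["risk"] = laplace_chernoff_risk(model_set, seg_design0)
    if true_index is not None:
        if families is not None:
            true_fam = families[true_index]
            errs = [1.0 - e["family_posteriors"][e["family_labels"].index(true_fam)]
                    for e in seg_results]
        else:
            errs = [1.0 - e["posteriors"][true_index] for e in seg_results]
        out["average_error_probability"] = float(np.mean(errs))
    else:
        out["average_error_probability"] = float(np.mean(
            [posterior_error_probability(e["posteriors"]) for e in seg_results]
        ))
    return out
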