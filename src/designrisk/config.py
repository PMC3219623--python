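"""Run configuration parsing, report serialization and provenance.

Configs are YAML (JSON is a subset and therefore also accepted).  Every
stochastic operation requires a seed, and every written report carries the
schema version, package version and a hash of the generating config so a
run can be reproduced from its artifacts.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .risk import RiskReport
from .studio import SCENARIO_NAMES, MonteCarloResult
from .vb import InversionResult

__all__ = ["RunConfig", "load_config", "save_config", "write_report",
           "config_hash", "load_model_set"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated configuration of a studio run."""

    seed: int
    scenario: Optional[str] = None
    model_set_path: Optional[str] = None
    epoch_duration: float = 16.0
    session_length: float = 300.0
    tr: float = 1.3
    dt: float = 0.1
    jitter_sd: float = 2.0
    eta: float = 0.5
    n_jitter_draws: int = 4
    noise_precision: float = 1.0
    n_noise_reps: int = 8
    n_splits: int = 1
    tol_free_energy: float = 1e-2
    max_iterations: int = 64
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("a seed is mandatory for any stochastic operation")
        if self.scenario is None and self.model_set_path is None:
            raise ConfigError("provide a scenario name or a model-set path")
        if self.scenario is not None and self.scenario not in SCENARIO_NAMES:
            raise ConfigError(
                f"unknown scenario {self.scenario!r}; "
                f"available: {', '.join(SCENARIO_NAMES)}"
            )
        if self.model_set_path is not None and not Path(self.model_set_path).exists():
            raise ConfigError(f"model-set path does not exist: {self.model_set_path}")
        for key in ("epoch_duration", "session_length", "tr", "dt",
                    "noise_precision"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Unknown keys are rejected with a close-match suggestion; missing optional
    keys take their defaults.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    bad = []
    for key in raw:
        if key not in _FIELDS:
            hint = difflib.get_close_matches(key, _FIELDS, n=1)
            bad.append(f"unknown key {key!r}"
                       + (f" (did you mean {hint[0]!r}?)" if hint else ""))
    if bad:
        raise ConfigError(f"{path}: " + "; ".join(bad))
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(cfg: Optional[RunConfig]) -> dict:
    out = {"schema_version": SCHEMA_VERSION, "package_version": __version__}
    if cfg is not None:
        out["config_hash"] = config_hash(cfg)
        out["seed"] = cfg.seed
    return out


def write_report(result, path, config: Optional[RunConfig] = None) -> Path:
    """Serialize a RiskReport / MonteCarloResult / InversionResult to JSON
    (plus a delimited-text per-cell table for Monte-Carlo results)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = _provenance(config)
    if isinstance(result, RiskReport):
        payload["kind"] = "risk_report"
        payload["risk"] = result.to_dict()
    elif isinstance(result, MonteCarloResult):
        payload["kind"] = "monte_carlo_result"
        payload["monte_carlo"] = result.to_dict()
        table = path.with_suffix(".cells.tsv")
        result.per_cell.to_csv(table, sep="\t", index=False)
        payload["per_cell_table"] = table.name
    elif isinstance(result, InversionResult):
        payload["kind"] = "inversion_result"
        payload["inversion"] = result.to_dict()
    elif isinstance(result, dict):
        payload["kind"] = "generic"
        payload["result"] = _jsonable(result)
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    try:
        path.write_text(json.dumps(payload, indent=2))
    except OSError as exc:
        raise OSError(f"failed writing report to {path}: {exc}") from exc
    return path


def load_model_set(path):
    """Load an explicit DCM comparison set from a YAML/JSON definition.

    Expected layout::

        models:
          - name: fbk+
            A: [[-1.0, 0.5], [0.5, -1.0]]
            B: [[[0, 0], [0, 0]]]          # one matrix per input
            C: [[1.0], [0.0]]
            free_parameters: [[A, 1, 0], [A, 0, 1], [C, 0, 0]]
            prior_variance: 1.0            # optional, default 1
            noise_precision_prior: [1.0, 0.1]   # optional Gamma (shape, scale)
          - ...
        model_priors: [0.5, 0.5]           # optional, default uniform
        families: {fbk+: with, fbk-: without}   # optional, by model name
    """
    from .dcm import DCMSpec, dcm_as_nonlinear_gaussian
    from .models import build_model_set

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "models" not in raw:
        raise ConfigError(f"{path}: expected a mapping with a 'models' list")
    models = []
    for i, entry in enumerate(raw["models"]):
        try:
            spec = DCMSpec(
                A=np.asarray(entry["A"], float),
                B=[np.asarray(b, float) for b in entry.get("B", [])],
                C=np.asarray(entry["C"], float),
                D=[np.asarray(d, float) for d in entry["D"]]
                if entry.get("D") else None,
                free_parameters=[tuple([t[0]] + [int(x) for x in t[1:]])
                                 for t in entry.get("free_parameters", [])],
                name=str(entry.get("name", f"model{i}")),
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(
                f"{path}: model #{i} ({entry.get('name', '?')}): {exc}"
            ) from exc
        models.append(dcm_as_nonlinear_gaussian(
            spec,
            prior_var=float(entry.get("prior_variance", 1.0)),
            noise_precision_prior=tuple(
                entry.get("noise_precision_prior", (1.0, 0.1))
            ),
        ))
    families = None
    if raw.get("families"):
        by_name = {m.name: idx for idx, m in enumerate(models)}
        try:
            families = {by_name[k]: v for k, v in raw["families"].items()}
        except KeyError as exc:
            raise ConfigError(f"{path}: family label for unknown model {exc}")
    return build_model_set(models, priors=raw.get("model_priors"),
                           families=families)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, RiskReport):
        return obj.to_dict()
    return obj
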