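"""Configuration files, output writers, and run manifests.

Config files are flat ``key = value`` text (``#`` comments allowed).
Numeric values accept scientific notation (``n_init = 1e7``).  A
``preset`` key resolves a named literature parameter set; any other
parameter key overrides the corresponding field.  Unknown keys are
rejected with the list of valid keys.

All data files are plain CSV (comma separator, header row, '.' decimal,
no thousands separators); floats are written with 12 significant digits.
Every run writes a JSON manifest with the fully resolved parameters,
seeds, and stop rule, so any output can be regenerated byte-identically.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np

from .params import ModelParams, available_presets, params_to_dict, preset
from .simulate import ReplicateSummary, StopRule, Trajectory

__all__ = [
    "RunConfig",
    "load_config",
    "resolve_params",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_ensemble_csv",
    "write_manifest",
    "format_float",
]

_PARAM_KEYS = {f.name for f in fields(ModelParams)}
_RUN_KEYS = {
    "preset", "method", "replicates", "seed", "out",
    "tau_step", "record_interval", "t_max", "max_events",
    "establishment_threshold", "recurrence_target", "detection_target",
    "standing_variation", "scaled",
}
VALID_KEYS = sorted(_PARAM_KEYS | _RUN_KEYS)

_INT_KEYS = {
    "n_init", "replicates", "seed", "max_events",
    "establishment_threshold", "recurrence_target", "detection_target",
}
_BOOL_KEYS = {"standing_variation", "scaled"}
_STR_KEYS = {"preset", "method", "out"}


@dataclass
class RunConfig:
    """A resolved run configuration (preset + overrides + run options)."""

    preset: Optional[str] = None
    overrides: dict = field(default_factory=dict)
    method: str = "ssa"
    replicates: int = 1
    seed: Optional[int] = None
    out: Optional[str] = None
    tau_step: float = 0.1
    record_interval: Optional[float] = None
    t_max: float = 1e6
    max_events: int = 1_000_000_000
    establishment_threshold: Optional[int] = None
    recurrence_target: Optional[int] = None
    detection_target: Optional[int] = None
    standing_variation: bool = False
    scaled: bool = False

    def stop_rule(self) -> StopRule:
        return StopRule(
            establishment_threshold=self.establishment_threshold,
            recurrence_target=self.recurrence_target,
            detection_target=self.detection_target,
            t_max=self.t_max,
            max_events=self.max_events,
        )

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "overrides"}
        d.update(self.overrides)
        return d


def _coerce(key: str, raw: str):
    if key in _STR_KEYS:
        return raw
    if key in _BOOL_KEYS:
        low = raw.lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
        raise ValueError(f"config key {key!r}: expected a boolean, got {raw!r}")
    try:
        val = float(raw)
    except ValueError:
        raise ValueError(f"config key {key!r}: expected a number, got {raw!r}") from None
    if key in _INT_KEYS:
        if not float(val).is_integer():
            raise ValueError(f"config key {key!r}: expected an integer, got {raw!r}")
        return int(val)
    return val


def _validate_param(key: str, val) -> None:
    if key in ("u", "u_pre", "v", "v_a") and not (0 <= val < 1):
        raise ValueError(f"config key {key!r}: expected a value in [0, 1), got {val}")
    if key in _PARAM_KEYS and key not in ("carrying_capacity",) and val < 0:
        raise ValueError(f"config key {key!r}: expected a nonnegative value, got {val}")


def load_config(path: str) -> RunConfig:
    """Parse a flat key = value config file into a :class:`RunConfig`."""
    cfg = RunConfig()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in _PARAM_KEYS and key not in _RUN_KEYS:
                raise ValueError(
                    f"{path}:{lineno}: unknown key {key!r}; valid keys: {', '.join(VALID_KEYS)}"
                )
            val = _coerce(key, raw)
            if key in _PARAM_KEYS:
                _validate_param(key, val)
                cfg.overrides[key] = val
            else:
                setattr(cfg, key, val)
    return cfg


def resolve_params(cfg: RunConfig) -> ModelParams:
    """Build the ModelParams a config describes (preset + field overrides)."""
    if cfg.preset is not None:
        base = params_to_dict(preset(cfg.preset))
    else:
        base = {}
    base.update(cfg.overrides)
    missing = {"lambda_s", "mu_s", "lambda_a", "mu_a", "lambda_m", "mu_m",
               "u", "v", "c", "n_init"} - set(base)
    if missing:
        raise ValueError(
            f"incomplete parameter set (missing {sorted(missing)}); "
            f"give a preset ({', '.join(available_presets())}) or all rate fields"
        )
    if "n_init" in base:
        base["n_init"] = int(base["n_init"])
    return ModelParams(**base)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def format_float(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return f"{x:.12g}"


def write_trajectory_csv(traj: Trajectory, path: str) -> None:
    """State trajectory as CSV: columns t (days), s, a, m (cells)."""
    with open(path, "w") as fh:
        fh.write("t,s,a,m\n")
        for t, s, a, m in zip(traj.times, traj.s, traj.a, traj.m):
            fh.write(f"{format_float(t)},{int(s)},{int(a)},{int(m)}\n")
        fs = traj.final_state
        if len(traj.times) == 0 or fs.t > traj.times[-1]:
            fh.write(f"{format_float(fs.t)},{fs.s},{fs.a},{fs.m}\n")


def read_trajectory_csv(path: str):
    """Read a trajectory CSV back into a DataFrame (t float; s,a,m int)."""
    import pandas as pd

    return pd.read_csv(path, dtype={"s": np.int64, "a": np.int64, "m": np.int64})


ENSEMBLE_COLUMNS = (
    "replicate", "seed", "outcome", "rescue_time", "recurrence_time",
    "detection_time", "final_s", "final_a", "final_m",
)


def write_ensemble_csv(summaries: Sequence[ReplicateSummary], path: str) -> None:
    """Replicate ensemble as CSV with the nine documented columns."""
    with open(path, "w") as fh:
        fh.write(",".join(ENSEMBLE_COLUMNS) + "\n")
        for r in summaries:
            fh.write(
                f"{r.replicate},{r.seed},{r.outcome},"
                f"{format_float(r.rescue_time)},{format_float(r.recurrence_time)},"
                f"{format_float(r.detection_time)},"
                f"{r.final_s},{r.final_a},{r.final_m}\n"
            )


def write_manifest(record: dict, path: str) -> None:
    """JSON manifest of a run (parameters, seeds, stop rule, versions)."""
    from . import __version__

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    record = dict(record)
    record.setdefault("evorescue_version", __version__)
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=default, allow_nan=True)
        fh.write("\n")
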