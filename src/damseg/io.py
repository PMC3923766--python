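"""Config files, deterministic tabular writers and run manifests.

All outputs are plain text (CSV, TSV, JSON) with fixed column order and
10-significant-digit formatting, so identical data always produces
identical bytes and any published table can be regenerated exactly from
its manifest.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Any, Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import Trajectory
from .params import PARAM_FIELDS, ParameterError

_FMT = "%.10g"

_DEFAULTS = {"mode": "symmetric", "topology": "well_mixed", "seed": 0}
_REQUIRED = ("n", "epsilon", "p", "delta")


def load_config(path: str | Path) -> Dict[str, Any]:
    """Read a flat JSON config keyed by the model parameter names.

    Required keys: n, epsilon, p, delta. Optional keys mode, topology and
    seed default to symmetric / well_mixed / 0. Unknown keys are an error
    (they are almost always typos of real parameters).
    """
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParameterError(f"malformed config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParameterError("config must be a flat JSON object")
    unknown = set(raw) - set(PARAM_FIELDS)
    if unknown:
        raise ParameterError(f"unknown key(s) in config: {sorted(unknown)}")
    missing = set(_REQUIRED) - set(raw)
    if missing:
        raise ParameterError(f"missing required key(s): {sorted(missing)}")
    merged = dict(_DEFAULTS)
    merged.update(raw)
    return {k: merged[k] for k in PARAM_FIELDS}


def write_config(mapping: Mapping[str, Any], path: str | Path) -> None:
    """Write a flat JSON config that :func:`load_config` round-trips."""
    ordered = {k: mapping[k] for k in PARAM_FIELDS if k in mapping}
    Path(path).write_text(json.dumps(ordered, indent=2) + "\n")


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """CSV with columns t, mean_damage, f0 and one column per increment bin."""
    bins = sorted({k for s in traj.stats for k in s.histogram})
    cols = ["t", "mean_damage", "f0"] + [f"x{k}" for k in bins]
    lines = [",".join(cols)]
    for s in traj.stats:
        row = [s.t, s.mean_damage, s.f0] + [s.histogram.get(k, 0.0) for k in bins]
        lines.append(",".join(_FMT % v for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_kymograph(matrix: np.ndarray, path: str | Path) -> None:
    """Tab-separated time-by-position damage matrix (one row per time unit)."""
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    lines = ["\t".join(_FMT % v for v in row) for row in m]
    Path(path).write_text("\n".join(lines) + "\n")


def write_sweep_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Sweep table CSV with stable column order and fixed float format."""
    table.to_csv(path, index=False, float_format=_FMT)


def write_manifest(
    path: str | Path,
    command: str,
    params: Mapping[str, Any],
    outputs: Sequence[str],
    extra: Optional[Mapping[str, Any]] = None,
) -> None:
    """JSON record sufficient to reproduce every listed output exactly."""
    from . import __version__

    manifest = {
        "command": command,
        "params": {k: params.get(k) for k in PARAM_FIELDS if k in params},
        "outputs": list(outputs),
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
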