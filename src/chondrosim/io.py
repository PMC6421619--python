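"""On-disk result layout.

A results directory is self-describing: ``profiles.csv`` holds every stored
profile in long format, ``means.csv`` the spatial-mean time series per field,
``params.json`` the full dimensionless parameter set plus solver metadata,
and ``manifest.json`` lists the files with SHA-256 checksums (the model is
deterministic, so identical configurations produce identical checksums).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from chondrosim.metrics import tbar_to_months
from chondrosim.pde import FIELDS, Trajectory

__all__ = ["write_results", "profiles_frame", "means_frame"]


def profiles_frame(traj: Trajectory) -> pd.DataFrame:
    """Long-format table: time_months, tbar, x, field, value."""
    months = np.asarray(tbar_to_months(traj.times))
    x = traj.grid.x
    rows = []
    for name in FIELDS:
        mat = traj.field_matrix(name)
        for ti, (mo, tb) in enumerate(zip(months, traj.times)):
            rows.append(pd.DataFrame({
                "time_months": mo,
                "tbar": tb,
                "x": x,
                "field": name,
                "value": mat[ti],
            }))
    return pd.concat(rows, ignore_index=True)


def means_frame(traj: Trajectory) -> pd.DataFrame:
    """Wide table of spatial means: one row per stored time, one column per
    field."""
    months = np.asarray(tbar_to_months(traj.times))
    data: dict[str, np.ndarray] = {"time_months": months, "tbar": traj.times}
    for name in FIELDS:
        data[name] = np.trapezoid(traj.field_matrix(name), traj.grid.x, axis=1)
    return pd.DataFrame(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(traj: Trajectory, out_dir: str | Path) -> dict:
    """Write the standard result files and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    profiles_frame(traj).to_csv(out / "profiles.csv", index=False,
                                float_format="%.10g")
    means_frame(traj).to_csv(out / "means.csv", index=False,
                             float_format="%.10g")
    with open(out / "params.json", "w") as fh:
        json.dump({"params": traj.params.to_dict(),
                   "solver_meta": traj.solver_meta},
                  fh, indent=2, sort_keys=True)
        fh.write("\n")

    manifest = {
        "files": {name: _sha256(out / name)
                  for name in ("profiles.csv", "means.csv", "params.json")},
        "n_times": int(len(traj.times)),
        "n_nodes": int(traj.grid.n_nodes),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
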