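"""Serialization: tidy CSV writers/readers, JSON metadata, run records.

Every writer has a matching reader with a lossless 64-bit numeric
round-trip (CSV floats are written with ``repr`` precision).
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .bulk import PyreneCurve
from .kinetics import Trajectory
from .spatial import RadialProfile, SpatialTrajectory

_CSV_KW = dict(index=False, float_format="%.17g")


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> Path:
    """Tidy long format: time_s, species, value, units."""
    path = Path(path)
    traj.to_frame().to_csv(path, **_CSV_KW)
    return path


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_profiles_csv(traj: SpatialTrajectory, path: str | Path) -> Path:
    """Radial profiles: time_s, r_um, barbed_ends_per_um2."""
    path = Path(path)
    traj.to_frame().to_csv(path, **_CSV_KW)
    return path


def read_profiles_csv(path: str | Path) -> list[RadialProfile]:
    df = pd.read_csv(path, float_precision="round_trip")
    profiles = []
    for t, grp in df.groupby("time_s", sort=True):
        grp = grp.sort_values("r_um")
        profiles.append(RadialProfile(grp["r_um"].to_numpy(),
                                      grp["barbed_ends_per_um2"].to_numpy(),
                                      float(t)))
    return profiles


def write_curve_csv(curve: PyreneCurve, path: str | Path) -> Path:
    path = Path(path)
    curve.to_frame().to_csv(path, **_CSV_KW)
    return path


def read_curve_csv(path: str | Path) -> PyreneCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    return PyreneCurve(df["time_s"].to_numpy(), df["f_poly"].to_numpy())


def write_spatial_h5(traj: SpatialTrajectory, path: str | Path) -> Path:
    """HDF5 container: named arrays plus attribute metadata."""
    import h5py
    from .spatial import FIELDS
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=traj.times)
        f.create_dataset("bulk", data=traj.bulk)
        f.create_dataset("fields", data=traj.fields)
        f.create_dataset("radii", data=traj.grid.centers)
        f.attrs["field_names"] = list(FIELDS)
        f.attrs["bulk_names"] = ["G", "P", "Arp_inactive", "CP_free"]
        f.attrs["r_max_um"] = traj.grid.r_max_um
        f.attrs["volume_um3"] = traj.volume_um3
        f.attrs["version"] = __version__
    return path


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json(data: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(data), indent=2, sort_keys=True))
    return path


@dataclasses.dataclass
class RunRecord:
    """Provenance of one run: enough to re-execute it byte-identically."""

    subcommand: str
    config: dict[str, Any]
    seed: int | None
    outputs: list[str]
    wall_time_s: float
    version: str = __version__
    platform: str = dataclasses.field(default_factory=platform.platform)

    def write(self, path: str | Path) -> Path:
        return write_json(dataclasses.asdict(self), path)


class Stopwatch:
    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.elapsed = time.perf_counter() - self.t0
        return False
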