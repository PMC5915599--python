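"""Run configuration: a flat YAML file with dotted key groups.

Recognized groups (all keys optional; defaults are the calibrated package
defaults):

* ``rates.*``           — kinetic constants (µM⁻¹s⁻¹ / s⁻¹), delta_nm (nm),
                          c_crit (µM), eta_seed_membrane, K_nuc_G_uM (µM)
* ``concentrations.*``  — actin_uM, vca_uM, arp_uM, profilin_uM (µM), cp_nM (nM)
* ``geometry.*``        — R_vesicle_um, shell_thickness_um (µm)
* ``spatial.*``         — alpha_spread, ell_step_um, D_VCA_um2_s,
                          D_Arp_star_um2_s, N_domains, seed_radius_um,
                          seed_density_per_um2, r_max_um, n_cells, t_end_s
* ``ratchet.*``         — F_mem_pN_per_um2, ratio_threshold, speed_threshold_frac
* ``bulk.*``            — t_end_s, noise_sd, smooth_window
* ``ensemble.*``        — EnsembleConfig fields plus n, cp_nominal_nM, mode
* ``solver.*``          — rtol, atol
* ``io.*``              — write_hdf5 (bool)

Unknown keys are rejected with an error naming the key.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .ensemble import EnsembleConfig
from .params import Concentrations, Geometry, RateParams
from .spatial import RadialGrid, SpatialParams


class ConfigError(ValueError):
    """Malformed configuration: parse failure, unknown key or bad value."""


@dataclass(frozen=True)
class SolverConfig:
    rtol: float = 1e-8
    atol: float = 1e-10
    spatial_rtol: float = 1e-6
    spatial_atol: float = 1e-9


@dataclass(frozen=True)
class RatchetConfig:
    F_mem_pN_per_um2: float = 15.0
    ratio_threshold: float = 1.5
    speed_threshold_frac: float = 0.1


@dataclass(frozen=True)
class BulkConfig:
    t_end_s: float = 2400.0
    noise_sd: float = 0.0
    smooth_window: int = 21


@dataclass(frozen=True)
class EnsembleRunConfig:
    n: int = 12
    cp_nominal_nM: float = 40.0
    mode: str = "full_spatial"


@dataclass(frozen=True)
class IOConfig:
    write_hdf5: bool = False


@dataclass(frozen=True)
class SpatialRunConfig:
    """SpatialParams plus grid and horizon (flattened under spatial.*)."""

    params: SpatialParams = field(default_factory=SpatialParams)
    r_max_um: float = 5.0
    n_cells: int = 128
    t_end_s: float = 120.0

    @property
    def grid(self) -> RadialGrid:
        return RadialGrid(self.r_max_um, self.n_cells)


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of every module's parameters."""

    rates: RateParams = field(default_factory=RateParams)
    concentrations: Concentrations = field(default_factory=Concentrations)
    geometry: Geometry = field(default_factory=Geometry)
    spatial: SpatialRunConfig = field(default_factory=SpatialRunConfig)
    ratchet: RatchetConfig = field(default_factory=RatchetConfig)
    bulk: BulkConfig = field(default_factory=BulkConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    ensemble_run: EnsembleRunConfig = field(default_factory=EnsembleRunConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    io: IOConfig = field(default_factory=IOConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_SPATIAL_EXTRA = {"r_max_um", "n_cells", "t_end_s"}
_ENSEMBLE_RUN = {"n", "cp_nominal_nM", "mode"}


def _build(cls, group: str, values: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    bad = set(values) - names
    if bad:
        raise ConfigError(f"unknown key {group}.{sorted(bad)[0]}")
    try:
        return cls(**values)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in group '{group}': {exc}") from exc


def load_config(path: str | Path | None = None,
                overrides: dict[str, Any] | None = None) -> RunConfig:
    """Load and validate a YAML config; ``None`` or an empty file gives the
    all-defaults configuration.  ``overrides`` maps dotted keys
    (e.g. ``"concentrations.cp_nM"``) to values and is applied last."""
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"top level of {path} must be a mapping")
        raw = loaded
    groups: dict[str, dict[str, Any]] = {}
    for key, val in raw.items():
        if isinstance(val, dict):        # nested style: {rates: {k_cap: ..}}
            groups.setdefault(key, {}).update(val)
        elif "." in key:                 # flat style: {"rates.k_cap": ..}
            g, k = key.split(".", 1)
            groups.setdefault(g, {})[k] = val
        else:
            raise ConfigError(f"unknown key {key}")
    for dotted, val in (overrides or {}).items():
        if "." not in dotted:
            raise ConfigError(f"override {dotted!r} must be group.key")
        g, k = dotted.split(".", 1)
        groups.setdefault(g, {})[k] = val

    known = {"rates", "concentrations", "geometry", "spatial", "ratchet",
             "bulk", "ensemble", "solver", "io"}
    bad = set(groups) - known
    if bad:
        raise ConfigError(f"unknown key group {sorted(bad)[0]}")

    sp_raw = dict(groups.get("spatial", {}))
    sp_extra = {k: sp_raw.pop(k) for k in list(sp_raw) if k in _SPATIAL_EXTRA}
    ens_raw = dict(groups.get("ensemble", {}))
    ens_run = {k: ens_raw.pop(k) for k in list(ens_raw) if k in _ENSEMBLE_RUN}

    return RunConfig(
        rates=_build(RateParams, "rates", groups.get("rates", {})),
        concentrations=_build(Concentrations, "concentrations",
                              groups.get("concentrations", {})),
        geometry=_build(Geometry, "geometry", groups.get("geometry", {})),
        spatial=SpatialRunConfig(
            params=_build(SpatialParams, "spatial", sp_raw),
            **sp_extra),
        ratchet=_build(RatchetConfig, "ratchet", groups.get("ratchet", {})),
        bulk=_build(BulkConfig, "bulk", groups.get("bulk", {})),
        ensemble=_build(EnsembleConfig, "ensemble", ens_raw),
        ensemble_run=_build(EnsembleRunConfig, "ensemble", ens_run),
        solver=_build(SolverConfig, "solver", groups.get("solver", {})),
        io=_build(IOConfig, "io", groups.get("io", {})),
    )
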