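"""Effective-2D (radially symmetric) spatial growth of a single actin domain.

A membrane patch of radius ``r_max`` carries six laterally resolved fields
(the three VCA states, Arp*, free and capped barbed ends) on an annular
finite-volume grid, coupled to a well-stirred finite bulk reservoir
(G-actin, Arp2/3, CP) that all membrane sites share.  Barbed ends perform a
diffusive random walk whose diffusivity is proportional to the local
polymerization speed; VCA and Arp* diffuse with ordinary membrane-protein
mobility.  Domain competition is represented by giving each domain an equal
share of the depleting pools (see :func:`domain_competition`).

The canonical pattern runs (:func:`pattern_run`) reproduce the CP-dependent
radial patterns: a flat profile at 40 nM CP, a double-peaked (rim-dominant)
profile at 80 nM, and a flat low-density profile at 120 nM where many
competing domains starve each other of monomer.  The rim pattern is a
transient of the growth process — a polymerization wave burning through the
accumulated Arp* stock — so the canonical classification snapshot is taken
at 25 s, while the domain is spreading.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.integrate import solve_ivp

from .kinetics import IntegrationError, PoolState
from .params import (Concentrations, Geometry, N_PER_UM3_PER_UM,
                     ParameterError, RateParams)

FIELDS = ("VCA_free", "VCA_G", "VCA_spent", "Arp_star", "B", "B_capped")
_F = {name: i for i, name in enumerate(FIELDS)}
BULK_FIELDS = ("G", "P", "Arp_inactive", "CP_free")


class ProfileError(ValueError):
    """Raised for degenerate density profiles (no support, never spread)."""


@dataclass(frozen=True)
class RadialGrid:
    """Uniform annular finite-volume grid on [0, r_max)."""

    r_max_um: float = 5.0
    n_cells: int = 128

    def __post_init__(self) -> None:
        if self.n_cells < 32:
            raise ParameterError("n_cells must be >= 32")
        if self.r_max_um <= 0:
            raise ParameterError("r_max_um must be > 0")

    @property
    def dr(self) -> float:
        return self.r_max_um / self.n_cells

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.r_max_um, self.n_cells + 1)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def areas(self) -> np.ndarray:
        e = self.edges
        return np.pi * (e[1:] ** 2 - e[:-1] ** 2)


@dataclass(frozen=True)
class SpatialParams:
    """Lateral-transport parameters of the domain simulation.

    ``alpha_spread`` couples the barbed-end random walk to growth:
    D_B = alpha_spread * v_pol * ell_step_um, with ``ell_step_um`` the step
    length of the walk (of order a filament length).  ``N_domains`` splits
    the vesicle reservoir between competing domains.
    """

    alpha_spread: float = 0.45
    ell_step_um: float = 0.3
    D_VCA_um2_s: float = 0.5
    D_Arp_star_um2_s: float = 0.2
    N_domains: int = 1
    seed_radius_um: float = 0.2
    seed_density_per_um2: float = 20.0

    def __post_init__(self) -> None:
        if self.alpha_spread < 0:
            raise ParameterError("alpha_spread must be >= 0")
        if self.N_domains < 1:
            raise ParameterError("N_domains must be >= 1")
        if self.seed_radius_um <= 0 or self.seed_density_per_um2 < 0:
            raise ParameterError("invalid seed parameters")

    def with_(self, **kw) -> "SpatialParams":
        return replace(self, **kw)


@dataclass
class FieldState:
    """Membrane fields (per cell) plus the shared bulk pools."""

    fields: np.ndarray          # (6, n_cells), µm⁻²
    bulk: np.ndarray            # (4,), µM: G, P, Arp_inactive, CP_free
    volume_um3: float           # reservoir volume backing the bulk pools

    def field(self, name: str) -> np.ndarray:
        return self.fields[_F[name]]


@dataclass
class RadialProfile:
    """Barbed-end areal density versus radius at one time point."""

    radii: np.ndarray
    density: np.ndarray
    time: float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.radii) > 0):
            raise ValueError("radii must be strictly increasing")


def domain_competition(conc: Concentrations, n_domains: int) -> Concentrations:
    """Partition the depleting pools equally between ``n_domains`` domains.

    The actin-monomer and Arp2/3 pools are divided by the domain count
    (each domain effectively polymerizes from a 1/N share of the
    reservoir); the CP and VCA concentrations are left untouched — capping
    is driven by the instantaneous CP concentration, which is common to
    every domain, and VCA is a surface density, not a consumable pool.
    """
    if n_domains < 1:
        raise ParameterError("n_domains must be >= 1")
    return conc.with_(actin_uM=conc.actin_uM / n_domains,
                      arp_uM=conc.arp_uM / n_domains)


def initial_fields(conc: Concentrations, geometry: Geometry, grid: RadialGrid,
                   params: SpatialParams) -> FieldState:
    """Uniform membrane-loaded VCA, a seeded barbed-end disc, fresh bulk.

    With ``N_domains > 1`` the depleting pools are first partitioned via
    :func:`domain_competition`.
    """
    conc = domain_competition(conc, params.N_domains)
    n = grid.n_cells
    fields = np.zeros((len(FIELDS), n))
    fields[_F["VCA_free"]] = geometry.areal_total_per_um2(conc.vca_uM)
    seeded = grid.centers <= params.seed_radius_um
    if not seeded.any():
        seeded = np.zeros(n, bool)
        seeded[0] = True
    fields[_F["B"], seeded] = params.seed_density_per_um2
    bulk = np.array([conc.actin_uM, 0.0, conc.arp_uM, conc.cp_uM])
    return FieldState(fields, bulk, geometry.volume_um3)


class _RHS:
    """Method-of-lines right-hand side with cached geometry factors."""

    def __init__(self, rates: RateParams, sp: SpatialParams,
                 geometry: Geometry, grid: RadialGrid, volume_um3: float):
        self.p = rates
        self.sp = sp
        self.grid = grid
        self.n = grid.n_cells
        self.areas = grid.areas
        self.dr = grid.dr
        self.face_circ = 2.0 * np.pi * grid.edges[1:-1]   # interior faces
        self.inv_bulk = 1.0 / (volume_um3 * N_PER_UM3_PER_UM)
        self.k2_branch = rates.k_branch / geometry.k2d_factor

    def diffuse(self, u: np.ndarray, D: float) -> np.ndarray:
        if D <= 0:
            return np.zeros_like(u)
        grad = (u[1:] - u[:-1]) / self.dr
        flux = D * self.face_circ * grad          # inward-positive convention
        out = np.zeros_like(u)
        out[:-1] += flux / self.areas[:-1]
        out[1:] -= flux / self.areas[1:]
        return out

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.p
        n = self.n
        bulk = np.maximum(y[:4], 0.0)
        f = np.maximum(y[4:].reshape(len(FIELDS), n), 0.0)
        G, P_bulk, Arp, CP = bulk
        Vf, Vg, Vs, Astar, B, _ = f

        s_nuc = p.nucleation_monomer_factor(G)
        r_bind = p.k_bind_VG * G * Vf
        r_act = p.k_act * Arp * Vg
        r_seed = p.k_seed * p.eta_seed_membrane * s_nuc * Astar
        r_branch = self.k2_branch * s_nuc * Astar * B
        r_elong = p.k_elong * (G - p.c_crit) * B
        if G < p.c_crit and P_bulk <= 0.0:
            r_elong = np.maximum(r_elong, 0.0)     # nothing to depolymerize
        r_cap = p.k_cap * CP * B
        r_regen = p.k_regen * Vs

        df = np.empty_like(f)
        df[_F["VCA_free"]] = -r_bind + r_regen
        df[_F["VCA_G"]] = r_bind - r_act
        df[_F["VCA_spent"]] = r_act - r_regen
        df[_F["Arp_star"]] = r_act - r_seed - r_branch
        df[_F["B"]] = r_seed + r_branch - r_cap
        df[_F["B_capped"]] = r_cap

        v_pol = p.v_free_um_s(G)
        D_B = self.sp.alpha_spread * v_pol * self.sp.ell_step_um
        df[_F["B"]] += self.diffuse(B, D_B)
        df[_F["Arp_star"]] += self.diffuse(Astar, self.sp.D_Arp_star_um2_s)
        for name in ("VCA_free", "VCA_G", "VCA_spent"):
            df[_F[name]] += self.diffuse(f[_F[name]], self.sp.D_VCA_um2_s)

        a = self.areas
        dbulk = np.array([
            self.inv_bulk * np.sum(a * (-r_bind + r_act - r_elong)),
            self.inv_bulk * np.sum(a * r_elong),
            self.inv_bulk * np.sum(a * (-r_act)),
            self.inv_bulk * np.sum(a * (-r_cap)),
        ])
        return np.concatenate([dbulk, df.ravel()])

    def sparsity(self) -> sparse.csr_matrix:
        nf = len(FIELDS)
        n = self.n
        size = 4 + nf * n
        rows, cols = [], []

        def add(r, c):
            rows.append(r)
            cols.append(c)

        for r in range(4):
            for c in range(size):
                add(r, c)
        for fi in range(nf):
            for i in range(n):
                r = 4 + fi * n + i
                for c in range(4):
                    add(r, c)
                for fj in range(nf):          # same-cell reaction coupling
                    add(r, 4 + fj * n + i)
                for j in (i - 1, i + 1):      # diffusion stencil
                    if 0 <= j < n:
                        add(r, 4 + fi * n + j)
        data = np.ones(len(rows))
        return sparse.csr_matrix((data, (rows, cols)), shape=(size, size))


@dataclass
class SpatialTrajectory:
    """Sequence of field states at the requested output times."""

    times: np.ndarray                 # (nt,)
    bulk: np.ndarray                  # (nt, 4)
    fields: np.ndarray                # (nt, 6, n_cells)
    grid: RadialGrid
    geometry: Geometry
    params: SpatialParams
    rates: RateParams
    volume_um3: float

    def state(self, k: int) -> FieldState:
        return FieldState(self.fields[k], self.bulk[k], self.volume_um3)

    def profile(self, k: int) -> RadialProfile:
        return RadialProfile(self.grid.centers.copy(),
                             self.fields[k, _F["B"]].copy(),
                             float(self.times[k]))

    def integrated_B(self) -> np.ndarray:
        """Total free barbed ends in the domain at each output time."""
        return self.fields[:, _F["B"], :] @ self.grid.areas

    def bulk_series(self, name: str) -> np.ndarray:
        return self.bulk[:, BULK_FIELDS.index(name)]

    def conservation_residuals(self) -> dict[str, float]:
        a = self.grid.areas
        inv = 1.0 / (self.volume_um3 * N_PER_UM3_PER_UM)

        def mem(name):
            return (self.fields[:, _F[name], :] @ a) * inv

        G, P = self.bulk[:, 0], self.bulk[:, 1]
        Arp, CP = self.bulk[:, 2], self.bulk[:, 3]
        totals = {
            "actin": G + P + mem("VCA_G"),
            "cp": CP + mem("B_capped"),
            "vca": mem("VCA_free") + mem("VCA_G") + mem("VCA_spent"),
            "arp": Arp + mem("Arp_star") + mem("B") + mem("B_capped"),
        }
        # zero-total laws are judged against 1% of the system scale
        scale = max(max(abs(v[0]) for v in totals.values()), 1e-6)
        return {k: float(np.max(np.abs(v - v[0]))
                         / max(abs(v[0]), 0.01 * scale))
                for k, v in totals.items()}

    def to_frame(self) -> pd.DataFrame:
        """Tidy profile table: time_s, r_um, barbed_ends_per_um2."""
        nt, n = self.fields.shape[0], self.grid.n_cells
        return pd.DataFrame({
            "time_s": np.repeat(self.times, n),
            "r_um": np.tile(self.grid.centers, nt),
            "barbed_ends_per_um2": self.fields[:, _F["B"], :].ravel(),
        })


def integrate_spatial(params: SpatialParams, rates: RateParams,
                      init: FieldState, grid: RadialGrid, geometry: Geometry,
                      t_end: float, output_times: Sequence[float] | None = None,
                      rtol: float = 1e-6, atol: float = 1e-9
                      ) -> SpatialTrajectory:
    """Integrate the radial domain model to ``t_end`` (stiff BDF, sparse
    Jacobian).  Conservation of every pool is checked to 1e-5 relative."""
    if output_times is None:
        output_times = np.linspace(0.0, t_end, 61)
    output_times = np.asarray(output_times, float)
    rhs = _RHS(rates, params, geometry, grid, init.volume_um3)
    y0 = np.concatenate([init.bulk, init.fields.ravel()])
    sol = solve_ivp(rhs, (0.0, float(t_end)), y0, method="BDF",
                    t_eval=output_times, rtol=rtol, atol=atol,
                    jac_sparsity=rhs.sparsity())
    if not sol.success:
        raise IntegrationError(f"spatial solver failed: {sol.message}")
    nt = len(output_times)
    states = np.maximum(sol.y.T, 0.0)
    traj = SpatialTrajectory(
        times=output_times,
        bulk=states[:, :4],
        fields=states[:, 4:].reshape(nt, len(FIELDS), grid.n_cells),
        grid=grid, geometry=geometry, params=params, rates=rates,
        volume_um3=init.volume_um3,
    )
    worst = max(traj.conservation_residuals().values())
    if worst > 1e-5:
        raise IntegrationError(
            f"spatial conservation drift {worst:.2e} exceeds 1e-5")
    return traj


def run_domain(conc: Concentrations, rates: RateParams | None = None,
               geometry: Geometry | None = None,
               spatial: SpatialParams | None = None,
               grid: RadialGrid | None = None, t_end: float = 120.0,
               output_times: Sequence[float] | None = None,
               ) -> SpatialTrajectory:
    """Convenience wrapper: default-calibrated single-domain simulation."""
    rates = rates or RateParams()
    geometry = geometry or Geometry()
    spatial = spatial or SpatialParams()
    grid = grid or RadialGrid()
    init = initial_fields(conc, geometry, grid, spatial)
    return integrate_spatial(spatial, rates, init, grid, geometry,
                             t_end, output_times)


#: classification snapshot time of the canonical pattern runs (s)
PATTERN_SNAPSHOT_S = 25.0


def default_n_domains(cp_nM: float) -> int:
    """Calibrated default domain count: a single domain below ~100 nM CP,
    several competing domains above (nucleation at multiple sites)."""
    return 1 if cp_nM < 100.0 else 6


def pattern_run(cp_nM: float, rates: RateParams | None = None,
                geometry: Geometry | None = None,
                grid: RadialGrid | None = None,
                n_domains: int | None = None,
                t_end: float = PATTERN_SNAPSHOT_S) -> SpatialTrajectory:
    """Canonical CP-dependent pattern run (finite pools, default calibration).

    Classify the final profile with :func:`classify_profile` to obtain the
    flat / double-peaked / flat sequence across 40 / 80 / 120 nM CP.
    """
    conc = Concentrations(cp_nM=cp_nM)
    spatial = SpatialParams(N_domains=n_domains if n_domains is not None
                            else default_n_domains(cp_nM))
    return run_domain(conc, rates=rates, geometry=geometry, spatial=spatial,
                      grid=grid, t_end=t_end,
                      output_times=np.linspace(0.0, t_end, 26))


# -- profile diagnostics ----------------------------------------------


def _occupancy(profile: RadialProfile, support_frac: float = 0.05
               ) -> np.ndarray:
    peak = profile.density.max()
    if peak <= 0:
        raise ProfileError("profile has no support")
    return profile.density >= support_frac * peak


def _band_means(profile: RadialProfile,
                center_band: tuple[float, float],
                rim_band: tuple[float, float]) -> tuple[float, float]:
    """Mean density over the central and rim bands, as fractions of the
    occupied radius.  Empty bands fall back to the nearest single cell so
    tiny occupied regions remain classifiable."""
    occ = _occupancy(profile)
    r_occ = profile.radii[occ].max()
    r = profile.radii
    center = (r >= center_band[0] * r_occ) & (r <= center_band[1] * r_occ)
    rim = (r >= rim_band[0] * r_occ) & (r <= rim_band[1] * r_occ)
    if not center.any():
        center = r <= r[0]
    if not rim.any():
        i = int(np.argmin(np.abs(r - 0.5 * (rim_band[0] + rim_band[1]) * r_occ)))
        rim = np.zeros_like(center)
        rim[i] = True
    return float(profile.density[center].mean()), \
        float(profile.density[rim].mean())


def classify_profile(profile: RadialProfile, ratio_threshold: float = 1.5,
                     center_band: tuple[float, float] = (0.0, 0.3),
                     rim_band: tuple[float, float] = (0.6, 0.95)) -> str:
    """``"double_peaked"`` if the rim band carries more than
    ``ratio_threshold`` times the central density, else ``"flat"``.

    Bands are fractions of the occupied radius (outermost radius whose
    density is at least 5% of the profile peak).
    """
    c_mean, r_mean = _band_means(profile, center_band, rim_band)
    if c_mean <= 0:
        return "double_peaked" if r_mean > 0 else "flat"
    return "double_peaked" if r_mean / c_mean > ratio_threshold else "flat"


def rim_center_ratio(profile: RadialProfile,
                     center_band: tuple[float, float] = (0.0, 0.3),
                     rim_band: tuple[float, float] = (0.6, 0.95)) -> float:
    """Rim-band to centre-band mean-density ratio (inf for a hollow ring)."""
    c_mean, r_mean = _band_means(profile, center_band, rim_band)
    return float(r_mean / c_mean) if c_mean > 0 else float("inf")


def flatness_time(traj: SpatialTrajectory, cv_threshold: float = 0.10,
                  support_frac: float = 0.05, min_spread: float = 0.5
                  ) -> float:
    """Earliest output time at which the density over the occupied region
    (the full disc out to the support radius, excluding the outermost 10%)
    has a coefficient of variation below ``cv_threshold``.  Interior holes
    count, so a hollow ring is never flat.  NaN if never; raises
    :class:`ProfileError` if the support never extends past ``min_spread``
    of the patch radius."""
    spread_seen = False
    result = float("nan")
    for k in range(len(traj.times)):
        prof = traj.profile(k)
        peak = prof.density.max()
        if peak <= 0:
            continue
        occ = prof.density >= support_frac * peak
        r_occ = prof.radii[occ].max()
        if r_occ <= min_spread * traj.grid.r_max_um:
            continue
        spread_seen = True
        core = prof.radii <= 0.9 * r_occ
        vals = prof.density[core]
        if len(vals) < 2 or vals.mean() <= 0:
            continue
        cv = vals.std() / vals.mean()
        if cv < cv_threshold and np.isnan(result):
            result = float(traj.times[k])
    if not spread_seen:
        raise ProfileError("domain never spread over the membrane patch")
    return result
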