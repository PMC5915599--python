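"""Well-mixed kinetics of membrane-localized, CP-regulated dendritic nucleation.

The model is a system of consecutive elementary reactions: membrane-bound
VCA loads an actin monomer, activates Arp2/3 complex to Arp*, Arp* either
seeds a first filament or branches off an existing barbed end, barbed ends
elongate from the monomer pool and are terminated by capping protein, and
spent VCA slowly regenerates.  Barbed ends are tracked as an areal density
at the membrane; bulk pools (G-actin, Arp2/3, CP) either deplete (finite
reservoir) or are clamped (infinite reservoir).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import Concentrations, Geometry, ParameterError, RateParams

SPECIES = ("G", "P", "Arp_inactive", "CP_free",
           "VCA_free", "VCA_G", "VCA_spent", "Arp_star", "B", "B_capped")
BULK = (0, 1, 2, 3)        # µM (or everything, in solution mode)
MEMBRANE = (4, 5, 6, 7, 8, 9)
_IDX = {name: i for i, name in enumerate(SPECIES)}

ReservoirMode = Literal["finite", "infinite"]


class IntegrationError(RuntimeError):
    """Stiff solver failed or produced an invariant-violating trajectory."""


class ConvergenceError(RuntimeError):
    """No steady state found within the iteration budget."""


class ReactionNetwork:
    """Stoichiometry and rate laws of the seven-reaction network.

    Parameters
    ----------
    params
        Rate constants.
    geometry
        Vesicle geometry; sets the µM ↔ µm⁻² conversion.  Ignored in
        solution mode (conversion factor 1).
    reservoir_mode
        ``"finite"``: bulk pools deplete.  ``"infinite"``: G, CP_free and
        Arp_inactive are held constant (zero net stoichiometry); P and
        B_capped then act as cumulative counters.
    localization
        ``"membrane"`` (default): VCA species and Arp*, B are areal
        densities.  ``"solution"``: every species is a bulk concentration
        (the pyrene-assay geometry, no membrane).
    volume_um3
        Override the reservoir volume (used by domain competition, where
        several domains split one vesicle volume).  Defaults to the vesicle
        volume from ``geometry``.
    """

    def __init__(self, params: RateParams, geometry: Geometry,
                 reservoir_mode: ReservoirMode = "finite",
                 localization: Literal["membrane", "solution"] = "membrane",
                 volume_um3: float | None = None) -> None:
        if reservoir_mode not in ("finite", "infinite"):
            raise ValueError(f"unknown reservoir_mode {reservoir_mode!r}")
        if localization not in ("membrane", "solution"):
            raise ValueError(f"unknown localization {localization!r}")
        self.params = params
        self.geometry = geometry
        self.reservoir_mode = reservoir_mode
        self.localization = localization
        self.volume_um3 = geometry.volume_um3 if volume_um3 is None else float(volume_um3)
        if self.volume_um3 <= 0:
            raise ParameterError("reservoir volume must be > 0")

        if localization == "solution":
            self.conv = 1.0          # everything in µM
            self._k_branch_eff = params.k_branch
            self._k_seed_eff = params.k_seed
        else:
            from .params import N_PER_UM3_PER_UM
            self.conv = geometry.area_um2 / (self.volume_um3 * N_PER_UM3_PER_UM)
            self._k_branch_eff = params.k_branch / geometry.k2d_factor
            self._k_seed_eff = params.k_seed * params.eta_seed_membrane
        self.S = self._stoichiometry()

    # -- construction -------------------------------------------------

    def _stoichiometry(self) -> np.ndarray:
        c = self.conv
        S = np.zeros((len(SPECIES), 7))
        i = _IDX
        # r0: VCA + G -> VCA·G
        S[i["VCA_free"], 0] = -1.0
        S[i["VCA_G"], 0] = 1.0
        S[i["G"], 0] = -c
        # r1: VCA·G + Arp -> Arp* + VCA_spent + G
        S[i["VCA_G"], 1] = -1.0
        S[i["VCA_spent"], 1] = 1.0
        S[i["Arp_star"], 1] = 1.0
        S[i["Arp_inactive"], 1] = -c
        S[i["G"], 1] = c
        # r2: Arp* -> B (seeding)
        S[i["Arp_star"], 2] = -1.0
        S[i["B"], 2] = 1.0
        # r3: Arp* + B -> 2B (branching)
        S[i["Arp_star"], 3] = -1.0
        S[i["B"], 3] = 1.0
        # r4: elongation, G -> P per barbed end
        S[i["G"], 4] = -c
        S[i["P"], 4] = c
        # r5: B + CP -> B_capped
        S[i["B"], 5] = -1.0
        S[i["B_capped"], 5] = 1.0
        S[i["CP_free"], 5] = -c
        # r6: VCA_spent -> VCA_free
        S[i["VCA_spent"], 6] = -1.0
        S[i["VCA_free"], 6] = 1.0
        if self.reservoir_mode == "infinite":
            for sp in ("G", "CP_free", "Arp_inactive"):
                S[i[sp], :] = 0.0
        return S

    # -- rate laws -----------------------------------------------------

    def rates(self, y: np.ndarray) -> np.ndarray:
        """The seven reaction rates at state ``y`` (areal units in
        membrane mode, µM/s in solution mode).  Species are clamped at
        zero so that small negative solver excursions stay harmless."""
        p = self.params
        yc = np.maximum(y, 0.0)
        G, P, Arp, CP, Vf, Vg, Vs, Astar, B, _ = yc
        s_nuc = p.nucleation_monomer_factor(G)
        r_elong = p.k_elong * (G - p.c_crit) * B   # signed: net elongation
        if r_elong < 0.0 and P <= 0.0:
            r_elong = 0.0                          # nothing to depolymerize
        return np.array([
            p.k_bind_VG * G * Vf,
            p.k_act * Arp * Vg,
            self._k_seed_eff * s_nuc * Astar,
            self._k_branch_eff * s_nuc * Astar * B,
            r_elong,
            p.k_cap * CP * B,
            p.k_regen * Vs,
        ])

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.S @ self.rates(y)

    # -- initial conditions & bookkeeping ------------------------------

    def initial_state(self, conc: Concentrations) -> "PoolState":
        y = np.zeros(len(SPECIES))
        y[_IDX["G"]] = conc.actin_uM
        y[_IDX["Arp_inactive"]] = conc.arp_uM
        y[_IDX["CP_free"]] = conc.cp_uM
        if self.localization == "membrane":
            y[_IDX["VCA_free"]] = conc.vca_uM / self.conv
        else:
            y[_IDX["VCA_free"]] = conc.vca_uM
        return PoolState.from_array(y, self)

    def totals(self, y: np.ndarray) -> dict[str, float]:
        """Conserved totals in µM-equivalents."""
        c = self.conv
        i = _IDX
        return {
            "actin": y[i["G"]] + y[i["P"]] + c * y[i["VCA_G"]],
            "cp": y[i["CP_free"]] + c * y[i["B_capped"]],
            "vca": c * (y[i["VCA_free"]] + y[i["VCA_G"]] + y[i["VCA_spent"]]),
            "arp": y[i["Arp_inactive"]]
                   + c * (y[i["Arp_star"]] + y[i["B"]] + y[i["B_capped"]]),
        }


def build_network(params: RateParams, geometry: Geometry,
                  reservoir_mode: ReservoirMode = "finite",
                  localization: Literal["membrane", "solution"] = "membrane",
                  volume_um3: float | None = None) -> ReactionNetwork:
    """Assemble the branching/capping reaction network."""
    return ReactionNetwork(params, geometry, reservoir_mode,
                           localization, volume_um3)


@dataclass
class PoolState:
    """Instantaneous amounts of every species (units per network mode)."""

    G: float
    P: float
    Arp_inactive: float
    CP_free: float
    VCA_free: float
    VCA_G: float
    VCA_spent: float
    Arp_star: float
    B: float
    B_capped: float

    @classmethod
    def from_array(cls, y: Sequence[float], network: ReactionNetwork | None = None
                   ) -> "PoolState":
        return cls(*[float(v) for v in y])

    def to_array(self) -> np.ndarray:
        return np.array([self.G, self.P, self.Arp_inactive, self.CP_free,
                         self.VCA_free, self.VCA_G, self.VCA_spent,
                         self.Arp_star, self.B, self.B_capped])


@dataclass
class Trajectory:
    """Time series of pool states plus derived branching/capping rates."""

    times: np.ndarray              # (n,)
    states: np.ndarray             # (n, n_species)
    network: ReactionNetwork

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __getitem__(self, species: str) -> np.ndarray:
        return self.states[:, _IDX[species]]

    @property
    def B(self) -> np.ndarray:
        return self["B"]

    @property
    def branch_rate(self) -> np.ndarray:
        return np.array([self.network.rates(y)[3] for y in self.states])

    @property
    def cap_rate(self) -> np.ndarray:
        return np.array([self.network.rates(y)[5] for y in self.states])

    def state_at(self, k: int) -> PoolState:
        return PoolState.from_array(self.states[k], self.network)

    def conservation_residuals(self) -> dict[str, float]:
        """Max relative drift of each conserved total along the trajectory
        (finite mode; in infinite mode only VCA is conserved)."""
        tot = [self.network.totals(y) for y in self.states]
        keys = ("vca",) if self.network.reservoir_mode == "infinite" else \
               ("actin", "cp", "vca", "arp")
        out = {}
        scale = max(max(abs(tot[0][k]) for k in keys), 1e-6)
        for k in keys:
            series = np.array([t[k] for t in tot])
            # zero-total laws are judged against 1% of the system scale
            ref = max(abs(series[0]), 0.01 * scale)
            out[k] = float(np.max(np.abs(series - series[0])) / ref)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame: time_s, species, value, units."""
        mem_unit = "per_um2" if self.network.localization == "membrane" else "uM"
        rows = []
        for j, name in enumerate(SPECIES):
            unit = "uM" if j in BULK else mem_unit
            rows.append(pd.DataFrame({
                "time_s": self.times, "species": name,
                "value": self.states[:, j], "units": unit,
            }))
        return pd.concat(rows, ignore_index=True)


def integrate_wellmixed(network: ReactionNetwork, init: PoolState | np.ndarray,
                        t_grid: np.ndarray, rtol: float = 1e-8,
                        atol: float = 1e-10) -> Trajectory:
    """Integrate the network deterministically on ``t_grid`` (stiff LSODA).

    Raises
    ------
    IntegrationError
        If the solver fails, or a finite-mode conservation law drifts by
        more than 1e-6 relative.
    """
    y0 = init.to_array() if isinstance(init, PoolState) else np.asarray(init, float)
    t_grid = np.asarray(t_grid, float)
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    sol = solve_ivp(network.rhs, (0.0, float(t_grid[-1])), y0, method="LSODA",
                    t_eval=t_grid, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    states = np.maximum(sol.y.T, 0.0)   # clip solver noise at -atol scale
    traj = Trajectory(t_grid, states, network)
    if network.reservoir_mode == "finite":
        worst = max(traj.conservation_residuals().values())
        if worst > 1e-6:
            raise IntegrationError(
                f"conservation drift {worst:.2e} exceeds 1e-6 — tighten tolerances")
    return traj


@dataclass
class GrowthPhases:
    """Boundaries of the seeding / initial growth / transient / steady regimes."""

    t_seed_end: float
    t_initial_end: float
    t_transient_end: float
    steady_reached: bool


def detect_phases(traj: Trajectory, seed_frac: float = 0.01,
                  steady_frac: float = 0.01) -> GrowthPhases:
    """Segment a barbed-end trajectory into its four growth regimes.

    Seeding ends when B first exceeds ``seed_frac`` of its maximum; initial
    growth ends at the maximum of dB/dt; the transient ends when |dB/dt|
    first falls below ``steady_frac`` of the peak rate.  Boundaries are
    clipped so the ordering invariant always holds.
    """
    t, B = traj.times, traj.B
    Bmax = B.max()
    if Bmax <= 0:
        return GrowthPhases(0.0, 0.0, 0.0, True)
    dBdt = np.gradient(B, t)
    above = np.nonzero(B > seed_frac * Bmax)[0]
    t_seed = float(t[above[0]]) if above.size else float(t[-1])
    t_init = max(float(t[np.argmax(dBdt)]), t_seed)
    peak_rate = np.max(np.abs(dBdt))
    later = np.nonzero((t >= t_init) & (np.abs(dBdt) < steady_frac * peak_rate))[0]
    if later.size:
        return GrowthPhases(t_seed, t_init, max(float(t[later[0]]), t_init), True)
    return GrowthPhases(t_seed, t_init, float("nan"), False)


def steady_state(network: ReactionNetwork, init: PoolState | np.ndarray,
                 t_long: float | None = None, atol: float = 1e-9) -> PoolState:
    """Fixed point of the infinite-reservoir rate laws.

    The cycling species (VCA states, Arp*, B) reach a genuine fixed point;
    P and B_capped are cumulative counters and are excluded from the
    fixed-point criterion.  A long integration supplies the starting guess
    and a Newton solve (with the VCA conservation law replacing one
    redundant balance) polishes it.
    """
    if network.reservoir_mode != "infinite":
        raise ValueError("steady_state requires an infinite-reservoir network")
    y0 = init.to_array() if isinstance(init, PoolState) else np.asarray(init, float)
    p = network.params
    scales = [p.k_regen, p.k_cap * max(y0[_IDX["CP_free"]], 1e-12),
              p.k_act * max(y0[_IDX["Arp_inactive"]], 1e-12),
              p.k_bind_VG * max(y0[_IDX["G"]], 1e-12)]
    slowest = max(1.0 / max(s, 1e-12) for s in scales)
    if t_long is None:
        t_long = 20.0 * slowest
    sol = solve_ivp(network.rhs, (0.0, t_long), y0, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise ConvergenceError(f"relaxation integration failed: {sol.message}")
    y_end = np.maximum(sol.y[:, -1], 0.0)

    cyc = [_IDX[s] for s in ("VCA_free", "VCA_G", "VCA_spent", "Arp_star", "B")]
    vca_tot = y_end[cyc[0]] + y_end[cyc[1]] + y_end[cyc[2]]

    def residual(x):
        y = y_end.copy()
        y[cyc] = x
        d = network.rhs(0.0, y)
        r = d[cyc]
        r[0] = x[0] + x[1] + x[2] - vca_tot   # replace redundant VCA balance
        return r

    sol_r = root(residual, y_end[cyc], method="hybr", tol=1e-13)
    y_fix = y_end.copy()
    if sol_r.success and np.all(sol_r.x > -1e-9):
        y_fix[cyc] = np.maximum(sol_r.x, 0.0)
    d = network.rhs(0.0, y_fix)
    check = [i for i in cyc]
    scale = np.maximum(np.abs(y_fix[check]), 1.0)
    if np.max(np.abs(d[check]) / scale) > max(atol, 1e-7):
        raise ConvergenceError(
            f"no fixed point: residual {np.max(np.abs(d[check])):.2e}")
    return PoolState.from_array(y_fix, network)
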