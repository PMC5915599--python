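"""Synthetic vesicle ensembles and morphology statistics.

Emulates the variability structure of reconstituted cytoskeletal-vesicle
experiments: vesicle radii uniform in 10-25 µm, encapsulated CP subject to
multiplicative lognormal fluctuation, and a CP-dependent number of
nucleation seeds (Poisson, with mean increasing in CP — higher CP slows
individual-domain nucleation so more, smaller domains appear).  Each
vesicle is simulated (or looked up in a precomputed surrogate) and yields
exactly one morphology label; labels are aggregated per nominal CP
condition with Wilson confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .morphology import classify_domain
from .params import Concentrations, Geometry, ParameterError, RateParams
from .spatial import (PATTERN_SNAPSHOT_S, RadialGrid, SpatialParams,
                      run_domain)

LABELS = ("protrusion", "concave", "flat", "cortex", "volume_network")


@dataclass(frozen=True)
class EnsembleConfig:
    """Distributional parameters of the synthetic vesicle population."""

    radius_min_um: float = 10.0
    radius_max_um: float = 25.0
    cp_noise_sd: float = 0.15          # lognormal sigma of CP fluctuation
    lambda_intercept: float = -1.3     # λ(CP) = max(min, a + b·CP[nM])
    lambda_slope_per_nM: float = 0.06
    lambda_min: float = 0.2
    cortex_seed_threshold: int = 6     # dense packing -> cortex
    volume_cp_nM: float = 150.0        # k_seed-dominated regime -> bulk net
    n_cells: int = 48                  # per-vesicle grid (speed over detail)
    t_end_s: float = PATTERN_SNAPSHOT_S

    def __post_init__(self) -> None:
        if not (0 < self.radius_min_um < self.radius_max_um):
            raise ParameterError("invalid radius range")
        if self.cp_noise_sd < 0:
            raise ParameterError("cp_noise_sd must be >= 0")
        if self.lambda_min < 0:
            raise ParameterError("lambda_min must be >= 0")

    def seed_mean(self, cp_nM: float) -> float:
        return max(self.lambda_min,
                   self.lambda_intercept + self.lambda_slope_per_nM * cp_nM)

    def with_(self, **kw) -> "EnsembleConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class VesicleSpec:
    """One synthetic vesicle: geometry, actual CP, seed count, RNG seed."""

    radius_um: float
    cp_nominal_nM: float
    cp_actual_nM: float
    n_seeds: int
    rng_seed: int

    def __post_init__(self) -> None:
        if self.radius_um <= 0 or self.cp_actual_nM <= 0 or self.n_seeds < 0:
            raise ParameterError("invalid vesicle spec")


def sample_vesicles(config: EnsembleConfig, cp_nominal_nM: float, n: int,
                    master_seed: int) -> list[VesicleSpec]:
    """Draw ``n`` vesicle specs; fully reproducible given ``master_seed``.

    Per-vesicle RNG seeds are spawned deterministically from the master
    seed, so downstream stochastic steps are reproducible per vesicle.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    ss = np.random.SeedSequence([int(master_seed), int(round(cp_nominal_nM * 1000))])
    rng = np.random.default_rng(ss)
    specs = []
    lam = config.seed_mean(cp_nominal_nM)
    for child in ss.spawn(n):
        radius = rng.uniform(config.radius_min_um, config.radius_max_um)
        cp = cp_nominal_nM * rng.lognormal(0.0, config.cp_noise_sd) \
            if config.cp_noise_sd > 0 else cp_nominal_nM
        n_seeds = int(rng.poisson(lam))
        specs.append(VesicleSpec(radius, cp_nominal_nM, cp, n_seeds,
                                 int(child.generate_state(1)[0] % (2 ** 31))))
    return specs


def classify_vesicle(spec: VesicleSpec, rates: RateParams,
                     config: EnsembleConfig) -> str:
    """Morphology label of one vesicle (rule layer + domain simulation).

    Extremes are rule-based: CP above ``volume_cp_nM`` leaves nucleation
    k_seed-dominated in the volume (volume-spanning network); seed counts
    above ``cortex_seed_threshold`` pack the membrane into a closed cortex,
    and a vesicle without discrete seeds grows a homogeneous cortex.
    Otherwise the domain model is run with the vesicle's pools shared
    between its ``n_seeds`` domains and the ratchet classifier applied.
    """
    if spec.cp_actual_nM >= config.volume_cp_nM:
        return "volume_network"
    if spec.n_seeds >= config.cortex_seed_threshold:
        return "cortex"
    if spec.n_seeds == 0:
        return "cortex"
    geometry = Geometry(R_vesicle_um=spec.radius_um)
    spatial = SpatialParams(N_domains=spec.n_seeds)
    grid = RadialGrid(n_cells=config.n_cells)
    conc = Concentrations(cp_nM=spec.cp_actual_nM)
    traj = run_domain(conc, rates=rates, geometry=geometry, spatial=spatial,
                      grid=grid, t_end=config.t_end_s,
                      output_times=[0.0, config.t_end_s])
    call = classify_domain(traj.profile(-1), rates,
                           float(traj.bulk_series("G")[-1]))
    return call.label


class LabelSurrogate:
    """Nearest-neighbour label lookup over a precomputed (CP, n_seeds) grid.

    Built from full spatial runs once, then reused for large ensembles.
    """

    def __init__(self, rates: RateParams, config: EnsembleConfig,
                 cp_grid=(30.0, 50.0, 70.0, 90.0, 110.0, 140.0),
                 seed_grid=(1, 2, 4, 8), radius_um: float = 15.0):
        self.cp_grid = np.asarray(cp_grid, float)
        self.seed_grid = np.asarray(seed_grid, int)
        self.config = config
        self.labels = {}
        for cp in self.cp_grid:
            for ns in self.seed_grid:
                spec = VesicleSpec(radius_um, cp, float(cp), int(ns), 0)
                self.labels[(float(cp), int(ns))] = \
                    classify_vesicle(spec, rates, config)

    def lookup(self, spec: VesicleSpec, config: EnsembleConfig) -> str:
        if spec.cp_actual_nM >= config.volume_cp_nM:
            return "volume_network"
        if spec.n_seeds >= config.cortex_seed_threshold or spec.n_seeds == 0:
            return "cortex"
        cp = self.cp_grid[np.argmin(np.abs(self.cp_grid - spec.cp_actual_nM))]
        ns = self.seed_grid[np.argmin(np.abs(self.seed_grid - spec.n_seeds))]
        return self.labels[(float(cp), int(ns))]


def _wilson(k: int, n: int, z: float = 1.959964) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


@dataclass
class MorphologyStats:
    """Per-condition label counts with seed-count bookkeeping."""

    counts: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: cp_nominal_nM, label, n_seeds, radius_um (one row per vesicle)
    failures: int = 0

    def add(self, spec: VesicleSpec, label: str) -> None:
        row = pd.DataFrame([{"cp_nominal_nM": spec.cp_nominal_nM,
                             "label": label, "n_seeds": spec.n_seeds,
                             "radius_um": spec.radius_um}])
        self.counts = pd.concat([self.counts, row], ignore_index=True)

    def fractions(self) -> pd.DataFrame:
        if self.counts.empty:
            raise ValueError("empty morphology statistics")
        rows = []
        for cp, grp in self.counts.groupby("cp_nominal_nM"):
            n = len(grp)
            for label in LABELS:
                k = int((grp["label"] == label).sum())
                lo, hi = _wilson(k, n)
                rows.append({"cp_nominal_nM": cp, "label": label,
                             "count": k, "n": n, "fraction": k / n,
                             "ci_low": lo, "ci_high": hi})
        return pd.DataFrame(rows)


def run_ensemble(specs: list[VesicleSpec], rates: RateParams | None = None,
                 config: EnsembleConfig | None = None,
                 mode: str = "full_spatial",
                 surrogate: LabelSurrogate | None = None) -> MorphologyStats:
    """Classify every vesicle; each contributes exactly one label.

    ``mode='full_spatial'`` simulates each vesicle; ``mode='surrogate'``
    uses (and if needed builds) a :class:`LabelSurrogate`.  Failed
    simulations are counted and excluded from the fractions.
    """
    rates = rates or RateParams()
    config = config or EnsembleConfig()
    if mode not in ("full_spatial", "surrogate"):
        raise ValueError(f"unknown ensemble mode {mode!r}")
    if mode == "surrogate" and surrogate is None:
        surrogate = LabelSurrogate(rates, config)
    stats = MorphologyStats()
    for spec in specs:
        try:
            if mode == "surrogate":
                label = surrogate.lookup(spec, config)
            else:
                label = classify_vesicle(spec, rates, config)
        except Exception:
            stats.failures += 1
            continue
        stats.add(spec, label)
    return stats


def summarize(stats: MorphologyStats) -> pd.DataFrame:
    """Tidy per-condition fraction table with Wilson confidence intervals."""
    return stats.fractions()
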