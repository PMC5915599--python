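"""Exact stochastic simulation of the reaction network (validation oracle).

Runs the same seven reactions as :mod:`actocap.kinetics` as a continuous-time
Markov jump process on molecule counts (Gillespie's direct method).  Used in
the test suite to check that the deterministic ODE trajectories agree with
the mean of the jump process at small copy numbers; not intended for
production-scale simulation.
"""

from __future__ import annotations

import numpy as np

from .kinetics import ReactionNetwork, SPECIES, _IDX
from .params import N_PER_UM3_PER_UM

# integer count changes per reaction (columns) — the conv-free stoichiometry
_COUNT_STOICH = np.zeros((len(SPECIES), 7), dtype=np.int64)


def _set(sp: str, r: int, v: int) -> None:
    _COUNT_STOICH[_IDX[sp], r] = v


_set("G", 0, -1); _set("VCA_free", 0, -1); _set("VCA_G", 0, 1)
_set("VCA_G", 1, -1); _set("Arp_inactive", 1, -1); _set("G", 1, 1)
_set("Arp_star", 1, 1); _set("VCA_spent", 1, 1)
_set("Arp_star", 2, -1); _set("B", 2, 1)
_set("Arp_star", 3, -1); _set("B", 3, 1)  # Arp* + B -> 2B, net +1 end
_set("G", 4, -1); _set("P", 4, 1)
_set("B", 5, -1); _set("CP_free", 5, -1); _set("B_capped", 5, 1)
_set("VCA_spent", 6, -1); _set("VCA_free", 6, 1)


class StochasticSimulator:
    """Gillespie direct-method simulator matched to a :class:`ReactionNetwork`.

    Counts: bulk species hold ``c_uM * N * V`` molecules, membrane species
    ``sigma * A``.  Bimolecular propensities are converted accordingly, so
    the ODE system is exactly the large-copy-number mean-field limit.
    """

    def __init__(self, network: ReactionNetwork) -> None:
        self.network = network
        self.V = network.volume_um3
        if network.localization == "membrane":
            self.A = network.geometry.area_um2
        else:
            self.A = None

    # -- count <-> density conversion ---------------------------------

    def counts_from_state(self, y: np.ndarray) -> np.ndarray:
        n = np.empty(len(SPECIES))
        for j in range(len(SPECIES)):
            if j in (0, 1, 2, 3) or self.A is None:
                n[j] = y[j] * N_PER_UM3_PER_UM * self.V
            else:
                n[j] = y[j] * self.A
        return np.round(n)

    def state_from_counts(self, n: np.ndarray) -> np.ndarray:
        y = np.empty(len(SPECIES))
        for j in range(len(SPECIES)):
            if j in (0, 1, 2, 3) or self.A is None:
                y[j] = n[j] / (N_PER_UM3_PER_UM * self.V)
            else:
                y[j] = n[j] / self.A
        return y

    def _propensities(self, n: np.ndarray) -> np.ndarray:
        p = self.network.params
        bulk_bi = 1.0 / (N_PER_UM3_PER_UM * self.V)  # per-pair rate, bulk partner
        i = _IDX
        G_uM = n[i["G"]] / (N_PER_UM3_PER_UM * self.V)
        if self.A is None:
            k_branch_pair = p.k_branch * bulk_bi
        else:
            k_branch_pair = (p.k_branch / self.network.geometry.k2d_factor) / self.A
        s_nuc = p.nucleation_monomer_factor(G_uM)
        return np.array([
            p.k_bind_VG * bulk_bi * n[i["G"]] * n[i["VCA_free"]],
            p.k_act * bulk_bi * n[i["Arp_inactive"]] * n[i["VCA_G"]],
            self.network._k_seed_eff * s_nuc * n[i["Arp_star"]],
            k_branch_pair * s_nuc * n[i["Arp_star"]] * n[i["B"]],
            p.k_elong * max(G_uM - p.c_crit, 0.0) * n[i["B"]],
            p.k_cap * bulk_bi * n[i["CP_free"]] * n[i["B"]],
            p.k_regen * n[i["VCA_spent"]],
        ])

    # -- simulation ----------------------------------------------------

    def run(self, y0: np.ndarray, t_grid: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
        """One realization sampled on ``t_grid``; returns states in the
        network's density/concentration units, shape (len(t_grid), n_species)."""
        infinite = self.network.reservoir_mode == "infinite"
        clamped = [_IDX[s] for s in ("G", "CP_free", "Arp_inactive")]
        n = self.counts_from_state(np.asarray(y0, float))
        out = np.empty((len(t_grid), len(SPECIES)))
        t = 0.0
        k_out = 0
        while k_out < len(t_grid):
            a = self._propensities(n)
            a_tot = a.sum()
            if a_tot <= 0:
                while k_out < len(t_grid):
                    out[k_out] = self.state_from_counts(n)
                    k_out += 1
                break
            dt = rng.exponential(1.0 / a_tot)
            while k_out < len(t_grid) and t_grid[k_out] < t + dt:
                out[k_out] = self.state_from_counts(n)
                k_out += 1
            t += dt
            j = rng.choice(7, p=a / a_tot)
            n_keep = n[clamped].copy() if infinite else None
            n += _COUNT_STOICH[:, j]
            if infinite:
                n[clamped] = n_keep
            np.maximum(n, 0, out=n)
        return out

    def run_ensemble(self, y0: np.ndarray, t_grid: np.ndarray, n_runs: int,
                     seed: int) -> tuple[np.ndarray, np.ndarray]:
        """Mean and standard error of the mean over ``n_runs`` realizations."""
        ss = np.random.SeedSequence(seed)
        runs = np.empty((n_runs, len(t_grid), len(SPECIES)))
        for k, child in enumerate(ss.spawn(n_runs)):
            runs[k] = self.run(y0, t_grid, np.random.default_rng(child))
        mean = runs.mean(axis=0)
        sem = runs.std(axis=0, ddof=1) / np.sqrt(n_runs)
        return mean, sem
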