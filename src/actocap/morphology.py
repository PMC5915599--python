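"""Brownian-ratchet mapping from barbed-end density to membrane deformation.

In the tension-dominated regime the membrane load is shared equally by the
local barbed ends, so each filament carries F_mem/B and the ratchet growth
velocity is

    v(B) = v_free * exp(-F_mem * delta / (B * kBT)),   v(0) = 0,

strictly increasing in B and saturating at the unloaded speed
v_free = k_elong (G - c_crit) delta.  A uniform high-density profile pushes
the membrane out coherently (protrusion); a rim-dominant profile grows
faster at the domain edge than in the centre and bends the membrane inward
(concave domain); a profile too sparse to push deforms nothing (flat).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .params import KBT_PN_NM_25C, ParameterError, RateParams
from .spatial import RadialProfile, rim_center_ratio


@dataclass(frozen=True)
class RatchetParams:
    """Load-sharing ratchet parameters.

    ``F_mem_pN_per_um2`` is the membrane load per unit area opposing
    growth (calibrated so v spans ~0-100 nm/s over the model's barbed-end
    density range); ``v_free_um_s`` the unloaded network growth speed.
    """

    F_mem_pN_per_um2: float = 15.0
    delta_nm: float = 2.7
    kBT_pN_nm: float = KBT_PN_NM_25C
    v_free_um_s: float = 0.0908    # k_elong (3 µM - c_crit) delta

    def __post_init__(self) -> None:
        if self.F_mem_pN_per_um2 < 0:
            raise ParameterError("F_mem must be >= 0")
        if self.kBT_pN_nm <= 0:
            raise ParameterError("kBT must be > 0")
        if self.v_free_um_s < 0:
            raise ParameterError("v_free must be >= 0")

    @classmethod
    def from_monomer_pool(cls, rates: RateParams, G_uM: float,
                          **kw) -> "RatchetParams":
        """Ratchet parameters with v_free set by the current monomer pool."""
        return cls(delta_nm=rates.delta_nm,
                   v_free_um_s=rates.v_free_um_s(G_uM), **kw)

    def with_(self, **kw) -> "RatchetParams":
        return replace(self, **kw)


@dataclass
class VelocityProfile:
    """Network growth speed versus radius."""

    radii: np.ndarray
    v: np.ndarray                  # µm/s

    def mean_speed(self) -> float:
        return float(np.mean(self.v))


@dataclass
class MorphologyCall:
    """Classified deformation mode with the quantities that produced it."""

    label: str                     # protrusion | concave | flat
    rim_center_ratio: float
    mean_speed_um_s: float
    ratio_threshold: float
    speed_threshold_um_s: float


def protrusion_velocity(B, p: RatchetParams):
    """Ratchet growth speed at barbed-end density ``B`` (µm⁻²).

    Scalar or array; v(0)=0 and v -> v_free as B -> infinity.
    """
    B = np.asarray(B, dtype=float)
    if np.any(B < 0):
        raise ValueError("barbed-end density must be >= 0")
    # F_mem*delta/(B*kBT): (pN/µm²)·nm / (µm⁻²·pN·nm) — dimensionless
    with np.errstate(divide="ignore"):
        x = np.where(B > 0, p.F_mem_pN_per_um2 * p.delta_nm
                     / (np.maximum(B, 1e-300) * p.kBT_pN_nm), np.inf)
    v = p.v_free_um_s * np.exp(-x)
    return v if v.ndim else float(v)


def velocity_profile(profile: RadialProfile, p: RatchetParams
                     ) -> VelocityProfile:
    """Pointwise ratchet map of a barbed-end density profile."""
    return VelocityProfile(profile.radii.copy(),
                           np.asarray(protrusion_velocity(profile.density, p)))


def classify_morphology(vp: VelocityProfile, ratio_threshold: float = 1.5,
                        speed_threshold_um_s: float | None = None,
                        v_free_um_s: float | None = None) -> MorphologyCall:
    """Deterministic deformation-mode call from a velocity profile.

    concave if the rim grows more than ``ratio_threshold`` times faster
    than the centre; otherwise protrusion if the mean speed exceeds the
    speed threshold (default 10% of v_free); otherwise flat.
    """
    if len(vp.v) == 0:
        raise ValueError("empty velocity profile")
    v_free = v_free_um_s if v_free_um_s is not None else float(np.max(vp.v))
    if speed_threshold_um_s is None:
        speed_threshold_um_s = 0.1 * (v_free_um_s if v_free_um_s is not None
                                      else RatchetParams().v_free_um_s)
    mean_v = vp.mean_speed()
    vprof = RadialProfile(vp.radii, vp.v, 0.0)
    if np.max(vp.v) <= 0:
        ratio = 1.0
    else:
        ratio = rim_center_ratio(vprof)
    if np.isfinite(ratio) and ratio > ratio_threshold and np.max(vp.v) > 0 \
            and mean_v > 0.01 * speed_threshold_um_s:
        label = "concave"
    elif mean_v > speed_threshold_um_s:
        label = "protrusion"
    else:
        label = "flat"
    return MorphologyCall(label, float(ratio), mean_v,
                          ratio_threshold, speed_threshold_um_s)


def front_shape(vp: VelocityProfile, duration_s: float
                ) -> tuple[np.ndarray, float]:
    """Displacement profile v(r)·t of the actin front and the sign of its
    discrete curvature at the centre (negative for rim-dominant growth)."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    disp = vp.v * duration_s
    if len(disp) < 3:
        return disp, 0.0
    # rim-dominant growth => displacement rises with r => d2 > 0 at the
    # centre => the actin front is concave (negative curvature)
    d2 = disp[2] - 2.0 * disp[1] + disp[0]
    scale = max(float(np.max(np.abs(disp))), 1e-300)
    if abs(d2) / scale < 1e-9:
        return disp, 0.0
    return disp, float(-np.sign(d2))


def classify_domain(profile: RadialProfile, rates: RateParams, G_uM: float,
                    F_mem_pN_per_um2: float = 15.0,
                    ratio_threshold: float = 1.5,
                    speed_threshold_frac: float = 0.1) -> MorphologyCall:
    """End-to-end call: density profile -> ratchet velocities -> morphology.

    The speed threshold is ``speed_threshold_frac`` of the unloaded speed
    at the reference 3 µM monomer pool, so a starved domain (low G, low B)
    is called flat rather than being normalized against its own slow
    v_free.
    """
    p = RatchetParams.from_monomer_pool(rates, G_uM,
                                        F_mem_pN_per_um2=F_mem_pN_per_um2)
    vp = velocity_profile(profile, p)
    v_free_ref = rates.v_free_um_s(3.0)
    return classify_morphology(vp, ratio_threshold=ratio_threshold,
                               speed_threshold_um_s=speed_threshold_frac * v_free_ref,
                               v_free_um_s=p.v_free_um_s)
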