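"""Leaf-to-canopy-to-whole-plant aggregation and NPP.

Big-leaf canopy scaling: leaf respiration is assumed to decline
exponentially with cumulative leaf area index L at rate k (default 0.5), so
all-canopy respiration is R_d,c = R_d * [1 - exp(-k L)] / k. Root and stem
maintenance respiration are linear in R_d,c with nitrogen-ratio coefficients
eta_root and eta_stem; growth respiration is a fixed fraction r_g of
(GPP - maintenance); NPP = GPP - R_p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .leaf import LeafEnvironment, Scheme, apply_light_inhibition, leaf_rd
from .pfts import PFTParams

#: Canopy light/nitrogen decay coefficient (dimensionless per unit LAI).
DEFAULT_K = 0.5
#: Growth-respiration coefficient r_g.
DEFAULT_RG = 0.25


@dataclass(frozen=True)
class VegetationState:
    """Per-PFT leaf area index and fractional cover plus the shared
    soil-moisture stress factor beta in [0,1] and GPP driver Pi_g
    (umol CO2 m^-2 s^-1)."""

    lai: object
    frac: object = 1.0
    beta: object = 1.0
    gpp: object = 0.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.lai) < 0):
            raise ValueError("negative LAI")
        b = np.asarray(self.beta, dtype=float)
        if np.any(b < 0) or np.any(b > 1):
            raise ValueError("beta outside [0, 1]")
        if np.any(np.asarray(self.gpp) < 0):
            raise ValueError("negative GPP driver")


@dataclass
class RespirationResult:
    """All respiration components (umol CO2 m^-2 s^-1) with optional
    one-standard-deviation bounds attached by the uncertainty module."""

    rd: object        # leaf-level, light-inhibited
    rdc: object       # canopy
    rpm: object       # whole-plant maintenance
    rpg: object       # growth
    rp: object        # whole-plant total
    npp: object       # GPP - R_p
    sigma_rd: object = 0.0
    sigma_rdc: object = 0.0
    sigma_rp: object = 0.0


def canopy_scale(rd, lai, k: float = DEFAULT_K):
    """All-canopy respiration R_d,c = R_d * [1 - exp(-k L)] / k.

    Bounded above by rd / k; implemented with expm1 so the k -> 0 limit
    (R_d,c -> R_d * L) is numerically stable.
    """
    if k <= 0:
        raise ValueError("canopy decay coefficient k must be positive")
    rd = np.asarray(rd, dtype=float)
    lai = np.asarray(lai, dtype=float)
    out = rd * (-np.expm1(-k * lai)) / k
    return out if np.ndim(out) else float(out)


def maintenance_respiration(rdc, beta, eta_root: float = 0.5,
                            eta_stem: float = 0.4,
                            beta_on_all: bool = False):
    """Whole-plant maintenance respiration R_p,m.

    Canopy respiration is reduced by the soil-moisture factor beta; root and
    stem terms are linear in R_d,c with coefficients eta_root, eta_stem.
    By default beta applies to the canopy term only; ``beta_on_all`` applies
    it to the root/stem terms as well.
    """
    rdc = np.asarray(rdc, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if beta_on_all:
        out = beta * rdc * (1.0 + eta_root + eta_stem)
    else:
        out = beta * rdc + rdc * (eta_root + eta_stem)
    return out if np.ndim(out) else float(out)


def growth_respiration(gpp, rpm, r_g: float = DEFAULT_RG):
    """Growth respiration R_p,g = r_g * (GPP - R_p,m).

    Not clamped: a negative value flags maintenance exceeding supply and
    propagates into (unsustainable) negative NPP.
    """
    if not 0.0 <= r_g < 1.0:
        raise ValueError("growth coefficient r_g must lie in [0, 1)")
    out = r_g * (np.asarray(gpp, dtype=float) - np.asarray(rpm, dtype=float))
    return out if np.ndim(out) else float(out)


def whole_plant(p: PFTParams, env: LeafEnvironment, veg: VegetationState,
                scheme: Scheme, k: float = DEFAULT_K, r_g: float = DEFAULT_RG,
                eta_root: float = 0.5, eta_stem: float = 0.4,
                light_inhibition: bool = True,
                beta_on_all: bool = False,
                clip_baseline: bool = True) -> RespirationResult:
    """Full chain: leaf R_d -> light inhibition -> canopy -> maintenance ->
    growth -> whole-plant respiration and NPP, for one PFT."""
    rd_dark = leaf_rd(p, env, scheme, clip_baseline=clip_baseline)
    rd = (apply_light_inhibition(rd_dark, env.irradiance)
          if light_inhibition else np.asarray(rd_dark, dtype=float))
    rdc = canopy_scale(rd, veg.lai, k)
    rpm = maintenance_respiration(rdc, veg.beta, eta_root, eta_stem, beta_on_all)
    rpg = growth_respiration(veg.gpp, rpm, r_g)
    rp = rpm + rpg
    npp = np.asarray(veg.gpp, dtype=float) - rp
    return RespirationResult(rd=rd, rdc=rdc, rpm=rpm, rpg=rpg, rp=rp, npp=npp)
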