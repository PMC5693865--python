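"""Analytic propagation of the baseline-regression standard errors.

The survey regression R_d,25 = r0 + r1*n_la - r2*T_G carries one-standard-
error bounds eps0, eps1, eps2 on its coefficients, assumed mutually
independent. The standard deviation of R_d,25 is then

    sqrt(eps0^2 + n_la^2 eps1^2)                 (fixed T_G = 25 schemes)
    sqrt(eps0^2 + n_la^2 eps1^2 + T_G^2 eps2^2)  (acclimated scheme)

The b,c temperature coefficients are treated as exact (their bounds are
negligible), so every downstream flux scales the sigma by the same
deterministic multiplier chain as its central value: relative uncertainty is
preserved through temperature response and canopy scaling. Growth
respiration treats GPP as exact, so sigma_rp = (1 - r_g) * sigma_rpm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .leaf import Scheme, SchemeTag
from .pfts import PFTParams

_GLOBRESP_TAGS = (SchemeTag.NEW_RD25, SchemeTag.NEW_RD25_BC,
                  SchemeTag.NEW_RD25_BC_ACCLIM)


@dataclass(frozen=True)
class UncertaintyBudget:
    """Standard deviations along the aggregation chain plus the individual
    eps0/eps1/eps2 contributions to sigma_rd25 (root-sum-square)."""

    sigma_rd25: object
    components: tuple
    sigma_rd: object = None
    sigma_rdc: object = None
    sigma_rp: object = None


def sigma_rd25(p: PFTParams, n_la, t_growth, scheme: Scheme) -> UncertaintyBudget:
    """Standard deviation of the survey baseline R_d,25 for one PFT.

    Two-term form for the fixed-T_G schemes, three-term for the acclimated
    scheme; raises for the STANDARD scheme, which has no uncertainty model.
    """
    if scheme.tag not in _GLOBRESP_TAGS:
        raise ValueError("no uncertainty model for the STANDARD scheme")
    if not p.has_globresp:
        raise ValueError(f"PFT {p.name!r} has no survey baseline regression")
    n_la = np.asarray(n_la, dtype=float)
    c0 = p.eps0 * np.ones_like(n_la)
    c1 = n_la * p.eps1
    if scheme.tag is SchemeTag.NEW_RD25_BC_ACCLIM:
        c2 = np.abs(np.asarray(t_growth, dtype=float)) * p.eps2
    else:
        c2 = np.zeros_like(n_la)
    sig = np.sqrt(c0 ** 2 + c1 ** 2 + c2 ** 2)
    if not np.ndim(sig):
        sig, c0, c1, c2 = float(sig), float(c0), float(c1), float(c2)
    return UncertaintyBudget(sigma_rd25=sig, components=(c0, c1, c2))


def propagate(budget: UncertaintyBudget, temperature_multiplier=1.0,
              canopy_factor=1.0, plant_factor=1.0) -> UncertaintyBudget:
    """Push sigma_rd25 through the deterministic multiplier chain.

    ``temperature_multiplier`` is the instantaneous-response factor (e.g.
    exp[b(T-25)+c(T^2-625)], including any light inhibition),
    ``canopy_factor`` the big-leaf factor [1-exp(-kL)]/k, and
    ``plant_factor`` the maintenance+growth factor. Each sigma scales
    linearly, so relative uncertainty of R_d,c equals that of R_d.
    """
    tm = np.asarray(temperature_multiplier, dtype=float)
    cf = np.asarray(canopy_factor, dtype=float)
    pf = np.asarray(plant_factor, dtype=float)
    if np.any(tm < 0) or np.any(cf < 0) or np.any(pf < 0):
        raise ValueError("multipliers must be non-negative")
    s_rd = budget.sigma_rd25 * tm
    s_rdc = s_rd * cf
    s_rp = s_rdc * pf
    if not np.ndim(s_rd):
        s_rd, s_rdc, s_rp = float(s_rd), float(s_rdc), float(s_rp)
    return UncertaintyBudget(sigma_rd25=budget.sigma_rd25,
                             components=budget.components,
                             sigma_rd=s_rd, sigma_rdc=s_rdc, sigma_rp=s_rp)


def plant_factor(beta, eta_root: float = 0.5, eta_stem: float = 0.4,
                 r_g: float = 0.25, beta_on_all: bool = False):
    """Multiplier taking sigma_rdc to sigma_rp under the linear chain.

    R_p depends on R_d,c through maintenance (factor beta + eta_root +
    eta_stem, or beta*(1+etas)) and growth R_p,g = r_g(GPP - R_p,m) with GPP
    exact, so sigma_rp = (1 - r_g) * sigma_rpm.
    """
    beta = np.asarray(beta, dtype=float)
    if beta_on_all:
        m = beta * (1.0 + eta_root + eta_stem)
    else:
        m = beta + eta_root + eta_stem
    out = (1.0 - r_g) * m
    return out if np.ndim(out) else float(out)
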