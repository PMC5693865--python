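"""Upper-canopy leaf dark-respiration kernels.

Four alternative schemes for leaf dark respiration R_d (umol CO2 m^-2 s^-1):

``STANDARD``
    Nitrogen-derived baseline R_d,25 = f_dr * V_cmax,25 with
    V_cmax,25 = 1e6 * n_e * n_l0, a Q10 = 2 instantaneous response, and
    sigmoidal suppression at high and low leaf temperatures.
``NEW_RD25``
    Survey-derived baseline R_d,25 = r0 + r1*n_la - r2*T_G evaluated at a
    fixed growth temperature of 25 degC, Q10 = 2 response, no suppression.
``NEW_RD25_BC``
    Same baseline, but the instantaneous response is an
    exponential-of-quadratic exp[b(T-25) + c(T^2 - 625)] whose effective Q10
    declines continuously with temperature.
``NEW_RD25_BC_ACCLIM``
    Full formulation: the baseline acclimates to the 10-day mean growth
    temperature T_G (cold-grown leaves respire more at a common measurement
    temperature), with the b,c instantaneous response.

C4 grasses, which the survey regression does not cover, use the STANDARD
pathway under every scheme.

All kernels are pointwise and broadcast over arbitrary numpy array shapes;
temperatures are in degC throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .pfts import PFTParams

logger = logging.getLogger(__name__)

#: Irradiance (W m^-2) above which light inhibition of dark respiration applies.
LIGHT_INHIBITION_THRESHOLD = 2.0
#: Fractional reduction of R_d under light (30% inhibition).
LIGHT_INHIBITION_FRACTION = 0.3


class SchemeTag(str, Enum):
    STANDARD = "STANDARD"
    NEW_RD25 = "NEW_RD25"
    NEW_RD25_BC = "NEW_RD25_BC"
    NEW_RD25_BC_ACCLIM = "NEW_RD25_BC_ACCLIM"


@dataclass(frozen=True)
class Scheme:
    """Scheme selector; ``tg_equals_tl`` enables the sensitivity mode where
    the acclimation temperature tracks instantaneous leaf temperature."""

    tag: SchemeTag
    tg_equals_tl: bool = False

    def __post_init__(self) -> None:
        if self.tg_equals_tl and self.tag is not SchemeTag.NEW_RD25_BC_ACCLIM:
            raise ValueError("tg_equals_tl only applies to the acclimated scheme")


#: The four factorial schemes in attribution order.
ALL_SCHEMES = (
    Scheme(SchemeTag.STANDARD),
    Scheme(SchemeTag.NEW_RD25),
    Scheme(SchemeTag.NEW_RD25_BC),
    Scheme(SchemeTag.NEW_RD25_BC_ACCLIM),
)


@dataclass(frozen=True)
class LeafEnvironment:
    """Instantaneous leaf temperature, 10-day-mean growth temperature (degC)
    and downward shortwave irradiance (W m^-2). Fields broadcast together."""

    t_leaf: object
    t_growth: object
    irradiance: object = 0.0


def rd25_standard(p: PFTParams) -> float:
    """Nitrogen-chain baseline: R_d,25 = f_dr * 1e6 * n_e * n_l0."""
    return p.f_dr * 1.0e6 * p.n_e * p.n_l0


def suppression_factor(t_leaf):
    """High/low-temperature suppression of the standard Q10 response.

    1 / [(1 + exp(0.3(13 - T_l))) * (1 + exp(0.3(T_l - 36)))], in (0, 1).
    """
    t = np.asarray(t_leaf, dtype=float)
    out = 1.0 / ((1.0 + np.exp(0.3 * (13.0 - t))) * (1.0 + np.exp(0.3 * (t - 36.0))))
    return out if out.ndim else float(out)


def q10_response(rd25, t_leaf, q10: float = 2.0, suppress: bool = False):
    """R_d = R_d,25 * Q10^{0.1(T_l - 25)}, optionally suppressed."""
    rd25 = np.asarray(rd25, dtype=float)
    t = np.asarray(t_leaf, dtype=float)
    rd = rd25 * q10 ** (0.1 * (t - 25.0))
    if suppress:
        rd = rd * suppression_factor(t)
    return rd if np.ndim(rd) else float(rd)


def rd25_globresp(p: PFTParams, n_la, t_growth, clip: bool = True):
    """Survey-regression baseline R_d,25 = r0 + r1*n_la - r2*T_G.

    Negative values (possible for very warm T_G with low leaf nitrogen) are
    clipped at zero and logged unless ``clip=False`` (diagnostic mode
    exposing the raw linear value).
    """
    if not p.has_globresp:
        raise ValueError(f"PFT {p.name!r} has no survey baseline regression")
    n_la = np.asarray(n_la, dtype=float)
    tg = np.asarray(t_growth, dtype=float)
    rd25 = p.r0 + p.r1 * n_la - p.r2 * tg
    if clip:
        n_neg = int(np.sum(rd25 < 0.0))
        if n_neg:
            logger.info("clipped %d negative R_d,25 values for %s", n_neg, p.name)
        rd25 = np.maximum(rd25, 0.0)
    return rd25 if np.ndim(rd25) else float(rd25)


def bc_response(rd25, t_leaf, b: float = 0.1012, c: float = -0.0005):
    """Exponential-of-quadratic response: rd25 * exp[b(T-25) + c(T^2 - 625)].

    Strictly increasing in T_l for T_l < -b/(2c) (~101 degC for the default
    coefficients), so it does not turn over at ecologically relevant
    temperatures.
    """
    rd25 = np.asarray(rd25, dtype=float)
    t = np.asarray(t_leaf, dtype=float)
    rd = rd25 * np.exp(b * (t - 25.0) + c * (t * t - 625.0))
    return rd if np.ndim(rd) else float(rd)


def effective_q10(t_leaf, b: float = 0.1012, c: float = -0.0005):
    """Local ratio R(T+10)/R(T) of the b,c curve: exp[10b + c(20 T + 100)].

    Declines with temperature whenever c < 0; reduces to exp(10b),
    independent of T, when c = 0.
    """
    t = np.asarray(t_leaf, dtype=float)
    q = np.exp(10.0 * b + c * (20.0 * t + 100.0))
    return q if np.ndim(q) else float(q)


def apply_light_inhibition(rd, irradiance,
                           threshold: float = LIGHT_INHIBITION_THRESHOLD,
                           fraction: float = LIGHT_INHIBITION_FRACTION):
    """Reduce R_d by ``fraction`` where irradiance strictly exceeds ``threshold``.

    Mitochondrial CO2 release in the light is ~30% lower than in darkness;
    the comparison is strict so exactly-threshold light is uninhibited.
    """
    rd = np.asarray(rd, dtype=float)
    sw = np.asarray(irradiance, dtype=float)
    if np.any(sw < 0.0):
        raise ValueError("negative irradiance in forcing")
    out = np.where(sw > threshold, (1.0 - fraction) * rd, rd)
    return out if np.ndim(out) else float(out)


def leaf_rd(p: PFTParams, env: LeafEnvironment, scheme: Scheme,
            clip_baseline: bool = True):
    """Uninhibited leaf dark respiration R_d under the requested scheme.

    Dispatch:

    - STANDARD: nitrogen-chain baseline, suppressed Q10 response.
    - NEW_RD25: survey baseline at T_G = 25, plain Q10 response.
    - NEW_RD25_BC: survey baseline at T_G = 25, b,c response.
    - NEW_RD25_BC_ACCLIM: survey baseline at the environment's T_G
      (or at T_l when ``scheme.tg_equals_tl``), b,c response.

    C4 grasses fall back to STANDARD under every scheme.
    """
    if not p.has_globresp or scheme.tag is SchemeTag.STANDARD:
        return q10_response(rd25_standard(p), env.t_leaf, p.q10, suppress=True)
    n_la = p.n_l0 * p.sigma_l * 1.0e3
    if scheme.tag is SchemeTag.NEW_RD25:
        rd25 = rd25_globresp(p, n_la, 25.0, clip=clip_baseline)
        return q10_response(rd25, env.t_leaf, p.q10, suppress=False)
    if scheme.tag is SchemeTag.NEW_RD25_BC:
        rd25 = rd25_globresp(p, n_la, 25.0, clip=clip_baseline)
        return bc_response(rd25, env.t_leaf, p.b, p.c)
    if scheme.tag is SchemeTag.NEW_RD25_BC_ACCLIM:
        tg = env.t_leaf if scheme.tg_equals_tl else env.t_growth
        rd25 = rd25_globresp(p, n_la, tg, clip=clip_baseline)
        return bc_response(rd25, env.t_leaf, p.b, p.c)
    raise ValueError(f"unknown scheme {scheme.tag!r}")
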