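"""Plant-functional-type (PFT) parameter registry.

Holds the per-PFT constants of the standard land-surface respiration scheme
(mass-based leaf nitrogen ``n_l0``, the V_cmax–N coefficient ``n_e``, the
R_d,25/V_cmax,25 ratio ``f_dr``, specific leaf density ``sigma_l``) together
with the GlobResp-style regression coefficients that express the respiration
baseline at 25 °C as a linear function of area-based leaf nitrogen and
acclimation growth temperature::

    R_d,25 = r0 + r1 * n_la - r2 * T_G

with one-standard-error bounds (eps0, eps1, eps2) on the three coefficients.
C4 grasses have no such regression (the survey data do not cover them) and
are flagged ``has_globresp = False``.

Defaults ship as a version-controlled CSV so alternative PFT sets can be
supplied; values are read verbatim from the file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from importlib import resources
from pathlib import Path

import pandas as pd

PFT_NAMES = ("broadleaf_tree", "needleleaf_tree", "shrub", "c3_grass", "c4_grass")

_FLOAT_FIELDS = (
    "n_l0", "n_e", "f_dr", "sigma_l",
    "r0", "r1", "r2", "eps0", "eps1", "eps2",
    "q10", "b", "c",
)


@dataclass(frozen=True)
class PFTParams:
    """Constants for one plant functional type.

    Units: n_l0 in kg N (kg C)^-1; n_e in mol CO2 m^-2 s^-1 kg C (kg N)^-1;
    f_dr dimensionless; sigma_l in kg C (m^2 leaf)^-1; r0 in umol CO2 m^-2
    s^-1; r1 in umol CO2 m^-2 s^-1 (gN m^-2)^-1; r2 in umol CO2 m^-2 s^-1
    degC^-1; eps* are one-standard-error bounds on r0, r1, r2; q10
    dimensionless; b in degC^-1; c in degC^-2.
    """

    name: str
    n_l0: float
    n_e: float
    f_dr: float
    sigma_l: float
    r0: float
    r1: float
    r2: float
    eps0: float
    eps1: float
    eps2: float
    q10: float = 2.0
    b: float = 0.1012
    c: float = -0.0005
    has_globresp: bool = True

    def __post_init__(self) -> None:
        if self.n_l0 < 0 or self.sigma_l <= 0 or self.f_dr <= 0:
            raise ValueError(f"non-physical leaf constants for {self.name!r}")
        if self.has_globresp:
            for eps in (self.eps0, self.eps1, self.eps2):
                if not eps >= 0:
                    raise ValueError(f"negative standard error for {self.name!r}")


@dataclass(frozen=True)
class NitrogenProfile:
    """Area-based upper-canopy leaf nitrogen and root/stem nitrogen ratios.

    ``eta_root`` and ``eta_stem`` scale root and stem maintenance respiration
    relative to canopy respiration; they are not constrained by the leaf
    survey data and default elsewhere to configurable placeholder values.
    """

    n_la: float
    eta_root: float = 0.5
    eta_stem: float = 0.4

    def __post_init__(self) -> None:
        if self.eta_root < 0 or self.eta_stem < 0:
            raise ValueError("nitrogen ratios must be non-negative")


def area_based_nitrogen(p: PFTParams) -> float:
    """Area-based leaf nitrogen n_la (gN m^-2) from mass-based constants.

    n_la = n_l0 * sigma_l * 10^3, converting kg N (kg C)^-1 times
    kg C m^-2 to gN m^-2.
    """
    return p.n_l0 * p.sigma_l * 1.0e3


def _default_params_path() -> Path:
    return Path(str(resources.files("plantresp").joinpath("data/pft_params.csv")))


def load_pfts(path: str | Path) -> dict[str, PFTParams]:
    """Load a PFT registry from a CSV parameter file (one row per PFT)."""
    df = pd.read_csv(path, dtype={"name": str})
    out: dict[str, PFTParams] = {}
    for _, row in df.iterrows():
        kwargs = {"name": row["name"], "has_globresp": _parse_bool(row["has_globresp"])}
        for f in _FLOAT_FIELDS:
            v = row[f]
            kwargs[f] = float("nan") if pd.isna(v) else float(v)
        p = PFTParams(**kwargs)
        if p.has_globresp != (p.name != "c4_grass") and p.name in PFT_NAMES:
            raise ValueError(f"has_globresp inconsistent for {p.name!r}")
        out[p.name] = p
    return out


def _parse_bool(v: object) -> bool:
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in ("true", "1", "yes")


def load_default_pfts() -> dict[str, PFTParams]:
    """The five default PFTs with the published trait-database constants."""
    return load_pfts(_default_params_path())


def save_pfts(pfts: dict[str, PFTParams], path: str | Path) -> None:
    """Serialise a registry back to the CSV parameter format (round-trips)."""
    rows = []
    for p in pfts.values():
        row = {f.name: getattr(p, f.name) for f in dc_fields(p)}
        for f in _FLOAT_FIELDS:
            if isinstance(row[f], float) and math.isnan(row[f]):
                row[f] = ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
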