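"""Per-region material properties: elasticity, density, dynamic yield.

Default dynamic yield strengths are the values measured for rabbit femur
at strain rates of order 10^3 1/s: 180 MPa for cortical and 8.9 MPa for
cancellous bone.  Elastic constants and densities default to
literature-typical continuum values (flagged "assumed" in run reports)
and are fully overridable from a YAML config with explicit unit
suffixes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .geometry import CANCELLOUS, CORTICAL, IMPLANT, REGIONS

__all__ = [
    "ElasticMaterial",
    "FailureParams",
    "MaterialLibrary",
    "MaterialConfigError",
    "default_library",
    "load_material_config",
    "lame_parameters",
    "elastic_from_lame",
    "dilatational_wave_speed",
]


class MaterialConfigError(ValueError):
    """Invalid material definition; ``fields`` lists the offending entries."""

    def __init__(self, fields: list[str]):
        self.fields = list(fields)
        super().__init__("invalid material config: " + "; ".join(self.fields))


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic linear-elastic constants (SI units)."""

    E: float          # Young's modulus, Pa
    nu: float         # Poisson ratio
    rho: float        # density, kg/m^3

    def validate(self, label: str = "") -> list[str]:
        bad = []
        pre = f"{label}." if label else ""
        if not self.E > 0:
            bad.append(f"{pre}E must be > 0 (got {self.E})")
        if not (-1.0 < self.nu < 0.5):
            bad.append(f"{pre}nu must lie in (-1, 0.5) (got {self.nu})")
        if not self.rho > 0:
            bad.append(f"{pre}rho must be > 0 (got {self.rho})")
        return bad


@dataclass(frozen=True)
class FailureParams:
    """Abrupt von Mises failure threshold for a set of regions."""

    yield_strength: float                    # Pa
    applies_to: frozenset = frozenset()

    def validate(self, label: str = "") -> list[str]:
        pre = f"{label}." if label else ""
        bad = []
        if not self.yield_strength > 0:
            bad.append(f"{pre}yield_strength must be > 0 (got {self.yield_strength})")
        return bad


@dataclass(frozen=True)
class MaterialLibrary:
    """Map region -> (elastic constants, optional failure params).

    All three regions must be present; the implant never fails (it is
    far stiffer and stronger than bone, and damage accounting concerns
    bone only).
    """

    elastic: dict
    failure: dict
    assumed_elastic: bool = True   # elastic defaults are literature-typical

    def __post_init__(self):
        bad = []
        for r in REGIONS:
            if r not in self.elastic:
                bad.append(f"missing region {r}")
        for r in (CORTICAL, CANCELLOUS):
            if r not in self.failure:
                bad.append(f"missing failure params for {r}")
        for r, m in self.elastic.items():
            bad += m.validate(r)
        for r, f in self.failure.items():
            bad += f.validate(r)
        if bad:
            raise MaterialConfigError(bad)

    def yield_of(self, region: str) -> float | None:
        f = self.failure.get(region)
        return f.yield_strength if f is not None else None

    def to_dict(self) -> dict:
        """JSON-serialisable echo for run reports."""
        out = {"elastic_defaults_assumed": self.assumed_elastic, "regions": {}}
        for r in REGIONS:
            m = self.elastic[r]
            entry = {"E_Pa": m.E, "nu": m.nu, "rho_kg_m3": m.rho}
            if r in self.failure:
                entry["yield_Pa"] = self.failure[r].yield_strength
            out["regions"][r] = entry
        return out


_DEFAULT_ELASTIC = {
    CORTICAL: ElasticMaterial(E=15e9, nu=0.3, rho=1900.0),
    CANCELLOUS: ElasticMaterial(E=0.5e9, nu=0.3, rho=500.0),
    IMPLANT: ElasticMaterial(E=110e9, nu=0.33, rho=4500.0),   # CP titanium
}
_DEFAULT_YIELD = {CORTICAL: 180e6, CANCELLOUS: 8.9e6}


def default_library() -> MaterialLibrary:
    """Library with measured dynamic yields and assumed elastic defaults."""
    return MaterialLibrary(
        elastic=dict(_DEFAULT_ELASTIC),
        failure={
            r: FailureParams(y, frozenset({r})) for r, y in _DEFAULT_YIELD.items()
        },
    )


def load_material_config(path: str | Path | None) -> MaterialLibrary:
    """Load a YAML material config, overriding defaults per field.

    Schema (all keys optional; unit suffixes are part of the key)::

        materials:
          cortical:   {E_Pa: 1.5e10, nu: 0.3, rho_kg_m3: 1900, yield_Pa: 1.8e8}
          cancellous: {E_Pa: 5.0e8,  nu: 0.3, rho_kg_m3: 500,  yield_Pa: 8.9e6}
          implant:    {E_Pa: 1.1e11, nu: 0.33, rho_kg_m3: 4500}

    An empty or missing file section yields the full default library.
    """
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    section = data.get("materials", data) or {}

    elastic = dict(_DEFAULT_ELASTIC)
    yields = dict(_DEFAULT_YIELD)
    overridden = False
    bad = []
    for key, entry in section.items():
        region = key.upper()
        if region not in REGIONS:
            bad.append(f"unknown region {key!r}")
            continue
        entry = entry or {}
        unknown = set(entry) - {"E_Pa", "nu", "rho_kg_m3", "yield_Pa"}
        if unknown:
            bad.append(f"{key}: unknown fields {sorted(unknown)}")
        m = elastic[region]
        elastic[region] = ElasticMaterial(
            E=float(entry.get("E_Pa", m.E)),
            nu=float(entry.get("nu", m.nu)),
            rho=float(entry.get("rho_kg_m3", m.rho)),
        )
        if "E_Pa" in entry or "nu" in entry or "rho_kg_m3" in entry:
            overridden = True
        if "yield_Pa" in entry:
            if region == IMPLANT:
                bad.append("implant: yield_Pa not allowed (implant never fails)")
            else:
                yields[region] = float(entry["yield_Pa"])
    if bad:
        raise MaterialConfigError(bad)
    return MaterialLibrary(
        elastic=elastic,
        failure={r: FailureParams(y, frozenset({r})) for r, y in yields.items()},
        assumed_elastic=not overridden,
    )


def lame_parameters(m: ElasticMaterial) -> tuple[float, float]:
    """Lame constants (lambda, mu) of an isotropic material.

    lambda = E nu / ((1+nu)(1-2nu)), mu = E / (2(1+nu)).  The
    incompressible limit nu -> 0.5 is rejected.
    """
    bad = m.validate()
    if bad:
        raise MaterialConfigError(bad)
    if 0.5 - m.nu < 1e-6:
        raise MaterialConfigError(["nu too close to 0.5 (incompressible unsupported)"])
    lam = m.E * m.nu / ((1.0 + m.nu) * (1.0 - 2.0 * m.nu))
    mu = m.E / (2.0 * (1.0 + m.nu))
    return lam, mu


def elastic_from_lame(lam: float, mu: float, rho: float) -> ElasticMaterial:
    """Inverse of :func:`lame_parameters` (algebraic round trip)."""
    E = mu * (3.0 * lam + 2.0 * mu) / (lam + mu)
    nu = lam / (2.0 * (lam + mu))
    return ElasticMaterial(E=E, nu=nu, rho=rho)


def dilatational_wave_speed(m: ElasticMaterial) -> float:
    """P-wave speed c_d = sqrt((lambda + 2 mu) / rho), the CFL speed."""
    lam, mu = lame_parameters(m)
    return math.sqrt((lam + 2.0 * mu) / m.rho)
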