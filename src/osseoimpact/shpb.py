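"""Split Hopkinson Pressure Bar one-dimensional stress-wave analysis.

Converts incident / reflected / transmitted bar strain records into
specimen stress, strain, and strain-rate histories:

    sigma_s(t) = E (A_b / A_s) eps_T(t)
    eps_s(t)   = -(2 C0 / l_s) \\int_0^t eps_R dtau
    epsdot_s(t) = -(2 C0 / l_s) eps_R(t)

with E, A_b, C0 the bar modulus, area and wave speed and l_s, A_s the
specimen length and area.  A forward generator synthesises gauge records
for an elastic-perfectly-plastic specimen under the standard SHPB
assumption of quasi-static specimen equilibrium, which closes the loop
for parameter-recovery testing: synthesise -> reconstruct -> extract
yield.

Sign convention: compression positive internally.  Records carrying the
opposite (tension-positive, i.e. raw gauge polarity with compressive
incident strain negative) convention are flipped on ingest.  Under the
internal convention the reflected wave of a compliant specimen is
negative, so the minus signs above produce positive specimen strain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "BarProperties",
    "SpecimenGeometry",
    "GaugeRecord",
    "StressStrainCurve",
    "YieldResult",
    "SHPBError",
    "specimen_stress",
    "specimen_strain",
    "specimen_strain_rate",
    "reconstruct_curve",
    "extract_yield_strength",
    "synthesize_waves",
    "STEEL_BAR",
    "CORTICAL_SPECIMEN",
    "CANCELLOUS_SPECIMEN",
]


class SHPBError(ValueError):
    pass


@dataclass(frozen=True)
class BarProperties:
    """Pressure-bar constants; the wave speed C0 = sqrt(E/rho) is derived."""

    E: float      # Young's modulus, Pa
    rho: float    # density, kg/m^3
    area: float   # cross-sectional area A_b, m^2

    def __post_init__(self):
        if self.E <= 0 or self.rho <= 0 or self.area <= 0:
            raise SHPBError("bar E, rho, area must all be positive")

    @property
    def C0(self) -> float:
        return math.sqrt(self.E / self.rho)


@dataclass(frozen=True)
class SpecimenGeometry:
    """Undeformed specimen length l_s (load axis) and area A_s."""

    length: float  # m
    area: float    # m^2

    def __post_init__(self):
        if self.length <= 0 or self.area <= 0:
            raise SHPBError("specimen length and area must be positive")


# steel bars used in the dynamic tests
STEEL_BAR = BarProperties(E=209e9, rho=7830.0, area=math.pi * 0.010**2)
# cortical specimen 6 x 3 x 8 mm loaded along the 8 mm axis
CORTICAL_SPECIMEN = SpecimenGeometry(length=0.008, area=6e-3 * 3e-3)
# cancellous specimen 5 x 6 x 6 mm loaded along the 5 mm axis
CANCELLOUS_SPECIMEN = SpecimenGeometry(length=0.005, area=6e-3 * 6e-3)


@dataclass
class GaugeRecord:
    """Time-sampled incident/reflected/transmitted bar strains.

    ``compression_positive`` states the polarity of the stored arrays;
    :meth:`as_compression_positive` normalises to the internal
    convention.
    """

    time: np.ndarray
    incident: np.ndarray
    reflected: np.ndarray
    transmitted: np.ndarray
    compression_positive: bool = True

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        for name in ("incident", "reflected", "transmitted"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.time.shape:
                raise SHPBError(f"{name} length differs from time axis")
            setattr(self, name, arr)
        if self.time.ndim != 1 or self.time.size < 2:
            raise SHPBError("time axis must be a 1-D array of >= 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise SHPBError("time axis must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-8, atol=0.0):
            raise SHPBError("time axis must be uniformly sampled")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def as_compression_positive(self) -> "GaugeRecord":
        if self.compression_positive:
            return self
        return GaugeRecord(
            self.time, -self.incident, -self.reflected, -self.transmitted, True
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time,
                "incident": self.incident,
                "reflected": self.reflected,
                "transmitted": self.transmitted,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, compression_positive: bool = True) -> "GaugeRecord":
        df = pd.read_csv(path)
        required = {"time_s", "incident", "reflected", "transmitted"}
        missing = required - set(df.columns)
        if missing:
            raise SHPBError(f"gauge CSV missing columns {sorted(missing)}")
        return cls(
            df["time_s"].to_numpy(),
            df["incident"].to_numpy(),
            df["reflected"].to_numpy(),
            df["transmitted"].to_numpy(),
            compression_positive,
        )


@dataclass
class StressStrainCurve:
    """Specimen histories on the gauge-record time grid."""

    time: np.ndarray
    strain: np.ndarray            # dimensionless, starts at 0
    stress: np.ndarray            # Pa
    strain_rate: np.ndarray       # 1/s
    equilibrium_residual: np.ndarray = field(default=None)  # eps_I + eps_R - eps_T

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "strain": self.strain,
                "stress_Pa": self.stress,
                "strain_rate_per_s": self.strain_rate,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class YieldResult:
    """Outcome of yield extraction; ``yielded`` False means a fully
    linear curve (an explicit no-yield result, not an error)."""

    yielded: bool
    value: float | None
    method: str


def specimen_stress(
    record: GaugeRecord, bar: BarProperties, spec: SpecimenGeometry
) -> np.ndarray:
    """Specimen stress sigma_s = E (A_b/A_s) eps_T, pointwise."""
    r = record.as_compression_positive()
    if r.transmitted is None:
        raise SHPBError("transmitted channel missing")
    return bar.E * (bar.area / spec.area) * r.transmitted


def specimen_strain(
    record: GaugeRecord, bar: BarProperties, spec: SpecimenGeometry
) -> np.ndarray:
    """Specimen strain eps_s = -(2 C0/l_s) int eps_R dt (cumulative trapezoid)."""
    r = record.as_compression_positive()
    integral = cumulative_trapezoid(r.reflected, r.time, initial=0.0)
    return -(2.0 * bar.C0 / spec.length) * integral


def specimen_strain_rate(
    record: GaugeRecord, bar: BarProperties, spec: SpecimenGeometry
) -> np.ndarray:
    """Specimen strain rate epsdot_s = -(2 C0/l_s) eps_R, pointwise."""
    r = record.as_compression_positive()
    return -(2.0 * bar.C0 / spec.length) * r.reflected


def reconstruct_curve(
    record: GaugeRecord, bar: BarProperties, spec: SpecimenGeometry
) -> StressStrainCurve:
    """Bundle the three wave equations into a stress-strain curve.

    Also reports the force-equilibrium residual eps_I + eps_R - eps_T,
    which vanishes for a specimen in quasi-static equilibrium (equal
    forces at the two bar/specimen interfaces) and is the standard
    validity diagnostic for an SHPB test.
    """
    r = record.as_compression_positive()
    return StressStrainCurve(
        time=r.time,
        strain=specimen_strain(r, bar, spec),
        stress=specimen_stress(r, bar, spec),
        strain_rate=specimen_strain_rate(r, bar, spec),
        equilibrium_residual=r.incident + r.reflected - r.transmitted,
    )


def extract_yield_strength(
    curve: StressStrainCurve,
    method: str = "plateau",
    tangent_fraction: float = 0.10,
    offset: float = 0.002,
) -> YieldResult:
    """Yield stress from a stress-strain curve.

    plateau: mean stress over the post-linear plateau, defined as the
    samples (up to peak strain) where the tangent modulus has dropped
    below ``tangent_fraction`` of the initial modulus.  Suits
    elastic-perfectly-plastic response.

    offset: stress at the intersection with the ``offset``-strain offset
    line of slope equal to the initial modulus.

    A curve that never leaves the linear regime returns an explicit
    no-yield result.
    """
    strain = np.asarray(curve.strain, dtype=float)
    stress = np.asarray(curve.stress, dtype=float)
    i_peak = int(np.argmax(strain))
    if i_peak < 3:
        return YieldResult(False, None, method)
    s, sig = strain[: i_peak + 1], stress[: i_peak + 1]

    # initial modulus from the early loading leg (first tenth of the
    # strain range, at least 3 samples)
    s_lo = s[2] + 0.1 * (s[-1] - s[2])
    head = np.flatnonzero(s <= s_lo)
    head = head[head >= 1]
    if head.size < 2:
        head = np.arange(1, min(5, s.size))
    E0 = float(np.polyfit(s[head], sig[head], 1)[0])
    if E0 <= 0:
        return YieldResult(False, None, method)

    if method == "plateau":
        tangent = np.gradient(sig, s, edge_order=1)
        plateau = np.flatnonzero(
            (tangent < tangent_fraction * E0) & (s > s_lo)
        )
        if plateau.size < 2:
            return YieldResult(False, None, method)
        return YieldResult(True, float(np.mean(sig[plateau])), method)

    if method == "offset":
        resid = sig - E0 * (s - offset)
        below = np.flatnonzero(resid <= 0)
        below = below[s[below] > offset]
        if below.size == 0:
            return YieldResult(False, None, method)
        j = below[0]
        # linear interpolation of the crossing
        r0, r1 = resid[j - 1], resid[j]
        w = r0 / (r0 - r1) if r0 != r1 else 0.0
        return YieldResult(True, float(sig[j - 1] + w * (sig[j] - sig[j - 1])), method)

    raise SHPBError(f"unknown yield-extraction method {method!r}")


@dataclass(frozen=True)
class EppMaterial:
    """Elastic-perfectly-plastic specimen material for the generator."""

    modulus: float          # Pa
    yield_strength: float | None = None   # Pa; None = purely elastic


def synthesize_waves(
    specimen_material: EppMaterial,
    spec: SpecimenGeometry,
    bar: BarProperties,
    striker_velocity: float,
    striker_length: float = 0.4,
    dt: float = 2e-7,
    tail_fraction: float = 0.2,
) -> GaugeRecord:
    """Forward-generate SHPB gauge records for an EPP specimen.

    The incident pulse is a trapezoid of amplitude v/(2 C0) and duration
    2 L_striker / C0 with 10% rise and fall ramps.  At each sample the
    transmitted strain solves specimen force equilibrium
    sigma(eps_s) A_s = E A_b eps_T with the specimen strain advanced by
    epsdot_s = (2 C0/l_s)(eps_I - eps_T) (compression positive), fixed-point
    iterated to 1e-10; the reflected wave is eps_R = eps_T - eps_I.
    """
    if striker_velocity < 0:
        raise SHPBError("striker velocity must be >= 0")
    C0 = bar.C0
    T_pulse = 2.0 * striker_length / C0
    if T_pulse / dt < 200:
        raise SHPBError("dt too coarse: need >= 200 samples across the pulse")
    n = int(round(T_pulse * (1.0 + tail_fraction) / dt)) + 1
    time = np.arange(n) * dt

    amp = striker_velocity / (2.0 * C0)
    t_rise = 0.1 * T_pulse
    eps_I = np.where(
        time < t_rise,
        amp * time / t_rise,
        np.where(
            time < T_pulse - t_rise,
            amp,
            np.where(time < T_pulse, amp * (T_pulse - time) / t_rise, 0.0),
        ),
    )

    E_s, Y = specimen_material.modulus, specimen_material.yield_strength
    k_rate = 2.0 * C0 / spec.length
    ratio = spec.area / (bar.E * bar.area)

    def epp_stress(eps, eps_p):
        sig = E_s * (eps - eps_p)
        if Y is not None:
            sig = min(max(sig, -Y), Y)
        return sig

    eps_T = np.zeros(n)
    eps_s = 0.0
    eps_p = 0.0
    rate_prev = 0.0
    for i in range(1, n):
        eT = eps_T[i - 1]
        for it in range(200):
            rate = k_rate * (eps_I[i] - eT)
            eps_trial = eps_s + 0.5 * dt * (rate_prev + rate)
            sig = epp_stress(eps_trial, eps_p)
            eT_new = sig * ratio
            if abs(eT_new - eT) < 1e-10:
                eT = eT_new
                break
            eT = eT_new
        else:
            raise SHPBError(
                f"equilibrium fixed point failed to converge at sample {i} "
                f"(t={time[i]:.3e}s, last eps_T={eT:.3e})"
            )
        rate = k_rate * (eps_I[i] - eT)
        eps_s = eps_s + 0.5 * dt * (rate_prev + rate)
        if Y is not None:
            sig_el = E_s * (eps_s - eps_p)
            if sig_el > Y:
                eps_p = eps_s - Y / E_s
            elif sig_el < -Y:
                eps_p = eps_s + Y / E_s
        eps_T[i] = eT
        rate_prev = rate

    eps_R = eps_T - eps_I
    return GaugeRecord(time, eps_I, eps_R, eps_T, compression_positive=True)
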