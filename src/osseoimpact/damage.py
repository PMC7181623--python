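"""Von Mises element-deletion failure rule and damage accounting.

Bone elements whose von Mises stress reaches the dynamic yield strength
of their region are marked ineffective and deleted (stiffness removed,
mass retained); implant elements are exempt.  Deletion is irreversible
and ties at the threshold break toward deletion (the criterion is
"reached", i.e. >=).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import CANCELLOUS, CORTICAL, Mesh
from .materials import MaterialLibrary

__all__ = ["DamageEvent", "DamageReport", "von_mises", "apply_failure", "tally_damage"]


@dataclass(frozen=True)
class DamageEvent:
    element: int
    region: str
    time: float        # s
    von_mises: float   # Pa at deletion


@dataclass
class DamageReport:
    """Ineffective-element tallies by region plus the interface view.

    ``interface`` counts deleted bone elements within one grid spacing of
    the implant surface; every interface element is also counted in its
    region total (a view, not a third region).
    """

    counts: dict = field(default_factory=dict)
    interface: int = 0
    total: int = 0
    events: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "cortical": self.counts.get(CORTICAL, 0),
            "cancellous": self.counts.get(CANCELLOUS, 0),
            "interface": self.interface,
        }

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "element": e.element,
                    "region": e.region,
                    "time_s": e.time,
                    "vm_Pa": e.von_mises,
                }
                for e in self.events
            ],
            columns=["element", "region", "time_s", "vm_Pa"],
        )


def von_mises(sigma: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress of symmetric tensors, shape (..., 3, 3).

    sqrt(1/2[(s11-s22)^2 + (s22-s33)^2 + (s33-s11)^2]
         + 3(s12^2 + s23^2 + s31^2));  rotation invariant.
    """
    sigma = np.asarray(sigma, dtype=float)
    if not np.all(np.isfinite(sigma)):
        raise ValueError("non-finite stress entries")
    s11, s22, s33 = sigma[..., 0, 0], sigma[..., 1, 1], sigma[..., 2, 2]
    s12, s23, s31 = sigma[..., 0, 1], sigma[..., 1, 2], sigma[..., 2, 0]
    return np.sqrt(
        0.5 * ((s11 - s22) ** 2 + (s22 - s33) ** 2 + (s33 - s11) ** 2)
        + 3.0 * (s12**2 + s23**2 + s31**2)
    )


def failure_thresholds(mesh: Mesh, materials: MaterialLibrary) -> np.ndarray:
    """Per-element yield threshold (inf for exempt implant elements)."""
    thr = np.full(mesh.n_elements, np.inf)
    for region in (CORTICAL, CANCELLOUS):
        y = materials.yield_of(region)
        if y is not None:
            thr[mesh.region == region] = y
    return thr


def apply_failure(
    vm: np.ndarray,
    active: np.ndarray,
    thresholds: np.ndarray,
    region: np.ndarray,
    time: float,
    events: list,
) -> np.ndarray:
    """Deactivate active bone elements whose von Mises stress >= threshold.

    Mutates ``active`` in place, appends :class:`DamageEvent`s, and
    returns the indices deleted this step.
    """
    hit = np.flatnonzero(active & (vm >= thresholds))
    for e in hit:
        events.append(DamageEvent(int(e), str(region[e]), float(time), float(vm[e])))
    active[hit] = False
    return hit


def tally_damage(events: list, mesh: Mesh) -> DamageReport:
    """Group deletion events by region, with the interface subset broken out."""
    interface_set = set(mesh.element_sets.get("INTERFACE", np.empty(0, int)).tolist())
    counts: dict[str, int] = {}
    interface = 0
    for e in events:
        if e.element < 0 or e.element >= mesh.n_elements:
            raise ValueError(f"damage event references unknown element {e.element}")
        counts[e.region] = counts.get(e.region, 0) + 1
        if e.element in interface_set:
            interface += 1
    return DamageReport(
        counts=counts, interface=interface, total=len(events), events=list(events)
    )
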