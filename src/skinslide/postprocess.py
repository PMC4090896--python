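"""Stress post-processing: von Mises fields, midline and interface profiles,
and per-simulation summary maxima.

The tissue-loading metric is the plane-stress von Mises (effective) stress.
Internal maxima are taken over the midline element column through the
prominence apex, which is where the load concentrates; whole-field maxima
are also reported for diagnostics.  Interface quantities come from the
contact tractions: the interface effective stress combines the normal
pressure p and shear traction tau as sqrt(p^2 + 3 tau^2), i.e. the von Mises
invariant of a uniaxial-compression-plus-shear state, the only von Mises
expression constructible from exactly those two tractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Mesh

__all__ = [
    "MidlineProfile",
    "InterfaceProfile",
    "SummaryRecord",
    "von_mises_plane_stress",
    "interface_effective",
    "extract_midline",
    "extract_interface",
    "summarize",
]


def von_mises_plane_stress(sxx, syy, txy):
    """Plane-stress effective stress sqrt(sxx^2 - sxx*syy + syy^2 + 3 txy^2)."""
    sxx = np.asarray(sxx, float)
    syy = np.asarray(syy, float)
    txy = np.asarray(txy, float)
    return np.sqrt(np.maximum(sxx**2 - sxx * syy + syy**2 + 3.0 * txy**2, 0.0))


def interface_effective(p, tau):
    """Effective stress of the interface traction state: sqrt(p^2 + 3 tau^2)."""
    p = np.asarray(p, float)
    tau = np.asarray(tau, float)
    return np.sqrt(p**2 + 3.0 * tau**2)


@dataclass
class MidlineProfile:
    """Centroid stresses along the midline element column, ordered by depth
    (0 at the outer skin surface, increasing into the tissue)."""

    layer: np.ndarray  # "skin" | "subcutis" per entry
    depth: np.ndarray  # mm
    effective: np.ndarray  # kPa
    shear: np.ndarray  # kPa (tau_xy)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "layer": self.layer, "depth_mm": self.depth,
            "effective_kPa": self.effective, "shear_kPa": self.shear,
        })


@dataclass
class InterfaceProfile:
    """Per contact-node interface state (non-open nodes only)."""

    x: np.ndarray  # current x position, mm
    pressure: np.ndarray  # kPa
    shear: np.ndarray  # kPa, signed
    effective: np.ndarray  # kPa
    status: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x_mm": self.x, "pressure_kPa": self.pressure,
            "shear_kPa": self.shear, "effective_kPa": self.effective,
            "status": self.status,
        })


@dataclass
class SummaryRecord:
    """End-point maxima of one simulation — one row of the sweep table."""

    mu: float
    E_skin: float
    max_skin_effective: float
    max_subcutis_effective: float
    max_interface_shear: float
    max_interface_effective: float
    extracted_at_time: float
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "mu": self.mu, "E_skin": self.E_skin,
            "max_skin_effective": self.max_skin_effective,
            "max_subcutis_effective": self.max_subcutis_effective,
            "max_interface_shear": self.max_interface_shear,
            "max_interface_effective": self.max_interface_effective,
            "extracted_at_time": self.extracted_at_time,
        }
        d.update(self.extras)
        return d


def extract_midline(solution, mesh: Mesh) -> MidlineProfile:
    """Profile of centroid stresses for the midline element column."""
    if mesh.midline_column.size == 0:
        raise ValueError("mesh carries no midline_column element set")
    if solution.element_stresses is None:
        raise ValueError("solution has no element stresses")
    els = mesh.midline_column
    cent = mesh.node_coords[mesh.quads[els]].mean(axis=1)
    depth = cent[:, 1] - mesh.node_coords[mesh.quads[els][:, 0], 1].min()
    order = np.argsort(depth)
    els = els[order]
    depth = depth[order]
    skin_set = set(mesh.element_sets.get("skin", np.empty(0, int)).tolist())
    layer = np.array(["skin" if e in skin_set else "subcutis" for e in els])
    s = solution.element_stresses[els]
    return MidlineProfile(
        layer=layer,
        depth=depth,
        effective=von_mises_plane_stress(s[:, 0], s[:, 1], s[:, 2]),
        shear=s[:, 2].copy(),
    )


def extract_interface(solution, mesh: Mesh) -> InterfaceProfile:
    """Interface traction profile from the converged contact snapshot."""
    snap = solution.contact_snapshot
    if snap is None:
        raise ValueError("solution carries no contact snapshot")
    keep = snap["status"] != "open"
    nodes = snap["slave_nodes"][keep]
    x = (mesh.node_coords[nodes, 0]
         + solution.u.reshape(-1, 2)[nodes, 0])
    p = snap["pressure"][keep]
    tau = snap["shear"][keep]
    return InterfaceProfile(
        x=x, pressure=p, shear=tau,
        effective=interface_effective(p, tau),
        status=snap["status"][keep],
    )


def summarize(solution, mesh: Mesh, mu: float, E_skin: float) -> SummaryRecord:
    """Reduce a converged final state to its summary maxima.

    Internal maxima are over the midline column; whole-field per-layer
    maxima are logged in ``extras`` for diagnostics.
    """
    if not solution.converged:
        raise ValueError("final state did not converge; refusing to summarize")
    prof = extract_midline(solution, mesh)
    skin = prof.layer == "skin"
    sub = ~skin
    iface = extract_interface(solution, mesh)
    if len(iface.pressure):
        max_shear = float(np.max(np.abs(iface.shear)))
        max_ieff = float(np.max(iface.effective))
    else:
        max_shear = 0.0
        max_ieff = 0.0

    s = solution.element_stresses
    vm = von_mises_plane_stress(s[:, 0], s[:, 1], s[:, 2])
    extras = {}
    for name in ("skin", "subcutis"):
        els = mesh.element_sets.get(name)
        if els is not None and len(els):
            extras[f"field_max_{name}_effective"] = float(vm[els].max())

    return SummaryRecord(
        mu=mu,
        E_skin=E_skin,
        max_skin_effective=float(prof.effective[skin].max()) if skin.any() else 0.0,
        max_subcutis_effective=float(prof.effective[sub].max()) if sub.any() else 0.0,
        max_interface_shear=max_shear,
        max_interface_effective=max_ieff,
        extracted_at_time=float(solution.time),
        extras=extras,
    )
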