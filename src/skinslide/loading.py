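"""Two-phase repositioning load regime and boundary-condition assembly.

Phase 1 (0 <= t <= t_phase1_end): the weight-bearing pressure ramps linearly
to its full value on the tissue top edge while that edge is held at zero
displacement.  Phase 2 (t_phase1_end < t <= t_end): the top edge — a rigid
driver standing in for the bony prominence — translates linearly to the full
lateral slide and downward immersion, carrying the pressure with it.

The top edge is displacement-controlled throughout.  Because every dof of
the driven edge is prescribed, the pressure applied there alters the edge
reactions but not the deformation; internal and interface stresses are set
by the imposed slide/immersion kinematics, which is how the repositioning
maneuver is specified.  The mattress is fully fixed on its sides and bottom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fe import BC
from .geometry import Mesh

__all__ = [
    "LoadCase",
    "ScheduleSpec",
    "BoundaryConditionSet",
    "schedule",
    "edge_pressure_loads",
]


@dataclass(frozen=True)
class LoadCase:
    """Repositioning regime (kPa, mm, s)."""

    bearing_pressure: float = 130.0
    slide_distance: float = 100.0
    immersion_depth: float = 10.0
    t_phase1_end: float = 1.0
    t_end: float = 10.0

    def __post_init__(self) -> None:
        if self.bearing_pressure < 0:
            raise ValueError("bearing_pressure must be >= 0")
        if self.slide_distance < 0 or self.immersion_depth < 0:
            raise ValueError("displacements must be >= 0")
        if not (0.0 < self.t_phase1_end < self.t_end):
            raise ValueError("need 0 < t_phase1_end < t_end")


@dataclass(frozen=True)
class ScheduleSpec:
    """Instantaneous boundary-condition magnitudes at one time."""

    pressure: float  # kPa on the tissue top edge
    ux: float  # prescribed lateral displacement of the top edge (mm)
    uy: float  # prescribed vertical displacement (mm, negative = downward)


def schedule(t: float, case: LoadCase) -> ScheduleSpec:
    """Prescribed loading magnitudes at time ``t``."""
    if t < 0.0 or t > case.t_end + 1e-12:
        raise ValueError(f"t={t} outside [0, {case.t_end}]")
    if t <= case.t_phase1_end:
        frac = t / case.t_phase1_end
        return ScheduleSpec(pressure=frac * case.bearing_pressure, ux=0.0, uy=0.0)
    s = (t - case.t_phase1_end) / (case.t_end - case.t_phase1_end)
    return ScheduleSpec(
        pressure=case.bearing_pressure,
        ux=s * case.slide_distance,
        uy=-s * case.immersion_depth,
    )


def edge_pressure_loads(edge_nodes, coords, pressure: float,
                        thickness: float = 1.0, n_dof: int | None = None
                        ) -> np.ndarray:
    """Work-equivalent nodal forces for a uniform pressure on an edge.

    ``edge_nodes`` is an ordered polyline of node indices; ``coords`` the
    (current) nodal coordinates.  The pressure acts against the edge's
    left-hand normal (downward for an edge ordered by increasing x with the
    body below), so the total force magnitude is
    ``pressure * edge length * thickness``.
    """
    edge_nodes = np.asarray(edge_nodes, int)
    if len(edge_nodes) < 2:
        raise ValueError("edge needs at least 2 nodes")
    xy = coords[edge_nodes]
    d = np.diff(xy, axis=0)
    L = np.linalg.norm(d, axis=1)
    if np.any(L <= 0):
        raise ValueError("zero-length edge segment")
    t_hat = d / L[:, None]
    n_hat = np.column_stack([-t_hat[:, 1], t_hat[:, 0]])
    if n_dof is None:
        n_dof = 2 * len(coords)
    f = np.zeros(n_dof)
    seg_force = -pressure * thickness * L[:, None] * n_hat  # into the body
    for k, (a, b) in enumerate(zip(edge_nodes[:-1], edge_nodes[1:])):
        f[2 * a:2 * a + 2] += 0.5 * seg_force[k]
        f[2 * b:2 * b + 2] += 0.5 * seg_force[k]
    return f


class BoundaryConditionSet:
    """Builds the instantaneous :class:`~skinslide.fe.BC` for the ROI model.

    Fixes the mattress sides and bottom, drives the tissue top edge as a
    rigid driver following :func:`schedule`, and applies the follower
    pressure on the (translated) top edge.
    """

    def __init__(self, mesh: Mesh, case: LoadCase, thickness: float = 1.0):
        self.mesh = mesh
        self.case = case
        self.thickness = thickness
        fixed = np.unique(np.concatenate([
            mesh.node_sets["mattress_sides"], mesh.node_sets["mattress_bottom"]]))
        driven = mesh.node_sets["tissue_top_edge"]
        self.fixed_nodes = fixed
        self.driven_nodes = driven
        self.prescribed_dofs = np.concatenate([
            2 * fixed, 2 * fixed + 1, 2 * driven, 2 * driven + 1])
        self._n_fixed = len(fixed)
        self._n_driven = len(driven)

    def at_time(self, t: float) -> BC:
        spec = schedule(t, self.case)
        nfix, ndrv = self._n_fixed, self._n_driven
        values = np.zeros(2 * nfix + 2 * ndrv)
        values[2 * nfix:2 * nfix + ndrv] = spec.ux
        values[2 * nfix + ndrv:] = spec.uy
        # follower pressure on the rigidly translated top edge
        coords = self.mesh.node_coords.copy()
        coords[self.driven_nodes] += [spec.ux, spec.uy]
        f_ext = edge_pressure_loads(
            self.driven_nodes, coords, spec.pressure, self.thickness)
        return BC(prescribed_dofs=self.prescribed_dofs,
                  prescribed_values=values, f_ext=f_ext)
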