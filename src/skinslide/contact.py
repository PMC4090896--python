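"""Node-to-segment frictional contact: penalty normal law + Coulomb stick-slip.

Slave nodes (the skin's outer boundary) are tested against an ordered master
polyline (the mattress top edge) in the current configuration.  Normal
contact is a linear penalty on penetration; friction is regularized Coulomb:
an elastic (penalty) tangential predictor followed by a return map onto the
friction cone.  Relative slip is measured as the change of the closest-point
arc-length coordinate along the master polyline between converged increments,
so arbitrarily large sliding is supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContactParams",
    "ContactPair",
    "ContactNodeState",
    "closest_point_projection",
    "normal_traction",
    "coulomb_return_map",
    "contact_contributions",
]

_STATUS = {0: "open", 1: "stick", 2: "slip"}


@dataclass(frozen=True)
class ContactParams:
    penalty_normal: float  # kPa/mm
    penalty_tangent: float  # kPa/mm
    max_penetration_check: float | None = None  # mm; None disables the check
    #: fraction of penalty_tangent added to the slip-state tangent matrix
    #: (not the forces).  A force-loaded body whose entire interface slips
    #: has a singular tangential rigid mode in the exact tangent; a small
    #: stabilization removes it.  Displacement-driven problems don't need it.
    slip_stabilization: float = 0.0

    def __post_init__(self) -> None:
        if self.penalty_normal <= 0 or self.penalty_tangent <= 0:
            raise ValueError("penalty stiffnesses must be positive")
        if self.slip_stabilization < 0:
            raise ValueError("slip_stabilization must be >= 0")


@dataclass
class ContactNodeState:
    """Converged record for one slave node."""

    node: int
    gap: float  # mm, negative = penetration
    pressure: float  # kPa
    shear: float  # kPa, signed along the master tangent
    status: str  # open | stick | slip
    accumulated_slip: float  # mm
    segment: int
    xi: float


def _project_points(points: np.ndarray, poly: np.ndarray,
                    smooth_normals: bool = False):
    """Vectorized closest-point projection of ``points`` (s,2) on the
    polyline ``poly`` (k,2).

    Returns (seg, xi, gap, normal, tangent, s_arc); the gap is the signed
    distance along the chosen segment's left-hand normal (outward for a
    polyline ordered by increasing x with the body below).
    Ties between segments resolve to the lower segment id (numpy argmin).

    With ``smooth_normals`` the normal (and the gap sign direction) is the
    averaged vertex normal interpolated along the segment, which makes the
    gap function continuous in the slave position across segment junctions
    of a deformed master surface.
    """
    if len(poly) < 2:
        raise ValueError("master polyline needs at least 2 nodes")
    d = poly[1:] - poly[:-1]  # (k-1, 2)
    L = np.linalg.norm(d, axis=1)
    if np.any(L <= 0):
        raise ValueError("degenerate master segment")
    t_hat = d / L[:, None]
    rel = points[:, None, :] - poly[None, :-1, :]  # (s, k-1, 2)
    xi = np.clip(np.einsum("ski,ki->sk", rel, t_hat) / L[None, :], 0.0, 1.0)
    foot = poly[None, :-1, :] + xi[:, :, None] * d[None, :, :]
    diff = points[:, None, :] - foot
    dist2 = np.einsum("ski,ski->sk", diff, diff)
    seg = np.argmin(dist2, axis=1)
    rows = np.arange(len(points))
    xi_s = xi[rows, seg]
    if smooth_normals:
        seg_n = np.column_stack([-t_hat[:, 1], t_hat[:, 0]])
        vert_n = np.vstack([seg_n[:1], seg_n[:-1] + seg_n[1:], seg_n[-1:]])
        vert_n /= np.linalg.norm(vert_n, axis=1)[:, None]
        n_s = (1.0 - xi_s[:, None]) * vert_n[seg] + xi_s[:, None] * vert_n[seg + 1]
        n_s /= np.linalg.norm(n_s, axis=1)[:, None]
        t_s = np.column_stack([n_s[:, 1], -n_s[:, 0]])
    else:
        t_s = t_hat[seg]
        n_s = np.column_stack([-t_s[:, 1], t_s[:, 0]])
    gap = np.einsum("si,si->s", diff[rows, seg], n_s)
    cum = np.concatenate([[0.0], np.cumsum(L)])
    s_arc = cum[seg] + xi_s * L[seg]
    return seg, xi_s, gap, n_s, t_s, s_arc


def closest_point_projection(point, master_coords):
    """Project a single 2D point onto the master polyline.

    Returns ``(segment_id, xi, gap)`` with xi in [0, 1] and the gap signed
    by the master outward normal.
    """
    pts = np.asarray(point, float)[None, :]
    seg, xi, gap, _, _, _ = _project_points(pts, np.asarray(master_coords, float))
    return int(seg[0]), float(xi[0]), float(gap[0])


def normal_traction(gap, penalty_normal: float):
    """Penalty normal pressure: p = k_n * max(0, -gap)."""
    return penalty_normal * np.maximum(0.0, -np.asarray(gap, float))


def coulomb_return_map(tau_trial: float, p: float, mu: float):
    """Return-map a trial tangential traction onto the Coulomb cone.

    Returns ``(tau, status)`` with status in {"open", "stick", "slip"}.
    """
    if p <= 0.0:
        return 0.0, "open"
    limit = mu * p
    if abs(tau_trial) <= limit:
        return float(tau_trial), "stick"
    return float(np.sign(tau_trial) * limit), "slip"


class ContactPair:
    """Frictional node-to-segment contact pair with persistent stick state.

    ``slave_nodes`` and ``master_nodes`` are ordered node-index arrays into
    the global mesh (master ordered along its polyline).  Tributary areas of
    the slave nodes are computed once from the reference configuration.
    """

    def __init__(self, mesh, slave_nodes, master_nodes, mu: float,
                 params: ContactParams, thickness: float = 1.0):
        if not (0.0 <= mu <= 2.0):
            raise ValueError("mu must lie in [0, 2]")
        self.slave = np.asarray(slave_nodes, int)
        self.master = np.asarray(master_nodes, int)
        if np.intersect1d(self.slave, self.master).size:
            raise ValueError("slave and master node sets must be disjoint")
        self.mu = float(mu)
        self.params = params
        self.thickness = float(thickness)

        ref = mesh.node_coords[self.slave]
        seg_len = np.linalg.norm(np.diff(ref, axis=0), axis=1)
        trib = np.zeros(len(self.slave))
        trib[:-1] += 0.5 * seg_len
        trib[1:] += 0.5 * seg_len
        self.area = trib * self.thickness  # mm^2 per slave node

        # material (reference) arc-length metric of the master polyline: slip
        # is measured in this metric so that stretching of the deformed
        # master surface does not register as relative sliding
        mref = mesh.node_coords[self.master]
        self._L_ref = np.linalg.norm(np.diff(mref, axis=0), axis=1)
        self._cum_ref = np.concatenate([[0.0], np.cumsum(self._L_ref)])

        ns = len(self.slave)
        self.tau_c = np.zeros(ns)  # committed tangential traction
        seg0, xi0, _, _, _, _ = _project_points(
            mesh.node_coords[self.slave], mref, smooth_normals=True)
        self.s_c = self._material_arc(seg0, xi0)
        self.acc_slip = np.zeros(ns)
        self._last = None
        self._prev_sign = None  # slip-direction chatter detection

    def _material_arc(self, seg, xi):
        return self._cum_ref[seg] + xi * self._L_ref[seg]

    # -- evaluation -------------------------------------------------------

    def evaluate(self, coords_current: np.ndarray, frozen: dict | None = None,
                 bound: np.ndarray | None = None):
        """Contact nodal forces and tangent triplets at the given current
        coordinates.  Returns ``(f, (rows, cols, vals))`` with ``f`` a full
        global force vector.

        With ``frozen`` (a dict from :meth:`capture_geometry`), the closest
        point, normal and tangent are held fixed and gap/slip are updated
        linearly from the captured configuration, making the residual
        piecewise affine in the displacements — the solver uses this to
        stabilize Newton when full geometric updates cycle.

        With ``bound`` (per-slave-node friction bounds, kPa), the Coulomb
        limit mu*p is replaced by the given fixed (Tresca) bound: the
        tangential force no longer couples to the normal pressure and the
        resulting problem is convex.  The solver's Uzawa fallback iterates
        ``bound <- mu * p`` to recover the Coulomb solution.
        """
        kn = self.params.penalty_normal
        kt = self.params.penalty_tangent
        pts = coords_current[self.slave]
        poly = coords_current[self.master]
        if frozen is None:
            seg, xi, gap, n_hat, t_hat, _ = _project_points(
                pts, poly, smooth_normals=True)
            s_arc = self._material_arc(seg, xi)
            self._capture = {
                "seg": seg, "xi": xi, "n": n_hat, "t": t_hat,
                "gap0": gap.copy(), "s0": s_arc.copy(),
                "xs0": pts.copy(),
                "xm10": poly[seg].copy(), "xm20": poly[seg + 1].copy(),
            }
        else:
            seg, xi = frozen["seg"], frozen["xi"]
            n_hat, t_hat = frozen["n"], frozen["t"]
            w1 = (1.0 - xi)[:, None]
            w2 = xi[:, None]
            d = ((pts - frozen["xs0"])
                 - w1 * (poly[seg] - frozen["xm10"])
                 - w2 * (poly[seg + 1] - frozen["xm20"]))
            gap = frozen["gap0"] + np.einsum("si,si->s", d, n_hat)
            s_arc = frozen["s0"] + np.einsum("si,si->s", d, t_hat)

        p = normal_traction(gap, kn)
        closed = p > 0.0
        slip = s_arc - self.s_c
        tau_trial = self.tau_c - kt * slip
        if bound is None:
            limit = self.mu * p
        else:
            limit = np.where(closed, bound, 0.0)
        slipping = np.abs(tau_trial) > limit
        tau = np.where(slipping, np.sign(tau_trial) * limit, tau_trial)
        tau[~closed] = 0.0
        status = np.where(closed, np.where(slipping, 2, 1), 0)

        # slip-direction chatter control: a node whose slip direction flips
        # between successive evaluations sits on the boundary between two
        # affine pieces of the return map; Newton can cycle between their
        # exact solutions forever.  Such nodes get a stick-type tangent
        # (forces are untouched), which pins them long enough for the
        # iteration to discover the true stick/slip partition.
        sign_now = np.sign(tau_trial)
        if self._prev_sign is not None and bound is None:
            chatter = slipping & (self._prev_sign * sign_now < 0)
        else:
            chatter = np.zeros(len(sign_now), bool)
        if bound is None:
            self._prev_sign = np.where(slipping, sign_now, 0.0)

        n_dof = 2 * len(coords_current)
        f = np.zeros(n_dof)
        # stiffness is assembled for gap <= 0 (subgradient at exactly zero
        # gap), so bodies resting in touching contact are never singular
        idx = np.where(gap <= 0.0)[0]
        rows_list, cols_list, vals_list = [], [], []
        for i in idx:
            force = (p[i] * n_hat[i] + tau[i] * t_hat[i]) * self.area[i]
            sn = self.slave[i]
            m1 = self.master[seg[i]]
            m2 = self.master[seg[i] + 1]
            w = np.array([1.0, -(1.0 - xi[i]), -xi[i]])
            nodes = np.array([sn, m1, m2])
            for a in range(3):
                f[2 * nodes[a]:2 * nodes[a] + 2] += w[a] * force
            # tangent: K_c = -d f_c / du (assembled onto the Newton matrix)
            M = kn * np.outer(n_hat[i], n_hat[i])
            if status[i] == 1 or chatter[i]:
                M = M + kt * np.outer(t_hat[i], t_hat[i])
            elif bound is None:
                # slip: friction magnitude follows the normal pressure; this
                # unsymmetric coupling is essential here because the soft
                # tissue makes the friction->gap feedback gain exceed one
                M = M + self.mu * kn * np.sign(tau_trial[i]) * np.outer(
                    t_hat[i], n_hat[i])
                if self.params.slip_stabilization:
                    M = M + self.params.slip_stabilization * kt * np.outer(
                        t_hat[i], t_hat[i])
            M = M * self.area[i]
            for a in range(3):
                for b in range(3):
                    blk = w[a] * w[b] * M
                    ra = 2 * nodes[a]
                    rb = 2 * nodes[b]
                    rows_list.extend([ra, ra, ra + 1, ra + 1])
                    cols_list.extend([rb, rb + 1, rb, rb + 1])
                    vals_list.extend([blk[0, 0], blk[0, 1], blk[1, 0], blk[1, 1]])

        self._last = {
            "seg": seg, "xi": xi, "gap": gap, "p": p, "tau": tau,
            "tau_trial": tau_trial, "status": status, "s_arc": s_arc,
            "slip": slip, "closed": closed,
        }
        return f, (np.asarray(rows_list, int), np.asarray(cols_list, int),
                   np.asarray(vals_list, float))

    def commit(self):
        """Accept the last evaluation as the converged increment state.

        Returns ``(dissipation, penalty_energy, snapshot)``; dissipation is
        the frictional energy dissipated over the increment (always >= 0 for
        a consistent return map) and penalty_energy the elastic energy stored
        in the normal and tangential penalties at the new state.
        """
        if self._last is None:
            return 0.0, 0.0, None
        L = self._last
        kt = self.params.penalty_tangent
        kn = self.params.penalty_normal
        tau, slip, closed = L["tau"], L["slip"], L["closed"]
        # plastic (irreversible) part of the incremental slip
        slip_p = np.where(closed, slip + (tau - self.tau_c) / kt, 0.0)
        diss = float(np.sum(-tau * slip_p * self.area))
        self.acc_slip += np.abs(slip_p)
        pen = float(np.sum(
            (L["p"]**2 / (2.0 * kn) + np.where(closed, tau**2, 0.0)
             / (2.0 * kt)) * self.area))
        self.tau_c = np.where(closed, tau, 0.0)
        self.s_c = L["s_arc"].copy()
        self._prev_sign = None
        snapshot = {
            "slave_nodes": self.slave.copy(),
            "gap": L["gap"].copy(),
            "pressure": L["p"].copy(),
            "shear": L["tau"].copy(),
            "status": np.array([_STATUS[s] for s in L["status"]]),
            "segment": L["seg"].copy(),
            "xi": L["xi"].copy(),
            "accumulated_slip": self.acc_slip.copy(),
            "mu": self.mu,
        }
        return diss, pen, snapshot

    def tresca_energy(self, coords_current: np.ndarray, frozen: dict,
                      bound: np.ndarray) -> float:
        """Contact part of the incremental potential for the fixed-bound
        (Tresca) problem on frozen geometry: quadratic normal penalty plus
        the convex elastic/slip tangential potential.  Used by the solver's
        energy line search; its negative gradient is the contact force of
        :meth:`evaluate` with the same ``frozen`` and ``bound``.
        """
        kn = self.params.penalty_normal
        kt = self.params.penalty_tangent
        pts = coords_current[self.slave]
        poly = coords_current[self.master]
        seg, xi = frozen["seg"], frozen["xi"]
        n_hat, t_hat = frozen["n"], frozen["t"]
        d = ((pts - frozen["xs0"])
             - (1.0 - xi)[:, None] * (poly[seg] - frozen["xm10"])
             - xi[:, None] * (poly[seg + 1] - frozen["xm20"]))
        gap = frozen["gap0"] + np.einsum("si,si->s", d, n_hat)
        s_arc = frozen["s0"] + np.einsum("si,si->s", d, t_hat)
        pen = np.maximum(0.0, -gap)
        closed = pen > 0.0
        en = 0.5 * kn * pen**2

        ds = s_arc - self.s_c
        g = np.where(closed, bound, 0.0)
        # convex tangential potential: elastic parabola capped by +-g slopes
        ds_hi = (self.tau_c + g) / kt   # beyond: tau = -g
        ds_lo = (self.tau_c - g) / kt   # below: tau = +g
        phi_el = -self.tau_c * ds + 0.5 * kt * ds**2
        phi_hi = (-self.tau_c * ds_hi + 0.5 * kt * ds_hi**2
                  + g * (ds - ds_hi))
        phi_lo = (-self.tau_c * ds_lo + 0.5 * kt * ds_lo**2
                  - g * (ds - ds_lo))
        phi = np.where(ds > ds_hi, phi_hi, np.where(ds < ds_lo, phi_lo,
                                                    phi_el))
        en = en + np.where(closed, phi, 0.0)
        return float(np.sum(en * self.area))

    def capture_geometry(self) -> dict:
        """Projection geometry captured at the last full evaluation, for use
        as the ``frozen`` argument of :meth:`evaluate`."""
        return self._capture

    def last_active_count(self):
        if self._last is None:
            return 0
        return int(np.count_nonzero(self._last["closed"]))

    def node_states(self) -> list[ContactNodeState]:
        if self._last is None:
            return []
        L = self._last
        return [
            ContactNodeState(
                node=int(self.slave[i]), gap=float(L["gap"][i]),
                pressure=float(L["p"][i]), shear=float(L["tau"][i]),
                status=_STATUS[int(L["status"][i])],
                accumulated_slip=float(self.acc_slip[i]),
                segment=int(L["seg"][i]), xi=float(L["xi"][i]))
            for i in range(len(self.slave))
        ]

    def max_penetration(self) -> float:
        if self._last is None:
            return 0.0
        return float(max(0.0, -np.min(self._last["gap"])))


def contact_contributions(pair: ContactPair, coords_current: np.ndarray):
    """Residual force vector and tangent triplets for the pair at the given
    current coordinates (equal-and-opposite slave/master transfer)."""
    return pair.evaluate(coords_current)
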