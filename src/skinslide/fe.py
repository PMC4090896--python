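"""Plane-stress Q4 finite-element engine with an incremental Newton solver.

Elements are 4-node isoparametric quadrilaterals integrated with 2x2 Gauss
quadrature.  Materials are linear elastic; the only nonlinearity is contact,
whose kinematics are evaluated on the current (deformed) configuration each
Newton iteration so that large relative sliding is captured while the element
response stays linear (engineering strain).

Convergence of each load increment is declared on an energy criterion —
the work of the Newton correction on the residual, relative to the first
iteration of the increment — with a relative residual-norm fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Mesh

__all__ = [
    "PlaneStressMaterial",
    "SolverSettings",
    "SolutionState",
    "BC",
    "FEModel",
    "constitutive_plane_stress",
    "q4_element_stiffness",
    "assemble",
    "newton_solve_increment",
    "solve_quasi_static",
]

_GP = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) / np.sqrt(3.0)
_NODES_REF = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], float)


@dataclass(frozen=True)
class PlaneStressMaterial:
    """Isotropic linear-elastic plane-stress material (E in kPa, lengths mm)."""

    E: float
    nu: float
    thickness: float = 1.0

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError("nu must lie in [0, 0.5) for plane stress")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")

    def d_matrix(self) -> np.ndarray:
        E, nu = self.E, self.nu
        c = E / (1.0 - nu**2)
        return c * np.array([
            [1.0, nu, 0.0],
            [nu, 1.0, 0.0],
            [0.0, 0.0, (1.0 - nu) / 2.0],
        ])


@dataclass(frozen=True)
class PlaneStrainMaterial(PlaneStressMaterial):
    """Plane-strain variant (out-of-plane strain suppressed).

    For nearly incompressible soft tissue this gives a much stiffer bulk
    response than plane stress, because material can no longer escape in
    the out-of-plane direction.  Provided for cross-section studies where
    the modeled slice is laterally confined.
    """

    def d_matrix(self) -> np.ndarray:
        E, nu = self.E, self.nu
        c = E / ((1.0 + nu) * (1.0 - 2.0 * nu))
        return c * np.array([
            [1.0 - nu, nu, 0.0],
            [nu, 1.0 - nu, 0.0],
            [0.0, 0.0, (1.0 - 2.0 * nu) / 2.0],
        ])


def constitutive_plane_stress(strain, material: PlaneStressMaterial):
    """Map engineering strain (exx, eyy, gxy) to stress (sxx, syy, txy)."""
    return tuple(material.d_matrix() @ np.asarray(strain, float))


def _shape_derivs(xi: float, eta: float) -> np.ndarray:
    """dN/d(xi, eta) of the bilinear quad, shape (4, 2)."""
    out = np.empty((4, 2))
    for a, (xa, ya) in enumerate(_NODES_REF):
        out[a, 0] = 0.25 * xa * (1.0 + ya * eta)
        out[a, 1] = 0.25 * ya * (1.0 + xa * xi)
    return out


def _batch_b_matrices(xy: np.ndarray, xi: float, eta: float):
    """B (m,3,8) and detJ (m,) at one reference point, for elements ``xy``
    of shape (m,4,2)."""
    dN = _shape_derivs(xi, eta)  # (4,2)
    J = np.einsum("eai,aj->eij", xy, dN)  # J[i,j] = dx_i/dxi_j
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    invJ = np.empty_like(J)
    invJ[:, 0, 0] = J[:, 1, 1]
    invJ[:, 1, 1] = J[:, 0, 0]
    invJ[:, 0, 1] = -J[:, 0, 1]
    invJ[:, 1, 0] = -J[:, 1, 0]
    invJ /= detJ[:, None, None]
    dN_xy = np.einsum("aj,eji->eai", dN, invJ)  # (m,4,2)
    m = len(xy)
    B = np.zeros((m, 3, 8))
    B[:, 0, 0::2] = dN_xy[:, :, 0]
    B[:, 1, 1::2] = dN_xy[:, :, 1]
    B[:, 2, 0::2] = dN_xy[:, :, 1]
    B[:, 2, 1::2] = dN_xy[:, :, 0]
    return B, detJ


def _batch_stiffness(xy: np.ndarray, D: np.ndarray, thickness: float):
    """Element stiffness matrices (m,8,8) by 2x2 Gauss quadrature."""
    K = np.zeros((len(xy), 8, 8))
    for xi, eta in _GP:
        B, detJ = _batch_b_matrices(xy, xi, eta)
        if np.any(detJ <= 0):
            raise ValueError("non-positive Jacobian at a quadrature point")
        K += np.einsum("eki,kl,elj,e->eij", B, D, B, detJ) * thickness
    return K


def q4_element_stiffness(coords, material: PlaneStressMaterial) -> np.ndarray:
    """Stiffness of a single Q4 element (8x8, dofs [u1,v1,...,u4,v4])."""
    xy = np.asarray(coords, float)[None]
    return _batch_stiffness(xy, material.d_matrix(), material.thickness)[0]


class FEModel:
    """Assembled global model: stiffness, dof bookkeeping, stress recovery."""

    def __init__(self, mesh: Mesh, materials: dict[str, PlaneStressMaterial]):
        missing = set(mesh.element_sets) - set(materials)
        if missing:
            raise ValueError(f"no material given for element sets {sorted(missing)}")
        self.mesh = mesh
        self.materials = materials
        self.n_dof = 2 * mesh.n_nodes
        self._assemble()

    def _assemble(self) -> None:
        mesh = self.mesh
        edof = np.empty((mesh.n_elements, 8), int)
        edof[:, 0::2] = 2 * mesh.quads
        edof[:, 1::2] = 2 * mesh.quads + 1
        self.edof = edof

        rows, cols, vals = [], [], []
        self._centroid_B = np.zeros((mesh.n_elements, 3, 8))
        self._D = np.zeros((mesh.n_elements, 3, 3))
        for name, els in mesh.element_sets.items():
            mat = self.materials[name]
            xy = mesh.node_coords[mesh.quads[els]]
            Ke = _batch_stiffness(xy, mat.d_matrix(), mat.thickness)
            ed = edof[els]
            rows.append(np.repeat(ed, 8, axis=1).ravel())
            cols.append(np.tile(ed, (1, 8)).ravel())
            vals.append(Ke.ravel())
            B0, _ = _batch_b_matrices(xy, 0.0, 0.0)
            self._centroid_B[els] = B0
            self._D[els] = mat.d_matrix()
        K = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_dof, self.n_dof),
        ).tocsr()
        K.sum_duplicates()
        self.K = K

    def internal_force(self, u: np.ndarray) -> np.ndarray:
        return self.K @ u

    def strain_energy(self, u: np.ndarray) -> float:
        return 0.5 * float(u @ (self.K @ u))

    def element_stresses(self, u: np.ndarray) -> np.ndarray:
        """Centroid stresses (sxx, syy, txy) per element, shape (m, 3)."""
        ue = u[self.edof]  # (m, 8)
        strain = np.einsum("eib,eb->ei", self._centroid_B, ue)
        return np.einsum("eij,ej->ei", self._D, strain)

    def current_coords(self, u: np.ndarray) -> np.ndarray:
        return self.mesh.node_coords + u.reshape(-1, 2)


def assemble(mesh: Mesh, materials: dict[str, PlaneStressMaterial]) -> FEModel:
    """Assemble the global stiffness and return the model object, which also
    serves as the internal-force evaluator (``model.internal_force``)."""
    return FEModel(mesh, materials)


@dataclass(frozen=True)
class SolverSettings:
    n_increments_phase1: int = 10
    n_increments_phase2: int = 90
    energy_tol: float = 1e-10
    force_tol: float = 1e-8
    max_newton_iters: int = 60
    penalty_normal: float | None = None  # kPa/mm; None -> auto from materials
    penalty_tangent: float | None = None  # kPa/mm; None -> same as normal

    def __post_init__(self) -> None:
        if self.energy_tol <= 0 or self.force_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.n_increments_phase1 < 1 or self.n_increments_phase2 < 1:
            raise ValueError("increments must be >= 1")


@dataclass
class BC:
    """Instantaneous boundary conditions: prescribed dofs and external loads."""

    prescribed_dofs: np.ndarray
    prescribed_values: np.ndarray
    f_ext: np.ndarray


@dataclass
class SolutionState:
    time: float
    u: np.ndarray
    element_stresses: np.ndarray | None
    contact_snapshot: dict | None
    converged: bool
    newton_iterations_used: int
    strain_energy: float = 0.0
    external_work: float = 0.0
    frictional_dissipation: float = 0.0  # cumulative
    increment_dissipation: float = 0.0
    penalty_energy: float = 0.0


class NonConvergenceError(RuntimeError):
    def __init__(self, msg, residual=None, active_set=None):
        super().__init__(msg)
        self.residual = residual
        self.active_set = active_set


def _free_mask(n_dof: int, prescribed: np.ndarray) -> np.ndarray:
    mask = np.ones(n_dof, bool)
    mask[prescribed] = False
    return mask


class _LinearSolver:
    """Solves (Kff + Kc_ff) x = b with a single factorization of Kff.

    The global stiffness is constant for a whole quasi-static run and the
    contact tangent touches only a few hundred dofs, so each Newton system
    is the factorized matrix plus a low-rank update and is solved with the
    Sherman-Morrison-Woodbury identity.  Columns of Kff^-1 for contact dofs
    are computed on first use and cached across increments.
    """

    def __init__(self, K, free_idx: np.ndarray):
        self.free_idx = free_idx
        self.n_free = len(free_idx)
        # global dof id -> position in the free vector (-1 if prescribed)
        self.pos = -np.ones(K.shape[0], dtype=int)
        self.pos[free_idx] = np.arange(self.n_free)
        self.Kff = K[free_idx][:, free_idx].tocsr()
        self.lu = spla.splu(self.Kff.tocsc())
        self._cols: dict[int, np.ndarray] = {}  # global dof -> Kff^-1 e_dof

    def _inv_cols(self, dofs: np.ndarray) -> np.ndarray:
        out = np.empty((self.n_free, len(dofs)))
        for k, d in enumerate(dofs):
            col = self._cols.get(d)
            if col is None:
                e = np.zeros(self.n_free)
                e[self.pos[d]] = 1.0
                col = self.lu.solve(e)
                self._cols[d] = col
            out[:, k] = col
        return out

    def solve(self, rf: np.ndarray, kc_coo) -> np.ndarray:
        rows, cols, vals = kc_coo
        if rows.size == 0:
            return self.lu.solve(rf)
        # restrict the contact triplets to free dofs
        keep = (self.pos[rows] >= 0) & (self.pos[cols] >= 0)
        rows, cols, vals = rows[keep], cols[keep], vals[keep]
        if rows.size == 0:
            return self.lu.solve(rf)
        dofs = np.unique(np.concatenate([rows, cols]))
        pos_d = self.pos[dofs]
        loc = {d: i for i, d in enumerate(dofs)}
        nc = len(dofs)
        M = np.zeros((nc, nc))
        np.add.at(M, ([loc[r] for r in rows], [loc[c] for c in cols]), vals)
        X = self._inv_cols(dofs)  # (n_free, nc)
        y = self.lu.solve(rf)
        S = X[pos_d, :]  # P^T Kff^-1 P
        rhs = M @ y[pos_d]
        x = None
        try:
            w = np.linalg.solve(np.eye(nc) + M @ S, rhs)
            x = y - X @ w
        except np.linalg.LinAlgError:
            pass
        if x is not None:
            # verify: the low-rank update is only valid when Kff itself is
            # nonsingular (contact may be what restrains a rigid mode)
            res = self._apply(x, rows, cols, vals) - rf
            if (np.all(np.isfinite(res))
                    and np.linalg.norm(res)
                    <= 1e-8 * (np.linalg.norm(rf) + 1e-30)):
                return x
        Kc = sp.coo_matrix(
            (vals, (self.pos[rows], self.pos[cols])),
            shape=(self.n_free, self.n_free)).tocsc()
        return spla.splu((self.Kff + Kc).tocsc()).solve(rf)

    def _apply(self, x, rows, cols, vals):
        out = self.Kff @ x
        np.add.at(out, self.pos[rows], vals * x[self.pos[cols]])
        return out


def newton_solve_increment(
    model: FEModel,
    state: SolutionState,
    bc: BC,
    contact,
    settings: SolverSettings,
    time: float | None = None,
    linsolver: _LinearSolver | None = None,
) -> SolutionState:
    """Advance the solution to the boundary conditions ``bc``.

    ``contact`` is a ``ContactPair`` (or None); its kinematics are
    re-evaluated from current coordinates at every iteration, and its
    internal stick/slip state is committed only on convergence.
    ``linsolver`` carries the factorized stiffness between increments.
    """
    K = model.K
    n = model.n_dof
    u = state.u.copy()
    u[bc.prescribed_dofs] = bc.prescribed_values
    free = _free_mask(n, bc.prescribed_dofs)
    free_idx = np.where(free)[0]
    if linsolver is None or not np.array_equal(linsolver.free_idx, free_idx):
        linsolver = _LinearSolver(K, free_idx)

    def residual(u_vec, frozen=None, bound=None):
        if contact is not None:
            fc_, kc_ = contact.evaluate(model.current_coords(u_vec),
                                        frozen=frozen, bound=bound)
        else:
            fc_, kc_ = np.zeros(n), (np.empty(0, int),) * 3
        fint_ = K @ u_vec
        r_ = bc.f_ext + fc_ - fint_
        ref_ = max(
            float(np.linalg.norm((bc.f_ext + fc_)[free_idx])),
            float(np.linalg.norm(fint_[free_idx])),
            1e-8,
        )
        return fc_, kc_, r_[free_idx], ref_

    def newton_step(u_vec, kc_coo, rf):
        du = linsolver.solve(rf, kc_coo)
        if not np.all(np.isfinite(du)):
            raise NonConvergenceError("singular or ill-posed system in "
                                      "Newton iteration")
        out = u_vec.copy()
        out[free_idx] += du
        return out, du

    # Two-mode Newton: plain iterations re-evaluate the full contact
    # kinematics each step (fast when it works); when they stall, the
    # projection geometry is frozen, making the residual piecewise affine,
    # and a semismooth phase polishes the state before geometry is updated
    # again.  Cycling across projection kinks otherwise prevents
    # convergence on kinked, deformed master surfaces.
    e0 = None
    converged = False
    fc, kc_coo, rf, ref = residual(u)
    last_res = float(np.linalg.norm(rf))
    plain_used = 0
    while plain_used < settings.max_newton_iters and not converged:
        # --- plain phase (full geometric updates), a short batch
        for _ in range(10):
            if last_res <= settings.force_tol * ref:
                converged = True
                break
            u_try, du = newton_step(u, kc_coo, rf)
            e = abs(float(du @ rf))
            if e0 is None:
                e0 = e
            fc, kc_coo, rf_t, ref = residual(u_try)
            u, rf = u_try, rf_t
            last_res = float(np.linalg.norm(rf))
            plain_used += 1
            if not np.isfinite(last_res):
                raise NonConvergenceError("residual diverged",
                                          residual=last_res)
            # energy exit, guarded by a loose residual bound so an
            # ill-scaled step cannot fake convergence
            if e0 <= 1e-300 or (e <= settings.energy_tol * e0
                                and last_res <= 1e-3 * ref):
                converged = True
                break
            if plain_used >= settings.max_newton_iters:
                break
        if converged or contact is None:
            break
        # --- frozen-geometry (semismooth) phase
        frozen = contact.capture_geometry()
        fc_f, kc_f, rf_f, ref_f = residual(u, frozen=frozen)
        for _ in range(30):
            res_f = float(np.linalg.norm(rf_f))
            if res_f <= max(settings.force_tol * ref_f, 1e-6 * last_res):
                break
            u, _ = newton_step(u, kc_f, rf_f)
            fc_f, kc_f, rf_f, ref_f = residual(u, frozen=frozen)
        # refresh the true residual and give plain Newton another chance
        fc, kc_coo, rf, ref = residual(u)
        last_res = float(np.linalg.norm(rf))

    # --- Uzawa fallback: Coulomb friction as a sequence of convex Tresca
    # problems (fixed friction bound, frozen geometry), the bound updated
    # from the converged normal pressures.  Handles configurations where
    # the coupled Newton iteration cycles (e.g. symmetric Poisson spreading
    # under settle, where slip directions sit on a knife edge).
    if not converged and contact is not None:
        for cycle in range(6):
            fc, kc_coo, rf, ref = residual(u)  # fresh geometry capture
            frozen = contact.capture_geometry()
            g = contact.mu * contact._last["p"]

            def potential(u_vec, g_vec):
                return (0.5 * float(u_vec @ (K @ u_vec))
                        - float(bc.f_ext @ u_vec)
                        + contact.tresca_energy(model.current_coords(u_vec),
                                                frozen, g_vec))

            for outer in range(15):
                fc_f, kc_f, rf_f, ref_f = residual(u, frozen=frozen, bound=g)
                for _ in range(40):
                    if (float(np.linalg.norm(rf_f))
                            <= 1e-3 * settings.force_tol * ref_f):
                        break
                    u_new, du = newton_step(u, kc_f, rf_f)
                    # Armijo line search on the convex incremental potential
                    slope = -float(rf_f @ du)  # dPi/dalpha at alpha=0 (<0)
                    E0 = potential(u, g)
                    alpha = 1.0
                    for _ls in range(30):
                        u_try = u.copy()
                        u_try[free_idx] += alpha * du
                        if potential(u_try, g) <= E0 + 1e-4 * alpha * slope:
                            break
                        alpha *= 0.5
                    u = u_try
                    fc_f, kc_f, rf_f, ref_f = residual(u, frozen=frozen,
                                                       bound=g)
                g_new = contact.mu * contact._last["p"]
                dg = float(np.linalg.norm(g_new - g))
                g = g_new
                if dg <= 1e-8 * max(1.0, float(np.linalg.norm(g))):
                    break
            # check the true (Coulomb, current-geometry) residual; if the
            # frozen-geometry error still dominates, recapture and repeat
            fc, kc_coo, rf, ref = residual(u)
            last_res = float(np.linalg.norm(rf))
            if last_res <= settings.force_tol * ref:
                converged = True
                break
            # energy criterion on one plain Newton correction from here
            u_new, du = newton_step(u, kc_coo, rf)
            e = abs(float(du @ rf))
            accept_energy = (e0 is not None and e0 > 1e-300
                             and e <= settings.energy_tol * e0
                             and last_res <= 1e-3 * ref)
            fc, kc_coo, rf, ref = residual(u_new)
            res_new = float(np.linalg.norm(rf))
            if res_new <= last_res:
                u, last_res = u_new, res_new
            else:
                fc, kc_coo, rf, ref = residual(u)
            if accept_energy or last_res <= settings.force_tol * ref:
                converged = True
                break

    it = plain_used
    if not converged:
        active = None
        if contact is not None:
            active = contact.last_active_count()
        raise NonConvergenceError(
            f"no convergence in {settings.max_newton_iters} Newton iterations "
            f"(last residual {last_res:.3e})",
            residual=last_res, active_set=active)

    t_new = state.time if time is None else time
    # external work: trapezoidal over the increment, including reaction work
    # on prescribed dofs
    du_tot = u - state.u
    fint_new = K @ u
    reac_new = fint_new - fc - bc.f_ext
    reac_old = getattr(state, "_reactions", np.zeros(n))
    fext_old = getattr(state, "_f_ext", np.zeros(n))
    w_inc = 0.5 * float((bc.f_ext + fext_old) @ du_tot)
    w_inc += 0.5 * float((reac_new + reac_old)[bc.prescribed_dofs]
                         @ du_tot[bc.prescribed_dofs])

    snap = None
    d_inc = 0.0
    pen_e = 0.0
    if contact is not None:
        d_inc, pen_e, snap = contact.commit()

    new = SolutionState(
        time=t_new,
        u=u,
        element_stresses=None,
        contact_snapshot=snap,
        converged=True,
        newton_iterations_used=it,
        strain_energy=model.strain_energy(u),
        external_work=state.external_work + w_inc,
        frictional_dissipation=state.frictional_dissipation + d_inc,
        increment_dissipation=d_inc,
        penalty_energy=pen_e,
    )
    new._reactions = reac_new
    new._f_ext = bc.f_ext.copy()
    return new


def solve_quasi_static(
    model: FEModel,
    bc_at_time,
    times,
    contact=None,
    settings: SolverSettings | None = None,
    keep_history: bool = False,
    callback=None,
):
    """Run the incremental quasi-static solution over ``times``.

    ``bc_at_time(t)`` must return a :class:`BC`.  Returns the final
    :class:`SolutionState` (with element stresses filled in), plus the list
    of all states when ``keep_history`` is true.
    """
    settings = settings or SolverSettings()
    state = SolutionState(
        time=float(times[0]) if len(times) else 0.0,
        u=np.zeros(model.n_dof),
        element_stresses=None,
        contact_snapshot=None,
        converged=True,
        newton_iterations_used=0,
    )
    history = [state] if keep_history else None
    context = {"linsolver": None}

    def advance(st, t0, t1, depth):
        """Solve the step t0 -> t1, bisecting it when Newton fails."""
        bc = bc_at_time(t1)
        free_idx = np.where(_free_mask(model.n_dof, bc.prescribed_dofs))[0]
        ls = context["linsolver"]
        if ls is None or not np.array_equal(ls.free_idx, free_idx):
            ls = _LinearSolver(model.K, free_idx)
            context["linsolver"] = ls
        try:
            return newton_solve_increment(
                model, st, bc, contact, settings, time=t1, linsolver=ls)
        except NonConvergenceError:
            if depth >= 6:
                raise
            mid = 0.5 * (t0 + t1)
            st = advance(st, t0, mid, depth + 1)
            return advance(st, mid, t1, depth + 1)

    for t in times:
        state = advance(state, state.time, float(t), 0)
        if keep_history:
            state.element_stresses = model.element_stresses(state.u)
            history.append(state)
        if callback is not None:
            callback(state)
    state.element_stresses = model.element_stresses(state.u)
    if keep_history:
        return state, history
    return state
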