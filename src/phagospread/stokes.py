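"""Perturbed axisymmetric Stokes solver on the quadrilateral mesh.

The creeping-flow problem is discretized with equal-order bilinear
velocity/pressure elements; the near-incompressibility perturbation
∇·(v − ε∇p) = 0 stabilizes the pair.  The coupled system is solved either
by the alternating velocity/pressure (Uzawa-style) iteration with the
relative pressure-change criterion, or monolithically by a sparse direct
factorization (used as the cross-check route).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu, spsolve

from .constitutive import BoundaryStressField
from .exceptions import InvalidArgumentError, NonConvergenceError
from .geometry import Mesh, _DN_GAUSS

__all__ = [
    "SolverSettings",
    "FlowField",
    "StokesOperators",
    "epsilon_bound",
    "assemble_system",
    "uzawa_solve",
    "solve_monolithic",
    "divergence_norm",
]

_GAUSS_PTS = [(-1 / np.sqrt(3), -1 / np.sqrt(3)), (1 / np.sqrt(3), -1 / np.sqrt(3)),
              (-1 / np.sqrt(3), 1 / np.sqrt(3)), (1 / np.sqrt(3), 1 / np.sqrt(3))]


def _shape_values():
    N = np.empty((4, 4))
    for g, (xi, eta) in enumerate(_GAUSS_PTS):
        N[g] = 0.25 * np.array([(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                                (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)])
    return N


_N_GAUSS = _shape_values()
# _DN_GAUSS from geometry uses the same corner ordering but its own Gauss
# point ordering; rebuild here so values and derivatives stay aligned.


def _shape_derivs():
    dN = np.empty((4, 4, 2))
    for g, (xi, eta) in enumerate(_GAUSS_PTS):
        dN[g] = 0.25 * np.array([
            [-(1 - eta), -(1 - xi)],
            [(1 - eta), -(1 + xi)],
            [(1 + eta), (1 + xi)],
            [-(1 + eta), (1 - xi)],
        ])
    return dN


_DN = _shape_derivs()


def epsilon_bound(h_mesh: float, mu: float) -> float:
    """Stability bound ε = h²/(2μ) for the pressure perturbation."""
    if h_mesh <= 0 or mu <= 0:
        raise InvalidArgumentError("h_mesh and mu must be positive")
    return h_mesh**2 / (2.0 * mu)


@dataclass
class SolverSettings:
    """Numerical settings of the perturbed-Stokes solve."""

    epsilon: float | None = None       # None → h_mesh²/(2μ)
    uzawa_tol: float = 1e-6
    max_iterations: int = 500
    relaxation: float = 1.0

    def __post_init__(self):
        if self.uzawa_tol <= 0 or self.max_iterations < 1:
            raise InvalidArgumentError("tolerances must be positive")
        if self.epsilon is not None and self.epsilon <= 0:
            raise InvalidArgumentError("epsilon must be positive")


@dataclass
class FlowField:
    """Velocity/pressure solution on the mesh nodes."""

    v: np.ndarray                # (N, 2) μm/s
    p: np.ndarray                # (N,) Pa
    iterations: int
    residual: float

    @property
    def max_speed(self) -> float:
        return float(np.max(np.hypot(self.v[:, 0], self.v[:, 1])))


@dataclass
class StokesOperators:
    """Assembled FEM operators for one mesh/stress configuration."""

    A: sp.csr_matrix             # viscous stiffness with Dirichlet rows/cols applied
    G: sp.csr_matrix             # pressure → velocity-equation coupling (∫ p ∇·w r)
    M: sp.csr_matrix             # pressure mass matrix (r-weighted)
    K: sp.csr_matrix             # pressure stiffness matrix (r-weighted)
    load: np.ndarray             # boundary traction load vector (2N,)
    dirichlet_dofs: np.ndarray
    dirichlet_values: np.ndarray
    lift: np.ndarray             # load correction for nonzero Dirichlet values
    mesh: Mesh
    mu: float
    epsilon: float

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_nodes


def assemble_system(
    mesh: Mesh,
    stresses: BoundaryStressField | np.ndarray,
    mu: float,
    settings: SolverSettings | None = None,
    p_out: float = 0.0,
    dirichlet_values: np.ndarray | None = None,
) -> StokesOperators:
    """Assemble the axisymmetric perturbed-Stokes operators.

    Neumann tractions −(σ_adh + σ_cortex + σ_prot) − p_out·n enter through
    the boundary load on Γ_free (given per free contour node); no-slip holds
    on Γ_adherent and v_r = 0 on the axis.  ``dirichlet_values`` optionally
    prescribes nonzero values on the adherent dofs (used for verification
    problems).
    """
    if settings is None:
        settings = SolverSettings()
    tractions = stresses.total() if isinstance(stresses, BoundaryStressField) else np.asarray(stresses, float)
    nf = len(mesh.free_node_ids)
    if tractions.shape != (nf, 2):
        raise InvalidArgumentError("traction array must be (n_free_nodes, 2)")

    coords = mesh.coords
    quads = mesh.quads
    E = len(quads)
    xy = coords[quads]                                   # (E, 4, 2)
    J = np.einsum("gai,eaj->egij", _DN, xy)              # (E, 4, 2, 2)
    detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
    if np.min(detJ) <= 0:
        raise InvalidArgumentError("mesh contains non-positive Jacobians")
    Jinv = np.empty_like(J)
    Jinv[..., 0, 0] = J[..., 1, 1]
    Jinv[..., 1, 1] = J[..., 0, 0]
    Jinv[..., 0, 1] = -J[..., 0, 1]
    Jinv[..., 1, 0] = -J[..., 1, 0]
    Jinv /= detJ[..., None, None]
    # dN/dx: (E, g, a, dim)
    dNdx = np.einsum("egij,gaj->egai", Jinv, _DN)
    r_g = np.einsum("ga,ea->eg", _N_GAUSS, xy[..., 0])   # (E, 4)
    wgt = detJ * r_g                                      # unit Gauss weights

    N_g = np.broadcast_to(_N_GAUSS, (E, 4, 4))
    dNdr = dNdx[..., 0]
    dNdz = dNdx[..., 1]
    N_over_r = N_g / r_g[..., None]

    # velocity stiffness: strains e = (err, ezz, ett, 2*erz), D = diag(2μ,2μ,2μ,μ)
    B = np.zeros((E, 4, 4, 8))
    B[:, :, 0, 0::2] = dNdr
    B[:, :, 1, 1::2] = dNdz
    B[:, :, 2, 0::2] = N_over_r
    B[:, :, 3, 0::2] = dNdz
    B[:, :, 3, 1::2] = dNdr
    dweights = np.array([2 * mu, 2 * mu, 2 * mu, mu])
    DB = B * dweights[None, None, :, None]
    Ke = np.einsum("egia,egib,eg->eab", B, DB, wgt, optimize=True)

    # coupling ∫ (∇·w) N_p r  → (8, 4) per element
    divW = np.zeros((E, 4, 8))
    divW[:, :, 0::2] = dNdr + N_over_r
    divW[:, :, 1::2] = dNdz
    Ge = np.einsum("ega,egb,eg->eab", divW, N_g, wgt, optimize=True)

    Me = np.einsum("ega,egb,eg->eab", N_g, N_g, wgt, optimize=True)
    Kpe = np.einsum("egai,egbi,eg->eab", dNdx, dNdx, wgt, optimize=True)

    ndof = 2 * mesh.n_nodes
    vdof = np.empty((E, 8), dtype=np.int64)
    vdof[:, 0::2] = 2 * quads
    vdof[:, 1::2] = 2 * quads + 1

    def scatter(elem_mat, rows_map, cols_map, shape):
        nr = rows_map.shape[1]
        nc = cols_map.shape[1]
        rows = np.repeat(rows_map, nc, axis=1).ravel()
        cols = np.tile(cols_map, (1, nr)).ravel()
        return sp.coo_matrix((elem_mat.reshape(-1), (rows, cols)), shape=shape).tocsr()

    A = scatter(Ke, vdof, vdof, (ndof, ndof))
    G = scatter(Ge, vdof, quads, (ndof, mesh.n_nodes))
    M = scatter(Me, quads, quads, (mesh.n_nodes, mesh.n_nodes))
    Kp = scatter(Kpe, quads, quads, (mesh.n_nodes, mesh.n_nodes))

    # boundary traction load on Γ_free (2-point Gauss per edge)
    load = np.zeros(ndof)
    fids = mesh.free_node_ids
    t_full = tractions - p_out * _free_normals(mesh)
    pts = coords[fids]
    seg = pts[1:] - pts[:-1]
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    for gp, wq in ((-1 / np.sqrt(3), 1.0), (1 / np.sqrt(3), 1.0)):
        N1, N2 = 0.5 * (1 - gp), 0.5 * (1 + gp)
        r_q = N1 * pts[:-1, 0] + N2 * pts[1:, 0]
        t_q = N1 * t_full[:-1] + N2 * t_full[1:]
        common = wq * 0.5 * seg_len * r_q
        for a, Na, ids in ((0, N1, fids[:-1]), (1, N2, fids[1:])):
            np.add.at(load, 2 * ids, Na * common * t_q[:, 0])
            np.add.at(load, 2 * ids + 1, Na * common * t_q[:, 1])

    # Dirichlet sets: no-slip (or prescribed) on Γ_adherent, v_r = 0 on axis
    adh = mesh.adherent_node_ids
    dir_dofs = np.concatenate([2 * adh, 2 * adh + 1, 2 * mesh.axis_node_ids])
    dir_dofs, order = np.unique(dir_dofs, return_index=True)
    if dirichlet_values is None:
        dir_vals = np.zeros(len(dir_dofs))
    else:
        vals_all = np.asarray(dirichlet_values, float).ravel()
        dir_vals = vals_all[dir_dofs]

    vfull = np.zeros(ndof)
    vfull[dir_dofs] = dir_vals
    lift = A @ vfull
    A_bc = _apply_dirichlet(A, dir_dofs)
    eps = settings.epsilon if settings.epsilon is not None else epsilon_bound(mesh.h_mesh, mu)
    return StokesOperators(A_bc, G, M, Kp, load, dir_dofs, dir_vals, lift,
                           mesh, mu, eps)


def _free_normals(mesh: Mesh) -> np.ndarray:
    """Outward unit normals at the free boundary nodes of the mesh."""
    pts = mesh.coords[mesh.free_node_ids]
    t = np.gradient(pts, axis=0)
    norm = np.hypot(t[:, 0], t[:, 1])
    n = np.column_stack([-t[:, 1] / norm, t[:, 0] / norm])
    return n


def _apply_dirichlet(A: sp.csr_matrix, dofs: np.ndarray) -> sp.csr_matrix:
    n = A.shape[0]
    keep = np.ones(n)
    keep[dofs] = 0.0
    P = sp.diags(keep)
    fix = np.zeros(n)
    fix[dofs] = 1.0
    return (P @ A @ P + sp.diags(fix)).tocsr()


def _constrained_rhs(ops: StokesOperators, p_vec: np.ndarray) -> np.ndarray:
    f = ops.load + ops.G @ p_vec - ops.lift
    f[ops.dirichlet_dofs] = ops.dirichlet_values
    return f


def uzawa_solve(
    ops: StokesOperators,
    p_init: np.ndarray | None = None,
    settings: SolverSettings | None = None,
    p_out: float = 0.0,
) -> FlowField:
    """Alternate velocity solves and pressure updates until the relative
    pressure-change criterion max|p − p_est| / max|p − p_out| ≤ tol."""
    if settings is None:
        settings = SolverSettings(epsilon=ops.epsilon)
    n = ops.n_nodes
    p_est = np.full(n, p_out) if p_init is None else np.asarray(p_init, float).copy()
    lu_A = splu(ops.A.tocsc())
    P_op = (ops.M / ops.mu + ops.epsilon * ops.K).tocsc()
    lu_P = splu(P_op)
    Gt = ops.G.T.tocsr()
    omega = settings.relaxation
    history = []
    for it in range(1, settings.max_iterations + 1):
        v_flat = lu_A.solve(_constrained_rhs(ops, p_est))
        # pressure update enforcing ∇·(v − ε∇p) = 0 at the fixed point;
        # the mass term damps the alternation so it contracts
        rhs_p = ops.M @ p_est / ops.mu - Gt @ v_flat
        p_new = lu_P.solve(rhs_p)
        if omega != 1.0:
            p_new = p_est + omega * (p_new - p_est)
        num = float(np.max(np.abs(p_new - p_est)))
        den = float(np.max(np.abs(p_new - p_out)))
        res = 0.0 if den == 0.0 and num == 0.0 else num / max(den, 1e-300)
        history.append(res)
        p_est = p_new
        if res <= settings.uzawa_tol:
            v_flat = lu_A.solve(_constrained_rhs(ops, p_est))
            return FlowField(v_flat.reshape(-1, 2), p_est, it, res)
    raise NonConvergenceError(
        f"Uzawa iteration did not reach {settings.uzawa_tol} in "
        f"{settings.max_iterations} iterations (last residual {history[-1]:.3e})",
        residual_history=history)


def solve_monolithic(ops: StokesOperators, p_out: float = 0.0) -> FlowField:
    """Direct sparse solve of the coupled perturbed-Stokes system.

    Independent route used to verify the Uzawa fixed point: the block system
    [[A, −G], [Gᵀ, −εK]] (x = (v, p)) shares its solution with the
    converged alternation.
    """
    n = ops.n_nodes
    Gt = ops.G.T.tocsr()
    top = sp.hstack([ops.A, -_zero_rows(ops.G, ops.dirichlet_dofs)])
    bottom = sp.hstack([Gt, ops.epsilon * ops.K])
    Kmono = sp.vstack([top, bottom]).tocsc()
    rhs = np.concatenate([ops.load - ops.lift, np.zeros(n)])
    rhs[ops.dirichlet_dofs] = ops.dirichlet_values
    sol = spsolve(Kmono, rhs)
    v = sol[: 2 * n].reshape(-1, 2)
    p = sol[2 * n:]
    return FlowField(v, p, 1, 0.0)


def _zero_rows(mat: sp.csr_matrix, rows: np.ndarray) -> sp.csr_matrix:
    keep = np.ones(mat.shape[0])
    keep[rows] = 0.0
    return (sp.diags(keep) @ mat).tocsr()


def divergence_norm(ops: StokesOperators, flow: FlowField,
                    interior_only: bool = False) -> float:
    """L2(r-weighted) average of the nodal divergence residual of v.

    With ``interior_only`` the average excludes nodes within two grid
    layers of the boundary, i.e. the pressure boundary layer created by the
    zero-normal-gradient pressure condition.
    """
    v_flat = flow.v.reshape(-1)
    dv = ops.G.T @ v_flat                       # ∫ (∇·v) N_i r
    w = np.asarray(ops.M.sum(axis=1)).ravel()
    w = np.maximum(w, 1e-30)
    if interior_only:
        mesh = ops.mesh
        tagged = np.zeros(mesh.n_nodes, bool)
        for ids in (mesh.free_node_ids, mesh.adherent_node_ids, mesh.axis_node_ids):
            tagged[np.asarray(ids)] = True
        for _ in range(2):  # grow the excluded band by element adjacency
            touched = tagged[mesh.quads].any(axis=1)
            grow = tagged.copy()
            grow[mesh.quads[touched].ravel()] = True
            tagged = grow
        keep = ~tagged
        if not np.any(keep):
            keep = np.ones(mesh.n_nodes, bool)
        dv, w = dv[keep], w[keep]
    return float(np.sqrt(np.mean(dv * dv / w)))
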