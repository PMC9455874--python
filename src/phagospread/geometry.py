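"""Axisymmetric cell-contour representation, measurement and meshing.

The cell surface is described by its generating curve in the (r, z)
half-plane.  Nodes run from the apex (r = 0, top of the cell) down the free
surface to the contact line (z = 0) and then inward along the substrate to
the axis, so the closed region bounded by the curve, the substrate and the
symmetry axis is the cell cross-section.  All lengths are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from shapely.geometry import LineString

from .exceptions import GeometryError, InvalidArgumentError, VolumeDriftError

__all__ = [
    "CellContour",
    "Mesh",
    "init_spherical_cap",
    "measure_contour",
    "compute_normals",
    "compute_normal_angles",
    "compute_curvature",
    "generate_mesh",
    "smooth_contour",
    "correct_volume",
    "resample_contour",
    "solve_cap_height",
]

Z_FLOOR_FREE = 1e-4  # μm; interior free nodes stay strictly off the substrate


# ---------------------------------------------------------------------------
# contour
# ---------------------------------------------------------------------------

@dataclass
class CellContour:
    """Ordered generating curve of the axisymmetric cell surface.

    ``r``, ``z``
        Node coordinates (μm).  Node 0 is the apex (r = 0); nodes up to
        ``contact_index`` trace the free surface; nodes from
        ``contact_index`` onward lie on the substrate (z = 0), ending on the
        axis at (0, 0).
    ``contact_index``
        Index of the contact-line node, i.e. the first adherent node.
    """

    r: np.ndarray
    z: np.ndarray
    contact_index: int
    _s: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.r.ndim != 1 or self.r.shape != self.z.shape:
            raise InvalidArgumentError("r and z must be 1-D arrays of equal length")
        if len(self.r) < 3:
            raise GeometryError("contour needs at least 3 nodes")
        if not (0 < self.contact_index < len(self.r)):
            raise InvalidArgumentError("contact_index out of range")
        if abs(self.r[0]) > 1e-9:
            raise GeometryError("first node must lie on the symmetry axis (r = 0)")
        self.r[0] = 0.0
        if np.any(self.r < -1e-12):
            raise GeometryError("negative radial coordinate")
        if np.any(self.z < -1e-9):
            raise GeometryError("node below the substrate plane (z < 0)")
        if np.any(np.abs(self.z[self.contact_index:]) > 1e-9):
            raise GeometryError("adherent nodes must have z = 0")
        self.z[self.contact_index:] = 0.0
        self._s = None

    # -- derived quantities -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.r)

    @property
    def s(self) -> np.ndarray:
        """Arc length from the apex (μm), per node."""
        if self._s is None:
            ds = np.hypot(np.diff(self.r), np.diff(self.z))
            if np.any(ds <= 0):
                raise GeometryError("coincident consecutive nodes")
            self._s = np.concatenate([[0.0], np.cumsum(ds)])
        return self._s

    @property
    def s_contact(self) -> float:
        """Arc length at the contact line (μm)."""
        return float(self.s[self.contact_index])

    @property
    def contact_radius(self) -> float:
        return float(self.r[self.contact_index])

    @property
    def free_r(self) -> np.ndarray:
        """Radial coordinates of the free surface incl. the contact node."""
        return self.r[: self.contact_index + 1]

    @property
    def free_z(self) -> np.ndarray:
        return self.z[: self.contact_index + 1]

    @property
    def n_free(self) -> int:
        """Number of free-surface nodes (contact-line node included)."""
        return self.contact_index + 1

    @property
    def phi(self) -> np.ndarray:
        """Angle of the outward normal vs. the +z axis, free nodes (rad)."""
        return compute_normal_angles(self)

    def is_simple(self) -> bool:
        pts = np.column_stack([self.r, self.z])
        return bool(LineString(pts).is_simple)

    def validate(self, check_simple: bool = True) -> None:
        _ = self.s  # raises on coincident nodes
        if check_simple and not self.is_simple():
            raise GeometryError("self-intersecting contour")

    def copy(self) -> "CellContour":
        return CellContour(self.r.copy(), self.z.copy(), self.contact_index)


def solve_cap_height(contact_area: float, volume: float) -> tuple[float, float]:
    """Height ``h`` and sphere radius ``R`` of the spherical cap with the
    given flat contact area and enclosed volume.

    Uses V = (π h / 6) (3 a² + h²), a = contact radius; monotone in h.
    """
    if volume <= 0:
        raise InvalidArgumentError("volume must be positive")
    if contact_area < 0:
        raise InvalidArgumentError("contact area must be non-negative")
    a2 = contact_area / np.pi
    # cubic: π h³ / 6 + π a² h / 2 − V = 0, single positive root
    roots = np.roots([np.pi / 6.0, 0.0, np.pi * a2 / 2.0, -volume])
    h = float(max(rt.real for rt in roots if abs(rt.imag) < 1e-9 * abs(rt.real) + 1e-12 and rt.real > 0))
    R = (a2 + h * h) / (2.0 * h)
    return h, R


def init_spherical_cap(
    diameter: float,
    footprint_area: float,
    n_free: int = 160,
    n_adherent: int = 8,
    grading: float = 4.0,
) -> CellContour:
    """Initial spherical-cap contour resting on the substrate.

    The enclosed volume equals the volume of the full sphere of the given
    diameter; the flat footprint has the given area.  Free-surface node
    spacing is graded finer toward the contact line.
    """
    if diameter <= 0:
        raise InvalidArgumentError("diameter must be positive")
    if footprint_area <= 0:
        raise InvalidArgumentError("footprint_area must be positive")
    if footprint_area >= np.pi * (diameter / 2.0) ** 2:
        raise InvalidArgumentError("footprint exceeds the sphere cross-section")
    volume = np.pi * diameter**3 / 6.0
    h, R = solve_cap_height(footprint_area, volume)
    a = np.sqrt(footprint_area / np.pi)
    # polar angle from the apex; cap meets substrate at theta_max
    theta_max = np.pi - np.arcsin(min(1.0, a / R))
    t = _graded_param(n_free, grading)
    theta = t * theta_max
    zc = h - R  # sphere centre height
    r = R * np.sin(theta)
    z = zc + R * np.cos(theta)
    r[0] = 0.0
    r[-1] = a
    z[-1] = 0.0
    z = np.maximum(z, 0.0)
    contour = _append_adherent(r, z, n_adherent)
    contour.validate(check_simple=False)
    return contour


def _graded_param(n: int, grading: float) -> np.ndarray:
    """n parameter values in [0, 1] whose spacing shrinks geometrically by a
    total factor ``grading`` from the start to the end."""
    if n < 2:
        raise InvalidArgumentError("need at least 2 nodes")
    if grading <= 0:
        raise InvalidArgumentError("grading must be positive")
    g = grading ** (1.0 / (n - 1))
    w = g ** -np.arange(n - 1, dtype=float)  # spacing shrinks toward the end
    t = np.concatenate([[0.0], np.cumsum(w)])
    return t / t[-1]


def _adherent_radii(contact_radius: float, n_adherent: int,
                    grading: float = 2.5) -> np.ndarray:
    """Radial positions of the adherent nodes from the contact line to the
    axis, mildly clustered near the contact line."""
    t = _graded_param(n_adherent, 1.0 / grading)  # gaps grow away from the line
    return contact_radius * (1.0 - t)


def _append_adherent(r_free, z_free, n_adherent) -> CellContour:
    a = r_free[-1]
    radii = _adherent_radii(a, max(3, n_adherent))[1:]  # contact node already present
    r = np.concatenate([r_free, radii])
    z = np.concatenate([z_free, np.zeros_like(radii)])
    return CellContour(r, z, contact_index=len(r_free) - 1)


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def measure_contour(c: CellContour, include_base: bool = True,
                    check_simple: bool = True) -> tuple[float, float]:
    """Surface area (μm²) and enclosed volume (μm³) of the contour.

    Area is 2π ∫ r ds over the free surface; with ``include_base`` the flat
    adherent disc π r_c² is added (the convention used for the tension law).
    Volume is the solid of revolution, V = π ∫ r² (−dz).
    """
    if c.n_nodes < 3 or c.n_free < 2:
        raise GeometryError("degenerate contour")
    c.validate(check_simple=check_simple)
    rf, zf = c.free_r, c.free_z
    dr = np.diff(rf)
    dz = np.diff(zf)
    ds = np.hypot(dr, dz)
    r_mid = 0.5 * (rf[:-1] + rf[1:])
    area = 2.0 * np.pi * float(np.sum(r_mid * ds))
    if include_base:
        area += np.pi * c.contact_radius**2
    # π ∮ r² (−dz); adherent part has dz = 0
    r2_mid = (rf[:-1] ** 2 + rf[:-1] * rf[1:] + rf[1:] ** 2) / 3.0
    volume = -np.pi * float(np.sum(r2_mid * dz))
    return area, volume


def compute_normals(c: CellContour) -> np.ndarray:
    """Outward unit normals at the free-surface nodes, shape (n_free, 2)."""
    rf, zf = c.free_r, c.free_z
    s = c.s[: c.n_free]
    tr = np.gradient(rf, s, edge_order=2)
    tz = np.gradient(zf, s, edge_order=2)
    norm = np.hypot(tr, tz)
    tr /= norm
    tz /= norm
    n = np.column_stack([-tz, tr])
    return n


def compute_normal_angles(c: CellContour) -> np.ndarray:
    """Unwrapped angle φ of the outward normal vs. +z, free nodes (rad)."""
    n = compute_normals(c)
    phi = np.unwrap(np.arctan2(n[:, 0], n[:, 1]))
    phi -= phi[0] - np.arcsin(np.clip(np.sin(phi[0]), -1, 1))  # keep apex near 0
    return phi


def _batched_cubic_fit(s: np.ndarray, y: np.ndarray, centers: np.ndarray,
                       windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares cubic fits of y(s) over index windows.

    ``windows`` is an (n, w) integer array of node indices per fit.  Returns
    fitted values and first derivatives at ``centers`` (the s value of each
    fit's own node).
    """
    ds = s[windows] - centers[:, None]
    scale = np.maximum(np.max(np.abs(ds), axis=1, keepdims=True), 1e-30)
    x = ds / scale
    # Vandermonde (n, w, 4)
    V = np.stack([np.ones_like(x), x, x * x, x * x * x], axis=-1)
    A = np.einsum("nwi,nwj->nij", V, V)
    b = np.einsum("nwi,nw->ni", V, y[windows])
    coef = np.linalg.solve(A, b[..., None])[..., 0]
    vals = coef[:, 0]
    derivs = coef[:, 1] / scale[:, 0]
    return vals, derivs


def _window_indices(n: int, width: int) -> np.ndarray:
    half = width // 2
    starts = np.clip(np.arange(n) - half, 0, max(0, n - width))
    return starts[:, None] + np.arange(width)[None, :]


def compute_curvature(c: CellContour, window: int = 7) -> np.ndarray:
    """Mean curvature ∂φ/∂s + sin(φ)/r at the free-surface nodes (μm⁻¹).

    φ and its arc-length derivative come from moving-window cubic
    polynomial fits; the on-axis term is resolved by its symmetric limit
    (curvature = 2 ∂φ/∂s at the apex).
    """
    nf = c.n_free
    if nf < 5:
        raise GeometryError("need at least 5 free-surface nodes for curvature")
    if np.any(c.free_r[1:] <= 0):
        raise GeometryError("free node with r = 0 off the apex")
    phi_raw = compute_normal_angles(c)
    s = c.s[:nf].copy()
    # odd extension about the apex keeps the fits symmetric there
    next_ = min(window, nf - 1)
    s_ext = np.concatenate([-s[next_:0:-1], s])
    phi_ext = np.concatenate([-phi_raw[next_:0:-1], phi_raw])
    centers_idx = np.arange(nf) + next_
    windows = _window_indices(len(s_ext), min(window, len(s_ext)))
    # recenter windows on the actual node indices
    half = min(window, len(s_ext)) // 2
    starts = np.clip(centers_idx - half, 0, len(s_ext) - min(window, len(s_ext)))
    windows = starts[:, None] + np.arange(min(window, len(s_ext)))[None, :]
    phi_fit, dphids = _batched_cubic_fit(s_ext, phi_ext, s_ext[centers_idx], windows)
    kappa = np.empty(nf)
    kappa[0] = 2.0 * dphids[0]
    kappa[1:] = dphids[1:] + np.sin(phi_fit[1:]) / c.free_r[1:]
    return kappa


# ---------------------------------------------------------------------------
# smoothing / resampling / volume correction
# ---------------------------------------------------------------------------

def smooth_contour(c: CellContour, window: int = 7) -> CellContour:
    """Local cubic least-squares (Savitzky–Golay-style) smoothing of the
    free surface.

    Interior free nodes are replaced by the value of a ``window``-point
    cubic fit of (r, z) against arc length; the apex, the contact node and
    all adherent nodes are unchanged.  A 7-point window damps a single-node
    spike by about two thirds while leaving smooth data unchanged.
    """
    nf = c.n_free
    if nf <= window:
        return c.copy()
    s = c.s[:nf]
    windows = _window_indices(nf, window)
    r_fit, _ = _batched_cubic_fit(s, c.free_r, s, windows)
    z_fit, _ = _batched_cubic_fit(s, c.free_z, s, windows)
    r = c.r.copy()
    z = c.z.copy()
    # keep the contact-line corner out of the fits: smoothing across the
    # slope discontinuity would drag the adjacent membrane onto the
    # substrate and artificially advance the zipper
    guard = window // 2
    hi = max(nf - 1 - guard, 2)
    r[1: hi] = r_fit[1: hi]
    z[1: hi] = np.maximum(z_fit[1: hi], Z_FLOOR_FREE)
    r[1: hi] = np.maximum(r[1: hi], 1e-9)
    return CellContour(r, z, c.contact_index)


def resample_contour(
    c: CellContour,
    n_free: int | None = None,
    grading: float = 4.0,
    n_adherent: int | None = None,
    ds_adherent: float | None = None,
) -> CellContour:
    """Redistribute nodes along the contour.

    Free nodes are placed at graded arc-length positions (finer toward the
    contact line) on a cubic-spline interpolant of the current free surface;
    the apex and the contact node are preserved exactly.  Adherent nodes are
    regridded on the substrate, clustered near the contact line.
    """
    # shape-preserving interpolation: a plain cubic spline overshoots at the
    # contact-line corner and can fold the resampled foot under the substrate
    from scipy.interpolate import PchipInterpolator

    nf_old = c.n_free
    n_free = nf_old if n_free is None else n_free
    s = c.s[:nf_old]
    u = s / s[-1]
    spline_r = PchipInterpolator(u, c.free_r)
    spline_z = PchipInterpolator(u, c.free_z)
    t = _graded_param(n_free, grading)
    r_new = spline_r(t)
    z_new = spline_z(t)
    r_new[0] = 0.0
    r_new[-1] = c.contact_radius
    # interior free nodes float strictly above the substrate so the free
    # polyline can never overlap the adherent base collinearly
    z_new[1:] = np.maximum(z_new[1:], Z_FLOOR_FREE)
    z_new[-1] = 0.0
    r_new[1:] = np.maximum(r_new[1:], 1e-9)
    if n_adherent is None:
        n_adh_old = c.n_nodes - c.contact_index
        if ds_adherent is not None:
            n_adherent = int(np.clip(np.ceil(c.contact_radius / ds_adherent) + 2, 4, 40))
        else:
            n_adherent = max(4, n_adh_old)
    return _append_adherent(r_new, z_new, n_adherent)


def correct_volume(c: CellContour, v_target: float, rel_tol: float = 1e-6) -> CellContour:
    """Displace free nodes along their normals so the volume hits ``v_target``.

    A single scalar offset (found by 1-D root finding) is applied to every
    free node except the contact node; the apex moves along the axis.
    """
    if v_target <= 0:
        raise InvalidArgumentError("target volume must be positive")
    _, v0 = measure_contour(c)
    drift = (v0 - v_target) / v_target
    if abs(drift) < 1e-14:
        return c.copy()
    if abs(drift) > 0.05:
        raise VolumeDriftError(
            f"volume drift {drift:.2%} exceeds 5% — upstream solver problem")
    normals = compute_normals(c)
    nf = c.n_free
    area_free = measure_contour(c, include_base=False)[0] - np.pi * c.contact_radius**2

    def displaced(delta: float) -> CellContour:
        r = c.r.copy()
        z = c.z.copy()
        r[1: nf - 1] += delta * normals[1: nf - 1, 0]
        z[1: nf - 1] += delta * normals[1: nf - 1, 1]
        z[0] += delta * normals[0, 1]
        z[1: nf - 1] = np.maximum(z[1: nf - 1], 0.0)
        r[1: nf - 1] = np.maximum(r[1: nf - 1], 1e-9)
        return CellContour(r, z, c.contact_index)

    def vol_err(delta: float) -> float:
        _, v = measure_contour(displaced(delta), check_simple=False)
        return v - v_target

    d0 = (v_target - v0) / max(area_free, 1e-12)
    lo, hi = min(0.0, 3.0 * d0), max(0.0, 3.0 * d0)
    for _ in range(60):
        if vol_err(lo) * vol_err(hi) <= 0:
            break
        lo, hi = 1.6 * lo - 0.1 * abs(d0), 1.6 * hi + 0.1 * abs(d0)
    else:
        raise GeometryError("could not bracket the volume correction")
    delta = brentq(vol_err, lo, hi, xtol=1e-13, rtol=8.9e-16)
    out = displaced(delta)
    _, v_new = measure_contour(out)
    if abs(v_new - v_target) / v_target > rel_tol:
        raise GeometryError("volume correction failed to converge")
    return out


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """Body-fitted quadrilateral mesh of the cell half cross-section.

    Structured grid with index u along the free contour (apex → contact
    line) and index w from the axis to the surface; the strip touching the
    apex degenerates to triangles (two coincident corner nodes).
    """

    coords: np.ndarray            # (N, 2) node coordinates (r, z)
    quads: np.ndarray             # (E, 4) connectivity, CCW
    free_edges: np.ndarray        # (n, 2) node-id pairs on Γ_free
    adherent_edges: np.ndarray    # (n, 2) node-id pairs on Γ_adherent
    axis_edges: np.ndarray        # (n, 2) node-id pairs on the axis
    free_node_ids: np.ndarray     # contour free node i → mesh node id
    adherent_node_ids: np.ndarray  # along the substrate, axis → contact line
    axis_node_ids: np.ndarray
    shape: tuple[int, int]        # (n_u, n_w)
    h_mesh: float                 # characteristic element radius (μm)
    elem_sizes: np.ndarray        # per-element size for Courant control

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_elements(self) -> int:
        return len(self.quads)

    def min_jacobian(self) -> float:
        return float(np.min(_gauss_jacobians(self.coords, self.quads)))


_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)


def _quad_shape_derivs():
    pts = [(xi, eta) for eta in _GP for xi in _GP]
    dN = np.empty((4, 4, 2))
    for g, (xi, eta) in enumerate(pts):
        dN[g] = 0.25 * np.array([
            [-(1 - eta), -(1 - xi)],
            [(1 - eta), -(1 + xi)],
            [(1 + eta), (1 + xi)],
            [-(1 + eta), (1 - xi)],
        ])
    return dN


_DN_GAUSS = _quad_shape_derivs()


def _gauss_jacobians(coords: np.ndarray, quads: np.ndarray) -> np.ndarray:
    xy = coords[quads]  # (E, 4, 2)
    J = np.einsum("gai,eaj->egij", _DN_GAUSS, xy)
    return J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]


def generate_mesh(c: CellContour, n_layers: int | None = None) -> Mesh:
    """Build the structured quad mesh bounded by the contour.

    Grid lines in the w direction run from the axis to the free surface;
    the substrate edge discretization matches the contour's adherent nodes,
    which gives tighter element packing near the flat surface.  Identical
    contours produce identical meshes.
    """
    c.validate(check_simple=False)
    nf = c.n_free
    adh_r = c.r[c.contact_index:][::-1].copy()   # axis → contact line
    if n_layers is not None and n_layers != len(adh_r):
        adh_r = _adherent_radii(c.contact_radius, n_layers)[::-1]
    n_w = len(adh_r)
    if nf < 3 or n_w < 2:
        raise GeometryError("contour too coarse to mesh")
    rc = c.contact_radius
    w = adh_r / rc if rc > 0 else np.linspace(0, 1, n_w)
    w[0], w[-1] = 0.0, 1.0
    s_free = c.s[:nf]
    u_hat = s_free / s_free[-1]
    z_apex = c.z[0]
    # inner path: straight down the axis, matched to normalized arc length
    A_z = z_apex * (1.0 - u_hat)
    C = np.column_stack([c.free_r, c.free_z])
    n_u = nf

    def node_id(i, j):
        return np.where(i == 0, 0, (i - 1) * n_w + j + 1)

    n_nodes = 1 + (n_u - 1) * n_w
    coords = np.empty((n_nodes, 2))
    coords[0] = C[0]
    ii = np.arange(1, n_u)
    R = np.outer(w, C[ii, 0]).T                      # (n_u-1, n_w)
    Z = (1 - w)[None, :] * A_z[ii, None] + w[None, :] * C[ii, 1][:, None]
    coords[1:, 0] = R.reshape(-1)
    coords[1:, 1] = Z.reshape(-1)

    I, Jj = np.meshgrid(np.arange(n_u - 1), np.arange(n_w - 1), indexing="ij")
    quads = np.stack([
        node_id(I, Jj), node_id(I + 1, Jj), node_id(I + 1, Jj + 1), node_id(I, Jj + 1)
    ], axis=-1).reshape(-1, 4)

    i_arr = np.arange(n_u)
    free_ids = node_id(i_arr, np.full(n_u, n_w - 1))
    adherent_ids = node_id(np.full(n_w, n_u - 1), np.arange(n_w))
    axis_ids = np.concatenate([[0], node_id(i_arr[1:], np.zeros(n_u - 1, int))])
    free_edges = np.column_stack([free_ids[:-1], free_ids[1:]])
    adherent_edges = np.column_stack([adherent_ids[:-1], adherent_ids[1:]])
    axis_edges = np.column_stack([axis_ids[:-1], axis_ids[1:]])

    detJ = _gauss_jacobians(coords, quads)
    if np.min(detJ) <= 0:
        coords = _untangle(coords, quads, n_u, n_w, node_id)
        detJ = _gauss_jacobians(coords, quads)
        if np.min(detJ) <= 0:
            raise GeometryError(
                f"mesh generation failed: {np.sum(np.min(detJ, axis=1) <= 0)} "
                "inverted elements after smoothing")
    areas = np.sum(detJ, axis=1)  # Σ w_g |J| with unit weights = element area
    elem_sizes = np.sqrt(np.maximum(areas, 1e-30))
    h_mesh = float(np.median(elem_sizes))
    return Mesh(coords, quads, free_edges, adherent_edges, axis_edges,
                free_ids, adherent_ids, axis_ids, (n_u, n_w), h_mesh, elem_sizes)


def _untangle(coords, quads, n_u, n_w, node_id, n_iter=30):
    """Laplacian smoothing of interior grid nodes with the boundary fixed."""
    coords = coords.copy()
    I, Jj = np.meshgrid(np.arange(1, n_u - 1), np.arange(1, n_w - 1), indexing="ij")
    ids = node_id(I, Jj)
    nbrs = np.stack([node_id(I - 1, Jj), node_id(I + 1, Jj),
                     node_id(I, Jj - 1), node_id(I, Jj + 1)])
    for _ in range(n_iter):
        coords[ids] = np.mean(coords[nbrs], axis=0)
        if np.min(_gauss_jacobians(coords, quads)) > 0:
            break
    return coords
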