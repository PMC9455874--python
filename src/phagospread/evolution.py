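"""Time evolution of the spreading cell: adaptive time step, boundary
advection, contact-line updates (continuum and discrete) and the full
per-step cycle combining geometry, constitutive laws and the Stokes solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constitutive as law
from . import geometry, stokes
from .constitutive import BoundaryStressField, PhysicalParams
from .exceptions import GeometryError, InvalidArgumentError
from .geometry import CellContour, Mesh

__all__ = [
    "AdhesionSites",
    "SimulationState",
    "compute_timestep",
    "advect",
    "update_contact_continuum",
    "update_contact_discrete",
    "step",
]


@dataclass
class AdhesionSites:
    """Concentric rings of discrete substrate binding sites.

    Ring radii are spaced by (ρ_l)^(−1/2); ``shift`` offsets the whole
    lattice laterally (used for ensemble averaging).  Bound sites are never
    released and record their binding time exactly once.
    """

    radii: np.ndarray
    bound: np.ndarray
    t_bind: np.ndarray
    spacing: float
    shift: float = 0.0

    @classmethod
    def create(cls, rho_l: float, r_max: float, shift: float = 0.0) -> "AdhesionSites":
        if rho_l <= 0:
            raise InvalidArgumentError("ligand density must be positive for discrete runs")
        spacing = rho_l ** -0.5
        if not 0.0 <= shift < spacing:
            shift = shift % spacing
        radii = np.arange(shift if shift > 0 else spacing, r_max, spacing)
        if shift > 0:
            radii = np.concatenate([[shift], np.arange(shift + spacing, r_max, spacing)])
        return cls(radii=radii, bound=np.zeros(len(radii), bool),
                   t_bind=np.full(len(radii), np.nan), spacing=spacing, shift=shift)

    @property
    def n_bound(self) -> int:
        return int(np.sum(self.bound))

    def bind(self, idx: int, t: float) -> None:
        if self.bound[idx]:
            raise InvalidArgumentError("site already bound (bonds are irreversible)")
        self.bound[idx] = True
        self.t_bind[idx] = t

    def outermost_bound_radius(self) -> float:
        if not np.any(self.bound):
            return 0.0
        return float(self.radii[self.bound].max())

    def last_bind_time(self) -> float:
        if not np.any(self.bound):
            return np.nan
        return float(np.nanmax(self.t_bind[self.bound]))


@dataclass
class SimulationState:
    """Everything that evolves during a run."""

    time: float
    contour: CellContour
    params: PhysicalParams
    v_target: float                      # conserved volume, μm³
    A_cell0: float                       # resting surface area, μm²
    A_c_trans: float                     # transition contact area, μm²
    sites: AdhesionSites | None = None
    mesh: Mesh | None = None
    flow: stokes.FlowField | None = None
    p_warm: np.ndarray | None = None
    warm_shape: tuple[int, int] | None = None
    t_last_bind: float = 0.0
    tau: float = 0.0                     # mN/m
    sigma_prot: float = 0.0              # Pa (current overall strength)
    A_c: float = 0.0
    A_cell: float = 0.0
    volume: float = 0.0
    diagnostics: dict = field(default_factory=dict)

    def measure(self) -> None:
        self.A_cell, self.volume = geometry.measure_contour(self.contour)
        self.A_c = np.pi * self.contour.contact_radius**2


def compute_timestep(
    mesh: Mesh,
    flow: stokes.FlowField,
    courant_fraction: float = 0.1,
    dt_max: float = 0.5,
) -> float:
    """Courant-limited time step: flow crosses at most ``courant_fraction``
    of any element; capped at ``dt_max`` when velocities are tiny."""
    speeds = np.hypot(flow.v[:, 0], flow.v[:, 1])
    elem_speed = np.max(speeds[mesh.quads], axis=1)
    with np.errstate(divide="ignore"):
        dt_elem = mesh.elem_sizes / np.maximum(elem_speed, 1e-300)
    dt = courant_fraction * float(np.min(dt_elem))
    return min(dt, dt_max)


def advect(
    c: CellContour,
    velocities: np.ndarray,
    dt: float,
    max_retries: int = 5,
) -> tuple[CellContour, float]:
    """Forward-Euler advection of the free contour nodes.

    The apex stays on the axis and adherent nodes do not move.  A step that
    produces a self-intersecting contour is rejected and retried with the
    time step halved, up to ``max_retries`` times.  Returns the new contour
    and the time step actually taken.
    """
    velocities = np.asarray(velocities, float)
    if velocities.shape != (c.n_free, 2):
        raise InvalidArgumentError("need one velocity vector per free node")
    for attempt in range(max_retries + 1):
        r = c.r.copy()
        z = c.z.copy()
        nf = c.n_free
        r[: nf - 1] += velocities[:-1, 0] * dt
        z[: nf - 1] += velocities[:-1, 1] * dt
        r[0] = 0.0
        z[: nf - 1] = np.maximum(z[: nf - 1], geometry.Z_FLOOR_FREE)
        z[0] = max(z[0], geometry.Z_FLOOR_FREE)
        r[1: nf - 1] = np.maximum(r[1: nf - 1], 1e-9)
        try:
            out = CellContour(r, z, c.contact_index)
            out.validate(check_simple=True)
            return out, dt
        except GeometryError:
            dt *= 0.5
    raise GeometryError(f"advection kept self-intersecting after {max_retries} halvings")


def update_contact_continuum(c: CellContour, z_capture: float = 0.0,
                             v_z: np.ndarray | None = None) -> CellContour:
    """Add free nodes that reached the substrate to the adherent set.

    Nodes adjacent to the contact line with z ≤ ``z_capture`` are clamped to
    z = 0 and become adherent; the scan repeats so a chain of nodes can be
    captured in one call.  Irreversible: the adherent set never shrinks.
    When nodal vertical velocities are supplied, only nodes still moving
    toward the substrate are captured — otherwise remeshing jitter would
    ratchet the irreversible contact line past its equilibrium.
    """
    r = c.r.copy()
    z = c.z.copy()
    ci = c.contact_index
    rc = r[ci]
    captured = False

    def approaching(i):
        return v_z is None or i >= len(v_z) or v_z[i] <= 1e-12

    while ci > 1 and z[ci - 1] <= z_capture + 1e-15 and approaching(ci - 1):
        ci -= 1
        z[ci] = 0.0
        if r[ci] <= rc:
            r[ci] = rc * (1.0 + 1e-9) + 1e-12
        rc = r[ci]
        captured = True
    if not captured:
        return c
    # drop the old adherent tail ordering and rebuild it from the new line
    free_r = r[: ci + 1]
    free_z = z[: ci + 1]
    n_adh = c.n_nodes - c.contact_index
    return geometry._append_adherent(free_r, free_z, max(3, n_adh))


def update_contact_discrete(
    c: CellContour,
    sites: AdhesionSites,
    tau: float,
    A_cell: float,
    t: float,
    p: PhysicalParams,
    touch_band: float = 2e-3,
) -> tuple[CellContour, AdhesionSites, int]:
    """Bind free ligand rings within the fluctuation threshold and pin the
    membrane at the newly bound sites.

    The threshold distance comes from the membrane-fluctuation formula at
    the current tension and cell area.  Binding is irreversible; when the
    outermost bound ring advances, the membrane inward of it is placed into
    contact (free nodes lying within ``touch_band`` of the substrate are
    flattened onto it).
    """
    d_thresh = law.fluctuation_threshold(tau, A_cell, p) * 1e-3  # nm → μm
    rc = c.contact_radius
    pts = np.column_stack([c.free_r, c.free_z])
    n_new = 0
    order = np.argsort(sites.radii)
    for idx in order:
        if sites.bound[idx] or sites.radii[idx] <= rc:
            # rings inside the contact line are already overrun; bind them
            if not sites.bound[idx] and sites.radii[idx] <= rc:
                sites.bind(idx, t)
                n_new += 1
            continue
        d = _min_distance_to_polyline(pts, np.array([sites.radii[idx], 0.0]))
        if d <= d_thresh:
            sites.bind(idx, t)
            n_new += 1
        else:
            break  # rings bind in order from the contact line outward
    r_bound = sites.outermost_bound_radius()
    if r_bound <= rc + 1e-12:
        return _drop_overrun_nodes(c, touch_band), sites, n_new
    # pin the membrane at the outermost bound ring: nodes sliding on the
    # substrate beyond the old line become adherent out to the ring
    r = c.r.copy()
    z = c.z.copy()
    ci = c.contact_index
    while (ci > 1 and z[ci - 1] <= touch_band and r[ci - 1] > r[ci]
           and r[ci - 1] <= r_bound + 1e-12):
        ci -= 1
        z[ci] = 0.0
    r[ci] = max(r[ci], r_bound)
    z[ci] = 0.0
    free_r = r[: ci + 1]
    free_z = z[: ci + 1]
    n_adh = c.n_nodes - c.contact_index
    out = geometry._append_adherent(free_r, free_z, max(3, n_adh))
    return _drop_overrun_nodes(out, touch_band), sites, n_new


def _drop_overrun_nodes(c: CellContour, touch_band: float) -> CellContour:
    """Remove free nodes lying on the substrate inside the contact radius.

    Membrane folded back over the already-bound contact disc carries no
    physics (the substrate there is occupied) and tangles the contour."""
    nf = c.n_free
    rc = c.contact_radius
    band = max(touch_band, 0.05)  # μm; adhesion-range scale
    bad = (c.free_z <= band) & (c.free_r < rc - 1e-9)
    bad[0] = False
    bad[-1] = False
    if not np.any(bad):
        return c
    keep = np.concatenate([~bad, np.ones(c.n_nodes - nf, bool)])
    return CellContour(c.r[keep], c.z[keep], c.contact_index - int(np.sum(bad)))


def _min_distance_to_polyline(pts: np.ndarray, q: np.ndarray) -> float:
    a = pts[:-1]
    b = pts[1:]
    ab = b - a
    denom = np.sum(ab * ab, axis=1)
    tpar = np.clip(np.einsum("ij,ij->i", q - a, ab) / np.maximum(denom, 1e-30), 0.0, 1.0)
    proj = a + tpar[:, None] * ab
    d = np.hypot(*(q - proj).T)
    return float(np.min(d))


# ---------------------------------------------------------------------------
# full step
# ---------------------------------------------------------------------------

def boundary_stresses(state: SimulationState, cfg) -> BoundaryStressField:
    """Evaluate the per-free-node stress vectors for the active variant."""
    p = state.params
    c = state.contour
    normals = geometry.compute_normals(c)
    f = BoundaryStressField(normals=normals)
    f.sigma_cortex = law.cortical_stress(c, state.tau)
    if cfg.variant != "brownian":
        sigma = law.protrusion_magnitude(state.A_c, state.A_c_trans,
                                         state.A_cell / state.A_cell0, p)
        if cfg.variant == "protrusive_discrete":
            sigma = law.protrusion_decay(sigma, state.time, state.t_last_bind, p)
        state.sigma_prot = float(sigma)
        f.sigma_prot = law.protrusion_profile(c, state.sigma_prot, p)
    else:
        state.sigma_prot = 0.0
    if cfg.variant != "protrusive_discrete" and cfg.adhesion_scale > 0.0:
        f.sigma_adh = law.adhesion_stress(c, p, cfg.adhesion_scale)
    return f


def step(state: SimulationState, cfg) -> SimulationState:
    """Advance the simulation by one adaptive time step.

    Cycle: measure → tension → boundary stresses → mesh → Uzawa solve →
    Courant Δt → advect → contact update → smooth → resample →
    volume-correct → diagnostics.
    """
    p = state.params
    state.measure()
    state.tau = float(law.cortical_tension(state.A_cell, state.A_cell0, p))
    stresses = boundary_stresses(state, cfg)
    mesh = geometry.generate_mesh(state.contour)
    settings = stokes.SolverSettings(
        epsilon=cfg.epsilon, uzawa_tol=cfg.uzawa_tol,
        max_iterations=cfg.max_uzawa_iterations)
    ops = stokes.assemble_system(mesh, stresses, p.mu, settings, p_out=p.p_out)
    settings = stokes.SolverSettings(
        epsilon=ops.epsilon, uzawa_tol=cfg.uzawa_tol,
        max_iterations=cfg.max_uzawa_iterations)
    p_init = _warm_pressure(state, mesh)
    flow = stokes.uzawa_solve(ops, p_init=p_init, settings=settings, p_out=p.p_out)
    dt = compute_timestep(mesh, flow, cfg.courant_fraction, cfg.dt_max)

    v_free = flow.v[mesh.free_node_ids]
    contour, dt = advect(state.contour, v_free, dt)

    if cfg.variant == "protrusive_discrete":
        contour, state.sites, n_new = update_contact_discrete(
            contour, state.sites, state.tau, state.A_cell, state.time + dt, p)
        if n_new > 0:
            state.t_last_bind = state.time + dt
    else:
        contour = update_contact_continuum(contour, cfg.z_capture,
                                           v_z=v_free[:, 1])
        n_new = 0

    contour = geometry.smooth_contour(contour)
    contour = geometry.resample_contour(
        contour, n_free=cfg.n_free, grading=cfg.grading,
        ds_adherent=cfg.ds_adherent)
    contour = geometry.correct_volume(contour, state.v_target)

    state.contour = contour
    state.mesh = mesh
    state.flow = flow
    state.p_warm = flow.p
    state.warm_shape = mesh.shape
    state.time += dt
    state.measure()
    state.diagnostics = {
        "dt": dt,
        "uzawa_iterations": flow.iterations,
        "uzawa_residual": flow.residual,
        "epsilon": ops.epsilon,
        "max_speed": flow.max_speed,
        "n_new_bonds": n_new,
        "p_min": float(flow.p.min()),
        "p_max": float(flow.p.max()),
    }
    return state


def _warm_pressure(state: SimulationState, mesh: Mesh) -> np.ndarray | None:
    """Previous pressure interpolated onto the new structured grid."""
    if state.p_warm is None or state.warm_shape is None:
        return None
    n_u0, n_w0 = state.warm_shape
    n_u1, n_w1 = mesh.shape
    grid = np.empty((n_u0, n_w0))
    grid[0, :] = state.p_warm[0]
    grid[1:, :] = state.p_warm[1:].reshape(n_u0 - 1, n_w0)
    u0 = np.linspace(0, 1, n_u0)
    w0 = np.linspace(0, 1, n_w0)
    u1 = np.linspace(0, 1, n_u1)
    w1 = np.linspace(0, 1, n_w1)
    tmp = np.empty((n_u1, n_w0))
    for j in range(n_w0):
        tmp[:, j] = np.interp(u1, u0, grid[:, j])
    out = np.empty((n_u1, n_w1))
    for i in range(n_u1):
        out[i, :] = np.interp(w1, w0, tmp[i, :])
    p_new = np.empty(1 + (n_u1 - 1) * n_w1)
    p_new[0] = out[0, :].mean()
    p_new[1:] = out[1:, :].reshape(-1)
    return p_new
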