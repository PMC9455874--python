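"""Boundary-stress laws and analytic relations of the spreading model.

Covers the biphasic cortical-tension law, Laplace cortical stress, the
short-range adhesion stress integral, the contact-area-dependent protrusion
stress (spatial exponential profile and temporal decay), the membrane
fluctuation threshold, per-bond energetics and the Young–Dupré equilibrium
map between adhesion energy density and spherical-cap contact area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq

from . import geometry
from .exceptions import InvalidArgumentError
from .geometry import CellContour, solve_cap_height

__all__ = [
    "PhysicalParams",
    "BoundaryStressField",
    "cortical_tension",
    "cortical_stress",
    "adhesion_stress",
    "adhesion_scale_from_energy",
    "adhesion_well_energy",
    "bare_plane_adhesion_stress",
    "protrusion_magnitude",
    "protrusion_profile",
    "protrusion_decay",
    "fluctuation_threshold",
    "adhesion_energy_density",
    "young_dupre_equilibrium",
    "young_dupre_contact_area",
    "contact_area_at_transition",
]

K_BOLTZMANN = 1.380649e-23  # J/K

# unit conversions to the internal μm–s–Pa system
MN_PER_M_TO_PA_UM = 1000.0       # tension: 1 mN/m = 1000 Pa·μm
UJ_PER_M2_TO_PA_UM = 1.0         # energy density: 1 μJ/m² = 1 Pa·μm
J_TO_PA_UM3 = 1.0e18             # energy: 1 J = 1e18 Pa·μm³


@dataclass
class PhysicalParams:
    """Material constants and model coefficients.

    Defaults are the reference values of the active (protrusive) model; the
    passive variant uses ``mu = 200`` Pa·s.  Tension-law coefficients are in
    mN/m, stresses in Pa, lengths in μm, times in s.
    """

    mu: float = 1660.0               # cytoplasmic viscosity, Pa·s
    cell_diameter: float = 8.5       # μm
    p_out: float = 0.0               # external pressure, Pa

    # biphasic tension law (mN/m per unit area-ratio)
    tau_a: float = 0.01
    k1: float = 0.16
    tau_b: float = 0.0516
    k2: float = 0.545
    ratio_trans: float = 1.26
    smoothing_width: float = 0.02    # knee half-width in area-ratio units

    # protrusion law
    sigma_prot_max: float = 3500.0   # Pa
    prot_c0: float = 0.05
    prot_c1: float = 0.3
    prot_c2: float = 0.35
    prot_c3: float = 0.65
    delta_A_sat: float = 120.0       # μm²
    prot_exponent: float = 0.5
    prot_smoothing_area: float = 5.0  # μm² half-width at protrusion-law knees
    s0: float = 0.8                  # protrusion decay length, μm
    t0: float = 66.0                 # protrusion temporal decay constant, s

    # adhesion potential
    D0: float = 0.05                 # range of the adhesion potential, μm (50 nm)
    d_min: float = 1e-3              # singularity clamp, μm (1 nm)
    adhesion_energy_ref: float = 1500.0  # μJ/m² at 100% relative ligand density
    rho_l_rel: float = 1.0           # relative ligand density (continuum runs)
    rho_l: float = 1000.0            # absolute ligand density, μm⁻² (discrete runs)

    # thermal / membrane constants
    kB: float = K_BOLTZMANN          # J/K
    T: float = 310.0                 # K
    kappa_b: float = 2.0e-20         # membrane bending modulus, J
    K_d: float = 1e-6                # receptor-ligand equilibrium constant, M

    def __post_init__(self):
        for name in ("mu", "cell_diameter", "tau_a", "k1", "tau_b", "k2",
                     "sigma_prot_max", "s0", "t0", "D0", "T", "kappa_b", "K_d"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be strictly positive")
        if self.ratio_trans <= 1.0:
            raise InvalidArgumentError("ratio_trans must exceed 1")
        knee_gap = self.tau_a + self.k1 * (self.ratio_trans - 1.0) - self.tau_b
        if abs(knee_gap) > 1e-9:
            raise InvalidArgumentError(
                f"tension law discontinuous at the knee (gap {knee_gap:.3g} mN/m)")

    # -- derived quantities --------------------------------------------------

    @property
    def area0(self) -> float:
        """Resting cell surface area π d² (μm²)."""
        return np.pi * self.cell_diameter**2

    @property
    def volume0(self) -> float:
        """Cell volume π d³/6 (μm³)."""
        return np.pi * self.cell_diameter**3 / 6.0

    @property
    def kBT(self) -> float:
        """Thermal energy (J)."""
        return self.kB * self.T

    @property
    def E_bind(self) -> float:
        """Per-bond binding energy −ln(K_d) in kBT units."""
        return -np.log(self.K_d)


@dataclass
class BoundaryStressField:
    """Per-free-node boundary stress vectors (Pa) and the normals used."""

    normals: np.ndarray                      # (n_free, 2) outward unit normals
    sigma_adh: np.ndarray = None             # (n_free, 2)
    sigma_cortex: np.ndarray = None
    sigma_prot: np.ndarray = None

    def __post_init__(self):
        n = len(self.normals)
        for name in ("sigma_adh", "sigma_cortex", "sigma_prot"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros((n, 2)))

    def total(self) -> np.ndarray:
        t = self.sigma_adh + self.sigma_cortex + self.sigma_prot
        if not np.all(np.isfinite(t)):
            raise InvalidArgumentError("non-finite boundary stress")
        return t


# ---------------------------------------------------------------------------
# cortical tension and stress
# ---------------------------------------------------------------------------

def cortical_tension(A_cell, A_cell0, p: PhysicalParams, smoothed: bool = True):
    """Biphasic cortical tension τ(A_cell) in mN/m.

    Piecewise linear with a steeper branch beyond the transition area ratio;
    with ``smoothed`` the knee is blended C¹ over ``p.smoothing_width``.
    Area ratios below 1 clamp to the resting tension.
    """
    A_cell = np.asarray(A_cell, dtype=float)
    if np.any(A_cell <= 0) or A_cell0 <= 0:
        raise InvalidArgumentError("areas must be positive")
    x = np.maximum(A_cell / A_cell0, 1.0)
    x0 = p.ratio_trans
    t1 = p.tau_a + p.k1 * (x - 1.0)
    t2 = p.tau_b + p.k2 * (x - x0)
    if not smoothed:
        out = np.where(x <= x0, t1, t2)
    else:
        w = p.smoothing_width
        blend = t1 + (p.k2 - p.k1) * (x - (x0 - w)) ** 2 / (4.0 * w)
        out = np.where(x <= x0 - w, t1, np.where(x >= x0 + w, t2, blend))
    return out if out.ndim else float(out)


def cortical_stress(c: CellContour, tau: float) -> np.ndarray:
    """Cortical (Laplace) stress −τ·κ·n per free node, Pa; (n_free, 2)."""
    kappa = geometry.compute_curvature(c)
    normals = geometry.compute_normals(c)
    tau_int = tau * MN_PER_M_TO_PA_UM
    return -tau_int * kappa[:, None] * normals


# ---------------------------------------------------------------------------
# adhesion stress (continuum)
# ---------------------------------------------------------------------------

# kernel: k(D) = (D0/D)^7 − (D0/D)^4 along the unit vector from the substrate
# element to the surface point, so D < D0 repels and D > D0 attracts, with
# the potential minimum at D0.  Closed forms below follow by integrating the
# kernel over the full substrate plane.

# well depth of the integrated plane potential: work per unit area gained
# moving the surface from infinity to the zero-stress hover height
# z* = (1/2)^(1/3) D0, per unit scale·D0³
_WELL_COEFF = 0.5 * np.pi * 2.0 ** (1.0 / 3.0)


def _plane_stress_z(z, D0):
    """Net z-kernel integral over the full bare plane (per unit scale)."""
    return (np.pi / 3.0) * (D0**7 / z**5 - 2.0 * D0**4 / z**2)


def adhesion_well_energy(scale: float, D0: float) -> float:
    """Adhesion energy density γ (Pa·μm = μJ/m²) of the plane potential well."""
    return _WELL_COEFF * scale * D0**3


def adhesion_scale_from_energy(gamma: float, D0: float) -> float:
    """Interaction scale σ0·ρ_l (Pa/μm²) giving well depth ``gamma`` (μJ/m²)."""
    if gamma < 0:
        raise InvalidArgumentError("adhesion energy must be non-negative")
    return gamma * UJ_PER_M2_TO_PA_UM / (_WELL_COEFF * D0**3)


def bare_plane_adhesion_stress(height: float, scale: float, p: PhysicalParams) -> float:
    """z-stress (Pa) on a surface point at ``height`` above an uncontacted
    infinite plane (negative = attraction toward the substrate)."""
    z = max(height, p.d_min)
    return scale * _plane_stress_z(z, p.D0)


def _disc_integral(r_p, z_p, r_c, D0, n_rho=48, n_psi=32):
    """∬ over the contact disc of the kernel times the unit vector from the
    substrate element to the point (r_p, 0, z_p); returns (I_r, I_z)."""
    if r_c <= 0:
        return 0.0, 0.0
    g_rho, w_rho = leggauss(n_rho)
    g_psi, w_psi = leggauss(n_psi)
    # cluster radial points toward the disc edge, azimuthal toward ψ = 0
    x = 0.5 * (g_rho + 1.0)
    rho = r_c * (1.0 - (1.0 - x) ** 2)
    drho = r_c * 2.0 * (1.0 - x) * 0.5 * w_rho
    y = 0.5 * (g_psi + 1.0)
    psi = np.pi * y**2
    dpsi = np.pi * 2.0 * y * 0.5 * w_psi
    RHO, PSI = np.meshgrid(rho, psi, indexing="ij")
    W = np.outer(drho, dpsi) * RHO
    D2 = r_p**2 + RHO**2 - 2.0 * r_p * RHO * np.cos(PSI) + z_p**2
    D = np.sqrt(D2)
    k = (D0 / D) ** 7 - (D0 / D) ** 4
    fr = (r_p - RHO * np.cos(PSI)) / D
    fz = z_p / D
    I_r = 2.0 * float(np.sum(W * k * fr))
    I_z = 2.0 * float(np.sum(W * k * fz))
    return I_r, I_z


def adhesion_stress(
    c: CellContour,
    p: PhysicalParams,
    scale: float,
    cutoff_factor: float = 60.0,
) -> np.ndarray:
    """Continuum adhesion stress vectors at the free nodes, Pa; (n_free, 2).

    For each node the kernel is integrated over the substrate plane minus
    the contact disc: the full-plane part is closed-form and the disc part
    is removed by graded 2-D quadrature.  Nodes farther than
    ``cutoff_factor·D0`` from the uncontacted substrate are skipped; the
    attractive tail decays as distance⁻², so the default cutoff keeps the
    neglected stress below ~1% of the well-depth scale.
    """
    nf = c.n_free
    out = np.zeros((nf, 2))
    if scale == 0.0:
        return out
    D0 = p.D0
    r_c = c.contact_radius
    rf, zf = c.free_r, c.free_z
    # evaluation height floored at the potential-well minimum: membrane
    # below the well is treated as (about-to-be) bound rather than being
    # pushed through the unresolvable repulsive core
    z_floor = max(0.5 ** (1.0 / 3.0) * D0, p.d_min)

    def traction(r_p, z_p):
        z_p = max(z_p, z_floor)
        I_z_plane = _plane_stress_z(z_p, D0)
        I_r_disc, I_z_disc = _disc_integral(r_p, z_p, r_c, D0)
        return scale * (-I_r_disc), scale * (I_z_plane - I_z_disc)

    # distance to the nearest uncontacted substrate point
    lateral = np.maximum(r_c - rf, 0.0)
    dist = np.hypot(lateral, zf)
    cutoff = cutoff_factor * D0
    active = np.flatnonzero(dist < cutoff)
    fine = dist < 6.0 * D0  # kernel varies on the D0 scale here
    gx, gw = leggauss(4)
    for i in active:
        if i == nf - 1:
            continue  # contact node is Dirichlet; stress there is irrelevant
        if not fine[i]:
            out[i] = traction(rf[i], zf[i])
            continue
        # consistent lumping: hat-function-weighted average of the traction
        # over the node's support, sub-sampled so the near-line boundary
        # layer (width ~D0) is integrated rather than point-sampled
        acc = np.zeros(2)
        wsum = 0.0
        for j0, j1 in ((i - 1, i), (i, i + 1)):
            if j0 < 0 or j1 > nf - 1:
                continue
            for x, w in zip(gx, gw):
                t = 0.5 * (x + 1.0)
                lam = t if j1 == i else 1.0 - t  # hat value of node i
                r_q = rf[j0] + t * (rf[j1] - rf[j0])
                z_q = zf[j0] + t * (zf[j1] - zf[j0])
                seg = np.hypot(rf[j1] - rf[j0], zf[j1] - zf[j0])
                tr = traction(r_q, z_q)
                acc += w * lam * seg * np.array(tr)
                wsum += w * lam * seg
        if wsum > 0:
            out[i] = acc / wsum
    return out


# ---------------------------------------------------------------------------
# protrusion stress
# ---------------------------------------------------------------------------

def _hermite(u, u0, u1, f0, f1, df0, df1):
    """Cubic Hermite blend of values/slopes at u0, u1."""
    t = (u - u0) / (u1 - u0)
    h00 = 2 * t**3 - 3 * t**2 + 1
    h10 = t**3 - 2 * t**2 + t
    h01 = -2 * t**3 + 3 * t**2
    h11 = t**3 - t**2
    dx = u1 - u0
    return h00 * f0 + h10 * dx * df0 + h01 * f1 + h11 * dx * df1


def protrusion_magnitude(A_c, A_c_trans, area_ratio, p: PhysicalParams,
                         smoothed: bool = True):
    """Overall protrusion stress strength (Pa) as a function of contact area.

    Three branches: linear growth in the low-tension regime, square-root
    growth past the tension transition, and saturation at
    ``p.sigma_prot_max`` once the contact area exceeds the transition value
    by ``p.delta_A_sat``.  ``smoothed`` applies C¹ blends at both joins.
    """
    A_c = np.asarray(A_c, dtype=float)
    if np.any(A_c < 0):
        raise InvalidArgumentError("contact area must be non-negative")
    if A_c_trans <= 0:
        raise InvalidArgumentError("transition contact area must be positive")
    dA = p.delta_A_sat
    b1 = p.prot_c0 + p.prot_c1 * (A_c / A_c_trans)
    u = A_c - A_c_trans

    if not smoothed:
        with np.errstate(invalid="ignore"):
            b2 = p.prot_c2 + p.prot_c3 * np.power(np.maximum(u, 0.0) / dA,
                                                  p.prot_exponent)
        frac = np.where(area_ratio <= p.ratio_trans, b1,
                        np.where(u > dA, 1.0, b2))
        out = p.sigma_prot_max * frac
        return out if out.ndim else float(out)

    w = p.prot_smoothing_area
    # smooth sqrt branch: Hermite blend over |u| < w, then saturation blend
    uu = np.asarray(u, dtype=float)
    sqrt_part = np.sqrt(np.maximum(uu, w) / dA)
    dsqrt = 0.5 / np.sqrt(np.maximum(uu, w) * dA)
    lower = _hermite(np.clip(uu, -w, w), -w, w,
                     0.0, np.sqrt(w / dA), 0.0, 0.5 / np.sqrt(w * dA))
    g = np.where(uu >= w, sqrt_part, lower)
    b2 = p.prot_c2 + p.prot_c3 * g
    # saturation knee at u = dA
    sat = _hermite(np.clip(uu, dA - w, dA + w), dA - w, dA + w,
                   p.prot_c2 + p.prot_c3 * np.sqrt((dA - w) / dA), 1.0,
                   p.prot_c3 * 0.5 / np.sqrt((dA - w) * dA), 0.0)
    b2 = np.where(uu >= dA + w, 1.0, np.where(uu > dA - w, sat, b2))
    # blend branch 1 → branch 2 across the tension knee in area ratio
    rw = p.smoothing_width
    lam = np.clip((area_ratio - (p.ratio_trans - rw)) / (2.0 * rw), 0.0, 1.0)
    lam = lam * lam * (3.0 - 2.0 * lam)
    frac = (1.0 - lam) * b1 + lam * b2
    out = p.sigma_prot_max * np.minimum(frac, 1.0)
    return out if out.ndim else float(out)


def protrusion_profile(c: CellContour, sigma_prot: float, p: PhysicalParams) -> np.ndarray:
    """Outward normal protrusion stress per free node, Pa; (n_free, 2).

    Exponential decay with arc-length distance from the contact line:
    σ_prot · exp(−(s_contact − s)/s0) · n.
    """
    s = c.s[: c.n_free]
    mag = sigma_prot * np.exp(-(c.s_contact - s) / p.s0)
    normals = geometry.compute_normals(c)
    return mag[:, None] * normals


def protrusion_decay(sigma_prot: float, t: float, t_bind: float, p: PhysicalParams) -> float:
    """Transient protrusion strength σ_prot·exp(−(t − t_bind)/t0)."""
    if t < t_bind:
        raise InvalidArgumentError("t must not precede the binding time")
    return sigma_prot * np.exp(-(t - t_bind) / p.t0)


# ---------------------------------------------------------------------------
# thermodynamic relations
# ---------------------------------------------------------------------------

def fluctuation_threshold(tau: float, A_cell: float, p: PhysicalParams) -> float:
    """RMS membrane fluctuation height (nm) at tension ``tau`` (mN/m).

    sqrt( kBT/(4πτ) · ln(1 + τ·A_cell/(π²·κ_b)) ), with A_cell in μm².
    """
    if tau <= 0:
        raise InvalidArgumentError("tension must be positive")
    tau_si = tau * 1e-3                      # N/m
    A_si = A_cell * 1e-12                    # m²
    arg = 1.0 + tau_si * A_si / (np.pi**2 * p.kappa_b)
    h2 = p.kBT / (4.0 * np.pi * tau_si) * np.log(arg)
    return float(np.sqrt(h2) * 1e9)


def adhesion_energy_density(rho_ligand: float, p: PhysicalParams) -> float:
    """Upper-limit adhesion energy density γ = ρ·E_bind·kBT in μJ/m².

    ``rho_ligand`` is the ligand surface density in μm⁻².
    """
    if rho_ligand < 0:
        raise InvalidArgumentError("ligand density must be non-negative")
    gamma_J_per_um2 = rho_ligand * p.E_bind * p.kBT      # J/μm²
    return gamma_J_per_um2 * 1e6 * 1e12                  # → μJ/m²


# ---------------------------------------------------------------------------
# Young–Dupré equilibrium
# ---------------------------------------------------------------------------

def _cap_from_contact_area(A_c: float, V: float):
    h, R = solve_cap_height(A_c, V)
    a = np.sqrt(A_c / np.pi)
    cos_theta = h / R - 1.0
    theta_c = float(np.arccos(np.clip(cos_theta, -1.0, 1.0)))
    A_cell = 2.0 * np.pi * R * h + A_c  # curved cap + flat base
    return theta_c, A_cell, R, h, a


def young_dupre_equilibrium(A_c: float, V: float, p: PhysicalParams):
    """Equilibrium (θ_c, A_cell, τ, γ) of the spherical cap with contact
    area ``A_c`` and volume ``V``.

    θ_c is the spreading contact angle (0 at tangent contact, π for a flat
    pancake); γ = τ(1 − cos θ_c) is returned in μJ/m², τ in mN/m.
    """
    if A_c <= 0 or A_c != A_c:
        raise InvalidArgumentError("contact area must be positive")
    theta_c, A_cell, R, h, a = _cap_from_contact_area(A_c, V)
    if h < 1e-6 * a:
        raise InvalidArgumentError("contact area too large for a resolvable cap")
    tau = float(cortical_tension(A_cell, p.area0, p, smoothed=False))
    gamma = tau * (1.0 - np.cos(theta_c)) * 1000.0  # mN/m → μJ/m²
    return theta_c, float(A_cell), tau, float(gamma)


def young_dupre_contact_area(gamma: float, V: float, p: PhysicalParams) -> float:
    """Inverse Young–Dupré map: contact area whose cap equilibrium has
    adhesion energy density ``gamma`` (μJ/m²)."""
    if gamma <= 0:
        raise InvalidArgumentError("adhesion energy must be positive")

    def f(A_c):
        return young_dupre_equilibrium(A_c, V, p)[3] - gamma

    lo, hi = 1e-4, 10.0
    while f(hi) < 0 and hi < 1e5:
        hi *= 2.0
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


def contact_area_at_transition(p: PhysicalParams) -> float:
    """Contact area of the spherical cap whose total surface area equals
    ``ratio_trans`` times the resting area, at the cell volume.

    Used as the reference transition contact area of the protrusion law.
    """
    target = p.ratio_trans * p.area0

    def f(A_c):
        return _cap_from_contact_area(A_c, p.volume0)[1] - target

    return float(brentq(f, 1e-3, p.area0 * 3.0, xtol=1e-10))
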