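"""Run configuration, the simulation loop, ligand-density sweeps and
discrete-site ensemble averaging."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constitutive as law
from . import evolution, geometry
from .constitutive import PhysicalParams
from .exceptions import InvalidArgumentError, PhagospreadError
from .geometry import init_spherical_cap, measure_contour

__all__ = [
    "RunConfig",
    "SpreadingTimeSeries",
    "run_simulation",
    "run_density_sweep",
    "run_discrete_ensemble",
    "equilibrium_check_brownian",
]

VARIANTS = ("brownian", "protrusive_continuum", "protrusive_discrete")


@dataclass
class RunConfig:
    """Complete specification of one simulation run."""

    variant: str = "protrusive_continuum"
    params: PhysicalParams = field(default_factory=PhysicalParams)

    # discretization
    n_free: int = 120                 # free-surface contour nodes
    grading: float = 5.0              # apex/contact spacing ratio
    ds_adherent: float = 0.35         # target substrate node spacing, μm
    n_adherent_init: int = 8
    footprint_area: float = 0.05      # initial contact footprint, μm²

    # time stepping / termination
    t_end: float = 200.0
    courant_fraction: float = 0.1
    dt_max: float = 0.5
    max_steps: int = 200_000
    plateau_rate: float = 0.01        # μm²/s — dA_c/dt below this ...
    plateau_window: float = 20.0      # ... for this long ⇒ stop
    output_every: float = 1.0         # record cadence, s (0 = every step)

    # solver
    epsilon: float | None = None      # None → h²/(2μ) each step
    uzawa_tol: float = 1e-6
    max_uzawa_iterations: int = 500

    contour_every: float | None = None  # contour snapshot cadence, s (None = final only)

    # adhesion
    rho_rel: float = 1.0              # relative ligand density (continuum), 1 = 100%
    rho_l: float = 1000.0             # absolute ligand density, μm⁻² (discrete)
    z_capture: float | None = None    # None → potential-well minimum height
    ensemble_shifts: int = 5

    out_dir: str | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise InvalidArgumentError(f"unknown variant {self.variant!r}")
        if self.variant == "protrusive_discrete" and self.rho_l <= 0:
            raise InvalidArgumentError("discrete runs need rho_l > 0 (μm⁻²)")
        if self.rho_rel < 0 or self.t_end <= 0:
            raise InvalidArgumentError("invalid sweep/termination settings")

    # -- derived -------------------------------------------------------------

    @property
    def adhesion_scale(self) -> float:
        """Interaction scale σ0·ρ_l (Pa/μm²) of the continuum potential."""
        if self.variant == "protrusive_discrete":
            return 0.0
        gamma = self.params.adhesion_energy_ref * self.rho_rel
        if gamma == 0.0:
            return 0.0
        return law.adhesion_scale_from_energy(gamma, self.params.D0)

    @property
    def adhesion_energy(self) -> float:
        """Effective adhesion energy density γ (μJ/m²) of this run."""
        return self.params.adhesion_energy_ref * self.rho_rel

    @property
    def effective_z_capture(self) -> float:
        if self.z_capture is not None:
            return self.z_capture
        if self.variant != "protrusive_discrete" and self.adhesion_scale > 0:
            # fraction of the potential-well hover height z* = (1/2)^(1/3) D0:
            # capture requires descending into the neutral zone below the
            # minimum, so the zipper stalls at force balance instead of
            # creeping while the foot hovers at z*
            return 0.8 * 0.5 ** (1.0 / 3.0) * self.params.D0
        return 0.01  # μm; bare mechanical touch-down tolerance

    # -- (de)serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "params" in d and isinstance(d["params"], dict):
            d["params"] = PhysicalParams(**d["params"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


_COLUMNS = ["t", "dt", "A_c", "A_cell", "V", "tau", "sigma_prot", "n_bonds",
            "uzawa_iterations", "max_speed", "epsilon"]


@dataclass
class SpreadingTimeSeries:
    """Per-step record of the spreading observables."""

    data: pd.DataFrame
    config: dict | None = None
    final_contour: geometry.CellContour | None = None

    def __post_init__(self):
        missing = [c for c in ("t", "A_c") if c not in self.data.columns]
        if missing:
            raise InvalidArgumentError(f"time series missing columns {missing}")
        t = self.data["t"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("time must be strictly increasing")

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy()

    @property
    def A_c(self) -> np.ndarray:
        return self.data["A_c"].to_numpy()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpreadingTimeSeries":
        return cls(pd.read_csv(path))


def _make_state(cfg: RunConfig, lattice_shift: float = 0.0) -> evolution.SimulationState:
    p = cfg.params
    contour = init_spherical_cap(p.cell_diameter, cfg.footprint_area,
                                 n_free=cfg.n_free, n_adherent=cfg.n_adherent_init,
                                 grading=cfg.grading)
    _, v0 = measure_contour(contour)
    state = evolution.SimulationState(
        time=0.0, contour=contour, params=p, v_target=v0,
        A_cell0=p.area0, A_c_trans=law.contact_area_at_transition(p))
    if cfg.variant == "protrusive_discrete":
        state.sites = evolution.AdhesionSites.create(
            cfg.rho_l, r_max=4.0 * p.cell_diameter, shift=lattice_shift)
    state.measure()
    return state


def run_simulation(
    cfg: RunConfig,
    lattice_shift: float = 0.0,
    progress: bool = False,
) -> SpreadingTimeSeries:
    """Run one simulation to ``t_end`` or to the contact-area plateau.

    Deterministic: identical configurations produce identical output.
    """
    state = _make_state(cfg, lattice_shift)
    rows = []
    next_record = 0.0
    next_contour = cfg.contour_every if (cfg.out_dir and cfg.contour_every) else None
    plateau_since = None
    last_Ac, last_t = state.A_c, 0.0
    aborted = None
    variant_cfg = _StepConfig(cfg)
    n = 0
    try:
        while state.time < cfg.t_end and n < cfg.max_steps:
            state = evolution.step(state, variant_cfg)
            n += 1
            d = state.diagnostics
            if state.time >= next_record or state.time >= cfg.t_end:
                rows.append([state.time, d["dt"], state.A_c, state.A_cell,
                             state.volume, state.tau, state.sigma_prot,
                             state.sites.n_bound if state.sites else 0,
                             d["uzawa_iterations"], d["max_speed"], d["epsilon"]])
                next_record = state.time + cfg.output_every
            if next_contour is not None and state.time >= next_contour:
                _dump_contour(state, Path(cfg.out_dir))
                next_contour = state.time + cfg.contour_every
            if progress and n % 200 == 0:
                print(f"  t={state.time:8.2f}s  A_c={state.A_c:7.2f}  "
                      f"dt={d['dt']:.3g}  its={d['uzawa_iterations']}")
            # plateau detection
            rate = (state.A_c - last_Ac) / max(state.time - last_t, 1e-12)
            if state.time - last_t > 1.0:
                if rate < cfg.plateau_rate:
                    if plateau_since is None:
                        plateau_since = state.time
                    elif state.time - plateau_since > cfg.plateau_window:
                        break
                else:
                    plateau_since = None
                last_Ac, last_t = state.A_c, state.time
    except PhagospreadError as exc:  # partial-output marker
        aborted = f"{type(exc).__name__}: {exc}"
        warnings.warn(f"run aborted at t={state.time:.2f}s: {aborted}")
    df = pd.DataFrame(rows, columns=_COLUMNS)
    meta = cfg.to_dict()
    meta["aborted"] = aborted
    meta["config_digest"] = cfg.digest()
    series = SpreadingTimeSeries(df, config=meta, final_contour=state.contour)
    if cfg.out_dir:
        _write_outputs(series, state, cfg)
    return series


class _StepConfig:
    """Flattened per-step options handed to evolution.step."""

    def __init__(self, cfg: RunConfig):
        self.variant = cfg.variant
        self.adhesion_scale = cfg.adhesion_scale
        self.z_capture = cfg.effective_z_capture
        self.n_free = cfg.n_free
        self.grading = cfg.grading
        self.ds_adherent = cfg.ds_adherent
        self.courant_fraction = cfg.courant_fraction
        self.dt_max = cfg.dt_max
        self.epsilon = cfg.epsilon
        self.uzawa_tol = cfg.uzawa_tol
        self.max_uzawa_iterations = cfg.max_uzawa_iterations


def _contour_table(state) -> pd.DataFrame:
    c = state.contour
    tag = np.where(np.arange(c.n_nodes) < c.contact_index, "free", "adherent")
    return pd.DataFrame({"t": state.time, "node": np.arange(c.n_nodes),
                         "r": c.r, "z": c.z, "tag": tag})


def _dump_contour(state, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    _contour_table(state).to_csv(out / f"contour_t{state.time:08.2f}.csv",
                                 index=False)


def _write_outputs(series, state, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series.to_csv(out / "timeseries.csv")
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(series.config, fh, indent=2, default=str)
    _contour_table(state).to_csv(out / "contour_final.csv", index=False)


def run_density_sweep(cfg: RunConfig, densities) -> dict:
    """Run the configured variant at several ligand densities.

    For continuum variants ``densities`` are relative fractions (1 = 100%);
    for the discrete variant they are absolute densities in μm⁻².
    """
    results = {}
    for rho in densities:
        c = dataclasses.replace(cfg)
        if cfg.variant == "protrusive_discrete":
            c.rho_l = float(rho)
        else:
            c.rho_rel = float(rho)
        c.out_dir = None
        results[float(rho)] = run_simulation(c)
    return results


def run_discrete_ensemble(cfg: RunConfig, n_shifts: int | None = None):
    """Average the discrete variant over lateral lattice shifts.

    Member offsets span one site spacing evenly; members are averaged on a
    common time grid by linear interpolation of A_c(t).  Returns
    ``(mean_series, member_series_list)``.
    """
    if cfg.variant != "protrusive_discrete":
        raise InvalidArgumentError("ensembles only apply to the discrete variant")
    n_shifts = cfg.ensemble_shifts if n_shifts is None else n_shifts
    if n_shifts < 2:
        raise InvalidArgumentError("need at least 2 lattice shifts")
    spacing = cfg.rho_l ** -0.5
    offsets = spacing * np.arange(n_shifts) / n_shifts
    members = []
    for off in offsets:
        try:
            members.append(run_simulation(cfg, lattice_shift=float(off)))
        except PhagospreadError as exc:
            warnings.warn(f"ensemble member at shift {off:.4g} failed: {exc}")
    if len(members) < 2:
        raise PhagospreadError("fewer than 2 ensemble members survived")
    t_max = min(m.t[-1] for m in members)
    t_grid = np.linspace(0.0, t_max, 400)
    curves = np.stack([np.interp(t_grid, m.t, m.A_c) for m in members])
    mean_df = pd.DataFrame({"t": t_grid[1:], "A_c": curves.mean(axis=0)[1:]})
    mean_series = SpreadingTimeSeries(mean_df, config={"ensemble_offsets": offsets.tolist(),
                                                       **(cfg.to_dict())})
    return mean_series, members


def equilibrium_check_brownian(series: SpreadingTimeSeries, cfg: RunConfig) -> dict:
    """Compare a plateaued Brownian run against the Young–Dupré prediction.

    Reports the relative deviation of the final contact area from the
    equilibrium map at the run's effective adhesion energy density, and the
    RMS deviation of the final free contour from its best-fit spherical cap.
    """
    if cfg.variant != "brownian":
        return {"status": "inconclusive", "reason": "not a Brownian run"}
    t, A = series.t, series.A_c
    if len(t) < 5:
        return {"status": "inconclusive", "reason": "too few samples"}
    # plateau test: late-phase growth rate
    tail = t > t[-1] - min(20.0, 0.25 * t[-1])
    rate = np.polyfit(t[tail], A[tail], 1)[0] if np.sum(tail) > 2 else np.inf
    if rate > 5.0 * cfg.plateau_rate:
        return {"status": "inconclusive",
                "reason": f"no plateau (late dA_c/dt = {rate:.3g} μm²/s)"}
    p = cfg.params
    A_pred = law.young_dupre_contact_area(cfg.adhesion_energy, p.volume0, p)
    A_sim = float(A[-1])
    report = {
        "status": "ok",
        "A_c_sim": A_sim,
        "A_c_young_dupre": A_pred,
        "relative_deviation": abs(A_sim - A_pred) / A_pred,
        "late_rate": float(rate),
    }
    if series.final_contour is not None:
        report["cap_rms_over_radius"] = _cap_fit_rms(series.final_contour)
    return report


def _cap_fit_rms(c: geometry.CellContour) -> float:
    """RMS deviation of the free contour from the best-fit sphere, relative
    to the fitted radius (algebraic circle fit in the (r, z) plane)."""
    x = c.free_r
    y = c.free_z
    # fit circle centred on the axis offset (0, z0): r² + (z − z0)² = R²
    A = np.column_stack([-2.0 * y, np.ones_like(y)])
    b = -(x**2 + y**2)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    z0 = sol[0]
    R2 = z0**2 - sol[1]
    R = np.sqrt(max(R2, 1e-30))
    d = np.abs(np.hypot(x, y - z0) - R)
    return float(np.sqrt(np.mean(d**2)) / R)
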