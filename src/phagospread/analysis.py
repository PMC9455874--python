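"""Post-processing of contact-area-versus-time curves.

Observables follow the conventions of the spreading measurements: the
spreading speed is the maximum slope of a sigmoidal fit, the maximum
contact area is the average over the plateau, and the early-phase growth
exponent is the slope of the log–log contact-area curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .exceptions import FitQualityError, InvalidArgumentError

__all__ = [
    "SpreadingSummary",
    "sigmoid_fit",
    "loglog_slope",
    "compare_to_benchmarks",
]

REFERENCE_SPREADING_SPEED = 3.0  # μm²/s, experimental anchor


@dataclass
class SpreadingSummary:
    """Summary observables of one spreading curve."""

    spreading_speed: float            # μm²/s: max slope of the sigmoid fit
    max_contact_area: float           # μm²: plateau average
    powerlaw_exponent: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.spreading_speed < 0:
            raise InvalidArgumentError("spreading speed must be non-negative")


def _logistic(t, A0, A_max, k, t_mid):
    return A0 + (A_max - A0) / (1.0 + np.exp(-k * (t - t_mid)))


def sigmoid_fit(t, A_c, plateau_band: float = 0.02) -> SpreadingSummary:
    """Fit a 4-parameter logistic to A_c(t) and extract speed and plateau.

    Speed is the slope at the inflection point, k(A_max − A0)/4; the
    maximum contact area is the mean of the data points within
    ``plateau_band`` of the fitted plateau.  Non-sigmoidal input (no
    resolved plateau or inflection) raises :class:`FitQualityError`.
    """
    t = np.asarray(t, float)
    A = np.asarray(A_c, float)
    if len(t) < 20:
        raise InvalidArgumentError("need at least 20 samples spanning rise and plateau")
    if np.any(np.diff(t) <= 0):
        raise InvalidArgumentError("time must be strictly increasing")
    span = A.max() - A.min()
    if span <= 0:
        raise FitQualityError("flat curve", {"span": 0.0})
    # initial guesses from the data
    t_mid0 = float(np.interp(A.min() + 0.5 * span, A, t))
    dA = np.gradient(A, t)
    k0 = max(4.0 * dA.max() / span, 1e-3)
    p0 = [A.min(), A.max(), k0, t_mid0]
    try:
        popt, _ = curve_fit(
            _logistic, t, A, p0=p0, maxfev=20000,
            bounds=([-np.inf, 0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf, np.inf]))
    except RuntimeError as exc:
        raise FitQualityError(f"sigmoid fit failed: {exc}") from exc
    A0, A_max, k, t_mid = popt
    resid = A - _logistic(t, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((A - A.mean())**2))
    r2 = 1.0 - ss_res / max(ss_tot, 1e-300)
    diagnostics = {"A0": A0, "A_max": A_max, "k": k, "t_mid": t_mid,
                   "r_squared": r2, "rms_residual": float(np.sqrt(ss_res / len(t)))}
    if t_mid <= t[0] or t_mid >= t[-1]:
        raise FitQualityError(
            "no interior inflection point — curve is not sigmoidal", diagnostics)
    # reference the smaller of fitted plateau and observed maximum: curves
    # that saturate abruptly sit a few percent below the logistic asymptote
    plateau_ref = min(A_max, float(A.max()))
    plateau_pts = A[np.abs(A - plateau_ref) <= plateau_band * plateau_ref]
    late = t >= t[-1] - 0.1 * (t[-1] - t[0])
    late_mean = float(np.mean(A[late]))
    if len(plateau_pts) < 3 or late_mean < 0.85 * A_max:
        raise FitQualityError("curve does not reach a plateau", diagnostics)
    if r2 < 0.95:
        raise FitQualityError(f"poor sigmoid fit (R² = {r2:.3f})", diagnostics)
    speed = k * (A_max - A0) / 4.0
    diagnostics["n_plateau_points"] = int(len(plateau_pts))
    return SpreadingSummary(
        spreading_speed=float(speed),
        max_contact_area=float(np.mean(plateau_pts)),
        diagnostics=diagnostics,
    )


def loglog_slope(t, A_c, window: tuple[float, float] | None = None,
                 r2_min: float = 0.98):
    """Least-squares slope of log A_c vs log t over a time window.

    Defaults to the early spreading phase: from the first point with
    A_c ≥ 1 μm² until A_c reaches 50% of its final value.  Returns
    ``(exponent, r_squared)``; the exponent is reported as None when the
    log–log fit has R² below ``r2_min``.
    """
    t = np.asarray(t, float)
    A = np.asarray(A_c, float)
    if window is None:
        mask = (A >= 1.0) & (A <= 0.5 * A[-1])
        if np.sum(mask) < 3:
            mask = A >= 0.05 * A[-1]
    else:
        lo, hi = window
        mask = (t >= lo) & (t <= hi)
    mask &= (t > 0) & (A > 0)
    if np.sum(mask) < 3:
        raise InvalidArgumentError("window contains fewer than 3 usable points")
    if window is not None and np.any(A[mask] > 0.9 * A[-1]):
        import warnings
        warnings.warn("log-log window reaches into the plateau; R² flagged")
    res = linregress(np.log(t[mask]), np.log(A[mask]))
    r2 = float(res.rvalue**2)
    exponent = float(res.slope) if r2 >= r2_min else None
    return exponent, r2


def compare_to_benchmarks(summary: SpreadingSummary | None,
                          density_summaries: dict | None = None) -> dict:
    """Tabulate simulated observables against the printed experimental
    anchors (spreading speed ≈ 3 μm²/s; maximum contact area increasing
    with ligand density).  Purely reporting — no pass/fail."""
    report: dict = {}
    if summary is not None:
        report["spreading_speed"] = summary.spreading_speed
        report["speed_ratio_to_reference"] = (
            summary.spreading_speed / REFERENCE_SPREADING_SPEED)
        report["max_contact_area"] = summary.max_contact_area
    if density_summaries:
        dens = sorted(density_summaries)
        speeds = np.array([density_summaries[d].spreading_speed for d in dens])
        areas = np.array([density_summaries[d].max_contact_area for d in dens])
        report["densities"] = list(map(float, dens))
        report["speeds"] = speeds.tolist()
        report["max_areas"] = areas.tolist()
        report["speed_spread_rel_mean"] = float(
            (speeds.max() - speeds.min()) / max(speeds.mean(), 1e-300))
        report["max_area_monotone_increasing"] = bool(np.all(np.diff(areas) > 0))
    return report
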