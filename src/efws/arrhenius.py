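"""Arrhenius analysis of (temperature, relaxation-time) points.

For a thermally activated process tau(T) = tau0 * exp(dU / (R T)), ln tau is
linear in 1/T, so ordinary least squares on (1/T, ln tau) yields the
activation energy dU = slope * R and the attempt time tau0 = exp(intercept).

The resolution-window analysis rests on the identification tau(T_on) = dt:
when an apparent onset is purely resolution-limited, the onset temperature
at instrument window dt marks where the relaxation time crosses dt.  That
identification is an *assumption* — the detected deviation onset
systematically precedes the crossing — so fits built from onsets carry an
explicit assumption flag, and both detected onsets and model crossings are
reported side by side downstream.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .core import (
    R_GAS,
    ArrheniusFit,
    DomainError,
    EfwsError,
    NoCrossingError,
    OnsetResult,
)

__all__ = ["fit_arrhenius", "crossing_temperature", "onsets_to_arrhenius"]


def fit_arrhenius(points: Sequence[tuple[float, float]]) -> ArrheniusFit:
    """Ordinary least squares of ln tau on 1/T.

    Parameters
    ----------
    points : sequence of (T, tau)
        Temperatures in K (> 0, at least two distinct) and relaxation times
        in ps (> 0).

    Returns
    -------
    ArrheniusFit
        With ``slope`` = dU/R in K, ``delta_u`` in kJ/mol, ``tau0`` in ps.
        Exact for two points.
    """
    pts = [(float(t), float(tau)) for t, tau in points]
    if len(pts) < 2:
        raise EfwsError("need at least 2 (T, tau) points")
    T = np.array([p[0] for p in pts])
    tau = np.array([p[1] for p in pts])
    if np.any(T <= 0):
        raise DomainError("temperatures must be > 0 K")
    if np.any(tau <= 0):
        raise DomainError("relaxation times must be > 0")
    if np.unique(T).size < 2:
        raise EfwsError("singular fit: all temperatures identical")
    x = 1.0 / T
    y = np.log(tau)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return ArrheniusFit(
        delta_u=float(slope * R_GAS / 1e3),
        tau0=float(np.exp(intercept)),
        slope=float(slope),
        points=tuple(pts),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def crossing_temperature(fit: ArrheniusFit, resolution_time: float) -> float:
    """Temperature where tau(T) equals the instrument resolution time.

    Inverts the Arrhenius law: T = (dU/R) / ln(dt / tau0).  Strictly
    decreasing in dt — a longer instrument window catches slower motions,
    so the crossing moves to lower temperature.
    """
    if resolution_time <= fit.tau0:
        raise NoCrossingError(
            f"resolution time {resolution_time} ps <= tau0 {fit.tau0} ps: "
            "tau(T) never decays to the window"
        )
    if fit.slope <= 0:
        raise NoCrossingError("non-positive activation energy: no crossing")
    return float(fit.slope / np.log(resolution_time / fit.tau0))


def onsets_to_arrhenius(
    onsets: Iterable[OnsetResult], spread_tol: float = 3.0
) -> ArrheniusFit:
    """Build an Arrhenius fit from onsets via the tau(T_on) = dt identification.

    Each onset must carry its ``resolution_time``; the pair (T_on, dt)
    becomes one (T, tau) point.  The fit's notes record the identification
    as an assumption and a diagnostic of whether the onsets look
    resolution-limited at all: onsets whose temperature spread across
    resolutions stays within ``spread_tol`` K (the behaviour of an intrinsic
    transition) are flagged ``resolution_limited = False`` and, when the
    temperatures are too degenerate to fit, returned with NaN parameters.

    The diagnostic slope d(1/T)/d(ln tau) equals R/dU for a genuinely
    activated process and collapses toward zero for a resolution-independent
    onset.
    """
    onsets = list(onsets)
    if len(onsets) < 2:
        raise EfwsError("need onsets at >= 2 distinct resolutions")
    for o in onsets:
        if o.resolution_time is None:
            raise EfwsError("every onset must carry its resolution_time")
    pts = [(o.t_on, float(o.resolution_time)) for o in onsets]
    T = np.array([p[0] for p in pts])
    tau = np.array([p[1] for p in pts])
    if np.unique(tau).size < 2:
        raise EfwsError("need onsets at >= 2 distinct resolutions")
    spread = float(T.max() - T.min())
    # inverse regression: 1/T on ln tau; ~R/dU if activated, ~0 if intrinsic
    inv_slope = float(np.polyfit(np.log(tau), 1.0 / T, 1)[0])
    resolution_limited = spread > spread_tol and inv_slope > 0
    notes = {
        "assumption": "tau(T_on) = resolution_time",
        "resolution_limited": resolution_limited,
        "onset_spread_K": spread,
        "inv_slope_per_lntau": inv_slope,
    }
    if np.unique(T).size < 2:
        # degenerate: identical onsets at every resolution (intrinsic case)
        return ArrheniusFit(
            delta_u=float("nan"),
            tau0=float("nan"),
            slope=float("nan"),
            points=tuple(pts),
            residual_rms=float("nan"),
            notes=notes,
        )
    fit = fit_arrhenius(pts)
    fit.notes.update(notes)
    return fit
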