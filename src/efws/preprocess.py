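"""Normalization, q-summation and Gaussian-approximation MSD extraction."""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np

from .core import DomainError, EfwsError, ElasticScan, MSDSeries, SummedSeries

__all__ = ["normalize_to_base", "sum_over_q", "gaussian_msd"]

#: q band used for the summed intensity curves, 1/Angstrom.
DEFAULT_SUM_Q_RANGE = (0.45, 1.75)
#: Narrower q band where the Gaussian approximation holds for the MSD fit.
DEFAULT_MSD_Q_RANGE = (0.45, 0.9)


def normalize_to_base(
    scan: ElasticScan, base_window: tuple[float, float] = (0.0, 20.0)
) -> ElasticScan:
    """Normalize each q column to its mean over the low-temperature base window.

    At ~10 K all relaxations are frozen, so the base value is the full elastic
    intensity; dividing by it removes detector efficiency and sample-mass
    scale factors column by column.  Intensity errors are scaled identically.
    """
    lo, hi = base_window
    mask = (scan.temperatures >= lo) & (scan.temperatures <= hi)
    if not mask.any():
        raise EfwsError(
            f"no temperatures inside base window [{lo}, {hi}] K"
        )
    base = scan.intensities[mask].mean(axis=0)
    if np.any(base <= 0):
        raise DomainError("zero or negative base-window mean; cannot normalize")
    errors = None
    if scan.intensity_errors is not None:
        errors = scan.intensity_errors / base
    out = replace(
        scan,
        intensities=scan.intensities / base,
        intensity_errors=errors,
        normalized=True,
    )
    out.meta = dict(scan.meta, base_window=tuple(base_window))
    return out


def sum_over_q(
    scan: ElasticScan, q_range: tuple[float, float] = DEFAULT_SUM_Q_RANGE
) -> SummedSeries:
    """Average the (normalized) intensity over a closed q band, per temperature.

    The conventional "sum over q" and this mean differ by the constant number
    of q points, which base-temperature normalization removes; the mean keeps
    the series <= 1 and comparable across instruments with different q grids.
    """
    mask = scan.q_mask(q_range)
    if mask.sum() < 2:
        raise EfwsError(
            f"need >= 2 q points inside {q_range}; found {int(mask.sum())}"
        )
    values = scan.intensities[:, mask].mean(axis=1)
    return SummedSeries(
        temperatures=scan.temperatures.copy(),
        values=values,
        q_range=(float(q_range[0]), float(q_range[1])),
        provenance={
            "scan_key": scan.key,
            "component": scan.component,
            "state": scan.state,
            "normalized": scan.normalized,
        },
    )


def gaussian_msd(
    scan: ElasticScan, q_range: tuple[float, float] = DEFAULT_MSD_Q_RANGE
) -> MSDSeries:
    """Extract the mean-squared displacement via the Gaussian approximation.

    In the Gaussian approximation S(q, dt) = exp(-q^2 <x^2(dt)> / 6), so at
    each temperature <x^2> is read off as -6 times the slope of an ordinary
    least-squares fit of ln S against q^2 over the low-q band.  The intercept
    is left free (not pinned to 0) so that EISF curvature is absorbed into it
    rather than biasing the slope.

    Temperatures with any non-positive intensity inside the band are flagged:
    their MSD and R^2 are NaN.
    """
    if not scan.normalized:
        raise EfwsError("gaussian_msd requires a normalized scan")
    mask = scan.q_mask(q_range)
    if mask.sum() < 3:
        raise EfwsError(
            f"need >= 3 q points inside {q_range}; found {int(mask.sum())}"
        )
    q2 = scan.q_values[mask] ** 2
    sub = scan.intensities[:, mask]
    n_t = scan.temperatures.size
    msd = np.full(n_t, np.nan)
    r2 = np.full(n_t, np.nan)
    valid = np.all(sub > 0, axis=1)
    if valid.any():
        y = np.log(sub[valid])
        # per-temperature OLS of ln S on q^2, slope via centered moments
        x = q2 - q2.mean()
        denom = float(np.sum(x**2))
        slope = (y * x).sum(axis=1) / denom
        intercept = y.mean(axis=1)
        fitted = intercept[:, None] + slope[:, None] * x
        ss_res = ((y - fitted) ** 2).sum(axis=1)
        ss_tot = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2_valid = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
        msd[valid] = -6.0 * slope
        r2[valid] = r2_valid
    return MSDSeries(
        temperatures=scan.temperatures.copy(),
        msd=msd,
        fit_q_range=(float(q_range[0]), float(q_range[1])),
        r_squared=r2,
        provenance={"scan_key": scan.key, "component": scan.component,
                    "state": scan.state},
    )
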