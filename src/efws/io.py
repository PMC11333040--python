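"""CSV readers and writers for elastic scans, DSC thermograms and result
tables.

Dialect: long (tidy) comma-separated tables, '.' decimal, UTF-8, one header
line, units encoded in the column names.  Temperatures and q are stored as
reported; no unit guessing.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DSCCurve,
    EfwsError,
    ElasticScan,
    NonRectangularScanError,
)

__all__ = ["read_scans", "write_scans", "read_dsc", "write_dsc", "write_results"]

SCAN_COLUMNS = [
    "sample_id",
    "component",
    "state",
    "hydration_h",
    "resolution_ueV",
    "resolution_ps",
    "temperature_K",
    "q_invA",
    "intensity",
    "intensity_err",
]

DSC_COLUMNS = ["temperature_K", "heat_flow_mW", "heating_rate_K_min"]

_GROUP_KEYS = ["sample_id", "component", "state", "hydration_h", "resolution_ps"]


def write_scans(scans: Iterable[ElasticScan], path) -> None:
    """Write scans as one long CSV table, one row per (scan, T, q)."""
    frames = []
    for scan in scans:
        n_t, n_q = scan.intensities.shape
        t_col = np.repeat(scan.temperatures, n_q)
        q_col = np.tile(scan.q_values, n_t)
        err = (
            scan.intensity_errors.ravel()
            if scan.intensity_errors is not None
            else np.full(n_t * n_q, np.nan)
        )
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": scan.sample_id,
                    "component": scan.component,
                    "state": scan.state,
                    "hydration_h": scan.hydration_h,
                    "resolution_ueV": (
                        scan.resolution_energy
                        if scan.resolution_energy is not None
                        else np.nan
                    ),
                    "resolution_ps": scan.resolution_time,
                    "temperature_K": t_col,
                    "q_invA": q_col,
                    "intensity": scan.intensities.ravel(),
                    "intensity_err": err,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=SCAN_COLUMNS
    )
    df.to_csv(path, index=False, columns=SCAN_COLUMNS)


def read_scans(path) -> list[ElasticScan]:
    """Read a long-format scan CSV back into :class:`ElasticScan` records.

    Rows are grouped by (sample_id, component, state, hydration_h,
    resolution_ps); each group must form a complete temperature x q grid.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise EfwsError(f"scan table is missing columns {missing}")
    bad = set(df["component"].unique()) - {"protein", "water"}
    if bad:
        raise EfwsError(f"unknown component value(s) {sorted(bad)}")
    scans = []
    for key, group in df.groupby(_GROUP_KEYS, sort=False):
        sample_id, component, state, h, res_ps = key
        pivot = group.pivot_table(
            index="temperature_K", columns="q_invA", values="intensity",
            aggfunc="first", sort=True,
        )
        if pivot.isna().any().any() or len(pivot) * pivot.shape[1] != len(group):
            raise NonRectangularScanError(
                f"non-rectangular scan: {key} does not form a complete T x q grid"
            )
        err_pivot = group.pivot_table(
            index="temperature_K", columns="q_invA", values="intensity_err",
            aggfunc="first", sort=True,
        )
        errors = None
        if not err_pivot.isna().all().all():
            errors = err_pivot.to_numpy()
        res_uev = group["resolution_ueV"].iloc[0]
        scans.append(
            ElasticScan(
                sample_id=str(sample_id),
                component=str(component),
                state=str(state),
                hydration_h=float(h),
                resolution_time=float(res_ps),
                resolution_energy=None if pd.isna(res_uev) else float(res_uev),
                temperatures=pivot.index.to_numpy(dtype=float),
                q_values=pivot.columns.to_numpy(dtype=float),
                intensities=pivot.to_numpy(),
                intensity_errors=errors,
            )
        )
    return scans


def write_dsc(curve: DSCCurve, path) -> None:
    pd.DataFrame(
        {
            "temperature_K": curve.temperatures,
            "heat_flow_mW": curve.heat_flow,
            "heating_rate_K_min": curve.heating_rate,
        }
    ).to_csv(path, index=False, columns=DSC_COLUMNS)


def read_dsc(path) -> DSCCurve:
    """Read one DSC thermogram; temperatures must be strictly increasing."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in DSC_COLUMNS if c not in df.columns]
    if missing:
        raise EfwsError(f"DSC table is missing columns {missing}")
    t = df["temperature_K"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise EfwsError("DSC temperatures must be strictly increasing")
    return DSCCurve(
        temperatures=t,
        heat_flow=df["heat_flow_mW"].to_numpy(dtype=float),
        heating_rate=float(df["heating_rate_K_min"].iloc[0]),
    )


def write_results(tables: Mapping[str, pd.DataFrame], path) -> list[str]:
    """Write result tables (e.g. onset temperatures as rows = sample/h,
    columns = resolution) as CSV files under directory ``path``.

    Returns the written file paths in deterministic (name-sorted) order;
    empty tables produce header-only files.
    """
    os.makedirs(path, exist_ok=True)
    written = []
    for name in sorted(tables):
        out = os.path.join(path, f"{name}.csv")
        tables[name].to_csv(out)
        written.append(out)
    return written
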