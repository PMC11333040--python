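"""Domain types, physical constants and Arrhenius / resolution-time primitives.

The central object is the :class:`ElasticScan`: a temperature x q grid of
elastic intensities S(q, dt) recorded on a backscattering spectrometer whose
energy resolution sets the longest observable relaxation time dt (the
"resolution time").  Motions slower than dt appear frozen, so the elastic
intensity is, to a good approximation, the value of the intermediate
scattering function at t = dt.

Downstream stages reduce a scan to a q-summed temperature series or a
mean-squared-displacement series, detect the onset temperature where a
hydrated sample departs from its dry companion, and fit an Arrhenius law
tau(T) = tau0 * exp(dU / (R T)) to (onset, resolution-time) pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "R_GAS",
    "HBAR_UEV_PS",
    "RESOLUTION_TIME_TABLE",
    "EfwsError",
    "DomainError",
    "NoOnsetError",
    "NoCrossingError",
    "NoTransitionError",
    "NonRectangularScanError",
    "ElasticScan",
    "SummedSeries",
    "DifferenceSeries",
    "MSDSeries",
    "ArrheniusFit",
    "OnsetResult",
    "DSCCurve",
    "DSCResult",
    "arrhenius_tau",
    "resolution_to_time",
]

#: Molar gas constant, J / (mol K).  Activation energies are per mole.
R_GAS = 8.314462

#: hbar in microelectronvolt-picoseconds, for the energy <-> time fallback.
HBAR_UEV_PS = 658.2

#: Canonical instrument resolutions (micro-eV) and the time windows they are
#: conventionally quoted as (ps).  These printed correspondences, not the
#: uncertainty-relation formula, are authoritative: 1 ueV ~ 1 ns (HFBS-class),
#: 13 ueV ~ 80 ps, 25.4 ueV ~ 40 ps (DNA/OSIRIS-class), 100 ueV ~ 10 ps.
RESOLUTION_TIME_TABLE = {1.0: 1000.0, 13.0: 80.0, 25.4: 40.0, 100.0: 10.0}


class EfwsError(Exception):
    """Base class for errors raised by this package."""


class DomainError(EfwsError, ValueError):
    """A physical-domain precondition was violated (non-positive T, ...)."""


class NoOnsetError(EfwsError):
    """The onset detector found no statistically supported onset."""


class NoCrossingError(EfwsError):
    """tau(T) never reaches the requested resolution time."""


class NoTransitionError(EfwsError):
    """No glass-transition step present in a DSC thermogram."""


class NonRectangularScanError(EfwsError, ValueError):
    """A scan table does not form a complete temperature x q grid."""


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-d sequence")
    return arr


def _strictly_increasing(x: np.ndarray) -> bool:
    return bool(np.all(np.diff(x) > 0))


@dataclass
class ElasticScan:
    """A temperature x q grid of elastic intensities with sample metadata.

    Parameters
    ----------
    sample_id : str
        Free-form sample label (e.g. ``"CYP"``).
    component : {"protein", "water"}
        Which component dominates the incoherent signal: H-protein in D2O
        reports on the protein, perdeuterated protein in H2O on the water.
    state : {"dry", "hydrated"}
    hydration_h : float
        Hydration level in g water / g protein (0 for dry samples).
    resolution_time : float
        Instrument resolution time dt in ps.
    resolution_energy : float, optional
        Energy resolution in micro-eV, if known.
    temperatures, q_values : 1-d arrays
        Strictly increasing grids in K and 1/Angstrom.
    intensities : 2-d array, shape (n_T, n_q)
        Elastic intensities (arbitrary counts, >= 0).
    intensity_errors : 2-d array, optional
        One-sigma uncertainties, same shape.
    normalized : bool
        True once each q column has been divided by its low-T base value.
    meta : dict
        Provenance (generator seed, model parameters, ...).
    """

    sample_id: str
    component: str
    state: str
    hydration_h: float
    resolution_time: float
    temperatures: np.ndarray
    q_values: np.ndarray
    intensities: np.ndarray
    intensity_errors: Optional[np.ndarray] = None
    resolution_energy: Optional[float] = None
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.component not in ("protein", "water"):
            raise ValueError(f"unknown component {self.component!r}")
        if self.state not in ("dry", "hydrated"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.hydration_h < 0:
            raise DomainError("hydration_h must be >= 0")
        if self.resolution_time <= 0:
            raise DomainError("resolution_time must be > 0")
        self.temperatures = _as_1d(self.temperatures, "temperatures")
        self.q_values = _as_1d(self.q_values, "q_values")
        if not _strictly_increasing(self.temperatures):
            raise ValueError("temperatures must be strictly increasing")
        if not _strictly_increasing(self.q_values):
            raise ValueError("q_values must be strictly increasing")
        self.intensities = np.asarray(self.intensities, dtype=float)
        shape = (self.temperatures.size, self.q_values.size)
        if self.intensities.shape != shape:
            raise ValueError(
                f"intensities shape {self.intensities.shape} != {shape}"
            )
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")
        if self.intensity_errors is not None:
            self.intensity_errors = np.asarray(self.intensity_errors, dtype=float)
            if self.intensity_errors.shape != shape:
                raise ValueError("intensity_errors shape mismatch")
            if np.any(self.intensity_errors < 0):
                raise ValueError("intensity_errors must be >= 0")

    @property
    def key(self) -> tuple:
        """Grouping key identifying one physical scan."""
        return (
            self.sample_id,
            self.component,
            self.state,
            float(self.hydration_h),
            float(self.resolution_time),
        )

    def q_mask(self, q_range: tuple[float, float]) -> np.ndarray:
        lo, hi = q_range
        return (self.q_values >= lo) & (self.q_values <= hi)


@dataclass
class SummedSeries:
    """Normalized elastic intensity vs temperature, averaged over a q band."""

    temperatures: np.ndarray
    values: np.ndarray
    q_range: tuple[float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures = _as_1d(self.temperatures, "temperatures")
        self.values = _as_1d(self.values, "values")
        if self.temperatures.size != self.values.size:
            raise ValueError("temperatures and values length mismatch")


@dataclass
class MSDSeries:
    """Mean-squared displacement <x^2(dt)> vs temperature (Gaussian fit).

    ``msd`` is NaN at temperatures where the fit was undefined (non-positive
    intensity inside the fit q-range); ``r_squared`` carries the per-point
    coefficient of determination of the ln S vs q^2 regression.
    """

    temperatures: np.ndarray
    msd: np.ndarray
    fit_q_range: tuple[float, float]
    r_squared: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures = _as_1d(self.temperatures, "temperatures")
        self.msd = np.asarray(self.msd, dtype=float)
        self.r_squared = np.asarray(self.r_squared, dtype=float)
        if not (self.temperatures.size == self.msd.size == self.r_squared.size):
            raise ValueError("length mismatch in MSDSeries")


@dataclass
class DifferenceSeries:
    """Hydrated-minus-dry deviation D(T) on a common temperature grid.

    For intensity series D = dry - hydrated (the hydrated curve drops below
    the dry one above the onset, so D grows positive); for MSD series
    D = hydrated - dry.
    """

    temperatures: np.ndarray
    values: np.ndarray
    kind: str  # "intensity" or "msd"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures = _as_1d(self.temperatures, "temperatures")
        self.values = _as_1d(self.values, "values")
        if self.temperatures.size != self.values.size:
            raise ValueError("length mismatch in DifferenceSeries")
        if self.kind not in ("intensity", "msd"):
            raise ValueError(f"unknown difference kind {self.kind!r}")


@dataclass
class OnsetResult:
    """A detected onset temperature T_on with fit diagnostics."""

    t_on: float
    method: str  # "bilinear" or "threshold"
    sse: float
    n_points: int
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    resolution_time: Optional[float] = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("bilinear", "threshold"):
            raise ValueError(f"unknown onset method {self.method!r}")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.t_on <= self.ci_high):
                raise ValueError("onset CI does not bracket t_on")


@dataclass
class ArrheniusFit:
    """Arrhenius parameters fitted to (T, tau) points.

    ``slope`` is dU/R in Kelvin; ``delta_u`` the activation energy in kJ/mol;
    ``tau0`` the attempt time in ps; ``residual_rms`` the RMS residual on
    ln tau.
    """

    delta_u: float
    tau0: float
    slope: float
    points: tuple
    residual_rms: float
    notes: dict = field(default_factory=dict)

    def tau(self, temperature) -> np.ndarray:
        """Evaluate tau(T) in ps at the fitted parameters."""
        return arrhenius_tau(temperature, self.delta_u, self.tau0)


@dataclass
class DSCCurve:
    """A DSC thermogram: heat flow (mW) vs temperature (K)."""

    temperatures: np.ndarray
    heat_flow: np.ndarray
    heating_rate: float = 1.0  # K/min
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures = _as_1d(self.temperatures, "temperatures")
        self.heat_flow = _as_1d(self.heat_flow, "heat_flow")
        if self.temperatures.size != self.heat_flow.size:
            raise ValueError("length mismatch in DSCCurve")
        if not _strictly_increasing(self.temperatures):
            raise ValueError("DSC temperatures must be strictly increasing")


@dataclass
class DSCResult:
    """Glass-transition midpoint T_DSC with the fitted baselines.

    Baselines are (intercept mW, slope mW/K) pairs; T_DSC is the temperature
    where the thermogram crosses the mean of the two extrapolated baselines,
    which for a symmetric step equals the equal-area midpoint.
    """

    t_dsc: float
    baseline_low: tuple[float, float]
    baseline_high: tuple[float, float]
    step_height: float
    notes: dict = field(default_factory=dict)


def arrhenius_tau(temperature, delta_u: float, tau0: float):
    """Relaxation time tau(T) = tau0 * exp(dU / (R T)) of a thermally
    activated process.

    Parameters
    ----------
    temperature : float or array
        Absolute temperature(s), K (> 0).
    delta_u : float
        Activation energy, kJ/mol (>= 0).
    tau0 : float
        Attempt time (high-temperature limit), ps (> 0).

    Returns
    -------
    float or ndarray
        tau in ps; strictly decreasing in T for delta_u > 0.
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise DomainError("temperature must be > 0 K")
    if tau0 <= 0:
        raise DomainError("tau0 must be > 0")
    if delta_u < 0:
        raise DomainError("delta_u must be >= 0")
    out = tau0 * np.exp(delta_u * 1e3 / (R_GAS * t))
    return float(out) if np.isscalar(temperature) else out


def resolution_to_time(resolution_energy: float, alpha: float = 1.0) -> float:
    """Map an instrument energy resolution (micro-eV) to a resolution time (ps).

    The four canonical backscattering resolutions are returned from the
    conventional lookup table (:data:`RESOLUTION_TIME_TABLE`); any other
    energy falls back to ``alpha * hbar / dE``.  The lookup is canonical
    because the quoted instrument time windows are set by the full resolution
    lineshape, not by the uncertainty relation alone.
    """
    if resolution_energy <= 0:
        raise DomainError("resolution_energy must be > 0")
    for energy, time in RESOLUTION_TIME_TABLE.items():
        if math.isclose(resolution_energy, energy, rel_tol=1e-9):
            return time
    return alpha * HBAR_UEV_PS / resolution_energy
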