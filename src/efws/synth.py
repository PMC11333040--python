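"""Synthetic elastic scans and DSC thermograms with the statistical structure
the downstream analysis assumes.

Two generative models span the two physical scenarios the pipeline is built
to distinguish:

* :class:`WaterModel` — a *resolution-limited* apparent onset.  The hydration
  water relaxes with an Arrhenius time tau(T); the elastic intensity follows
  the step-function resolution picture
  ``I(q, T) = DW(q, T) * [A0 + (1 - A0) * exp(-dt / tau(T))]``
  so the hydrated curve peels away from the dry Debye-Waller envelope only
  where tau(T) approaches the instrument window dt.  Change the instrument
  and the apparent onset moves: there is no transition in the material.

* :class:`ProteinModel` — an *intrinsic*, hydration-dependent transition.
  The mean-squared displacement gains an extra anharmonic slope above a
  glass-transition-like temperature T_g(h) that decreases with hydration;
  the kernel is independent of the resolution time, so every instrument sees
  the same onset.

The dry companion of either component carries the Debye-Waller (harmonic
vibration) factor only.  Methyl-rotation anharmonicity is deliberately
absent from the dry model: the onset statistic subtracts the dry curve
precisely to remove such hydration-independent contributions, so including
them would only cancel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .core import (
    R_GAS,
    DSCCurve,
    DomainError,
    EfwsError,
    ElasticScan,
    arrhenius_tau,
)

__all__ = [
    "WaterModel",
    "ProteinModel",
    "StudyConfig",
    "StudyBundle",
    "simulate_water_scan",
    "simulate_protein_scan",
    "simulate_dsc_curve",
    "make_study",
    "default_temperatures",
    "default_q_values",
]


def default_temperatures() -> np.ndarray:
    """Default temperature ramp: 10-300 K in 2 K steps."""
    return np.arange(10.0, 300.0 + 1e-9, 2.0)


def default_q_values() -> np.ndarray:
    """Default q grid spanning the analysis band 0.45-1.75 1/Angstrom."""
    return np.arange(0.45, 1.75 + 1e-9, 0.1)


def _tau0_for(delta_u: float, t_ref: float = 250.0, tau_ref: float = 10.0) -> float:
    """Attempt time pinning tau(t_ref) = tau_ref for activation energy delta_u."""
    return tau_ref * np.exp(-delta_u * 1e3 / (R_GAS * t_ref))


@dataclass
class WaterModel:
    """Arrhenius relaxation model for hydration-water dynamics.

    Parameters
    ----------
    delta_u : float
        Activation energy of the water relaxation, kJ/mol.  Default 38, the
        value implied by the (250 K, 10 ps) / (234 K, 40 ps) / (200 K, 1 ns)
        correspondence between onset temperature and instrument window.
    tau0 : float, optional
        Attempt time, ps.  Default pins tau(250 K) = 10 ps.
    eisf_a0 : float
        Elastic incoherent structure factor (long-time plateau) in (0, 1);
        sets the maximal relaxational drop 1 - A0.  Taken q-independent: the
        analysis averages over q, so the q-shape of the EISF is second-order.
    vib_slope : float
        Harmonic (Debye-Waller) MSD slope, Angstrom^2 / K.
    noise_sigma : float
        Relative sd of multiplicative Gaussian counting noise.
    """

    delta_u: float = 38.0
    tau0: Optional[float] = None
    eisf_a0: float = 0.7
    vib_slope: float = 1.5e-3
    noise_sigma: float = 0.005

    def __post_init__(self) -> None:
        if self.tau0 is None:
            self.tau0 = _tau0_for(self.delta_u)
        if not (0.0 < self.eisf_a0 < 1.0):
            raise DomainError("eisf_a0 must lie in (0, 1)")
        if self.tau0 <= 0 or self.delta_u < 0 or self.vib_slope < 0:
            raise DomainError("water model rates must be positive")

    def tau(self, temperature):
        return arrhenius_tau(temperature, self.delta_u, self.tau0)


@dataclass
class ProteinModel:
    """Intrinsic glass-transition-like model for protein dynamics.

    ``tg_anchors`` are (h, T_g) pairs between which T_g(h) is linearly
    interpolated; the defaults (0.2, 248) and (0.4, 228) describe a
    CYP-like globular protein whose transition moves down by 20 K when the
    hydration shell approaches monolayer coverage (h ~ 0.4).  Above T_g the
    hydrated MSD grows with an extra anharmonic slope; the dry companion
    stays harmonic.
    """

    tg_anchors: tuple = ((0.2, 248.0), (0.4, 228.0))
    vib_slope: float = 1.5e-3
    anh_slope: float = 5.0e-3
    noise_sigma: float = 0.005

    def __post_init__(self) -> None:
        if len(self.tg_anchors) == 0:
            raise EfwsError("tg_anchors must be non-empty")
        hs = [h for h, _ in self.tg_anchors]
        tgs = [t for _, t in self.tg_anchors]
        if sorted(hs) != list(hs) or len(set(hs)) != len(hs):
            raise ValueError("tg_anchors must have strictly increasing h")
        if any(b >= a for a, b in zip(tgs, tgs[1:])):
            raise ValueError("T_g must be strictly decreasing in h")
        if self.vib_slope < 0 or self.anh_slope < 0:
            raise DomainError("slopes must be >= 0")

    def t_g(self, h: float) -> float:
        """T_g at hydration h (linear interpolation between anchors)."""
        hs = np.array([a for a, _ in self.tg_anchors])
        tgs = np.array([b for _, b in self.tg_anchors])
        if h < hs[0] or h > hs[-1]:
            warnings.warn(
                f"hydration h={h} outside anchor range [{hs[0]}, {hs[-1]}]; "
                "extrapolating T_g linearly",
                stacklevel=2,
            )
            # linear extrapolation from the nearest pair
            i = 0 if h < hs[0] else len(hs) - 2
            slope = (tgs[i + 1] - tgs[i]) / (hs[i + 1] - hs[i])
            return float(tgs[i] + slope * (h - hs[i]))
        return float(np.interp(h, hs, tgs))


def _apply_noise(
    intensities: np.ndarray, noise_sigma: float, seed: Optional[int]
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    if noise_sigma < 0:
        raise DomainError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        return intensities, None
    if seed is None:
        raise EfwsError("a seed is required when noise_sigma > 0")
    rng = np.random.default_rng(seed)
    noisy = intensities * (1.0 + noise_sigma * rng.standard_normal(intensities.shape))
    errors = noise_sigma * intensities
    return np.clip(noisy, 0.0, None), errors


def simulate_water_scan(
    model: WaterModel,
    resolution_time: float,
    temperatures: Sequence[float],
    q_values: Sequence[float],
    seed: Optional[int] = None,
    state: str = "hydrated",
    sample_id: str = "D-CYP",
    hydration_h: float = 0.4,
) -> ElasticScan:
    """Simulate an elastic scan dominated by hydration-water motion.

    The noiseless hydrated kernel is
    ``exp(-q^2 vib_slope T / 6) * [A0 + (1 - A0) exp(-dt / tau(T))]``;
    the dry companion (``state="dry"``) keeps only the Debye-Waller factor.
    Multiplicative Gaussian noise of relative sd ``model.noise_sigma`` is
    applied with the given seed (required whenever the noise is non-zero).
    """
    T = np.asarray(temperatures, dtype=float)
    q = np.asarray(q_values, dtype=float)
    if T.size == 0 or q.size == 0:
        raise ValueError("temperature and q grids must be non-empty")
    dw = np.exp(-np.outer(model.vib_slope * T, q**2) / 6.0)
    if state == "hydrated":
        # exp(-dt/tau): evaluate in log space to avoid overflow at low T
        log_ratio = np.log(resolution_time) - (
            np.log(model.tau0) + model.delta_u * 1e3 / (R_GAS * T)
        )
        relax = model.eisf_a0 + (1.0 - model.eisf_a0) * np.exp(
            -np.exp(np.clip(log_ratio, -745.0, 700.0))
        )
        kernel = dw * relax[:, None]
        h = hydration_h
    elif state == "dry":
        kernel = dw
        h = 0.0
    else:
        raise ValueError(f"unknown state {state!r}")
    noisy, errors = _apply_noise(kernel, model.noise_sigma, seed)
    return ElasticScan(
        sample_id=sample_id,
        component="water",
        state=state,
        hydration_h=h,
        resolution_time=float(resolution_time),
        temperatures=T,
        q_values=q,
        intensities=noisy,
        intensity_errors=errors,
        meta={
            "generator": "water",
            "seed": seed,
            "delta_u": model.delta_u,
            "tau0": model.tau0,
            "eisf_a0": model.eisf_a0,
            "vib_slope": model.vib_slope,
            "noise_sigma": model.noise_sigma,
        },
    )


def simulate_protein_scan(
    model: ProteinModel,
    h: float,
    resolution_time: float,
    temperatures: Sequence[float],
    q_values: Sequence[float],
    seed: Optional[int] = None,
    state: str = "hydrated",
    sample_id: str = "H-CYP",
) -> ElasticScan:
    """Simulate an elastic scan dominated by protein motion.

    MSD(T) = vib_slope * T + anh_slope * max(0, T - T_g(h)) for the hydrated
    sample, harmonic only for the dry one; the Gaussian kernel
    ``exp(-q^2 MSD / 6)`` is independent of the resolution time, which makes
    the detected onset instrument-independent by construction.
    """
    T = np.asarray(temperatures, dtype=float)
    q = np.asarray(q_values, dtype=float)
    if T.size == 0 or q.size == 0:
        raise ValueError("temperature and q grids must be non-empty")
    if state == "hydrated":
        tg = model.t_g(h)
        msd = model.vib_slope * T + model.anh_slope * np.clip(T - tg, 0.0, None)
        h_out = h
    elif state == "dry":
        tg = None
        msd = model.vib_slope * T
        h_out = 0.0
    else:
        raise ValueError(f"unknown state {state!r}")
    kernel = np.exp(-np.outer(msd, q**2) / 6.0)
    noisy, errors = _apply_noise(kernel, model.noise_sigma, seed)
    return ElasticScan(
        sample_id=sample_id,
        component="protein",
        state=state,
        hydration_h=h_out,
        resolution_time=float(resolution_time),
        temperatures=T,
        q_values=q,
        intensities=noisy,
        intensity_errors=errors,
        meta={
            "generator": "protein",
            "seed": seed,
            "t_g": tg,
            "vib_slope": model.vib_slope,
            "anh_slope": model.anh_slope,
            "noise_sigma": model.noise_sigma,
        },
    )


def simulate_dsc_curve(
    t_g: float,
    step_height: float = -0.3,
    width: float = 3.0,
    baseline_low: tuple[float, float] = (-0.8, -0.002),
    baseline_high: Optional[tuple[float, float]] = None,
    heating_rate: float = 1.0,
    noise_sigma: float = 0.0,
    seed: Optional[int] = None,
    temperatures: Optional[Sequence[float]] = None,
) -> DSCCurve:
    """Simulate a DSC thermogram with a glass-transition-like step.

    Heat flow blends between two linear baselines through a logistic sigmoid
    centred at ``t_g`` with scale ``width`` (K).  When ``baseline_high`` is
    not given it is the low baseline shifted by ``step_height`` (mW), so a
    zero step height produces a featureless thermogram.
    """
    if width <= 0:
        raise DomainError("width must be > 0")
    if temperatures is None:
        temperatures = np.arange(150.0, 300.0 + 1e-9, 0.5)
    T = np.asarray(temperatures, dtype=float)
    if baseline_high is None:
        baseline_high = (baseline_low[0] + step_height, baseline_low[1])
    low = baseline_low[0] + baseline_low[1] * T
    high = baseline_high[0] + baseline_high[1] * T
    s = expit((T - t_g) / width)
    hf = (1.0 - s) * low + s * high
    if noise_sigma > 0:
        if seed is None:
            raise EfwsError("a seed is required when noise_sigma > 0")
        rng = np.random.default_rng(seed)
        hf = hf + noise_sigma * rng.standard_normal(T.shape)
    return DSCCurve(
        temperatures=T,
        heat_flow=hf,
        heating_rate=heating_rate,
        meta={
            "generator": "dsc",
            "t_g": t_g,
            "width": width,
            "baseline_low": tuple(baseline_low),
            "baseline_high": tuple(baseline_high),
            "noise_sigma": noise_sigma,
            "seed": seed,
        },
    )


@dataclass
class StudyConfig:
    """Experimental design of a synthetic study.

    Defaults mirror the canonical design: protein scans (dry + D2O-hydrated)
    and water scans (dry + H2O-hydrated perdeuterated protein) at instrument
    windows ~1 ns / ~40 ps / ~10 ps, hydration levels 0.2 and 0.4, plus DSC
    thermograms for dry, h = 0.2 (step at 245 K) and h = 0.4 (step at 225 K).
    """

    seed: int = 0
    resolutions_ueV: tuple = (1.0, 25.4, 100.0)
    protein_h: tuple = (0.2, 0.4)
    water_h: tuple = (0.2, 0.4)
    dsc_steps: tuple = (("dry", None), (0.2, 245.0), (0.4, 225.0))
    water_model: WaterModel = field(default_factory=WaterModel)
    protein_model: ProteinModel = field(default_factory=ProteinModel)
    temperatures: np.ndarray = field(default_factory=default_temperatures)
    q_values: np.ndarray = field(default_factory=default_q_values)
    dsc_noise_sigma: float = 0.01  # mW
    protein_sample_id: str = "H-CYP"
    water_sample_id: str = "D-CYP"

    def noiseless(self) -> "StudyConfig":
        """A copy of this design with all noise switched off."""
        return replace(
            self,
            water_model=replace(self.water_model, noise_sigma=0.0),
            protein_model=replace(self.protein_model, noise_sigma=0.0),
            dsc_noise_sigma=0.0,
        )


@dataclass
class StudyBundle:
    """Deterministic bundle of scans and DSC curves for one study."""

    scans: list
    dsc_curves: dict  # label -> DSCCurve
    config: StudyConfig


def make_study(config: Optional[StudyConfig] = None) -> StudyBundle:
    """Generate the full synthetic study a config describes.

    Every (component, state, h, resolution) cell receives its own
    reproducible seed derived from ``config.seed`` via a seed sequence; the
    per-scan seeds are logged in the scan metadata, so identical configs give
    bit-identical bundles and distinct master seeds change only the noise,
    never the noiseless kernels.
    """
    from .core import resolution_to_time

    if config is None:
        config = StudyConfig()
    ss = np.random.SeedSequence(config.seed)
    n_cells = (
        len(config.resolutions_ueV)
        * (2 + len(config.protein_h) + len(config.water_h))
        + len(config.dsc_steps)
    )
    child_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_cells)]
    seeds = iter(child_seeds)

    scans: list[ElasticScan] = []
    seen = set()
    for energy in config.resolutions_ueV:
        dt = resolution_to_time(energy)
        # one dry companion per (component, resolution), shared across h
        scan = simulate_protein_scan(
            config.protein_model,
            0.0,
            dt,
            config.temperatures,
            config.q_values,
            seed=next(seeds),
            state="dry",
            sample_id=config.protein_sample_id,
        )
        scan.resolution_energy = energy
        scans.append(scan)
        for h in config.protein_h:
            scan = simulate_protein_scan(
                config.protein_model,
                h,
                dt,
                config.temperatures,
                config.q_values,
                seed=next(seeds),
                state="hydrated",
                sample_id=config.protein_sample_id,
            )
            scan.resolution_energy = energy
            scans.append(scan)
        scan = simulate_water_scan(
            config.water_model,
            dt,
            config.temperatures,
            config.q_values,
            seed=next(seeds),
            state="dry",
            sample_id=config.water_sample_id,
        )
        scan.resolution_energy = energy
        scans.append(scan)
        for h in config.water_h:
            scan = simulate_water_scan(
                config.water_model,
                dt,
                config.temperatures,
                config.q_values,
                seed=next(seeds),
                state="hydrated",
                hydration_h=h,
                sample_id=config.water_sample_id,
            )
            scan.resolution_energy = energy
            scans.append(scan)
    for scan in scans:
        if scan.key in seen:
            raise EfwsError(f"duplicate scan cell {scan.key}")
        seen.add(scan.key)

    dsc_curves = {}
    for label, tg in config.dsc_steps:
        seed = next(seeds)
        if tg is None:
            curve = simulate_dsc_curve(
                t_g=225.0,
                step_height=0.0,
                noise_sigma=config.dsc_noise_sigma,
                seed=seed if config.dsc_noise_sigma > 0 else None,
            )
        else:
            curve = simulate_dsc_curve(
                t_g=tg,
                noise_sigma=config.dsc_noise_sigma,
                seed=seed if config.dsc_noise_sigma > 0 else None,
            )
        key = str(label)
        if key in dsc_curves:
            raise EfwsError(f"duplicate DSC cell {key}")
        dsc_curves[key] = curve
    return StudyBundle(scans=scans, dsc_curves=dsc_curves, config=config)
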