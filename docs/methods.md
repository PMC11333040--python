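# Methods

## The measurement model

A backscattering spectrometer with energy resolution ΔE integrates all
motion slower than its resolution time Δt into the elastic peak, so the
elastic intensity is approximately the intermediate scattering function
evaluated at t = Δt. We use the step-function picture throughout: a
relaxation with characteristic time τ contributes its full relaxational
drop once τ ≪ Δt and none of it once τ ≫ Δt, blended by exp(−Δt/τ). No
resolution-lineshape convolution (Gaussian/Lorentzian) is performed; for
onset analysis the step picture captures the phenomenology and keeps every
stage analytically checkable.

The canonical energy↔time correspondences (1 µeV ↔ 1 ns, 13 µeV ↔ 80 ps,
25.4 µeV ↔ 40 ps, 100 µeV ↔ 10 ps) are a lookup table, because quoted
instrument windows are set by the full resolution function rather than by
ħ/ΔE alone; energies outside the table fall back to α·ħ/ΔE with
configurable α (default 1).

## Generator models

The synthetic study stands in for facility data and defines the conditions
every recovery test runs under.

**Water (resolution-effect scenario).** Hydrated kernel

    I(q,T) = exp(−q²·a_vib·T/6) · [A₀ + (1−A₀)·exp(−Δt/τ(T))],
    τ(T) = τ₀·exp(ΔU/(R·T))

with ΔU = 38 kJ/mol and τ₀ pinned so that τ(250 K) = 10 ps
(τ₀ ≈ 1.15·10⁻⁷ ps); the dry companion carries the Debye–Waller factor
only. The EISF plateau A₀ = 0.7 is taken q-independent — the analysis
averages over q, so the q-shape of the EISF is second order — and its
value is a plausible choice, not a fitted one (no amplitude scale for the
water drop is available). Vibrational MSD slope a_vib = 1.5·10⁻³ Å²/K
(≈0.45 Å² at 300 K, typical of protein powders).

**Protein (intrinsic-transition scenario).** Hydrated MSD

    ⟨x²⟩(T) = a_vib·T + a_anh·max(0, T − T_g(h)),

with T_g(h) interpolated linearly between anchors (0.2, 248 K) and
(0.4, 228 K) — a CYP-like globular protein whose transition drops 20 K as
hydration approaches monolayer coverage — and kernel exp(−q²⟨x²⟩/6),
independent of Δt by construction. Anharmonic slope a_anh = 5·10⁻³ Å²/K
gives a clearly resolved but not caricatured break. The dry protein shares
a_vib and deliberately omits methyl-rotation anharmonicity: the onset
statistic subtracts the dry curve precisely to remove such
hydration-independent contributions, so modelling them would only cancel.

**DSC.** Heat flow blends between two linear baselines through a logistic
sigmoid centred at t_g (width 3 K, step −0.3 mW on a −0.8 mW baseline);
study defaults place steps at 245 K (h = 0.2) and 225 K (h = 0.4), with a
featureless dry curve. Heating rate metadata (1 K/min, matching the
neutron ramps) is carried but unused.

Noise is multiplicative Gaussian, relative sd 0.005 (neutron) and 0.01 mW
additive (DSC); a seed is mandatory whenever noise is on, and per-cell
seeds are spawned deterministically from the study seed and logged in scan
metadata, so identical configs are bit-identical and different seeds share
identical noiseless kernels.

What the generator does **not** emulate: multiple scattering, coherent
contributions, q-dependent EISF shape, detector-efficiency structure,
non-Arrhenius (super-Arrhenius/VFT) water dynamics, enthalpy-relaxation
overshoots, and resolution-function wings. Passing recovery tests
therefore demonstrate estimator correctness under the stated statistical
model, not robustness to every artefact of measured spectra.

## Preprocessing

Each q column is normalized by its mean over the base window 0–20 K
(default grid 10–300 K in 2 K steps puts six points there). Averaging the
mean rather than the sum over the q band (0.45–1.75 Å⁻¹, closed interval,
unweighted) differs only by a constant that normalization removes and
keeps series ≤ 1 across instruments with different q grids. The
Gaussian-approximation MSD uses q = 0.45–0.9 Å⁻¹ with a free intercept, so
q-independent prefactors (EISF level) land in the intercept and only the
slope −⟨x²⟩/6 is read off. Two consequences worth knowing: the recovered
MSD is referenced to the base-window mean temperature (normalization
subtracts the base-window MSD), and the log of the base-window *mean*
intensity is not exactly quadratic in q, which offsets the absolute MSD
level by ~2·10⁻⁶ Å² while leaving temperature increments exact.

## Onset detection

The primary estimator is a continuous two-segment linear fit of the
difference curve D(T) (dry − hydrated for intensities, hydrated − dry for
MSD, interpolated onto the coarser common grid): the breakpoint is
searched exhaustively over interior sample points with ≥ 3 points and a
30 K margin per segment (ties toward lower temperature), then refined
continuously between the bracketing samples. Featureless data are
rejected by requiring both that the slope increase across the break and
that an F-test against the single-line fit pass at level 10⁻³. The first
segment may be constrained to slope 0 (`flat_first`), which the
dry-subtracted difference satisfies by construction. The secondary
threshold estimator reports the first of m = 3 consecutive points
exceeding the lowest-quartile baseline mean by k = 3 sd, with the crossing
interpolated between samples (on noiseless data the sd floor is 10⁻¹²).

The two estimators answer subtly different questions on a
resolution-limited curve. The water deviation grows gradually (the
exp(−Δt/τ) factor turns on over ~4 decades of τ), so the SSE-optimal
breakpoint sits well below the τ = Δt crossing, while the threshold
estimator fires at a fixed small deviation — i.e. at a fixed ratio Δt/τ —
which shifts every resolution's onset by the *same* amount in ln τ.
Consequently the breakpoint track gives the cleaner onset *tables* (its
bias cancels in spreads), but the threshold track is the right input for
activation-energy recovery via the τ(T_on) = Δt identification: a constant
ln τ offset biases only τ₀, not ΔU. The pipeline uses the breakpoint
detector for tables and verdict, and reports the threshold-based ΔU; on
the default noisy study the breakpoint route would give ~16 kJ/mol where
the threshold route recovers 36–43 kJ/mol across seeds (generator: 38).
That the detected deviation onset is not the model crossing is also why
the report always lists both the onsets and the fitted-law crossings.

Uncertainty comes from a residual-resampling bootstrap of the breakpoint
(percentile 95% interval, seeded). Residual resampling assumes the
two-segment model is correctly specified; that holds exactly on the
MSD-difference track (the generator's hydrated-minus-dry MSD is exactly
piecewise linear), where coverage of the generator T_g is 98% over 50
replicate noisy studies. On the intensity track the difference is slightly
concave above T_g (Debye–Waller decay), biasing the breakpoint ~1 K low
and dropping coverage to ~70% — a model-misspecification bias the
bootstrap cannot see, documented here as a known limitation; calibration
checks therefore run on the MSD track with `flat_first=True`.

## Arrhenius analysis

Unweighted OLS of ln τ on 1/T (no uncertainties are available for the
canonical pairs); exact for two points; slope ΔU/R in K with
R = 8.314462 J/(mol·K), ΔU per mole. Inversion
T = (ΔU/R)/ln(Δt/τ₀) requires Δt > τ₀ and positive barrier, otherwise "no
crossing". `onsets_to_arrhenius` records τ(T_on) = Δt explicitly as an
assumption and diagnoses whether onsets look resolution-limited at all via
the inverse regression slope d(1/T)/d(ln τ): ≈ R/ΔU for an activated
process, ≈ 0 for an intrinsic transition (flagged when the onset spread is
within 3 K). Perfectly resolution-invariant onsets make the (1/T, ln τ)
regression singular; that degenerate case returns NaN parameters with the
flag rather than an error, so the protein diagnostic path stays usable.

## DSC midpoint

Linear baselines are fitted on disjoint windows (defaults 160–190 K and
260–290 K — the exact windows are conventions, configurable); T_DSC is the
interpolated temperature where the thermogram crosses the mean of the two
extrapolated baselines inside the gap. For a symmetric step this is
exactly the equal-area midpoint; for asymmetric steps it is an
approximation. Detection requires the baseline separation to exceed 3× the
pooled baseline-residual noise (with a 10⁻⁹ mW floor for the noiseless
degenerate case); the construction is invariant under adding a common
linear trend to curve and baselines.

## Decoupling verdict

A study is *decoupled* when all four hold with default tolerances
(tol_protein = 5 K, min_water_spread = 20 K): protein onset spread across
resolutions ≤ tol; water onset spread across resolutions ≥ min spread;
protein onsets vary with hydration beyond tol; water onsets do not. A
complete design failing any clause is *coupled*; fewer than two
resolutions or hydration levels per component is *inconclusive*.

## Problem sizes and determinism

Default grids — 146 temperatures (10–300 K, 2 K), 14 q points, 3
resolutions, 2 hydration levels, both components — were chosen so a full
study analyses in ~1 s and the 50-replicate bootstrap calibration
(n_boot = 200) in ~20 s. All randomness flows from a single study seed
through a seed sequence; reports rerun bit-identically, and the breakpoint
grid search is solved by batched normal equations so the bootstrap stays
cheap.
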