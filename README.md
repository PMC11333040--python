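# efws — elastic fixed-window scan analysis

`efws` is a Python toolkit for analysing elastic incoherent neutron
scattering fixed-window scans (EFWS) of hydrated protein powders, together
with the companion DSC thermograms. Its purpose is to separate two
phenomena that look identical on a single spectrometer:

* an **intrinsic protein dynamical transition** — a glass-transition-like
  onset at a temperature T_on that depends on the protein and on the
  hydration level *h* (g water / g protein) but **not** on the instrument;
* a **resolution-limited apparent onset** in the hydration water — the
  relaxation time τ(T) of a thermally activated process simply crosses the
  instrument's resolution time Δt, so the apparent onset moves with the
  instrument and there is no transition in the material at all.

Isotope labelling selects the component: H-protein in D₂O reports on the
protein, perdeuterated protein in H₂O on its hydration water.

## The analysis

The elastic intensity S(q, Δt) is normalized to its value at ~10 K and
averaged over q = 0.45–1.75 Å⁻¹. The onset temperature T_on is where the
hydrated sample's curve deviates from the dry sample's — a definition that
subtracts hydration-independent contributions such as methyl rotations.
The deviation curve D(T) is fitted with a continuous two-segment
(breakpoint) regression; a threshold rule (first sustained excursion above
k·σ of the low-T baseline) provides a cross-check.

In the Gaussian approximation S(q, Δt) = exp(−q²⟨x²(Δt)⟩/6), so the
mean-squared displacement is read from the slope of ln S versus q² over
q = 0.45–0.9 Å⁻¹.

For a thermally activated water relaxation,

    τ(T) = τ₀ · exp(ΔU / (R T)),

so identifying τ(T_on) = Δt at each instrument turns the per-resolution
onsets into (T, τ) points; ordinary least squares of ln τ on 1/T yields the
activation energy ΔU and attempt time τ₀, and the inverse,
T = (ΔU/R) / ln(Δt/τ₀), predicts where any instrument window is crossed.
The DSC midpoint T_DSC is where the thermogram crosses the mean of two
extrapolated linear baselines fitted below and above the step.

Because the raw neutron data require facility access, the package includes
a first-class synthetic-data generator (`efws.synth`) that emulates both
scenarios — an Arrhenius water model and a glass-transition protein model
with T_g(h) anchors — plus DSC curves, at the canonical resolutions
1, 13, 25.4 and 100 µeV (≈1 ns, 80 ps, 40 ps, 10 ps).

## Worked example

Fitting the Arrhenius law to the three canonical (onset temperature,
resolution time) pairs for hydration water — 10 ps at 250 K, 40 ps at
234 K, 1 ns at 200 K:

```sh
$ efws arrhenius --point 250:10 --point 234:40 --point 200:1000 \
      --crossing-at 1000 --crossing-at 40
delta_U = 37.99 kJ/mol
tau0    = 1.222e-07 ps
slope   = 4569.3 K (dU/R)
crossing at 1000.0 ps: 200.2 K
crossing at 40.0 ps: 233.1 K
```

The barrier is ~38 kJ/mol, and the fitted law reproduces the input points:
a 1 ns window is crossed at ~200 K, a 40 ps window at ~233 K — the
signature of an onset that is set by the instrument, not the sample.

Running the full synthetic study end to end (simulate, normalize, q-sum,
difference vs dry, onset detection, Arrhenius analysis, DSC midpoints,
verdict):

```sh
$ efws report --out report_dir --seed 1
verdict: decoupled
water delta_U = 16.0 kJ/mol (tau(T_on) = dt assumption)
  protein_resolution_spread_K: 1.3513989204485028
  water_resolution_spread_K: 68.8668647096915
  protein_hydration_spread_K: 20.85355464553075
  water_hydration_spread_K: 0.12885777805118437
```

Protein onsets agree to 1.4 K across a two-decade range of resolution
times while shifting by ~20 K between h = 0.2 and h = 0.4; water onsets
spread by ~69 K across resolutions while ignoring hydration — the
decoupling signature. (The breakpoint detector fires early on the gradual
water deviation, which biases the ΔU inferred from *detected* onsets low;
the threshold detector, which the pipeline reports for this purpose,
recovers ΔU within ~15% — see `docs/methods.md`.)

The same analysis runs on measured data exported to the package's CSV
dialect via `efws analyze --scans scans.csv --dsc curve.csv --out report/`.

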