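# Methods

This note records the models implemented in `radioswitch`, the provenance
and defaults of every load-bearing parameter, what the synthetic-data
generators do and do not emulate, and the numerical and design choices made
where the problem left them open.

## 1. Units and the G-value algebra

All internal computation uses one canonical unit system — dose in Gy,
concentration in µM, time in hours, yields in µmol/J — converted only at
I/O boundaries. The G-value (molecules per 100 eV) and µmol/J
representations of a radiochemical yield are interconverted with the exact
SI elementary charge and Avogadro constant,

    1 per 100 eV = 10⁶ / (100 · 1.602176634e-19 · 6.02214076e23) µmol/J
                 ≈ 0.103642 µmol/J,

rather than the rounded "100 eV ≈ 1.60e-17 J" often used in dosimetry
shorthand; the printed 81 ↔ 8.4 µmol/J pairing is reproduced to its printed
precision either way. Dose-to-concentration bookkeeping assumes a dilute
aqueous medium with density 1.0 kg/L (configurable), so
`c[µM] = G[µmol/J] · D[Gy] · ρ[kg/L]` exactly.

## 2. Effective hydroxyl-radical yield

The homogeneous (~10⁻⁷ s post-deposition) HO• yield is modelled as

    G_eff(HO•) = G_base(source) · gas_factor · (1 + f_Gd(c_Gd))

with

- **G_base**: 0.280 µmol/J for the 662 keV γ source and the 4.5 MeV
  electron beam, 0.200 µmol/J for the 80 keV X-ray generator (low-energy
  photons lose more HO• to intratrack recombination). These are preset
  data, replaceable per source.
- **gas_factor**: 2.0 under N₂O (all hydrated electrons converted to HO•,
  hence G = 0.56 µmol/J for γ), 1.0 for N₂ and for no inerting. N₂
  saturation only strips O₂; since the activation chemistry does not
  involve the HO₂•/O₂•⁻ couple, oxygen chemistry is not modelled at all.
- **f_Gd**: a shape-preserving (PCHIP in log(1+c)) interpolation through
  anchor tables per source. Only the curve maxima (20% at 500 µM for γ,
  33% at 200 µM for X-ray) and the qualitative rise (10–200 µM), plateau
  (25–500 µM) and decline (500–2000 µM) are measured facts; intermediate
  anchors are smooth fill-in respecting that shape, shipped as editable
  data. Monotone interpolation guarantees the curve's maximum is attained
  at an anchor, so the printed maxima are reproduced exactly. Outside
  0–2000 µM the endpoint value is returned with an extrapolation warning.
  The electron beam has no dedicated measurement and reuses the γ curve
  (same baseline yield); this is an explicit, swappable assumption. Whether
  the free-ion Gd³⁺ curve applies unchanged to chelated Gd is unknown; the
  curve is therefore data, not doctrine.

Scavengers do not change G_eff; they partition the HO• budget by standard
competition kinetics, `f_i = k_i·c_i / Σ_j k_j·c_j`. Each scavenger carries
a qualitative fate — `quench` (captured HO• leaves the oxidising budget) or
`convert_to_oxidant` (budget preserved as another oxidant) — stored as data
and mirrored in `oxidising_fraction`, not mechanistically simulated. Only
the coumarin rate constant (1.05×10¹⁰ L mol⁻¹ s⁻¹) is a measured input; the
rest of the panel carries literature-typical constants as replaceable
presets.

**Fenton budget.** Chemically generated HO• is modelled phenomenologically:
H₂O₂ is consumed pseudo-first-order at a rate proportional to Fe²⁺
(reference 75 µM, 0.1 min⁻¹), and a fixed fraction of consumed peroxide
appears as bulk HO•. That fraction (3.246×10⁻⁵) was calibrated once by
inverting the single measured Fenton outcome (trans 16.7% → 48.4% in 5 min
at 50 mM H₂O₂ / 75 µM Fe²⁺) through the monoexponential activation model;
`calibrate_fenton_yield` reproduces the constant. The two parameters
summarise an unresolved radical chain and carry no elementary-rate meaning.

## 3. Switch kinetics

Two first-order processes act on the two-species (cis/trans) composition;
conservation `cis + trans = 1` holds by construction.

- **Thermal back relaxation**: rate ln2/t½ with t½ = 2.3 h (37 °C, PBS).
  No Arrhenius extrapolation is attempted — the half-life is a parameter
  the caller overrides for other temperatures.
- **Radiation activation**: monoexponential in cumulative dose with
  `k_eff = k_act · G_eff/G_ref`, `k_act = 0.21 Gy⁻¹` at
  `G_ref = 0.280 µmol/J`. The linear scaling of k with G_eff is the
  package's central modelling assumption; it is what the N₂O equivalence
  experiments support (5 Gy under N₂O ≡ 10 Gy in water), but it was never
  written as a formula in the source work. Consequences: activation
  depends on conditions only through `D · G_eff`, and dose composes as a
  semigroup. Irradiation steps are treated as instantaneous (minutes of
  beam time vs a 2.3 h thermal half-life).
- **PSS1** (90% cis) is an input parameter, not derived from
  photoisomerisation quantum yields (not available).
- The radical-cation mechanism appears only through its macroscopic
  consequence: stoichiometric, non-catalytic conversion, i.e. yields
  linear in switch concentration.

**Dose-efficiency model.** `G(trans)/[cis]₀ = a·ln D + b` with defaults
(−0.036, 0.1304) G-value/µM, fitted over 2–20 Gy. The model warns outside
that range and clips negative predictions (~37 Gy onward) to zero. It is
kept as a *separate empirical description* and deliberately not reconciled
with the monoexponential: the efficiency model implies ≈0.13 G-value/µM at
1 Gy while the single-point G = 81 at 2 Gy / 50 µM implies ≈1.6 G-value/µM
— an order-of-magnitude tension in the source data whose resolution (the
concentration range behind the per-dose slopes is unpublished) is not ours
to invent. Both are implemented faithfully; a loose order-of-magnitude
coherence check (2 Gy at 8.4 µmol/J deposits ~37% of a 45 µM cis pool,
comparable to the measured ~33% raw activation) is part of the test suite.

**Fenton equivalent dose** inverts the monoexponential,
`D = ln[(1−trans₀)/(1−trans₁)]/k_eff`, tolerating one-ulp rounding of
no-op jumps and rejecting genuine reversals or full conversion.

## 4. Estimators

All regressions are ordinary least squares via statsmodels.

- **Activation constant.** `y = ln[(A0−Ainf)/(At−Ainf)]` against dose,
  through-origin by default because the transform forces y(0) = 0; an
  intercept option exists for diagnostics (whether the original analysis
  included one is not stated, so neither choice is asserted). Absorbance
  readouts convert to trans fractions by linear two-component mixing at
  367 nm (Beer–Lambert additivity). When a paired dark control is present
  the correction is applied in log-survival space: first-order activation
  and relaxation are *additive* in y, so subtracting the control's own
  drift at matched timestamps removes the thermal term exactly, for any
  measurement schedule or preparation lag — at zero noise the generating k
  is recovered to machine precision regardless of timing. (A
  fraction-space subtraction, used for the G-value estimator below, is
  only approximately exact.)
- **G-value at a dose.** Corrected increment
  `Δtrans_irr − Δtrans_ctrl` at matched timestamps, scaled by the switch
  pool (initial cis / (1 − trans₀)), divided by dose → µmol/J → per
  100 eV. A model-based thermal fallback (flagged in the result record) is
  used when no control exists. Negative corrected increments warn and clip
  to zero, since a yield is non-negative by definition. Uncertainty for a
  single series is reported as 0 (no replicate information); a seeded
  bootstrap over ≥3 replicate series is provided.
- **Coumarin dosimetry.** Fluorescence → [7-OH-Coum] via the standard
  curve; OLS slope vs dose (intercept fitted, absorbing the blank);
  division by the 3.1% conversion yield gives G(HO•).
- **Thermal half-life.** OLS of ln(1−trans) vs time; saturated points
  (trans ≥ 1) are filtered with a warning, non-monotone noise jitter is
  kept (dropping dips would bias the slope), and a non-decaying course is
  rejected. t½ = ln2/|slope| with delta-method standard error.
- **Efficiency model.** OLS of the per-concentration slopes against
  ln(dose); ≥3 positive doses required.
- **Enhancement profile.** `G(c)/G(0) − 1` with a required positive
  baseline.

On noiseless generator output every estimator recovers its generating
parameter to numerical precision (exact-inverse property); on seeded noisy
ensembles (200 replicates at the assays' own designs) ensemble means are
tested against the generating values within twice the Monte-Carlo standard
error — the statistically meaningful version of a "no bias" check for a
finite ensemble.

## 5. Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure the estimators assume*:
photostationary start (90% cis), incremental irradiation with thermal
relaxation between measurements on both plates, a control plate prepared
`lag_h` earlier (default 0.5 h) and measured concurrently, measurement
intervals of 0.25 h per dose step, replicate-averaged noise (triplicate by
default), the nine-dose coumarin schedule (0–40 Gy), and Gaussian two-band
spectra (cis 322 nm / trans 367 nm, trans ≫ cis at 367 nm — only the
367 nm two-point mixing is load-bearing). Noise defaults (fraction SD
0.018 ≈ 2% of the 0.9 dynamic range, absorbance SD 0.01 OD, fluorescence
3% relative) approximate the few-percent triplicate scatter of the wet
assays and are never silently changed.

Not emulated: HPLC chromatograms and peak integration, plate-geometry or
photon-transport effects, dose-rate effects (dose is the only radiation
variable), spur/track chemistry, compound degradation at high H₂O₂, and
any cell-based readout. Passing recovery tests therefore demonstrates that
the estimators invert the assumed generative model at realistic noise —
not that real assays are free of systematic effects outside that model.

Randomness: one root seed; each assay type draws from a deterministically
derived child stream (`default_rng([seed, stream_id])`), so corpora are
bit-identical per seed and independent across assay types.

## 6. Problem sizes and numerical choices

Stochastic recovery checks use 200-replicate ensembles at the real assay
designs (4–5 dose points, 8-point time courses, 9-point fluorescence
series); these sizes give Monte-Carlo standard errors an order of magnitude
below the experimental tolerance bands while keeping the full suite and the
acceptance script in the seconds range. Tie-breaks and degeneracies:
dose-0 rows are excluded from the through-origin k regression (they carry
no information and their transform is 0/identically undefined under noise);
readouts outside the open (Ainf, A0) interval raise a data-ordering error
naming the dose; scavenger competition with zero total capacity, missing
Gd baselines, and fewer than the minimum usable points all raise typed
errors mapped to distinct CLI exit codes (3 config / 4 data / 5 numerical).

## 7. Known limitations

- The Gd-enhancement curve between its anchors is interpolation, not
  measurement; its transfer from free Gd³⁺ to chelated Gd is assumed data.
- The k ∝ G_eff scaling is validated only via N₂O equivalence; a different
  kinetic regime of HO• capture (coumarin vs switch) at early times could
  bend it, and the X-ray/γ activation gap at 2–5 Gy is noted but not
  modelled.
- The efficiency model and the single-point G-value anchor disagree by an
  order of magnitude (see §3); both are exposed, neither is adjusted.
- The Fenton model is an effective two-parameter summary calibrated to one
  outcome; it interpolates sensibly but should not be extrapolated far
  from the calibration conditions.
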