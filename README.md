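# radioswitch

Quantitative toolkit for **ionising-radiation activation of azobenzene
photoswitches** ("radioswitches"): G-value dosimetry, water-radiolysis
hydroxyl-radical yields under modified solution conditions, cis→trans
activation kinetics, and the matching estimators — plus seeded
synthetic-assay generators so the whole analysis pipeline can be verified
end-to-end by parameter recovery.

## The scientific problem

Conventional photoswitches need UV–visible photons and therefore cannot be
actuated more than a few millimetres under the skin. A gadolinium-chelated
azobenzene can instead be switched by clinical radiotherapy beams (γ, X-ray,
electron): the radiation radiolyses water, the resulting hydroxyl radical
HO• oxidises the azo bond, and the radical cation isomerises essentially
instantaneously from *cis* to *trans*. The quantitative framework is:

- **Radiochemical yield (G-value).** Species produced per energy absorbed,
  either µmol/J or molecules per 100 eV; the two scales are related by
  `1 per 100 eV = 10⁶/(100·e·N_A) ≈ 0.103642 µmol/J`, so G = 81 ↔ 8.40 µmol/J.
- **Effective HO• yield.** `G_eff = G_base · gas_factor · (1 + f_Gd(c))` with
  baseline yields 0.280 (γ), 0.200 (X-ray), 0.280 (electron) µmol/J,
  a gas factor of 2 under N₂O (hydrated electrons are converted to HO•)
  and an anchored Gd³⁺ dose-enhancement curve `f_Gd` (rise → plateau →
  decline; maxima 20% at 500 µM for γ, 33% at 200 µM for X-ray).
- **Activation kinetics.** Monoexponential approach to all-trans in dose,
  `trans(D) = 1 − (1 − trans₀)·exp(−k_eff·D)` with
  `k_eff = k_act·G_eff/G_ref`, `k_act = 0.21 Gy⁻¹`; thermal back relaxation
  `trans(t) = 1 − (1 − trans₀)·exp(−ln2·t/t½)` with t½ = 2.3 h at 37 °C.
- **Dose-efficiency model.** `G(trans)/[cis]₀ = a·ln D + b` over 2–20 Gy
  with (a, b) = (−0.036, 0.1304) G-value/µM.
- **Estimators.** Through-origin OLS of `ln[(A0−Ainf)/(At−Ainf)]` vs dose
  for k (with exact paired-plate thermal correction), the coumarin/
  7-hydroxycoumarin fluorescent probe for G(HO•) (3.1% conversion yield),
  log-linear regression for t½, and OLS in ln-dose for (a, b).

## Worked example

```python
import radioswitch as rs

params = rs.SwitchParameters()                 # γ-in-water defaults
n2o = rs.SolutionConditions(gas="N2O")

rs.effective_g_ho(rs.GAMMA_SOURCE, n2o).value_umol_per_J
# 0.56  -- N₂O doubles the 0.280 µmol/J water yield

rs.equivalent_dose(5.0, n2o, rs.WATER, rs.GAMMA_SOURCE)
# 10.0  -- 5 Gy under N₂O generates the HO• of 10 Gy in water

state = rs.pss1_state(params)                  # 90% cis photostationary start
rs.radiation_activate(state, 2.0, params).trans_fraction
# 0.40865786216644895  -- 2 Gy at k = 0.21 Gy⁻¹

rs.fenton_equivalent_dose(0.167, 0.484, params)
# 2.2806041746918093  -- the chemical (Fenton) trans jump ≡ ~2.3 Gy

series = rs.gen_dose_response(                 # synthetic paired-plate assay
    params, rs.GAMMA_SOURCE, doses_Gy=[0, 0.5, 1.0, 1.5, 2.0],
    noise=rs.AssayNoiseModel(fraction_sigma=0.018, seed=11),
)
rs.fit_activation_constant(series).k_per_Gy
# 0.2090...  -- recovered within the ±0.02 experimental band
```

The numbers printed above are produced by the code as shown: the first two
are exact algebraic consequences of the yield rules; the third is the
closed-form monoexponential; the last is a seeded noisy recovery of the
generating constant.

## Analysis scripts

`analysis/01_simulate_assays.py` … `05_efficiency_and_fenton.py` are thin
narrative drivers over the library: they generate the synthetic corpus for
all three sources, fit activation constants and the thermal half-life,
perform coumarin HO• dosimetry and equivalent-dose bookkeeping, compute
Gd³⁺ enhancement profiles, and refit the dose-efficiency model. Tables are
written under `results/`.

## Command line

```sh
radioswitch defaults                 # print the default run config (YAML)
radioswitch simulate --seed 5 --outdir out/   # synthetic corpus + provenance
radioswitch fit out/coumarin.csv --estimator g_ho
radioswitch convert 81               # → 8.39506 µmol/J
radioswitch report out/*.result.json
```

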