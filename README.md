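# mitoflux

Mitochondrial flux analysis for skeletal muscle from two complementary
measurements:

* **Unidirectional ATP synthesis rate** by in-vivo ³¹P NMR saturation
  transfer: with γ-ATP saturated, the Pi magnetization settles at
  M/M₀ = 1/(1 + k_f·T₁(Pi)) and relaxes with 1/T₁app = 1/T₁(Pi) + k_f,
  so k_f = (ΔM/M₀)/T₁app and the flux is (dATP/dt)synth = k_f·[Pi].
* **TCA cycle flux** by dynamic ¹³C metabolic flux analysis: during a
  [2-¹³C]acetate infusion the glutamate M+1 and M+2 mass-isotopomer
  timecourses (GC/MS) are fitted with a one-compartment metabolic
  network model written in fragmented-mass-isotopomer (bonded-cumomer)
  form, [M]·dμ(i)/dt = Σⱼ Fⱼσⱼ(i) − (Σⱼ Fⱼ)·μ(i), with two free fluxes:
  the cycle flux F_TCA and the α-ketoglutarate ↔ glutamate exchange F_X.

The per-animal ratio of the two fluxes is the **mitochondrial coupling
index**, a proxy for oxidative-phosphorylation efficiency; cohort tools
summarize both groups (control vs tumor-bearing), compute percent
changes, and test differences (Mann-Whitney U, one-tailed Welch t).

The package is aimed at researchers quantifying muscle bioenergetics in
cachexia and related wasting models. Since raw data for this design are
rarely shared, a synthetic-data generator with known ground truth is a
first-class component: every estimator is validated end to end against
the truths it was generated from, and the dynamic model is verified
against a brute-force positional-isotopomer simulator.

## Worked example

Generate one synthetic saturation-transfer acquisition at the default
control-group physiology (k_f = 0.04 s⁻¹, T₁(Pi) = 2 s, [Pi] = 2.1
μmol/g, so a true flux of 0.084 μmol/g/s) with instrument noise, and
analyze it:

```python
from mitoflux import analyze_animal_st
from mitoflux.synthetic_data import (
    AcquisitionParams, TruthRecord, generate_saturation_transfer_dataset,
)

truth = TruthRecord()
ds = generate_saturation_transfer_dataset(
    truth, AcquisitionParams(noise_sd=0.01, seed=7)
)
res = analyze_animal_st(ds)
print(f"dM/M0    = {res.dM_frac:.4f}")
print(f"T1app    = {res.T1app:.3f} s")
print(f"kf       = {res.kf:.4f} 1/s")
print(f"[Pi]     = {res.Pi_conc:.3f} umol/g")
print(f"ATP flux = {res.atp_flux:.4f} umol/g/s")
```

prints

```
dM/M0    = 0.0731
T1app    = 1.845 s
kf       = 0.0396 1/s
[Pi]     = 2.100 umol/g
ATP flux = 0.0832 umol/g/s
```

The fractional saturation transfer (7.3%) over an apparent T₁ of 1.85 s
gives k_f ≈ 0.0396 s⁻¹; multiplied by the Pi concentration scaled from
the Pi/γ-ATP peak areas (2.10 μmol/g) this recovers the generating flux
0.084 μmol/g/s to within the 1% instrument noise.

The same round trip for the ¹³C arm:

```python
from mitoflux import (
    FitConfig, assemble_mass_isotopomer_odes, build_default_network,
    fit_fluxes, observations_from_timecourse,
)
from mitoflux.synthetic_data import AcetateInput, generate_labeling_dataset

network = build_default_network()
system = assemble_mass_isotopomer_odes(network)   # 164 equations
acetate = AcetateInput()                          # [2-13C]acetate infusion
tc = generate_labeling_dataset(
    network, TruthRecord(F_TCA_true=0.018, F_X_true=0.06), acetate,
    noise_sd=0.02, seed=0,
)
obs = observations_from_timecourse(tc, sd=0.02)   # glutamate M+1, M+2
est = fit_fluxes(obs, system, FitConfig(), input_fn=acetate.as_function())
print(f"F_TCA = {est.F_TCA:.4f} umol/g/s, F_X = {est.F_X:.4f} umol/g/s")
```

recovers F_TCA within the Monte Carlo uncertainty of the generating
value 0.018 μmol/g/s (exactly, at zero noise).

A command-line interface wraps the same pipeline:
`mitoflux simulate-cohort`, `mitoflux fit-st`, `mitoflux fit-flux`,
`mitoflux cohort` (see `mitoflux --help`).

## Layout

| module | role |
| --- | --- |
| `synthetic_data` | ground-truth generators for both modalities and cohorts |
| `nmr_processing` | FID → spectrum → baseline → pseudo-Voigt peak areas |
| `saturation_transfer` | inversion recovery, k_f, [Pi], ATP synthesis flux |
| `isotopomer_model` | metabolic network, fragmented-isotopomer ODEs, positional oracle |
| `flux_fitting` | weighted least-squares two-flux fit, goodness of fit, Monte Carlo errors |
| `cohort_stats` | coupling index, group table, rank/t tests |

`docs/methods.md` documents the models, defaults and design decisions in
detail; the default metabolic network ships as an editable YAML file in
`src/mitoflux/data/`.
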