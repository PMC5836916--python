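# bloodwalk

Monte-Carlo simulation and measurement analysis of the apparent diffusion
coefficient (ADC) of human blood, for intravoxel-incoherent-motion (IVIM)
diffusion MRI.

## Why

IVIM separates perfusion from tissue diffusion by modeling blood flow with a
pseudo-diffusion coefficient D*; with flow-compensated (FC) gradients the
blood *self*-diffusion constant D_b stops being negligible and must be known
accurately.  Blood is a two-compartment medium — plasma and red blood cells
(RBCs) exchanging water across a permeable membrane — so its ADC depends on
hematocrit (HCT), diffusion time T, and the gradient profile (monopolar, MP,
vs flow-compensated, FC).  `bloodwalk` is for physicists and sequence
developers who need to simulate that dependence, analyze phantom/blood
measurements, or pick a D_b for IVIM modeling from a routine blood count.

## The model in brief

* **Substrate**: an oblate-cylinder RBC (8.00 × 1.75 µm, scaled to the MCV)
  centered in a periodic cuboid sized so the RBC volume fraction equals HCT,
  with equal plasma gap g on all axes.  Defaults: D_p = 2.75, D_e = 1.00
  µm²/ms; c_p = 0.95, c_e = 0.70; τ_e = 12 ms, giving κ_e = (V/S)/τ_e.
* **Walk**: fixed-length isotropic steps (plasma step = 1 % of g by default,
  dt = ds_p²/6D_p); membrane crossings transmit with P = 2 d_s κ_i/D_i (d_s
  the pre-step membrane distance) or reflect specularly — a scheme whose
  transmitted flux is exactly κ·c.
* **Encoding**: spin-echo effective waveforms; MP switch times
  t_k = TE/2 + (k−1)T/2, FC t_k = TE/2 + (T/4)·sgn(k−2)·(√2)^{|k−2|};
  b = a·γ²g²T³ with a = 1/12 (MP), √2/8 − 1/6 (FC).  Phase per particle:
  φ = φ′√b = γ g Σ_k Δt_k x_cm,k·n (−1)^k from interval trajectory centers
  of mass.
* **Estimators**: ADC_b = −(1/b) ln|⟨e^{iφ}⟩|, ADC_0 = ⟨φ′²⟩/2,
  K_app = ⟨φ′⁴⟩/⟨φ′²⟩² − 3, with bootstrap errors.
* **Measurement side**: sum-of-squares noise-floor correction
  S_c = √(S_m² − 6σ²), the √60·σ (SNR < √10) exclusion rule, three-b-value
  ADC fits, mono-exponential T2 fits, Pearson/critical-r gated regressions
  against blood counts, MP-vs-FC paired t-test, and the blood-count → D_b
  calibration (e.g. FC: 1.545 + (0.42 − HCT)·2.169 µm²/ms).

See `docs/methods.md` for assumptions, parameter meanings and limitations.

## Worked example

```python
from bloodwalk import (CompartmentParams, WalkConfig, adc_from_phases,
                       build_unit_cell, isotropic_directions, phases,
                       simulate, switch_times)

cell = build_unit_cell(hct=0.43, mcv=87.7)      # gap = 0.8566 um
params = CompartmentParams().for_cell(cell)     # f = 0.357, kappa_e = 0.051
profiles = (switch_times("MP", 40.0, 120.0), switch_times("FC", 70.0, 120.0))
record = simulate(cell, params, WalkConfig(
    n_particles=2500, TE=120.0, profiles=profiles, step_fraction=0.05, seed=1))
dirs = isotropic_directions(1000, seed=8)
for prof in profiles:
    s = adc_from_phases(phases(record, prof, dirs, b_s_mm2=400.0), seed=5)
    print(prof.kind, round(s.adc_b, 3), round(s.k_app, 3))
```

prints (seed 1):

```
MP 1.431 0.695
FC 1.439 0.466
```

i.e. at HCT 43 % the two-point ADC at b = 400 s/mm² is ≈1.43–1.44 µm²/ms
(±0.03 Monte-Carlo error at this particle count) with clearly positive
apparent kurtosis — blood diffusion is visibly non-Gaussian.  Averaged over
seeds and diffusion times FC sits above MP (the kurtosis penalty is larger
for MP), which is the profile ordering the measurement side calibrates.  The `examples/` scripts walk through the
unit cell, the waveforms, the free-diffusion calibration check, a hematocrit
sweep and the measurement pipeline; a CLI (`bloodwalk waveform|simulate|
sweep|analyze|fixtures`) wraps the same functions for shell use.

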