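# Methods

## The physical problem

Blood is a two-compartment medium for water: plasma and red blood cells
(RBCs), exchanging water across the RBC membrane.  Its apparent diffusion
coefficient (ADC) — the quantity that enters intravoxel-incoherent-motion
(IVIM) modeling as the blood self-diffusion constant D_b — therefore depends
on hematocrit, on the diffusion time of the encoding waveform, and on whether
the gradient profile is monopolar (MP) or flow-compensated (FC).  `bloodwalk`
simulates this system with a Monte-Carlo random walk and provides the
measurement-side estimators used on real ROI signal tables.

## Substrate model

The RBC is an oblate cylinder with the reference dimensions 8.00 µm diameter
× 1.75 µm height (surface-to-volume ratio 2/h + 2/r ≈ 1.64 µm⁻¹), scaled
isotropically so its volume equals the mean corpuscular volume (MCV, fL).  It
sits centered in a periodic cuboid unit cell.  The text this model derives
from specifies only "cuboid"; we close that freedom with the **equal-gap
construction**: the cuboid edges are d+g and h+g with one gap g solving
(d+g)²(h+g) = MCV/HCT, so the plasma gap between periodic RBC images is the
same along all three axes and "the shortest dimension" is unambiguous.  At
HCT 0.43 and MCV 87.7 fL this yields g = 0.8566 µm, whose 1 % step is the
8.56 nm reference step size.  The construction is feasible only for
HCT < π/4 ≈ 0.785 (the zero-gap box already has volume fraction π/4); beyond
that `build_unit_cell` raises an infeasible-geometry error.  Physiological
hematocrits are far below this limit.

Compartment parameters (defaults, overridable): plasma diffusivity
D_p = 2.75 µm²/ms (37 °C) and erythrocyte-interior D_e = 1.00 µm²/ms;
free-water concentrations c_p = 0.95, c_e = 0.70; intracellular pre-exchange
lifetime τ_e = 12 ms.  Derived quantities: intracellular water fraction
f = c_e·HCT/[c_e·HCT + c_p·(1−HCT)]; membrane permeability
κ_e = (V/S)/τ_e ≈ 0.051 µm/ms, with κ_p = κ_e·c_e/c_p so that the
compartment concentrations are stationary.  Internal units are µm and ms
throughout; b-values cross the interface in clinical s/mm² (1 s/mm² = 10⁻³
ms/µm²).

## Random walk

Particles take fixed-length steps in uniformly random directions.  The
plasma step is a configurable fraction of the gap (default 1 %); the shared
time step is dt = ds_p²/(6 D_p) and the intracellular step ds_e = √(6 D_e dt),
so both compartments run on one clock.  Initial positions are
water-concentration weighted: intracellular with probability f, uniform
within the chosen compartment.

**Membrane interaction.**  When a proposed step segment crosses the
membrane, the particle is transmitted with probability P = 2·d_s·κ_i/D_i,
where d_s is the perpendicular distance from the *pre-step position* to the
membrane and (κ_i, D_i) belong to the compartment being left; on failure it
is specularly reflected at the crossing point with the residual path length
preserved (on transmission the residual path is rescaled to the destination
step length).  The distance-based form is not cosmetic: for isotropic
fixed-length steps, a crossing attempt from perpendicular distance x occurs
with probability (1−x/ds)/2, so the transmitted flux is
∫₀^ds (1−x/ds)/2 · (2xκ/D) c dx/dt = κ·c exactly — the scheme reproduces the
nominal permeability with no step-size-dependent correction factor.
(Evaluating P with d_s fixed to the step length instead transmits exactly 3×
the intended flux; we measured a mean intracellular lifetime of ≈4 ms
instead of τ_e = 12 ms under that variant.)  With the distance-based scheme
the measured mean first-exit time of intracellularly started particles is
12.9 ms at a 5 % step, and the long-run intracellular occupancy matches f
within Monte-Carlo error (detailed balance).

Rare corner case: a reflected path can slip through the rim where the
lateral wall meets a cap; such steps are rejected (the particle stays put),
which keeps impermeable membranes exactly impermeable.

**Recording.**  Under a piecewise-constant effective gradient the accrued
phase depends on the trajectory only through the per-interval time-averaged
position x_cm,k.  The walker therefore records running sums of the unwrapped
position, sampled at the union of all requested profiles' interval-boundary
step indices (boundaries snapped to the nearest step edge, O(dt) error); one
trajectory set serves every (profile, T) combination of a sweep.  Positions
are wrapped into the primary cell only for membership tests, which realizes
the periodic lattice of RBCs.

**Randomness and determinism.**  The kernel uses an inlined xoshiro256++
generator seeded via splitmix64 from the run seed, with Marsaglia polar
sampling for directions; identical (cell, params, config) reproduce the walk
record bit for bit.  This in-kernel generator keeps the per-step cost low
enough (≈40 ns/step single-threaded) that the desk-scale sweep below runs in
minutes.

## Phase encoding and estimators

Effective waveforms (sign flipped after the spin-echo refocusing pulse at
TE/2):

* MP, K = 2 intervals: switch times t_k = TE/2 + (k−1)·T/2;
* FC, K = 4: t_k = TE/2 + (T/4)·sgn(k−2)·(√2)^{|k−2|}, giving interval
  durations (T(2−√2)/4, √2T/4, √2T/4, T(2−√2)/4).

Interval polarity is (−1)^k.  Both waveforms null the zeroth moment; FC also
nulls the first moment (no phase from constant velocity).  The b-value obeys
b = a·γ²g²T³ with a = 1/12 for MP and a = √2/8 − 1/6 ≈ 0.010110 for FC; the
FC coefficient appears in print with a typographically mangled radical
("2/8−1/6"), and we restored √2/8 − 1/6, which an independent piecewise
quadrature of γ²∫q(t)² dt confirms to 10⁻⁹ together with exact M0/M1
nulling.  `b_value_numeric` integrates the piecewise-linear q(t) in closed
form per segment; `amplitude_for_b` inverts it (g ∝ √b).

Phases: φ = φ′√b = γ g·Σ_k Δt_k (x_cm,k·n)(−1)^k along each unit direction
n.  Directions are seeded uniform-random unit vectors shared by all
particles (a variance-reduction device; the reference count is 10⁴, the
sweep default 10³).  Estimators:

* ADC_b = −(1/b)·ln|⟨e^{iφ}⟩|, the complex signal averaged jointly over
  particles and directions (the per-direction-then-magnitude alternative is
  a documented variant we did not adopt);
* ADC_0 = ⟨φ′²⟩/2 (Gaussian-phase small-b limit; a second-moment estimator,
  not a multi-b fit);
* K_app = ⟨φ′⁴⟩/⟨φ′²⟩² − 3, linked by
  ADC_b = ADC_0 − (b/6)·ADC_0²·K_app + O(b²).

`kurtosis_expansion_check` returns the residual of that expansion together
with the next cumulant term |κ₆|·b²/720 estimated from the same ensemble —
note that a *two-component* Gaussian scale mixture has identically zero κ₆,
so property tests of the O(b²) behavior use a three-component mixture.

Standard errors come from a 200-resample bootstrap over particles only
(directions are not independent samples).

## Desk-scale sweep

The reference sweep runs HCT ∈ {0.36, 0.43, 0.47} (the blood-sample range),
MCV 87.7 fL, TE = 120 ms, b = 400 s/mm², MP at T ∈ {40, 100} ms and FC at
T ∈ {70, 100} ms — the extremes of the protocol's diffusion-time ranges —
with 2500 particles and a step of 5 % of the gap.  These sizes are the
package's desk-scale defaults (about 5–6 minutes on one CPU); the
full-fidelity configuration (300 000 particles, 1 % step, multi-hour
runtime) is the same code with `n_particles=300000, step_fraction=0.01`
(see `examples/long_run_config.json`).  At the 5 % step the coarse
discretization under-resolves the membrane curvature and biases ADC upward
by roughly +0.1 µm²/ms at the lowest hematocrit (measured against a 2.5 %
step), which is why the sweep acceptance band is applied with a
3-Monte-Carlo-SE tolerance.  The sweep reproduces the published qualitative
structure: ADC₄₀₀ within 1.33–1.58 µm²/ms (within MC error), decreasing
with HCT; K_app > 0 everywhere and decreasing with T; FC ADC₀ starting
above the MP level at T = 70 ms and decreasing toward it at T = 100 ms.

## Measurement-side analysis

* **Noise floor**: S_c = √(max(0, S_m² − 6σ²)) for the six-channel
  sum-of-squares reconstruction in which the lower coil elements contribute
  half the signal of the upper ones; the factor is configurable
  (`n_factor`).  Negative corrected squares are floored to zero and flagged
  rather than raised.
* **Exclusion**: an ADC measurement is dropped when its direction-averaged
  S_c at b = 400 s/mm² is below √(10·n_factor)·σ = √60·σ, i.e. SNR < √10 ≈
  3.2, to avoid noise-floor underestimation of the ADC.
* **ADC fit**: unweighted OLS of ln S_c on b over the three b-values
  (0, 50, 400 s/mm²), directions and b = 0 repeats averaged first.  With
  three points and typical SNR, weighted and unweighted OLS differ
  negligibly, so the simpler estimator is used; the 95 % CI comes from the
  residual-based slope standard error.
* **T2 fit**: log-linear LS of b = 0 signal vs TE; T2 = −1/slope, flagged
  and infinite when the fit does not decay.
* **Correlation/calibration**: Pearson r with two-sided p from the exact t
  transform (df = n−2); regression coefficients are reported only when
  |r| > r_crit = t_{α/2,df}/√(df+t²) (0.666 at df = 7).  No
  multiple-testing correction is applied across the three covariates — raw
  p-values are reported, as is conventional for this analysis.  The sample
  count n is exposed rather than hard-coded, since published critical
  values may reflect excluded samples.
* **MP vs FC**: paired two-sided t-test on per-sample mean ADCs; degenerate
  all-equal pairs return NaN with a flag rather than failing.
* **D_b calibration** (`predict_Db`): with HCT —
  MP: 1.307 + (0.42−HCT)·2.846, FC: 1.545 + (0.42−HCT)·2.169; with HGB —
  MP: 1.312 + (14.5−HGB)·0.087, FC: 1.551 + (14.5−HGB)·0.053; with no
  covariate the recommended constants 1.30 ± 0.18 (MP) and 1.54 ± 0.12
  (FC) µm²/ms, the spread attached as metadata.

## Synthetic fixtures

No raw acquisition exists, so `fixtures.generate_signals` emulates the
acquisition: 3 b-values × 6 directions × multi-TE, with complex Gaussian
noise realized per coil element (never added to magnitudes) and combined by
sum of squares over 12 elements (6 channels × gains 1.0/0.5).  The reported
σ is the RMS background magnitude of one accessible channel (σ = 2σ_element),
which makes the noise floor exactly 6σ² — the quantity the correction
removes.  Ground truth is embedded in the table metadata and identical
seeds reproduce identical tables.  The fixtures emulate the noise topology
and protocol grid of a real measurement but not EPI artifacts, motion,
sedimentation drift or T2-dependent SNR structure across samples; passing
recovery tests therefore validates the estimator chain, not robustness to
those real-world effects.

## Known limitations

* Cylindrical (not biconcave) RBCs, one RBC per cell, no orientation
  dispersion — the same simplifications the substrate model is defined
  with; they raise S/V relative to real cells by design choice.
* No relaxation weighting or susceptibility-induced local gradients inside
  the walk, so the simulated ADC carries no TE dependence.
* The coarse desk-scale step (5 % of the gap) biases ADC slightly upward;
  use the 1 % step for production accuracy.
* The two-point ADC_b estimator fails (by design, with an error) when the
  encoded signal magnitude vanishes.
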