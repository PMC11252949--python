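# Methods

## Signal models

All models return normalized attenuations S(b)/S(0) ∈ (0, 1] for a
single-diffusion-time experiment. Units are fixed package-wide — b in
ms/µm², diffusivities in µm²/ms, lengths in µm, times in ms — so b·D is
dimensionless.

**Sticks.** A stick is a zero-radius segment: free 1-D diffusion with
diffusivity D along its axis, no displacement across it. At angle θ to the
gradient the signal is exp(−b·D·cos²θ); the isotropic orientation (powder)
average has the exact closed form

    S_stick(b, D) = √(π/(4bD)) · erf(√(bD)),

evaluated by a Taylor series for bD < 1e-6. The numerical orientation
integral ∫₀¹ exp(−bD x²) dx is retained as the test oracle.

**Spheres (GPD).** Diffusion restricted in an impermeable sphere of radius
r is evaluated under the Gaussian phase distribution (GPD) approximation
with the Bessel-root series (Murday–Cotts form): the eigenvalues x_m are the
roots of 2x·cos x + (x² − 2)·sin x = 0 (equivalently j₁'(x) = 0,
x₁ ≈ 2.0816). Because the GPD log-signal is proportional to the squared
gradient amplitude, the signal is exp(−b·A(r, D, timing)) with an apparent
diffusivity A independent of b. Two timing branches exist:

- *narrow pulse* (default): A = (2/t_d) Σ_m (1 − e^{−x_m² D t_d / r²})
  · r² / (x_m²(x_m² − 2)). The protocol prints only the diffusion time
  t_d = 53.2 ms, so the narrow-pulse branch is the only one fully
  determined by printed numbers; it is the package default.
- *finite pulse*: the full Murday–Cotts bracket in δ and Δ, with
  t_d = Δ − δ/3 enforced. Exposed for users who know their pulse timing.

**Cylinders.** The robustness variant: Gaussian diffusion with diffusivity
D along the axis and GPD-restricted diffusion across a disk of radius r
(eigenvalues J₁'(x) = 0, denominator x² − 1). Since both components have
log-signals linear in their b-share, the powder average reduces to a
stick-like closed form with apparent parallel/radial diffusivities; it
converges to the stick model as r → 0.

**Series truncation.** The root series is truncated at 20 roots by default.
In the restricted regime the terms decay like x_m⁻⁶ and the truncation
error is far below 1e-6 relative. In the quasi-free corner (D t_d/r² ≪ 1,
visited by the optimizer) the terms decay only like x_m⁻², so the
evaluation escalates the root count (20 → 128 → 1024) and, on the
narrow-pulse branch, adds an analytic integral tail (midpoint rule over the
asymptotically π-spaced roots, with erfc closed forms) so that the residual
relative truncation error stays below the documented 1e-6 tolerance; a
`NumericalError` with diagnostics is raised if the tolerance is unreachable
(possible only on the finite-pulse branch in extreme corners).

**Accuracy of the GPD approximation.** The GPD closed form is an
approximation, not an expansion of the exact signal. At the strongest
weighting used here (sphere r = 3.1 µm, b = 20 ms/µm², t_d = 53.2 ms,
qr ≈ 1.9) it overestimates the exact narrow-pulse signal
((3 j₁(qr)/qr)² in the long-time limit) by ≈ 0.02 in signal units. The
Monte-Carlo comparisons therefore use an absolute tolerance of 0.02 plus
three Monte-Carlo standard errors; agreement to arbitrary precision is not
expected and would not indicate correctness.

## Monte-Carlo oracle

`mc_random_walk_signal` simulates fixed-length random walkers (step
duration t_d/n_steps, default n_steps = 2000; step length √(6D·dt) in 3-D)
with specular reflection at sphere/disk boundaries, under narrow-pulse
encoding: phase φ = q·(x(t_d) − x(0)) with q = √(b/t_d), signal ⟨cos φ⟩
with its standard error. Sticks and cylinders are powder-averaged by
drawing an isotropic orientation per walker. All b-values are evaluated on
one trajectory ensemble, so estimates across b share their sampling noise.
A warning (not an error) is emitted when the step length exceeds r/10; in
the strongly restricted regime the resulting bias is small because the
phase variance itself is small.

## Fitting

All fits are bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) restarted from a deterministic grid of interior
quantiles of the bounds (default 3 per parameter, i.e. 3×3×3 for the
microstructure fit) keeping the best converged start; a `FitFailureError`
with per-start diagnostics is raised if none converges, and parameters
landing on a bound are flagged. Fits are performed on normalized
attenuations: both data and model are divided by their value at the lowest
b, making the fits insensitive to overall scaling.

- Microstructure: (D_intra, r_soma, f_sphere) within [0.01, 1.5] µm²/ms ×
  [0.1, 15] µm × [0, 1]. f_sphere is free by default; it can be fixed at
  any value (the stick/sphere-ratio robustness mode), and a cylinders-only
  geometry is available. At least 4 distinct b-values spanning a decade are
  required.
- Two-pool: (f_extra, D_extra) within [0, 1] × [0.2, 3] µm²/ms. The
  D_extra bounds bracket free-water-scale diffusivities; no reference value
  exists for brain extracellular lactate, so this is a documented
  assumption. f_extra = 0 at the bound is reported without a warning (a
  legitimate "no extracellular pool" answer).
- Biexponential comparator: f·e^{−b·D_fast} + (1−f)·e^{−b·D_slow} with
  D_fast ≥ D_slow enforced by relabeling; the effectively monoexponential
  case is flagged as degenerate. Note the two-pool model is *not* nested in
  the biexponential (S_intra_Lac is not an exponential); the true nesting
  relation, asserted in tests, is biexponential ≤ best monoexponential.

**Weights.** When a curve carries per-point SDs the residuals are weighted
1/sd, with sd floored at its median positive value: empirical SDs estimated
from as few as two curves are themselves noisy, and the floor prevents a
point with an accidentally tiny SD from dominating the fit. Rician bias
correction is not applied (off by default; magnitude data at these SNRs are
treated as Gaussian).

**Confidence intervals** are residual-bootstrap half-widths (1.96 × SD of
refitted parameters over resampled-residual surrogates; 200 draws
recommended, seeded). They are off by default (`bootstrap_draws = 0`)
because the repeated-cohort studies would otherwise refit thousands of
surrogates; any fit can switch them on.

**Study configuration.** The repeated-cohort studies (power, null
calibration) use a single interior start and optimizer tolerances of 1e-10
(`studies.STUDY_FIT`); this was verified to give results identical to the
default multi-start on these well-conditioned synthetic fits, at a fraction
of the cost.

## Lactate scaling

λ is the ratio of lactate's free diffusivity to that of the larger
intracellular metabolites; default 1.3 ("~30% larger"), configurable in
[1, 2] and recorded in output metadata. Step (ii) evaluates the fitted
intracellular geometry at D = λ·D_intra.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
spectra: per animal it draws (D_intra, r_soma, f_extra) with Gaussian
jitter, evaluates the forward models (NAA and Ins from the sticks-and-
spheres geometry; lactate from the two-pool mixture with the λ-scaled
intracellular curve), applies multiplicative Gaussian noise independently
per (metabolite, b) point, and renormalizes at the lowest b. Defaults are
the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_per_group | 5 | five animals per group in the reference design |
| b-grid | 10 points, 0.02–20 ms/µm² | the printed range; the shell count/spacing is a package choice (roughly geometric) |
| t_d | 53.2 ms | printed diffusion time |
| micro truth | D_intra 0.40, r_soma 3.1, f_sphere 0.5 | reported microstructure; the stick/sphere ratio is not printed, 0.5 chosen with robustness checked downstream |
| f_extra truth | 0.36 control / 0.23 APP/PS1 | reported group fractions |
| D_extra truth | 1.3 µm²/ms | no printed value; a fast, free-water-scale diffusivity inside the fit bounds |
| λ | 1.3 | "~30% larger" free diffusivity |
| noise_sigma | 0.02 | relative SD per measurement; makes the 5-vs-5 group separation comfortably but not trivially detectable |
| between_animal_cv | 0.11 | one CV for (D_intra, r_soma, f_extra); chosen so the f_extra jitter SD matches the reported ±0.04 spread |

What the generator does **not** emulate: spectral quantification noise
structure (Rician magnitude floors, baseline/macromolecule contamination),
b-dependent SNR, animal-level correlations between metabolites' noise, or
any microstructure difference between groups. Passing tests therefore show
that the pipeline recovers its own generative model under realistic noise —
a necessary self-consistency — not that the biological assumptions hold in
vivo.

## Group statistics

Two-sided unpaired Student's t-tests (equal-variance by default, Welch
optional) computed from first principles — means, pooled variance, t, p via
the t CDF — and cross-checked in tests against an independent
implementation and an exact permutation enumeration. Per-b-value tests on
normalized attenuations are reported without multiple-testing correction,
matching how attenuation plots are conventionally annotated. Degenerate
zero-variance comparisons return p → 0 (means differ; warned) or p = 1
(identical groups). `percent_decrease(ref, test) = 100·(ref − test)/ref`;
increases come out negative.

## Sensitivity audit

On noiseless control-group curves, the pipeline is refitted with the
stick/sphere ratio imposed at 0.3/0.5/0.7, with the cylinders-only
geometry, and with λ = 1. Under the defaults the measured f_extra shifts
are ≈ 0.013–0.015 (imposed ratio), ≈ 0.030 (cylinders only) and ≈ 0.028
(λ = 1): ignoring lactate's higher diffusivity costs more than
misspecifying the stick/sphere ratio, but about the same as swapping the
whole geometry family for cylinders (which describes the intracellular
curve to ≈ 0.007 max residual, i.e. well within the 2% noise). At these
desk-scale conditions the λ correction changes the predicted intracellular
lactate curve by ≲ 0.04 in signal units at high b, which bounds how large
the λ shift can be; conditions with deeper attenuation or denser
high-b sampling would separate the effects further.

## Known limitations

- Narrow-pulse timing is assumed unless δ/Δ are supplied; the GPD closed
  forms carry an intrinsic ≈ 2-percentage-point bias at the strongest
  weighting (see above).
- No compartment exchange (no Kärger-type terms), single diffusion time,
  isotropic orientation distributions only, impermeable boundaries.
- The two-pool decomposition inherits whatever bias the microstructure
  step leaves in S_intra_Lac; per-animal microstructure parameters are
  individually poorly determined at 2% noise (a known sticks-vs-spheres
  trade-off ridge) even though the downstream f_extra is robust to this.
- The interchange schema expects already-quantified attenuation tables;
  spectral fitting and macromolecule handling are out of scope.
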