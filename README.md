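# lacdiff

Noninvasive splitting of brain lactate into intracellular and extracellular
pools from diffusion-weighted MR spectroscopy (dMRS).

Most MRS-visible metabolites (NAA, myo-inositol, creatine, choline) are
almost exclusively intracellular: their diffusion-weighted signal attenuation
S(b) reflects restricted motion inside cells and retains substantial signal
at high diffusion weighting b. Extracellular diffusion, in contrast, is fast
and approximately monoexponential, so an extracellular pool vanishes quickly
as b grows. Lactate lives in both spaces — which makes its attenuation curve
a probe of its intracellular–extracellular distribution, a quantity of
direct interest for the astrocyte-to-neuron lactate shuttle and for
Alzheimer's-disease mouse models (APP/PS1), where the extracellular lactate
fraction drops.

`lacdiff` implements the three-step biophysical pipeline that extracts that
fraction, plus everything needed to validate it without access to in-vivo
data:

1. **Microstructure** — pool NAA and Ins attenuations and fit a
   sticks-and-spheres model (powder-averaged zero-radius neurites + GPD
   spheres) for the intracellular diffusivity `D_intra`, soma radius
   `r_soma` and sphere fraction `f_sphere`.
2. **Intracellular lactate prediction** — evaluate the same geometry with
   diffusivity `λ·D_intra` (λ ≈ 1.3: lactate is smaller and diffuses ~30%
   faster than the larger intracellular metabolites), giving
   `S_intra_Lac(b)`.
3. **Two-pool fit** — fit the measured lactate attenuation with

   ```
   S_Lac(b) = f_extra · exp(−b·D_extra) + (1 − f_extra) · S_intra_Lac(b)
   ```

   for the extracellular fraction `f_extra` and diffusivity `D_extra`,
   assuming Gaussian extracellular diffusion and negligible exchange over
   the diffusion time.

The package also provides a Monte-Carlo random-walk oracle validating the
closed forms, a cylinders-only robustness variant, a phenomenological
biexponential comparator, a synthetic two-group cohort generator (5 control
vs 5 APP/PS1 animals, b = 0.02–20 ms/µm² at t_d = 53.2 ms, multiplicative
noise and between-animal jitter), unpaired t-test group statistics, and
CSV/TSV attenuation-table IO. Units throughout: b in ms/µm², D in µm²/ms,
r in µm, times in ms.

## Worked example

```python
import lacdiff as ld
from lacdiff import studies

cfg = ld.SyntheticCohortConfig(seed=5)          # 5 vs 5 animals, 2% noise
curves = ld.generate_cohort(cfg)                # NAA, Ins, Lac per animal
frame = ld.fit_cohort(curves, cfg.scheme, studies.STUDY_FIT)

for g, sub in frame.groupby("group"):
    print(g, sub.f_extra.mean().round(3), "+/-", sub.f_extra.std().round(3))
a = frame.loc[frame.group == "control", "f_extra"]
b = frame.loc[frame.group == "APP/PS1", "f_extra"]
res = ld.compare_groups(a, b, quantity="f_extra")
print("t =", round(res.t_stat, 2), "p =", round(res.p_value, 4))
print("decrease:", round(ld.percent_decrease(a.mean(), b.mean()), 1), "%")
```

prints

```
APP/PS1 0.224 +/- 0.055
control 0.354 +/- 0.008
t = 5.23 p = 0.0008
decrease: 36.8 %
```

The per-animal pipeline recovers the generating extracellular fractions
(truth 0.36 vs 0.23) and detects the ~one-third group decrease at n = 5 per
group. The `examples/` directory contains one short script per capability:
forward models and the random-walk oracle, the microstructure fit with
bootstrap confidence intervals, the two-pool and biexponential lactate
fits, group statistics, and the full table-to-JSON pipeline.

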