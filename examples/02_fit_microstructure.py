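"""Step (i): fit intracellular microstructure from NAA + Ins diffusion.

Generates one noisy synthetic cohort, pools the NAA and Ins attenuations
across animals, fits the sticks-and-spheres model, and prints the
recovered geometry with residual-bootstrap confidence half-widths.
"""

import lacdiff as ld
from lacdiff.fitting import FitOptions

cfg = ld.SyntheticCohortConfig(seed=42)
curves = ld.generate_cohort(cfg)

intracellular = [c for c in curves if c.metabolite in ("NAA", "Ins")]
pooled = ld.pool_intracellular(intracellular)
print(f"pooled {len(intracellular)} curves (NAA+Ins, both groups), "
      f"{pooled.n_points} b-values")

micro = ld.fit_microstructure(
    pooled, cfg.scheme, FitOptions(bootstrap_draws=200, seed=0))
lo = micro.ci or (float("nan"),) * 3
print(f"D_intra  = {micro.D_intra:.3f} +/- {lo[0]:.3f} um^2/ms  (truth 0.40)")
print(f"r_soma   = {micro.r_soma:.2f} +/- {lo[1]:.2f} um        (truth 3.1)")
print(f"f_sphere = {micro.f_sphere:.2f} +/- {lo[2]:.2f}          (truth 0.5)")
# D_intra is the intracellular diffusivity probed by the metabolites,
# r_soma the cell-body radius, f_sphere the soma signal fraction.
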