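"""Group statistics on per-animal extracellular lactate fractions.

Fits the full pipeline per animal on one synthetic cohort and compares
the control and APP/PS1 groups with an unpaired Student's t-test, plus
per-b-value tests on the raw lactate attenuations.
"""

import lacdiff as ld
from lacdiff import studies

cfg = ld.SyntheticCohortConfig(seed=5)
curves = ld.generate_cohort(cfg)
frame = ld.fit_cohort(curves, cfg.scheme, studies.STUDY_FIT)

for g, sub in frame.groupby("group"):
    print(f"{g:8s}: f_extra = {sub.f_extra.mean():.3f} +/- {sub.f_extra.std():.3f} "
          f"(n = {len(sub)})")

a = frame.loc[frame.group == "control", "f_extra"]
b = frame.loc[frame.group == "APP/PS1", "f_extra"]
res = ld.compare_groups(a, b, quantity="f_extra")
print(f"unpaired t-test: t = {res.t_stat:.2f}, p = {res.p_value:.4f}")
print(f"percent decrease of f_extra: {ld.percent_decrease(a.mean(), b.mean()):.1f}%")
# Truth is 36% vs 23% extracellular lactate: a ~one-third decrease,
# detectable at n = 5 per group under 2% measurement noise.

lac_a = [c for c in curves if c.metabolite == "Lac" and c.group == "control"]
lac_b = [c for c in curves if c.metabolite == "Lac" and c.group == "APP/PS1"]
print("\nper-b tests on lactate attenuation (stars mark p < 0.05):")
for t in ld.per_b_group_tests(lac_a, lac_b):
    star = "*" if t.p_value < 0.05 else " "
    print(f"  {t.quantity:12s} p = {t.p_value:.3f} {star}")
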