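"""Cr-51 label survival with elution, and the x2.61 half-life rule.

All red cells share a lifespan L; a cohort labelled at steady state has ages
uniform on [0, L], so the surviving labelled fraction decays linearly while
label elution multiplies it by exp(-lambda_e t).  With L = 120 d and elution
calibrated so the apparent half-life is the normal 23 d, multiplying the
half-life by 2.61 recovers the true mean age L/2 = 60 d.
"""

from rbcage import (
    SurvivalModel,
    apparent_halflife,
    calibrate_elution_rate,
    halflife_to_mrbc,
    survival_fraction,
)

lam = calibrate_elution_rate(target_halflife=23.0, lifespan=120.0)
model = SurvivalModel(lifespan=120.0, elution_rate=lam)
print(f"elution rate for a 23 d apparent half-life at L=120: {lam:.6f} /d")

for t in (0, 23, 60, 120):
    print(f"  survival fraction at t={t:3d} d: {survival_fraction(t, model):.4f}")

hl = apparent_halflife(model)
print(f"apparent half-life: {hl:.3f} d")
print(f"x2.61 rule -> mean age {halflife_to_mrbc(hl):.2f} d (true mean age 60 d)")
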