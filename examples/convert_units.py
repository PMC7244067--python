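"""Convert erythrocyte creatine between the historical and modern units.

Older assays report EC in mg per dL of packed red cells; the calibration
uses umol per gram of hemoglobin.  The divisor is MW x MCHC / 1000 = 4.328
with creatine MW 131.15 g/mol and MCHC 33 g/dL.
"""

from rbcage import ConversionConstants, conversion_divisor, mgdl_to_umol_per_ghb

print(f"divisor (default MCHC 33 g/dL): {conversion_divisor():.5f}")

x = 6.0592  # mg/dL of red cells
print(f"{x} mg/dL RBC = {mgdl_to_umol_per_ghb(x):.3f} umol/g Hb")

# In iron deficiency the MCHC drops; the same mg/dL then represents more
# creatine per gram of hemoglobin:
low_mchc = ConversionConstants(mchc=28.0)
print(f"{x} mg/dL RBC at MCHC 28 = {mgdl_to_umol_per_ghb(x, low_mchc):.3f} umol/g Hb")
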