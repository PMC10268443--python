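"""Close the charge balance of a measured blood gas for unmeasured anions.

A metabolic-acidosis blood gas: pH 7.16 with total CO2 17.6 mmol/L despite
a high strong ion difference of 38.6 mEq/L.  Electroneutrality then forces
a large pool of anions that no analyzer reports — here typically organic
acids from an inborn metabolic defect.
"""

from stewartab import unmeasured_anions

u = unmeasured_anions(
    7.16,               # measured pH
    total_co2=17.6,     # mmol/L
    albumin=16.0,
    phosphate=2.26,     # mmol/L
    sid_app=38.6,       # mEq/L
)
print(f"unmeasured anions [U-] = {u:.1f} mEq/L")
print()
print("Values above ~8 mEq/L flag an anion load beyond what chloride,")
print("lactate and the weak acids explain; this sample's ~14 mEq/L is the")
print("signature of an organic acidosis.")
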