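"""Solve a single plasma sample for its blood gas.

A normal neonatal plasma composition: total CO2 26.4 mmol/L, albumin 25,
phosphate 1.64 mmol/L, apparent strong ion difference 35.9 mEq/L, no
unmeasured anions.  The solver finds the pH at which the plasma's net
charge vanishes, then reads pCO2 and bicarbonate off the equilibrium
speciation at that pH.
"""

from stewartab import PlasmaSample, solve_acid_base

sample = PlasmaSample(
    total_co2=26.4,   # mmol/L
    albumin=25.0,     # g/L scale
    phosphate=1.64,   # mmol/L
    sid_app=35.9,     # mEq/L
    u_minus=0.0,      # mEq/L
)
result = solve_acid_base(sample)

print(f"pH    {result.ph:.2f}")
print(f"pCO2  {result.pco2:.1f} kPa")
print(f"HCO3  {result.hco3:.1f} mmol/L")
print(f"(converged in {result.iterations} iterations, "
      f"|net charge| = {abs(result.speciation.net_charge):.2g} mEq/L)")
print()
print("A mildly alkaline gas: with these (clinically rounded) inputs the")
print("electroneutral pH sits slightly above the measured 7.40 of the")
print("blood sample the inputs were taken from.")
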