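"""Dynamic CO2 accumulation in a perfused compartment.

A 1 L compartment perfused at 0.1 L/min (time constant 10 min) starts in
equilibrium with its inflow at 22 mmol/L total CO2; metabolic production of
0.2 mmol/min then drives the pool toward the steady state
inflow + production/flow = 24 mmol/L.  At every step the equilibrium
acid-base model converts the current pool into a blood gas.
"""

from stewartab import CompartmentState, PlasmaSample, simulate, steady_state_total_co2

template = PlasmaSample(total_co2=22.0, albumin=25.0, phosphate=1.64,
                        sid_app=35.0, u_minus=4.0)
initial = CompartmentState(total_co2=22.0, volume=1.0, inflow_rate=0.1,
                           inflow_total_co2=22.0, co2_production=0.2)

series = simulate(initial, duration=60.0, time_step=0.1,
                  sample_template=template)

print("  t (min)   total CO2   pH     pCO2 (kPa)   HCO3")
for t in (0, 10, 20, 40, 60):
    row = series[series.time_min == t].iloc[0]
    print(f"  {t:5.0f}     {row.total_co2:7.2f}   {row.ph:5.2f}   "
          f"{row.pco2_kpa:7.2f}    {row.hco3:6.2f}")

print()
print(f"analytic steady state: {steady_state_total_co2(22.0, 0.1, 0.2):.1f} mmol/L")
print("The pool rises with a 10-minute time constant; pH falls and pCO2")
print("climbs as the retained CO2 acidifies the plasma (respiratory acidosis).")
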