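# stewartab

Physicochemical (Stewart) acid–base balance for blood plasma: a white-box
simulator that computes pH, pCO₂ and bicarbonate from total CO₂ content and
the plasma's strong-ion/weak-acid makeup. Built for physiological
simulation and education — real-time explanatory models, blood-gas
teaching, and quantitative exploration of metabolic and respiratory
acid–base disturbances in neonatal intensive care ranges.

## The model

In the Stewart approach, pH is not a state of its own: it is determined by
electroneutrality given three independent quantities — the strong ion
difference, the total weak-acid pool, and (here) the total CO₂
concentration. The package solves, over a physiological pH bracket, the
net-charge balance

```
NC(pH) = [H⁺] − [HCO₃⁻] − [A⁻] − [OH⁻] − 2[CO₃²⁻] + SID_app − [U⁻] = 0
```

with the CO₂ species partitioned from the conserved total

```
[CO₂]Σ = [CO₂]dissolved + [HCO₃⁻] + [CO₃²⁻]
```

by mass action (carbonic-acid pK 6.10, bicarbonate pK 10.2, composite water
pK′ 13.6, all at 37 °C, concentrations in mmol/L), the weak-acid charge from
the Figge linearization

```
[A⁻] = [ALB]·(0.123·pH − 0.631) + [PI]·(0.309·pH − 0.469)
```

and the apparent strong ion difference from the measured electrolytes

```
SID_app = [Na⁺] + [K⁺] + 2[Ca²⁺] + 2[Mg²⁺] − [Cl⁻] − [La⁻].
```

The root is found with a hand-implemented Brent method on pH ∈ [6.5, 7.8],
accepting a solution when |NC| ≤ 10⁻⁸ mEq/L; pCO₂ then follows from the
dissolved CO₂ via the solubility coefficient α = 0.23 mmol/(L·kPa). Around
this core the package provides:

- a single-compartment total-CO₂ mass balance (`dynamics`) with quasi-static
  blood-gas readout — the transport side of a circulatory simulator;
- back-calculation of unmeasured anions `[U⁻]` from a measured blood gas
  (`unmeasured_anions`), the charge-balance closure used to parameterize
  individual patients;
- a Bland–Altman verification pipeline (`verification`) comparing model
  predictions against measured blood gases;
- a seeded synthetic generator (`synthetic`) of neonatal-like blood-gas
  records, in a model-consistent dialect (for exact round-trip checks) and
  an analyzer-like dialect (emulating a clinical analyzer's derived
  bicarbonate and rounding);
- a thin CLI (`stewartab solve|uanions|verify|simulate|synth`).

## Worked example

```python
from stewartab import PlasmaSample, solve_acid_base

sample = PlasmaSample(total_co2=26.4, albumin=25.0, phosphate=1.64,
                      sid_app=35.9, u_minus=0.0)
result = solve_acid_base(sample)
print(f"pH {result.ph:.2f}  pCO2 {result.pco2:.1f} kPa  "
      f"HCO3 {result.hco3:.1f} mmol/L")
```

prints

```
pH 7.52  pCO2 4.2 kPa  HCO3 25.4 mmol/L
```

— the electroneutral blood gas of a normal neonatal plasma panel. The
inputs are clinically rounded values; because the net-charge curve is flat
in pH at fixed total CO₂, that rounding shifts the solved pH a tenth or so
above the 7.40 measured in the sample the panel came from, while
bicarbonate is recovered to within 0.3 mmol/L. The same solve from the
shell:

```
$ stewartab solve --tco2 26.4 --alb 25 --pi 1.64 --sid 35.9 --uminus 0.0
pH    7.52
pCO2  4.2 kPa
HCO3  25.4 mmol/L
```

The `examples/` directory holds one short script per capability (single
solve, anion back-calculation, CO₂ wash-in dynamics, agreement analysis);
each prints its numbers with a line on what they mean.

## Documentation

`docs/methods.md` describes the model assumptions, the unit convention of
the equilibrium constants, the solver's numerical choices, what the
synthetic generator does and does not emulate, and known limitations.
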