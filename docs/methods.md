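# Methods

## Model and assumptions

The package implements the physicochemical (Stewart) description of
acid–base state in blood plasma. The independent quantities of one solve
are the total CO₂ concentration `[CO₂]Σ`, the weak-acid pools (albumin
`[ALB]` and inorganic phosphate `[PI]`), the apparent strong ion difference
`SID_app`, and an unmeasured-anion concentration `[U⁻]` treated as a
patient/condition parameter. Everything else — [H⁺], the CO₂ species,
[OH⁻], the weak-acid anion charge — is a dependent equilibrium quantity.
The plasma pH is defined as the root of the net charge

    NC(pH) = [H⁺] − [HCO₃⁻] − [A⁻] − [OH⁻] − 2[CO₃²⁻] + SID_app − [U⁻]

which is strictly decreasing in pH on the physiological bracket (each anion
term grows with pH and [H⁺] shrinks), so the root is unique when it exists.

Scope assumptions: plasma only — no erythrocyte buffering (hemoglobin), no
interstitial or Gibbs–Donnan effects, no activity coefficients, constants
fixed at 37 °C with no temperature correction. The weak-acid charge uses
the Figge linear pH dependence, an empirical fit valid in the physiological
range; it can go negative at extreme low pH and is deliberately not
clamped, because clamping would silently break the charge balance the
solver relies on.

## Unit convention of the equilibrium constants

All concentrations are mmol/L (so `[H⁺] = 1000·10^(−pH)`), charges mEq/L,
pCO₂ kPa. The dissociation constants are stored on the same scale:

| constant | meaning | default | unit |
|---|---|---|---|
| `kc` | carbonic acid | 10^−3.10 | mmol/L |
| `kd` | bicarbonate | 10^−7.20 | mmol/L |
| `kw_prime` | water (composite) | 10^−7.60 | (mmol/L)² |
| `alpha` | CO₂ solubility | 0.23 | mmol/(L·kPa) |

These are the familiar mol/L pK values 6.10, 10.2 and 13.6 rescaled by the
factor of 1000 between mol/L and mmol/L (one factor for `kc` and `kd`, two
minus one for the squared-unit `kw_prime`), so that
`[HCO₃⁻]/[CO₂]di = 10^(pH−6.10)` holds identically — the
Henderson–Hasselbalch identity the test suite uses as the unit-convention
smoke test. Keeping the printed mol/L magnitudes unscaled while expressing
[H⁺] in mmol/L would shift the effective carbonic-acid pK to 9.10 and leave
no electroneutral root anywhere near physiological pH. Albumin deserves a
unit caveat: the Figge coefficients pair with albumin on the g/L scale, and
the package accepts the clinical numeric values (10–30) as given without
rescaling.

The constants are an injectable frozen dataclass
(`DissociationConstants`), so sensitivity studies and the analyzer-dialect
emulation can override any of them; the defaults are bit-stable module
constants.

## Solver

The electroneutral pH is found by an explicitly coded Brent method
(bisection / secant / inverse quadratic interpolation with the classical
acceptance guards) on pH — not [H⁺] — over the bracket [6.5, 7.8]. The
stopping criterion is the charge residual, |NC| ≤ δ with δ = 10⁻⁸ mEq/L,
rather than bracket width, so every accepted root is electroneutral to a
stated physical tolerance. Numerical choices:

- **Final polish.** When the residual tolerance is first met, one extra
  secant step is taken and kept if it reduces |NC|. The step is free (a
  single function evaluation), keeps the residual ≤ δ, and typically leaves
  it near 10⁻¹³, which makes the root-for-root comparison against library
  root finders and the unmeasured-anion round trip exact to well below
  10⁻⁹.
- **Endpoint grace.** If |NC| ≤ δ already at a bracket endpoint, that
  endpoint is returned without iterating (degenerate synthetic cases).
- **Bracket collapse.** If the bracket shrinks to machine precision
  (≈4·ε·|pH|) while |NC| > δ, the best point is returned flagged converged
  only if |NC| ≤ 10⁻⁶ mEq/L, else non-converged; the iteration cap (100)
  raises rather than returning silently.
- **No extrapolation.** Compositions whose net charge does not change sign
  across the bracket raise a bracketing error quoting NC at both endpoints;
  nothing is solved outside [6.5, 7.8].

Converged solves on physiological compositions take 5–7 iterations with
the polish, well under the cap.

`unmeasured_anions` inverts the charge balance at a measured pH. The CO₂
speciation can come from total CO₂ (default — this route exactly inverts
the package's own forward solve, making the verification round trip an
identity) or from measured pCO₂ via the solubility coefficient (what a
clinical analyzer actually measures); exactly one must be supplied.

## Compartment dynamics

The transport model is a single well-mixed compartment's total-CO₂ mass
balance

    d[CO₂]Σ/dt = (f_in·([CO₂]in − [CO₂]Σ) + V_CO₂)/v

with volume `v` (L), inflow `f_in` (L/min) and metabolic production
`V_CO₂` (mmol/min); time is minutes throughout (these units are the
package's documented convention). Additional inflow streams can be summed.
Integration is fixed-step classical 4th-order Runge–Kutta — deterministic
and directly testable against the linear ODE's closed forms (exponential
wash-out with time constant v/f_in; steady state `[CO₂]in + V_CO₂/f_in`);
forward Euler is available for real-time applications that prefer one
function evaluation per step. The acid–base solve is a quasi-static output
map: it is evaluated from the current pool at each reporting step and holds
no state, so readouts never perturb the trajectory.

## Verification pipeline

For each blood-gas record the pipeline computes `SID_app` from the
electrolyte panel (or accepts a precomputed value), closes the charge
balance at the measured pH for `[U⁻]`, forward-solves the resulting sample,
and collects differences predicted − measured for pH, pCO₂ and HCO₃⁻.
Bland–Altman agreement per variable reports the mean bias, the n−1 sample
standard deviation, and limits of agreement bias ± 1.96·SD. Records that
fail to bracket are excluded from the statistics but always reported by
identifier. Because `[U⁻]` is derived from the measured values themselves,
the comparison verifies the code and the numerical procedure, not the
model's physiological validity — on records generated by the model itself
the pipeline must return zero bias and zero-width limits up to solver
precision, and does (≈10⁻¹⁴).

## Synthetic data generator

The generator emulates anonymized neonatal intensive-care blood-gas panels:
independent uniform draws of Na 130–150, K 3–6, ionized Ca 1.0–1.5, Mg
0.7–1.1, Cl 95–115, lactate 0.5–10, albumin 10–30, phosphate 1.0–2.8,
unmeasured anions 0–15 mEq/L and total CO₂ 10–35 mmol/L, with blood-gas
fields filled by the forward solve. Two dialects:

- **model-consistent** — measured pH/pCO₂/HCO₃⁻ are the solver's own
  outputs at full precision; the CO₂ conservation between the reported
  fields holds exactly. This dialect exists to give the verification
  pipeline an exact oracle.
- **analyzer-like** — bicarbonate and total CO₂ are re-derived from the
  solved pH and pCO₂ using analyzer constants (effective carbonic-acid pK
  6.105, solubility 0.225 mmol/(L·kPa) — typical clinical-analyzer values),
  and all reported fields are rounded to the clinical grid (pH 2 decimals,
  pCO₂ 0.1 kPa, concentrations 0.1 mmol/L). The re-derivation keeps the
  (small) carbonate term with the model's own `kd`, which makes the dialect
  exactly degenerate with the model-consistent one when the analyzer
  constants match the model's and rounding is disabled. This dialect
  reproduces the qualitative signature seen against real analyzers: a
  systematic negative pCO₂ bias of a few tenths of a kPa.

What passing tests on synthetic data do **not** show: the marginals are
independent and uniform, so the generator reproduces neither the joint
distribution, the longitudinal structure, nor the disease-class mixture of
a real cohort; agreement statistics on it say nothing quantitative about
agreement on clinical data.

Unconstrained uniform draws over full reference ranges frequently combine
a strong-ion load with a CO₂/weak-acid pool that admits no physiological
root (about two thirds of draws; real panels are correlated and do not
behave this way). Such draws are discarded and redrawn; a guard aborts with
a range diagnosis if the rejection rate exceeds 80% (`max_rejection_rate`),
i.e. well above the expected baseline of the default ranges, which is the
signature of genuinely misconfigured ranges rather than ordinary rejection.
Randomness is numpy's PCG64 `default_rng`, and the generator records the
algorithm, seed and full configuration in its output metadata.

The package also ships `table2_fixtures()`: six published single-sample
disturbances (normal, respiratory acidosis, hyperchloremia,
hypoalbuminemia, hyperlactatemia, metabolic acidosis) with their printed
inputs, measured target gases and simulated outputs, used as reference
points by the tests and the acceptance script. The printed inputs are
rounded to clinical precision; evaluated exactly, they leave a residual net
charge of 0.1–0.8 mEq/L at the printed simulated pH, and since the
net-charge curve is flat in pH at fixed total CO₂, fresh solves land within
about 0.04–0.18 pH of the printed values while recovering bicarbonate to
better than 0.5 mmol/L. The printed simulated outputs also imply an
effective carbonic-acid pK nearer 6.07 than the tabulated 6.10; this
package implements the tabulated constants and documents the discrepancy
rather than tuning toward the printed outputs — it is the main reason
printed pCO₂ values are reproduced only to within 10–25%.

## Problem sizes

The test suite and acceptance script use 200–1000 randomized compositions
for the solver contracts, 2000 synthetic records per dialect for the
agreement pipeline, and 100 minutes of simulated time at 0.05–0.1 min steps
for the dynamics closed forms; each stage completes in seconds on one CPU,
and all randomness is seeded.

## Known limitations

- Plasma-only: no hemoglobin/erythrocyte buffering, interstitium, or
  whole-blood base excess; predictions are for separated-plasma chemistry.
- The Figge linearization is a fit around physiological pH; far outside
  [6.5, 7.8] its charge (and hence `[U⁻]` back-calculations at extreme
  measured pH) lose meaning.
- Constants are fixed at 37 °C; no temperature correction of pK or α.
- The compartment model has no ventilation mechanics, diffusion or
  autonomic coupling; it is the minimal transport closure needed to drive
  the equilibrium model dynamically.
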