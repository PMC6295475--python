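# Methods

## Gibbs energy model

Actual Gibbs free energy changes are computed as ΔG = ΔG° + RT ln Q with
R = 8.314462618 J mol⁻¹ K⁻¹. ΔG° is the stoichiometric sum of standard Gibbs
free energies of formation taken from the shipped table (Thauer, Jungermann &
Decker 1977 values: pH 0 reference with ΔGf°(H⁺) = 0, 1 atm gas standard
state, 298.15 K). Two deliberate simplifications:

* **No temperature correction of ΔG°.** The tabulated 298.15 K values are
  used directly while RT uses the actual temperature (default 303.15 K).
  The van't Hoff correction over 5 K is ≲1 kJ/mol for these reactions,
  well inside the ±3 kJ/mol reproduction tolerance adopted throughout.
* **1 atm (101 325 Pa) gas standard state.** Classical formation-energy
  tables are referenced to atm; the atm-vs-bar difference is <0.1 kJ/mol per
  stoichiometric unit of gas.

Stoichiometric coefficients are exact `fractions.Fraction`s, so element and
charge balance are checked exactly, `ΔG°` of an unbalanced reaction is
refused, and Hess additivity / reversal antisymmetry hold to machine
precision in floating point.

## Activities in 1 M soda brine

Concentration → activity conversion uses fixed electrolyte correction
factors rather than an ionic-strength model: f = 0.5 for monovalent and
f = 0.04 for divalent ions at 1 M Na⁺, 1.0 for neutral aqueous species.
These fixed factors *are* the model; no Debye–Hückel or Pitzer treatment is
attempted, because at 1 M carbonate brine those limiting laws are outside
their validity range anyway and the fixed factors subsume ion pairing.

Conventions: water activity is 1 even in 1 M brine; H⁺ activity is 10^(−pH)
with no further factor (pH already measures an activity); sulfide is modeled
entirely as HS⁻ and carboxylic acids as their anions (pKa values are ≥4
units below pH 9.5).

Gases enter as a = p/101325. **H₂ alone** carries an additional salting-out
factor of 0.2 (its solubility in 1 M soda brine relative to pure water),
applied only in the `soda_corrected` frame. Every reaction is therefore
reported as a (ΔG¹, ΔG¹\*) pair; the two differ by exactly ν_H₂·RT·ln 0.2
(= ∓16.2 kJ/mol for the ±4 H₂ reactions at 303.15 K) and coincide for
H₂-free reactions. CH₄ and CO₂ are not salted out: the correction exists
specifically because uncorrected Henry behaviour of H₂ makes both
H₂-producing and H₂-consuming reactions look unrealistic, and no analogous
estimate is adopted for the other gases.

## Carbonate speciation

When a total dissolved inorganic carbon is declared, it is partitioned over
CO₂(aq)/HCO₃⁻/CO₃²⁻ with the freshwater 25 °C constants pK1 = 6.35,
pK2 = 10.33 used as conditional constants, the fixed activity factors folded
into the quotients:

    [HCO₃⁻]/[CO₂aq] = K1 / (a_H · f_mono)
    [CO₃²⁻]/[HCO₃⁻] = K2 · f_mono / (a_H · f_di)

CO₂(aq) is computed as the residual so the three species sum to the total
exactly. The equilibrium CO₂ partial pressure follows from a configurable
Henry constant (default 0.0339 M/atm). With the default factors this puts
the HCO₃⁻/CO₃²⁻ crossover at an effective pK of ~9.23, i.e. carbonate
slightly dominates at pH 9.5. Both constants and the Henry coefficient are
user-overridable; the benchmark scenarios bypass speciation entirely by
declaring bicarbonate explicitly (below), so their results do not depend on
this choice.

## Reference scenarios (reconstructed in-situ values)

The four benchmark scenarios fix: T = 303.15 K, pH 9.5, f = 0.5/0.04,
H₂ salting factor 0.2, **HCO₃⁻ = 0.6 M**. Scenario-specific values:

| scenario    | acetate | SO₄²⁻ | HS⁻  | CH₄       | H₂      | consumer |
|-------------|---------|-------|------|-----------|---------|----------|
| M-SAO       | 45 mM   | –     | –    | 20 265 Pa | 11.5 Pa | methanogenesis |
| M-SAO+BES   | 45 mM   | –     | –    | –         | 47.9 Pa | none (inhibited) |
| S-SAO       | 25 mM   | 20 mM | 5 mM | –         | 4.7 Pa  | sulfate reduction |
| S-SAO+MoO₄  | 25 mM   | 20 mM | 5 mM | –         | 13.7 Pa | none (inhibited) |

The H₂ pressures are measured quasi-steady values; the solute
concentrations are documented reconstructions of mid-incubation conditions
(the source tables print only the H₂ pressures), chosen once and shipped as
data. The 0.6 M bicarbonate value is consistent with a 1 M Na⁺
carbonate/bicarbonate medium at pH 9.5 and reproduces the published energy
table within the stated tolerance; because every reported ΔG depends only
logarithmically on these concentrations, ±50% errors in them move ΔG by
≲1 kJ/mol. Inhibited scenarios (BES blocks methanogenesis, molybdate blocks
sulfate reduction) are represented as producer-only scenarios.

## Derived quantities

* **Equilibrium formate.** Solving ΔG = 0 for HCOO⁻ + H₂O → HCO₃⁻ + H₂ at
  fixed H₂ (in the conditions' own frame) and HCO₃⁻ gives the formate
  *activity* in closed form; dividing by f_mono returns a concentration,
  the quantity compared against the 50 µM assay detection limit. The result
  is strictly linear in the H₂ partial pressure and in the HCO₃⁻ activity.
* **Critical H₂ and feasibility window.** ΔG is log-linear in the H₂
  pressure, so the pressure at which a reaction hits a threshold (default
  0 kJ/mol; a configurable minimum energy quantum can be supplied instead)
  is closed-form: p* = p_ref·exp((θ − ΔG(p_ref))/(ν RT)). The window is the
  interval between the consumer's floor and the producer's ceiling; it is
  empty when the floor exceeds the ceiling. A bisection oracle over the
  full ΔG evaluation agrees with the closed form to <10⁻⁶ relative in tests.
* **Energy partition.** Partner shares are ΔG_partner/ΔG_total, defined
  only for an exergonic total; the consumer share is computed as
  1 − producer share so the two sum to exactly 1.

## Time-series layer

Measurements carry explicit units (mM for solutes, Pa for gas partial
pressures, mmol per liter medium for cumulative methane) and a
detection-limit censoring flag; censored values are recorded *at* the limit.
Consumption rates are per-replicate least-squares slopes (censored points
excluded, never substituted at limit/2 — non-detects are treated
qualitatively), negated and averaged; the default fitting window is the
longest interval over which the replicate-mean profile declines
monotonically, matching how a single rate describes near-linear batch
curves. Stoichiometric yields convert headspace gas changes to mmol per
liter of medium via the ideal gas law at the series temperature with the
declared vial geometry (default 30 mL liquid / 20 mL headspace); the
dissolved CH₄ fraction is neglected, consistent with reporting methane per
liter of medium.

## Synthetic-data generator

The generator emulates the structure of the batch incubations, not their
microbial kinetics: zero-order (linear) substrate decline at a configured
rate until exhaustion — the observed curves are near-linear and are
summarized by single rates — with products accumulating by exact reaction
stoichiometry; H₂ following a saturating rise (time constant 50 h) to a
quasi-steady plateau (11.5 Pa methanogenic, 4.7 Pa sulfate-reducing) or, in
inhibited configurations, a monotone rise toward the measured ceiling
(47.9 Pa) with substrate consumption capped at 1.6 mM; a formate trace
pinned to its H₂ equilibrium value and censored at 0.05 mM; and
multiplicative Gaussian noise (default CV 0.10 — reported standard
deviations scale roughly with signal magnitude) applied per measurement.
All replicate streams are spawned from one seed, so a config plus seed
reproduces byte-identical series.

What the generator does **not** model: lag phases, biomass growth, sulfide
toxicity, gas-liquid mass-transfer limitation, or the transient H₂/formate
dynamics of cross-feeding experiments. Passing recovery tests on these
series therefore demonstrates estimator correctness under the assumed
structure (linear decline, constant CV, exact stoichiometry), not robustness
to the full messiness of culture data.

## Numerical choices and degenerate inputs

* Balance residuals and stoichiometry are exact rationals; everything else
  is double precision.
* ΔG displays round to 0.1 kJ/mol; internal values are full precision.
* Zero or negative activities, pressures and temperatures are rejected with
  errors naming the offending species rather than propagating NaN/−inf.
* An empty reaction is balanced and has ΔG = 0 (vacuous sums).
* Problem sizes are small by construction (≤11 species, ≤7 reactions, a few
  hundred measurements per simulated series; the statistical recovery tests
  use 100 seeded triplicate series), so the whole analysis runs in seconds.

## Known limitations

* The fixed f-factors and the 0.2 salting factor are order-of-magnitude
  estimates inherited from the haloalkaline literature; the ±3 kJ/mol
  tolerance on the benchmark table absorbs their uncertainty together with
  the reconstructed concentrations and the 25→30 °C approximation.
* The published inhibited-culture formate estimates cannot all be matched
  simultaneously by any single linear-in-H₂ parameterization; the package
  therefore targets the detection-limit bound and order-of-magnitude
  agreement for those values rather than exact reproduction.
* No kinetic or growth coupling: the feasibility window says where both
  partners *can* conserve energy, not at what rate they do.
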