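# hemotherm

Computational model of how ageing changes arterial blood flow and
whole-body heat transfer in humans.

Ageing stiffens the large elastic arteries, raises peripheral resistance,
remodels the left ventricle, thins muscle, fat and skin, lowers the basal
metabolic rate, and blunts the thermoregulatory reflexes (sweating,
cutaneous vasomotion, shivering). `hemotherm` implements each of these
effects as an explicit parameter law of age ξ and couples three
sub-models:

1. **1D pulse-wave haemodynamics** in a tree of elastic vessels governed by
   the tube law `p = p_ext + β(√A − √A0)`, with mass/momentum/energy
   conservation solved by an explicit two-step Taylor–Galerkin scheme and
   boundary conditions imposed through the characteristic variables
   `w1,2 = u ± 4c`, `c = √(β√A/2ρ)`. Terminals are short stiff tapers whose
   characteristic impedance supplies the peripheral load.
2. **A time-varying elastance left ventricle**: `p_LV = E(t)(V_LV − V_LV,0)`
   with a double-Hill elastance curve between `E_LV,min` and
   `E_LV,min + E_LV,max`, a four-phase cycle machine, and an aortic valve
   transmission coefficient blending the LV-driven forward characteristic
   into the network inlet.
3. **Bioheat transfer and thermoregulation**: 14 layered tissue cylinders
   (bone/muscle/fat/skin, plus brain, lung and viscera cores) with radial
   conduction `ρ_t c_t ∂T/∂t − k_t (1/r)∂_r(r∂_r T) = q_v + perfusion +
   vessel sources` (backward Euler), Newton-cooling/linearised-radiation
   and evaporative skin fluxes, and controllers for sweating, skin blood
   flow and shivering driven by core temperature `T_cr` and mean skin
   temperature `T̄_sk`.

Age enters only through one module (`hemotherm.ageing`), so every other
component is age-agnostic: stiffness scaling (pulse-wave velocity doubling
from 20 to 80 years ⇒ compliance ÷ 4, or the per-vessel diameter/PWV fit
`c = ā d^(−b̄)`), terminal-resistance growth, the LV decade table, the
tissue-thickness/bone-density/metabolic regressions, cutaneous-flow
attenuation, and threshold shifts of all three reflexes.

## Worked example

```python
import hemotherm as ht

# age-parameterised cardiac run on a seeded synthetic arterial tree
young = ht.run_flow_experiment(30, n_generations=2, seed=0, n_cycles=6)
old   = ht.run_flow_experiment(80, n_generations=2, seed=0, n_cycles=6)
for r in (young, old):
    a = r.indicators[0]
    print(f"age {r.age:.0f}: p_sys {a.p_sys:.1f}  p_dia {a.p_dia:.1f}  "
          f"PP {a.PP:.1f} mmHg   CO {r.cardiac_output_L_min:.2f} L/min")
```

prints

```
age 30: p_sys 120.7  p_dia 45.1  PP 75.6 mmHg   CO 5.43 L/min
age 80: p_sys 146.9  p_dia 13.3  PP 133.7 mmHg   CO 3.88 L/min
```

— ageing raises systolic pressure and nearly doubles the pulse pressure on
this synthetic tree, while cardiac output falls, the qualitative signature
of arterial stiffening plus increased peripheral resistance.

The coupled hot-exposure experiment (bare body, 40 °C air, 42 % relative
humidity, one hour) with the ageing mechanisms switched on cumulatively:

```python
from hemotherm.driver import ExperimentConfig, run_ladder
base = ExperimentConfig(age=80, T_air=40, RH=42, duration=3600,
                        dt_thermal=1.0, flow_mode="pool")
for case, res in run_ladder(base).items():
    print(f"{case:11s} final T_cr {res.final_T_cr:.3f} °C")
```

```
young       final T_cr 36.816 °C
fluid       final T_cr 36.816 °C
tissues     final T_cr 36.775 °C
vasomotion  final T_cr 36.787 °C
sweating    final T_cr 37.071 °C
```

Flow ageing alone is thermally negligible; reduced tissue metabolism lowers
the core temperature; blunted vasodilation and, above all, deteriorated
sweating drive it back up (+0.28 °C from the sweating mechanism here).

A CLI wraps the same drivers:

```bash
hemotherm age-params --age 80 --terminal-model maksuti
hemotherm make-fixtures --generations 3 --seed 7 --out network.json
hemotherm simulate-flow --age 60 --out flow.csv
hemotherm simulate-coupled --set toggles.sweating=false --out coupled.csv
```

## Scope

The anatomical 91-segment arterial tree and the per-tissue thermophysical
property sets used in the original full-scale studies are not shipped (they
are external data); the package runs on any network conforming to its JSON
schema and ships a seeded synthetic-tree generator plus literature-style
tissue property defaults. The venous circulation, 3D anatomy and
viscoelastic wall behaviour are out of scope. See `docs/methods.md` for
model details, parameter defaults and limitations.
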