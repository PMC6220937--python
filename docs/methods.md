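# Methods

## Model overview

The package couples three sub-models. Age ξ (years, 20–90) enters only
through `hemotherm.ageing`; all other modules consume the resulting
parameters.

### 1D arterial haemodynamics

State per vessel node: cross-sectional area A (cm²), mean velocity u
(cm/s), mean temperature T (°C). Pressure follows the elastic tube law
`p = p_ext + β(√A − √A0)` with `β = √π h_w E/(A0(1−σ²))`, σ = 0.5. The
conservation system (mass, momentum with Poiseuille friction
`−8πμu/(ρA)`, temperature advection–diffusion with a wall heat source
`2h_in/(ρc_p√(A/π))·(T_w − T)`) is hyperbolic with characteristic speeds
`u ± c`, `c = √(β√A/2ρ)`.

**Numerics.** The named locally conservative Taylor–Galerkin family does
not pin down one stencil; this implementation uses the two-step
predictor/corrector (Richtmyer) form, which on linear elements over a
uniform grid with lumped mass coincides with second-order Taylor–Galerkin.
Verified properties: second-order grid convergence against the linear
analytic pulse (error ratio ≥ 3–4 per refinement), pulse propagation at the
intrinsic wave speed within 0.5 %, junction reflection/transmission within
0.2 % of linear transmission-line coefficients on an inviscid fluid, exact
nodal terminal reflection. The scheme is explicit; the CFL bound
`dt ≤ min(Δx/(|u|+c))` is checked every step and violation aborts the run.

**Boundaries.** All boundary values are imposed through the characteristic
variables `w1,2 = u ± 4c`, extrapolated semi-Lagrangially (the boundary
value at t+Δt is the interior value a distance λΔt inside the vessel).
Terminals apply `w2 = w2⁰ − R_R (w1 − w1⁰)`; junctions solve mass
conservation, total-pressure continuity `p + ρu²/2` (chosen as the momentum
surrogate; the source formulation names momentum conservation without a
formula) and characteristic compatibility by damped Newton iteration,
batched over junctions of equal arity, to a relative residual of 1e-10.
Outflow temperature is extrapolated in time when u > 0 and set to the local
tissue temperature otherwise.

**Terminal load.** Peripheral circulation is represented by short stiff
taper vessels (step decrease in A0, step increase in β). Their
characteristic impedance Z_c = ρc/A provides both the resistive load and
the physiological reflection; an optional extra reflection coefficient R_R
sits at the taper outlet (default 0). The synthetic-network generator sizes
the tapers so that the parallel sum of Z_c equals a target total peripheral
resistance (default 1.0 mmHg·s/mL, giving ~90 mmHg mean pressure at
~90 mL/s cardiac output).

### Left ventricle

`p_LV = E(t)(V_LV − V_LV,0)` with the double-Hill elastance
`E = E_min + E_max ψ [x^η1/(1+x^η1)][1/(1+y^η2)]`,
`x = t/(ζ1 T_card)`, `y = t/(ζ2 T_card)`. The decade table supplies
E_max, E_min, p_ED and heart rate; between decades all quantities
interpolate linearly. The unprinted shape constants default to
η1 = 1.32, η2 = 21.9, ζ1 = 0.269, ζ2 = 0.452 (standard double-Hill values
for the human elastance curve); ψ is computed numerically at construction
so the bracket's maximum over one period is exactly 1, making
max E = E_min + E_max and E(0) = E_min exactly. V_LV,0 = 10 mL,
p_ven = 5 mmHg and R_mv = 0.0125 mmHg·s/mL are configuration defaults.

The cycle is a four-phase machine: isovolumetric contraction (until p_LV
exceeds the instantaneous inlet pressure), ejection with
`dV/dt = −G_AV` (forward Euler; G_AV is the net inlet flow), ending at the
elastance peak time; isovolumetric relaxation until p_LV ≤ p_ED; filling
with `dV/dt = (p_ven − p_LV)/R_mv` until the period ends. The aortic valve
enters the inlet characteristic as a transmission coefficient R_AV ramped
linearly over 5 ms (configurable), blending the LV-driven forward
characteristic `w1,in = w2⁰ + 4√((2/ρ)(p_LV − p_ext + β√A0))` (equal to
`w2⁰ + 8c(A_eq)` with A_eq the area equilibrated to p_LV) with total
reflection.

**Known behaviours.** (i) The end-diastolic volume settles below the
initialisation value V_LV,0 + p_ED/E_min when the filling time constant
R_mv/E_min (~0.5 s) exceeds the diastolic window — a property of the
printed filling law, not a defect. (ii) With the elastance amplitude forced
to ~0 the model does not reach exactly zero flow immediately: the valve
phase machine rectifies the decaying startup oscillation, so output decays
over tens of cycles toward the uniform-pressure state instead of vanishing
in one. Tests assert the order-of-magnitude collapse and monotone decay.
(iii) Ejection ends at the elastance *peak time* (the alternative — a
threshold fraction of E_max — is not used).

### Body thermal model

Fourteen solid cylinders (head, neck, thorax, abdomen; paired shoulders,
arms, forearms, thighs, legs) with concentric layers; the reference
(30-year) layer radii and lengths are the shipped geometry table,
reproduced exactly by construction. Radial conduction with metabolic,
shivering, perfusion and vessel-coupling sources is discretised by a
cell-centred finite-volume scheme (spacing ≤ 1 mm, faces pinned at layer
interfaces, harmonic-mean interface conductances) and integrated by
backward Euler (unconditionally stable; conduction, perfusion and the
Robin skin boundary are implicit, all other sources explicit). Verified:
steady annulus within 0.04 % of the analytic log profile; exact uniform
heating under insulation; per-step global energy closure at the
backward-Euler pairing to 1e-9 relative.

**Blood pool.** In the default (pool) coupling the perfusion term exchanges
heat with a zero-capacity central blood pool whose temperature is the
perfusion-weighted mean tissue temperature — energy-conserving by
construction. In live coupling, mapped vessels exchange heat with tissue
cells: core vessels are adiabatic with their inlet temperature reset to
T_cr each step; central vessels exchange at the cylinder's innermost cell;
transversal vessels act as volumetric sources in the host muscle layer.
The tissue-side power equals the fluid-side term integrated along the
vessel, so the exchange is two-sidedly bookkept. The core-vessel inlet
reset injects a small unbalanced enthalpy (audited in tests, not
corrected), as the source formulation implies.

**Properties.** Per-tissue k, ρ, c, basal q_v and perfusion are
literature-style defaults shipped as configuration (`_tables.py`),
override-friendly. Basal volumetric sources are normalised at build time so
whole-body production equals the resting-metabolic-rate regression at the
reference age (87.7 W at 30 y), then scaled by the per-tissue metabolic
ageing ratio; 9 % of production (configurable) is removed at the lung as
respiration loss. Bone conductivity follows the quadratic density fit, with
density aged by its own regression.

**Ageing of geometry.** Muscle, fat and skin layer thicknesses scale by
`fit(ξ)/fit(30)` of the respective regression (arm/forearm muscle fit for
all skeletal muscle except the abdomen, which has its own; the same for
fat). Scaling relative to the fit's value at the model's 30-year reference
geometry keeps the reference body exact at ξ = 30; the alternative (raw fit
value, reference age 20) would contradict that and differs by ≤ 3 % at 80.
Bone and inner-organ radii are age-fixed. The abdominal fat fit decreases
with age even though abdominal fat physiologically accumulates — the
regression is implemented as printed and this tension is simply noted.

**Indicators.** T_cr = mass-weighted mean over brain, lung and viscera
cells (a hypothalamic proxy is a selectable alternative in principle;
the mass-weighted mean is the default operationalisation). T̄_sk =
skin-area-weighted mean of the surface temperatures, which are recovered
from the outer-face flux balance.

### Thermoregulation

Sweating: the per-segment rate combines tanh drives in the skin and core
deviations, clipped by the age-dependent sensitivity-decline steps, and a
local-skin factor `α_swe·2^((T_sk−T_sk,0)/10)`. Rates are in g/(min·m²);
the evaporative loss is `min(40.6·ṁ·A_sk, 2.2·h_swe·f_cl·(p_v,sk −
p_v,a)·A_sk)` with Antoine saturation pressures (mmHg); 40.6 W per
g/(min·m²) is the latent heat conversion. Insensible baseline 0.3
g/(min·m²), h_swe = 5 W/(m²·K), f_cl = 1 (bare body) — all configurable.
The perfusion table's max/min columns are transposed as printed (the max
column holds zeros); the package swaps them by default with a
strict-literal flag. Vasomotion: dilation ramps with T_cr between the
dilation thresholds, constriction with T̄_sk; the min/max flows carry the
age attenuation factor `1.198 − 0.007677ξ` applied as printed (it is 1.0445
rather than 1 at ξ = 20 — a fit artifact). Shivering: active only for
T_cr ≤ 37.1 °C; threshold quadratic in T_cr (plateau 35.5 °C below
35.8 °C), shifted by −0.031 °C/y (the −0.029 °C/y recomputed from the
quoted endpoints is selectable); maximum production quadratic in T_cr with
the 1/3600 factor; the `(40 − T_shiv)` gate and quadratic skin-temperature
ramp are implemented exactly as printed (their physical role is odd — all
constants are config-exposed). The distribution `q_shiv =
α_shiv Q_shiv/V_mus,glob` is likewise as printed, so the volume integral
recovers Q_shiv only approximately. Setpoints T_cr,0 = 36.8 °C,
T̄_sk,0 = 33.7 °C align with the neutral vasomotion thresholds.

Whole-body coefficient sums with limb multiplicities: Σα_swe = 1.000,
Σα_shiv = 1.001 (asserted to ±0.002).

### Coupled experiments

The driver exposes independent ageing toggles {fluid, tissues, vasomotion,
sweating, shivering}, reproducing the hot-exposure case ladder. Coupling is
loose (latest available fields; no sub-iteration). Two cadences:

* **pool** — conduction + pool perfusion only; thermal step default 0.5–1 s
  (backward Euler allows this); used for hour-long exposures. The fluid
  toggle has no thermal pathway in this mode, which is consistent with the
  finding it reproduces (flow ageing is thermally negligible).
* **live** — `dt_thermal/dt_flow` flow sub-steps nested in every thermal
  step with two-way vessel–tissue exchange; used for short windows (the
  fluid-ageing effect measurement in `scripts/acceptance.py` runs 10 s
  windows; an hour of live coupling at the flow time step is not a
  desk-scale computation).

## Synthetic data

No anatomical network is shipped: the generator builds a symmetric binary
tree (root area 4 cm², unstressed wave speed 6 m/s, per-generation area
ratio 1.16 per pair and wave-speed growth 8 %, lengths ×0.75, ±10 % seeded
jitter) with terminal tapers sized to a total peripheral resistance of
1.0 mmHg·s/mL; all wave speeds stay in the physiological 2–15 m/s band.
The network document records its reference age (40 y for the uniform
stiffening baseline; the thermal geometry reference is 30 y).

What passing tests show about real data is therefore structural, not
anatomical: the ageing laws evaluate as published; the solvers reproduce
closed-form wave and conduction physics; and the *orderings* survive the
scale-down (pulse pressure and systolic pressure rise with age; in the hot
exposure the regulation-deterioration ladder is strictly ordered and the
sweating effect is ≈ +0.3 °C here versus ≈ +0.2 °C at full scale). Absolute
waveform shapes, the 6–7 L/min cardiac-output window of the anatomical
tree, and experimental temperature overlays require the external
91-segment geometry and calibrated tissue properties, and are explicitly
out of desk scope. The cardiac-output sanity band for the synthetic tree is
3–9 L/min (configuration, not a published value).

## Numerical choices and tolerances

* Flow time step: 2·10⁻⁵ s is the published full-network value; the
  synthetic trees resolve comfortably at 1.5–2·10⁻⁴ s (CFL ≈ 0.5), which
  the experiment drivers use as default. Thermal step: 10⁻⁴ s published;
  pool-mode backward Euler is stable and accurate at 0.5–1 s.
* Junction Newton: damped steps (area floor 10 % per iteration), 50
  iteration cap, relative tolerance 1e-10; non-convergence aborts with the
  parent ids.
* Cycle-to-cycle pointwise periodicity of the cardiac runs plateaus at
  ~3–4 % of pulse amplitude because valve transition times are quantised to
  the time step; amplitude metrics (PP, CO, p_sys) are stable to < 0.5 %
  after 8 cycles, and tests assert that form.
* PV-loop closure is measured as the end-to-start gap in the (V, p) plane
  relative to the stroke-volume extent (< 1 % at convergence).
* Linear regressions extrapolated to extreme ages clamp at a 10⁻³ floor
  with a logged warning; ages outside table ranges clamp to the nearest
  tabulated value.
* The diameter/PWV fit is implemented with a negative exponent
  `c = ā d^(−b̄)` (the inverse relationship the positive-exponent printing
  contradicts; a literal mode is available via `pwv_exponent_sign=+1`).
  The fit underestimates β for vessels below ~5 mm diameter; no correction
  is applied.

## Limitations

* No venous return, no countercurrent artery–vein heat exchange, no 3D
  anatomy, no wall viscoelasticity, no acclimatisation or behavioural
  regulation, no gender-specific laws (the underlying regressions are
  male-data fits), no pediatric ages.
* The heat-transfer coefficients (h_con = 5, h_rad = 4.7 W/(m²·K)) are
  standard Newton-cooling/linearised-radiation constants, config-exposed,
  not a detailed convection/radiation model.
* The elastance-amplitude-zero limit and the core-vessel inlet reset carry
  the small artifacts described above; both are audited by tests rather
  than silently corrected.
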