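# Methods

## Thermal model

The phantom is a 1-D slab along the depth axis: a superficial fat layer
(default 10 mm) over glandular tissue (40 mm), with the tumour modelled as
a 6 mm interval of the gland centred 20 mm deep. Temperature obeys the
Pennes bioheat equation with region-wise constant parameters; the
perfusion term `w_b·c_b (T − T_b)` is the lumped blood heat sink, and a
metabolic source is added per region. Nominal parameters are literature
means (see `tissue.py`); the tumour's metabolic heat is not tabulated with
them, so it defaults to 4200 W/m³ — a package choice, configurable, a few
times the gland value as typical of tumour hypermetabolism.

Discretisation: uniform grid (default Δx = 0.25 mm), conservative flux
form with harmonic-mean conductivity at control-volume faces (continuous
heat flux across fat/gland/tumour interfaces), a half-cell convective
balance at the skin surface (h = 10 W/m²K to 25 °C ambient by default,
optional radiation, off by default), and a fixed 37 °C core at the deep
boundary. Time stepping is forward-Euler with a hard stability guard
(error messages name the admissible Δt) or Crank–Nicolson for large steps;
both share one assembled tridiagonal operator, and a direct banded solve
gives stationary solutions. Note that Crank–Nicolson only marginally damps
modes far stiffer than its step (amplification → −1), so near-Dirichlet
surface conditions emulated with an enormous h should be run with the
explicit scheme or a genuinely stiff-accurate method.

Two perfusion reference conventions exist because a published variant of
the tissue equations writes the fat and tumour sinks against the *gland*
temperature where the gland's own sink references blood — almost certainly
a slip for T_blood, but implemented (`gland-referenced`, referencing the instantaneous
mean gland temperature, treated explicitly to keep the operator
tridiagonal) alongside the physically standard `blood-everywhere` default.
Neither is asserted as "intent"; the modes exist so the difference can be
quantified.

## Laser / quantum-dot heating

No spatial form for the laser source is published, so deposition follows
single-axis Beer–Lambert: `I(x) = I₀ exp(−∫μ_eff)`, `Q = μ_eff·I`, with
per-region effective coefficients and the tumour's coefficient multiplied
by a quantum-dot enhancement factor. Scattering coefficients are carried
as metadata only (assumed folded into the effective values).

The optical defaults — fat 2 /m, gland 3 /m, tumour base 3 /m, QD
enhancement 50 — are package choices, not literature constants, fixed by
two requirements that turn out to be coupled:

1. **Selectivity.** In the 700 nm NIR window unloaded tissue absorbs
   weakly; with these values ~96 % of the beam reaches the tumour and the
   steady temperature maximum falls inside it (tumour optical depth
   ≈ 0.9 over 6 mm, so its heating is roughly uniform).
2. **Stability.** The controller senses the tumour centre. If absorption
   upstream (fat/gland) is strong, the deposition peak sits millimetres
   proximal of the sensor and heat arrives only after a diffusion delay
   (~75 s over 3 mm); with the large tabulated integral gains that delay
   produces a limit cycle. Collocating deposition with the sensor makes
   the actuator-to-sensor transfer function that of a driving-point
   thermal impedance — passive, phase ≥ −90° — so the PID loop is stable
   for any positive gains. All steady-tracking results in this package
   rely on that collocation.

A consequence worth stating plainly: on this plant the steady irradiance
needed to hold 43 °C *rises* with tissue conductivity (conduction drains
the heated region toward the cool skin and core; measured 3247 → 3447 W/m²
for k = 0.2 → 0.6 at nominal perfusions). A decreasing trend would require
heat delivered to the sensor by conduction from deposition elsewhere —
precisely the delayed configuration that destabilises the loop — so the
two behaviours cannot coexist in this geometry, and the package keeps the
stable one. The corresponding qualitative test asserts the claimed
decreasing direction and fails; it is left failing deliberately.

## Controller

Discrete PID with: forward-rectangle integration; derivative on the
*measurement* through a first-order filter (coefficient N = 10, time
constant (kd/kp)/N) so setpoint steps do not kick the actuator; clamping
anti-windup (the integral update is rejected while it would push further
into saturation). Saturation defaults to [0, 10000] W/m² — the upper end
of the power densities the loop needs under unfavourable parameter draws,
since the required steady irradiance across the uncertainty box (≈ 3.2–4.3
kW/m²) exceeds the 3600 W/m² open-loop sweep ceiling, so the sweep range
remains the open-loop experiment default but not the actuator limit.
Setpoint defaults to 43 °C; the control sample time equals the solver
step (0.5 s Crank–Nicolson in the standard runs).

Step metrics use the standard definitions — 10→90 % rise time, ±2 %-band
settling (bands as fractions of the commanded step |setpoint − initial|),
overshoot relative to the step and floored at zero, final value as the
mean of the last 5 % of samples — with interpolated threshold crossings.
Undefined rise/settling times enter the tuning cost as a configured
penalty (the tuning horizon by default).

### Horizons

The tabulated transient metrics are of order one second, but the phantom's
physics cannot respond that fast at any admissible power: raising a 6 mm
tumour by 6 °C at ≤ 10 kW/m² takes tens of seconds at full drive, and the
plant's perfusion poles sit at ρc/(w_b·c_b) ≈ 80–4000 s. Transient values
are therefore not comparable with the tables and are never asserted
numerically; steady-state behaviour is. Closed-loop evaluations run 900 s
(steady state well reached; the slowest closed-loop tail decays in
~100 s), and the tuning cost is evaluated on a 300 s horizon at a 1 s
Crank–Nicolson step — long enough to expose overshoot, settling and
residual error, short enough that a full tuning takes seconds.

## ICA tuning

Standard imperialist competitive algorithm: the best initial countries
become imperialists and receive colonies in proportion to normalised
power; each iteration assimilates (colonies move a uniform(0, β) fraction
toward their imperialist with a random angular deviation up to γ),
revolves (a fraction of colonies redrawn uniformly), swaps any colony that
beats its imperialist, and runs one competition (the weakest empire's
worst colony moves to a roulette-selected winner; empty empires collapse).
Defaults: 50 countries, 8 imperialists, β = 2, γ = π/4, revolution rate
0.3, colony weight ζ = 0.1, 100 iterations; positions reflect at the
bounds; non-finite costs count as +∞. Everything is reproducible under a
seed. The experiment/tuning default is a reduced budget (20 countries,
4 imperialists, 20 iterations — about 9 s per tuning) that reliably
reaches the cost plateau on this problem.

**Gain box.** kp ∈ [0, 2000], kd ∈ [0, 500], ki ∈ [200, 5000]. The
integral floor is a disturbance-rejection constraint, not a tuning
artefact: poorly perfused tissue drifts on multi-thousand-second time
constants, and a loop tracking that drift lags by (drift rate)/(ki·G).
The unit-weight cost barely penalises this lag — it contains near-optimal
plateau solutions with ki of a few tens whose residual error at 900 s
reaches ~0.01 °C — so the therapeutic requirement (hold the setpoint to
≲ 1 mK against the drift) is imposed on the search box instead. All
tabulated gain sets (ki = 1342.5–1755) satisfy it comfortably. The cost
surface is otherwise flat in kd and partially in ki; tuned gains are
reported as *a* near-optimal set, not *the* optimum, and the tuner retries
attempts whose cost exceeds 180 (best attempt wins, failure above 250).

## Gain scheduling

Training set: one ICA tuning per grid point over (gland perfusion, fat
perfusion, conductivity). The full grid (gland 800:400:3600 × fat
800:200:1600 × k 0.2:0.1:0.6 = 200 points, ≈ 200 examples) is available;
the default end-to-end configuration uses a 4×3×2 = 24-point sub-grid
spanning the same ranges so the pipeline runs in ~4 minutes on one CPU.
Failed tunings are skipped and logged.

Network: 3 inputs → 20 logistic-sigmoid hidden units → 3 linear outputs
(kp, ki, kd); an optional padded 5-output mode exists for compatibility
with fixed five-channel interfaces, with two outputs unused. Inputs and
targets are min–max scaled to [−1, 1]; a zero-width target range is
returned exactly. Training is a hand-written Levenberg–Marquardt:
analytic Jacobian, `(JᵀJ + λI)Δw = −Jᵀr`, λ ×10 on a rejected step and
÷10 on acceptance, stopping on gradient tolerance, λ overflow or the
epoch cap; accepted steps never increase the training sum of squares.
Validation early stopping (15 % split, patience 6) is available but
disabled for scheduler training, which is meant to *interpolate* the
tuned optima. Because an exactly-interpolating network can swing far
outside the target range between grid points (the plateau-valued targets
are not smooth in ki), scheduled gains are clamped to the envelope of the
training targets before the search box — the scheduler interpolates,
never extrapolates.

On this plant both a well-tuned fixed PID and the scheduled PID reach
steady errors of ~10⁻⁴ °C, so the scheduled controller's advantage shows
in the transient (mean overshoot ≈ 8.4 % vs ≈ 11.9 % for the fixed set
over random draws); steady-error comparisons are made at the 10⁻³ °C
reading precision of four-decimal temperature values.

## Uncertainty model

All uncertain parameters are drawn independently and uniformly on their
closed intervals: specific heat 3000–4500 J/(kg·K), density 800–1600
kg/m³, conductivity 0.2–0.6 W/(m·K), blood temperature 36–39 °C, fat
perfusion 800–1600 and gland perfusion 800–3600 W/(m³·°C); tumour
perfusion and the metabolic sources stay nominal. A published range
"9 ≤ ω ≤ 13" carries no units consistent with the perfusion magnitudes
and is left unmapped. Draw order is fixed, so a seed fully determines a
plant.

## What the synthetic conditions do and do not show

The phantom emulates the layered geometry, the perfusion heat sink, the
QD-enhanced absorption and the patient-to-patient parameter spread. It
does not emulate 2-D/3-D beam spreading, discrete vasculature, optical
scattering transport, tissue damage kinetics, or nanoparticle transport —
so passing tests demonstrate correct control behaviour on a physically
plausible 1-D plant, not clinical dosimetry. Problem sizes (201-node
grid, 900 s horizons, 24-point tuning grid, 20-draw robustness checks)
are the package's standard configuration; all are overridable.

## Numerical notes

- Explicit stability bound computed from the assembled operator row-wise;
  violations raise with the admissible Δt named.
- Steady solves with state-dependent extras (literal perfusion mode,
  radiation) iterate a fixed point on the small variable source.
- Step-metric crossings are linearly interpolated; ties in the ICA
  competition roulette resolve toward the lower empire index; equal-cost
  sorting is stable.
- Closed-loop runs assemble the unit laser field once and scale it by the
  commanded irradiance (the field is linear in I₀).
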