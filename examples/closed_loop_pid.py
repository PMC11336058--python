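"""Closed-loop temperature control with a reported PID gain set.

The controller reads the tumour-centre temperature, compares it with the
43 C setpoint and commands the laser irradiance.  Plant: gland perfusion
3357 and fat perfusion 901.58 W/(m^3 C) — a random patient draw.
"""

from hypertherm import (
    BoundaryConditions,
    LaserParams,
    PIDGains,
    SolveConfig,
    compute_step_metrics,
    run_closed_loop,
)
from hypertherm.tuning import PlantCondition, make_plant

phantom = make_plant(PlantCondition(gc_gland=3357.0, gc_fat=901.58))
gains = PIDGains(kp=638.42, ki=1755.0, kd=51.28)

trace = run_closed_loop(
    phantom, BoundaryConditions(), LaserParams(), gains,
    setpoint=43.0, cfg=SolveConfig(dt=0.5, t_end=900.0, scheme="crank-nicolson"),
)
m = compute_step_metrics(trace)

print(f"final tumour-centre temperature : {m.final_value:9.4f} C  (setpoint 43)")
print(f"steady-state error              : {m.ess:9.2e} C")
print(f"rise time (10-90%)              : {m.tr:9.1f} s")
print(f"settling time (2% band)         : {m.ts:9.1f} s")
print(f"overshoot                       : {m.mo:9.2f} %")
print(f"steady irradiance               : {trace.irradiance[-1]:9.0f} W/m^2")
print("\nIntegral action pins the tumour centre exactly at the setpoint even")
print("though the perfusions were never told to the controller.")
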