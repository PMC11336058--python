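"""Neural-network gain scheduling across patient uncertainty.

Tunes the PID on a small grid of plant conditions (gland/fat perfusion and
conductivity), trains the 20-neuron MLP on the tuned gains with
Levenberg-Marquardt, then schedules gains for an unseen condition and runs
the loop.  Takes a few minutes (one ICA tuning per grid point).
"""

from hypertherm import (
    BoundaryConditions,
    ICAConfig,
    LaserParams,
    SolveConfig,
    compute_step_metrics,
    run_closed_loop,
)
from hypertherm.scheduler import (
    LMSettings,
    generate_training_set,
    predict_gains,
    train_mlp,
)
from hypertherm.tuning import PlantCondition, make_plant, tune_condition

ICA = dict(n_countries=20, n_imperialists=4, max_iterations=20)
grid = [
    PlantCondition(g, f, k)
    for g in (800.0, 3600.0)
    for f in (800.0, 1600.0)
    for k in (0.2, 0.6)
]

tuner = lambda cond, seed: tune_condition(cond, ica_cfg=ICAConfig(seed=seed, **ICA))
ts = generate_training_set(grid, tuner, seed=1)
print(f"training set: {ts.n_rows} rows of (gland gc, fat gc, k) -> (kp, ki, kd)")

model = train_mlp(ts, lm=LMSettings(val_fraction=0.0, max_epochs=300), seed=1)
print(f"Levenberg-Marquardt training SSE (scaled space): {model.train_sse:.2e}")

# schedule gains for an unseen patient draw and close the loop
cond = PlantCondition(gc_gland=3357.0, gc_fat=901.58, k=0.48)
gains = predict_gains(model, cond)
trace = run_closed_loop(
    make_plant(cond), BoundaryConditions(), LaserParams(), gains,
    setpoint=43.0, cfg=SolveConfig(dt=0.5, t_end=900.0, scheme="crank-nicolson"),
)
m = compute_step_metrics(trace)
print(f"\nscheduled gains at unseen condition: kp={gains.kp:.1f}, "
      f"ki={gains.ki:.1f}, kd={gains.kd:.1f}")
print(f"closed-loop final temperature: {m.final_value:.4f} C, "
      f"overshoot {m.mo:.2f} %, steady error {m.ess:.2e} C")
print("\nThe scheduler interpolates the tuned optima, so the controller")
print("re-tunes itself for a patient whose perfusions cannot be measured.")
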