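"""PID tuning with the imperialist competitive algorithm.

Minimises the step-response cost (overshoot + rise time + settling time +
steady error) over the gain box for one plant condition.  Takes ~10 s.
"""

from hypertherm import ICAConfig
from hypertherm.tuning import PlantCondition, make_plant, tune_pid

phantom = make_plant(PlantCondition(gc_gland=2400.0, gc_fat=800.0, k=0.48))
gains, cost, history = tune_pid(
    phantom,
    ica_cfg=ICAConfig(n_countries=20, n_imperialists=4, max_iterations=20, seed=3),
)

print(f"tuned gains: kp={gains.kp:.1f}, ki={gains.ki:.1f}, kd={gains.kd:.1f}")
print(f"best cost  : {cost:.2f}  (sum of overshoot %, rise s, settling s, error C)")
print(f"cost history (every 4th iteration): "
      f"{[round(c, 1) for c in history[::4]]}")
print("\nThe history is non-increasing; the cost is dominated by the settling")
print("time of the ~minute-scale thermal transient.")
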