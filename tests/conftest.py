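"""Shared fixtures: phantoms, boundary sets, and the (expensive) trained scheduler."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hypertherm import (
    BoundaryConditions,
    ICAConfig,
    LaserParams,
    PhantomGeometry,
    build_phantom,
)
from hypertherm.scheduler import (
    LMSettings,
    generate_training_set,
    reduced_param_grid,
    train_mlp,
)
from hypertherm.tuning import PlantCondition, make_plant, tune_pid

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: small, fast ICA budget used everywhere a tuning is needed in tests
TEST_ICA = dict(n_countries=20, n_imperialists=4, max_iterations=20)


@pytest.fixture(scope="session")
def bc() -> BoundaryConditions:
    return BoundaryConditions()

@pytest.fixture(scope="session")
def laser() -> LaserParams:
    return LaserParams()


@pytest.fixture(scope="session")
def default_phantom():
    return build_phantom()


@pytest.fixture(scope="session")
def t1_phantom():
    """Default phantom with the reported random perfusion draw
    (gland 3357, fat 901.58 W/(m^3 C))."""
    return make_plant(PlantCondition(gc_gland=3357.0, gc_fat=901.58))


@pytest.fixture(scope="session")
def small_phantom():
    """A 5 mm fat/gland/tumour stack on a fine grid — fast to relax to
    steady state, used by the solver-oracle tests."""
    geom = PhantomGeometry(
        fat_depth=0.002,
        gland_depth=0.003,
        tumour_diameter=0.0016,
        tumour_centre_depth=0.0035,
        dx=1e-4,
    )
    return build_phantom(geom)


def tune_condition(cond: PlantCondition, seed: int):
    """One reduced-budget ICA tuning with the stall gate (shared helper)."""
    from hypertherm.tuning import tune_condition as _tune

    return _tune(cond, ica_cfg=ICAConfig(seed=seed, **TEST_ICA))


@pytest.fixture(scope="session")
def nominal_gains():
    """Fixed PID set: ICA-tuned once on the mean-parameter plant."""
    gains = tune_condition(PlantCondition(2400.0, 800.0, 0.48), seed=99)
    assert gains is not None
    return gains


def second_order_step(zeta: float, wn: float = 1.0, t_end: float = 40.0, n: int = 8000):
    """Analytic unit step response of a standard underdamped 2nd-order system."""
    t = np.linspace(0.0, t_end, n)
    wd = wn * np.sqrt(1 - zeta**2)
    phi = np.arccos(zeta)
    y = 1 - np.exp(-zeta * wn * t) / np.sqrt(1 - zeta**2) * np.sin(wd * t + phi)
    return t, y


def brute_force_metrics(t, y, sp, band=0.02, final_fraction=0.05):
    """Naive scan oracle for step metrics: plain loops, interpolated crossings."""
    y0 = y[0]
    mag = abs(sp - y0)
    s = 1.0 if sp > y0 else -1.0

    def cross(level):
        prev = s * (y[0] - y0)
        if prev >= level:
            return t[0]
        for i in range(1, len(y)):
            cur = s * (y[i] - y0)
            if cur >= level:
                f = (level - prev) / (cur - prev)
                return t[i - 1] + f * (t[i] - t[i - 1])
            prev = cur
        return None

    t10, t90 = cross(0.1 * mag), cross(0.9 * mag)
    tr = None if (t10 is None or t90 is None) else t90 - t10
    ts = None
    if abs(y[-1] - sp) <= band * mag:
        ts = t[0]
        for i in range(len(y) - 1, -1, -1):
            if abs(y[i] - sp) > band * mag:
                ts = t[i + 1]
                break
    peak = max(s * (v - y0) for v in y)
    mo = max(0.0, 100.0 * (peak - mag) / mag)
    n_tail = max(1, int(np.ceil(final_fraction * len(y))))
    final = float(np.mean(y[-n_tail:]))
    return tr, ts, mo, abs(sp - final), final


@pytest.fixture(scope="session")
def scheduler_bundle():
    """(training set, interpolating MLP) over the reduced tuning grid.

    This is the expensive fixture (one ICA tuning per grid point); it is
    built once per session and shared by the scheduler and comparison tests.
    """
    ts = generate_training_set(reduced_param_grid(), tune_condition, seed=1)
    model = train_mlp(ts, lm=LMSettings(val_fraction=0.0, max_epochs=300), seed=1)
    return ts, model
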