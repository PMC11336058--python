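"""Discrete PID control of the laser, closed-loop simulation and step metrics.

The controller measures the tumour-centre temperature, compares it with the
therapeutic setpoint (default 43 C — inside the 43-44 C window that kills
tumour cells while limiting damage to healthy tissue) and commands the
surface irradiance of the laser:

    u(t) = clamp( Kp e + Ki int e dt + Kd d(e_f)/dt ,  [u_min, u_max] )

with e = setpoint - measurement.  The derivative acts on a low-pass filtered
measurement (derivative-on-measurement, filter coefficient N) so that
setpoint steps do not kick the actuator, and the integrator is frozen while
the actuator is saturated in the direction of the error (clamping
anti-windup).  Actuator limits default to [0, 10000] W/m^2, covering the
highest power densities the loop needs under unfavourable parameter draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bioheat import BioheatModel, BoundaryConditions, SolveConfig
from .optics import LaserParams, laser_volumetric_heating, metabolic_heating
from .tissue import Phantom

DEFAULT_SETPOINT = 43.0
DEFAULT_LIMITS = (0.0, 10000.0)
SWEEP_LIMITS = (10.0, 3600.0)  # the open-loop power sweep range


@dataclass(frozen=True)
class PIDGains:
    """PID gains: kp (W/m^2 per C), ki (W/m^2 per C s), kd (W/m^2 per C/s)."""

    kp: float
    ki: float
    kd: float

    def __post_init__(self) -> None:
        for name in ("kp", "ki", "kd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"gain {name} must be finite and >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.kp, self.ki, self.kd])


@dataclass
class PIDState:
    """Mutable controller state carried between samples."""

    integral: float = 0.0
    prev_measurement: float | None = None
    deriv_filtered: float = 0.0
    limits: tuple[float, float] = DEFAULT_LIMITS
    filter_coeff: float = 10.0  # derivative filter N; pole at N*kp/kd rad/s

    def __post_init__(self) -> None:
        lo, hi = self.limits
        if lo > hi:
            raise ValueError(f"saturation limits inverted: {self.limits}")


def pid_step(
    gains: PIDGains,
    st: PIDState,
    setpoint: float,
    measurement: float,
    dt: float,
) -> tuple[float, PIDState]:
    """One controller sample: returns (clamped command, new state).

    The integral uses forward rectangles; the derivative is the filtered
    derivative of the measurement (sign-flipped), first sample zero.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    e = setpoint - measurement
    lo, hi = st.limits

    if st.prev_measurement is None:
        d_meas = 0.0
    else:
        d_meas = (measurement - st.prev_measurement) / dt
    # first-order filter with time constant Td/N (Td = kd/kp); falls back to
    # an unfiltered derivative when kp or kd is zero
    if gains.kp > 0 and gains.kd > 0:
        tf = gains.kd / (gains.kp * st.filter_coeff)
        alpha = dt / (tf + dt)
    else:
        alpha = 1.0
    d_f = st.deriv_filtered + alpha * (d_meas - st.deriv_filtered)

    integral_cand = st.integral + e * dt
    u_unsat = gains.kp * e + gains.ki * integral_cand - gains.kd * d_f
    u = float(np.clip(u_unsat, lo, hi))
    # clamping anti-windup: only accept the integral update when it does not
    # push further into saturation
    if (u_unsat > hi and e > 0) or (u_unsat < lo and e < 0):
        integral_cand = st.integral
        u = float(np.clip(gains.kp * e + gains.ki * integral_cand - gains.kd * d_f, lo, hi))
    new_state = replace(
        st, integral=integral_cand, prev_measurement=measurement, deriv_filtered=d_f
    )
    return u, new_state


@dataclass(frozen=True)
class ClosedLoopTrace:
    """Sampled closed-loop record: time, setpoint, measurement, command, saturation."""

    time: np.ndarray
    setpoint: np.ndarray
    temperature: np.ndarray
    irradiance: np.ndarray
    saturated: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("setpoint", "temperature", "irradiance", "saturated"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"trace column {name!r} length mismatch")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time,
                "setpoint_C": self.setpoint,
                "temperature_C": self.temperature,
                "irradiance_W_m2": self.irradiance,
                "saturated": self.saturated.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ClosedLoopTrace":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            time=df["time_s"].to_numpy(float),
            setpoint=df["setpoint_C"].to_numpy(float),
            temperature=df["temperature_C"].to_numpy(float),
            irradiance=df["irradiance_W_m2"].to_numpy(float),
            saturated=df["saturated"].to_numpy(bool),
        )


def run_closed_loop(
    phantom: Phantom,
    bc: BoundaryConditions,
    laser: LaserParams,
    gains: PIDGains,
    setpoint: float = DEFAULT_SETPOINT,
    cfg: SolveConfig | None = None,
    limits: tuple[float, float] = DEFAULT_LIMITS,
) -> ClosedLoopTrace:
    """Co-simulate plant and controller; the PID output at each sample sets
    the surface irradiance for the next plant step.

    The control sample time equals the solver time step.  The laser field is
    linear in the commanded irradiance, so a unit field is assembled once
    and scaled each sample.
    """
    cfg = cfg or SolveConfig(t_end=900.0, scheme="crank-nicolson", dt=0.5)
    model = BioheatModel(phantom, bc, cfg.perfusion_reference)
    if cfg.dt is None:
        dt = 0.8 * model.stable_dt() if cfg.scheme == "explicit" else 0.5
    else:
        dt = cfg.dt
        if cfg.scheme == "explicit" and dt > model.stable_dt():
            raise ValueError(
                f"dt={dt:g} exceeds the explicit stability bound {model.stable_dt():g} s"
            )
    q_unit = laser_volumetric_heating(1.0, phantom, laser)
    q_met = metabolic_heating(phantom)
    stepper = model.step_explicit if cfg.scheme == "explicit" else model.step_crank_nicolson

    T = np.full(phantom.n_nodes, cfg.initial_temperature, dtype=float)
    T[-1] = bc.core_temperature
    st = PIDState(limits=limits)
    n_steps = max(int(round(cfg.t_end / dt)), 1)
    # probe by interpolation weights, fixed grid
    depth = phantom.tumour_centre
    times = np.empty(n_steps + 1)
    temps = np.empty(n_steps + 1)
    cmds = np.empty(n_steps + 1)
    sats = np.zeros(n_steps + 1, dtype=bool)
    j = int(np.searchsorted(phantom.x, depth) - 1)
    j = min(max(j, 0), phantom.n_nodes - 2)
    w = (depth - phantom.x[j]) / (phantom.x[j + 1] - phantom.x[j])

    t = 0.0
    for i in range(n_steps + 1):
        y = float((1 - w) * T[j] + w * T[j + 1])
        u, st = pid_step(gains, st, setpoint, y, dt)
        times[i], temps[i], cmds[i] = t, y, u
        sats[i] = u <= limits[0] + 1e-12 or u >= limits[1] - 1e-12
        if i == n_steps:
            break
        T = stepper(T, q_met + u * q_unit, dt)
        t += dt
    return ClosedLoopTrace(
        time=times, setpoint=np.full(n_steps + 1, setpoint), temperature=temps,
        irradiance=cmds, saturated=sats,
    )


@dataclass(frozen=True)
class StepMetrics:
    """Standard step-response metrics.

    ``tr``: 10->90% rise time (s); ``ts``: 2%-band settling time (s);
    ``mo``: percent overshoot (>= 0); ``ess``: |setpoint - final| (C);
    ``final_value``: mean of the last 5% of samples (C).  ``tr``/``ts`` are
    ``None`` when the response never reaches the corresponding threshold.
    """

    tr: float | None
    ts: float | None
    mo: float
    ess: float
    final_value: float

    def to_dict(self) -> dict:
        return {"tr": self.tr, "ts": self.ts, "mo": self.mo, "ess": self.ess,
                "final_value": self.final_value}


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """First time y reaches ``level`` (linear interpolation between samples)."""
    if y[0] >= level:
        return float(t[0])
    idx = np.nonzero(y >= level)[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    frac = (level - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def compute_step_metrics(
    trace: ClosedLoopTrace | tuple[np.ndarray, np.ndarray],
    setpoint: float | None = None,
    settle_band: float = 0.02,
    final_fraction: float = 0.05,
) -> StepMetrics:
    """Extract step-response metrics from a closed-loop trace or a (t, y) pair.

    All thresholds are fractions of the commanded step size
    |setpoint - initial value|: rise time is measured 10% -> 90%, settling
    within a ±2% band around the setpoint, overshoot relative to the step
    size and floored at zero.
    """
    if isinstance(trace, ClosedLoopTrace):
        t, y = trace.time, trace.temperature
        sp = float(trace.setpoint[-1]) if setpoint is None else float(setpoint)
    else:
        t, y = np.asarray(trace[0], float), np.asarray(trace[1], float)
        if setpoint is None:
            raise ValueError("setpoint required for a bare (t, y) trace")
        sp = float(setpoint)
    if len(t) == 0:
        raise ValueError("empty response trace")
    y0 = float(y[0])
    step_size = sp - y0
    if step_size == 0:
        raise ValueError("setpoint equals the initial value; step metrics undefined")
    sign = np.sign(step_size)
    yn = sign * (y - y0)  # normalised upward response
    mag = abs(step_size)

    t10 = _first_crossing(t, yn, 0.10 * mag)
    t90 = _first_crossing(t, yn, 0.90 * mag)
    tr = (t90 - t10) if (t10 is not None and t90 is not None) else None

    inside = np.abs(y - sp) <= settle_band * mag
    ts = None
    if inside[-1]:
        outside = np.nonzero(~inside)[0]
        ts = float(t[0]) if len(outside) == 0 else float(t[outside[-1] + 1])

    peak = float(yn.max())
    mo = max(0.0, 100.0 * (peak - mag) / mag)

    n_tail = max(1, int(np.ceil(final_fraction * len(y))))
    final_value = float(np.mean(y[-n_tail:]))
    ess = abs(sp - final_value)
    return StepMetrics(tr=tr, ts=ts, mo=mo, ess=ess, final_value=final_value)


def cost_function(
    m: StepMetrics,
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    undefined_penalty: float = 1e3,
) -> float:
    """Scalar tuning cost: w1*mo + w2*tr + w3*ts + w4*ess.

    The default unit weights make the cost the plain sum of the four
    metrics; an undefined rise/settling time contributes
    ``undefined_penalty`` instead.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (4,) or (w < 0).any():
        raise ValueError(f"weights must be 4 non-negative reals, got {weights!r}")
    tr = m.tr if m.tr is not None else undefined_penalty
    ts = m.ts if m.ts is not None else undefined_penalty
    return float(w[0] * m.mo + w[1] * tr + w[2] * ts + w[3] * m.ess)
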