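"""Neural-network gain scheduling: an MLP maps plant parameters to PID gains.

The scheduler learns the map from the uncertain physiological parameters
(gland perfusion, fat perfusion, thermal conductivity) to the ICA-optimal
PID gains, so the controller can re-tune itself online for a patient whose
blood-dependent parameters cannot be measured.  Architecture: one hidden
layer of 20 logistic-sigmoid neurons, linear output layer (3 outputs for
kp, ki, kd; an optional padded 5-output mode exists for compatibility with
hardware that expects five channels).  Training minimises the sum of
squared errors with a hand-rolled Levenberg-Marquardt loop
((J^T J + lambda I) dw = -J^T r, lambda scaled x10 on a rejected step and
/10 on an accepted one), on inputs and targets min-max scaled to [-1, 1].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .control import PIDGains
from .ica import DEFAULT_GAIN_BOUNDS
from .tuning import PlantCondition

logger = logging.getLogger(__name__)


# -- training data -----------------------------------------------------------


@dataclass(frozen=True)
class GainTrainingSet:
    """Rows of plant conditions and the PID gains tuned for them.

    ``inputs``: (n, 3) array of (gland perfusion, fat perfusion, thermal
    conductivity) in native units; ``targets``: (n, n_out) array of
    (kp, ki, kd[, 0, 0]).
    """

    inputs: np.ndarray
    targets: np.ndarray

    def __post_init__(self) -> None:
        if len(self.inputs) != len(self.targets):
            raise ValueError("inputs and targets row counts differ")

    @property
    def n_rows(self) -> int:
        return len(self.inputs)

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = ["gc_gland", "gc_fat", "k"]
        tcols = ["kp", "ki", "kd"] + [f"pad{i}" for i in range(self.targets.shape[1] - 3)]
        df = pd.DataFrame(np.hstack([self.inputs, self.targets]), columns=cols + tcols)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GainTrainingSet":
        import pandas as pd

        df = pd.read_csv(path)
        ins = df[["gc_gland", "gc_fat", "k"]].to_numpy(float)
        tcols = [c for c in df.columns if c not in ("gc_gland", "gc_fat", "k")]
        return cls(inputs=ins, targets=df[tcols].to_numpy(float))


def default_param_grid() -> list[PlantCondition]:
    """The full tuning grid: gland perfusion 800:400:3600, fat perfusion
    {800, 1000, 1200, 1400, 1600}, conductivity {0.2, 0.3, 0.4, 0.5, 0.6}
    — 200 conditions."""
    glands = np.arange(800.0, 3600.0 + 1, 400.0)
    fats = np.arange(800.0, 1600.0 + 1, 200.0)
    ks = np.arange(0.2, 0.6 + 1e-9, 0.1)
    return [
        PlantCondition(gc_gland=float(g), gc_fat=float(f), k=round(float(k), 10))
        for g in glands
        for f in fats
        for k in ks
    ]


def reduced_param_grid() -> list[PlantCondition]:
    """A coarse 4 x 3 x 2 sub-grid spanning the same ranges (24 tunings),
    the default for end-to-end runs on one CPU."""
    glands = [800.0, 1700.0, 2600.0, 3600.0]
    fats = [800.0, 1200.0, 1600.0]
    ks = [0.2, 0.6]
    return [PlantCondition(g, f, k) for g in glands for f in fats for k in ks]


def generate_training_set(
    param_grid: Sequence[PlantCondition],
    tuner: Callable[[PlantCondition, int], PIDGains | None],
    seed: int = 0,
    n_outputs: int = 3,
) -> GainTrainingSet:
    """Run one tuning per grid point and collect (condition, gains) rows.

    ``tuner(cond, seed)`` returns the tuned :class:`PIDGains` for one plant
    condition (or ``None`` on failure, in which case the row is skipped and
    logged).  Per-point seeds are derived deterministically from ``seed``,
    so identical seeds give identical training sets.
    """
    if len(param_grid) == 0:
        raise ValueError("empty parameter grid")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(param_grid))]
    rows_in, rows_out = [], []
    for cond, s in zip(param_grid, child_seeds):
        try:
            gains = tuner(cond, s)
        except Exception as exc:  # tuning failure: skip the grid point
            logger.warning("tuning failed at %s: %s", cond, exc)
            gains = None
        if gains is None:
            logger.warning("skipping grid point %s (no gains)", cond)
            continue
        rows_in.append(cond.as_array())
        out = gains.as_array()
        if n_outputs > 3:
            out = np.concatenate([out, np.zeros(n_outputs - 3)])
        rows_out.append(out)
    return GainTrainingSet(inputs=np.array(rows_in), targets=np.array(rows_out))


# -- the MLP -----------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class MLPModel:
    """n_in -> hidden (sigmoid) -> n_out (linear) perceptron with min-max scaling."""

    w1: np.ndarray  # (hidden, n_in)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (n_out, hidden)
    b2: np.ndarray  # (n_out,)
    in_lo: np.ndarray
    in_hi: np.ndarray
    out_lo: np.ndarray
    out_hi: np.ndarray
    train_sse: float = np.nan  # final scaled-space training SSE

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        return (self.w1.shape[1], self.w1.shape[0], self.w2.shape[0])

    def _scale_in(self, x: np.ndarray) -> np.ndarray:
        span = np.where(self.in_hi > self.in_lo, self.in_hi - self.in_lo, 1.0)
        return 2.0 * (x - self.in_lo) / span - 1.0

    def _unscale_out(self, y: np.ndarray) -> np.ndarray:
        # a zero-width target range is a constant output: return it exactly
        span = self.out_hi - self.out_lo
        return np.where(span > 0, (y + 1.0) / 2.0 * span + self.out_lo, self.out_lo)

    def forward_scaled(self, xs: np.ndarray) -> np.ndarray:
        """Forward pass in scaled space; xs is (n, n_in)."""
        a1 = _sigmoid(xs @ self.w1.T + self.b1)
        return a1 @ self.w2.T + self.b2

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Native-units prediction for (n, n_in) or a single (n_in,) vector."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.w1.shape[1]:
            raise ValueError(
                f"expected {self.w1.shape[1]} input features, got {x.shape[1]}"
            )
        y = self._unscale_out(self.forward_scaled(self._scale_in(x)))
        return y[0] if y.shape[0] == 1 else y

    def to_json(self, path=None) -> str:
        d = {
            "layer_sizes": list(self.layer_sizes),
            "w1": self.w1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2.tolist(),
            "in_lo": self.in_lo.tolist(), "in_hi": self.in_hi.tolist(),
            "out_lo": self.out_lo.tolist(), "out_hi": self.out_hi.tolist(),
            "train_sse": None if np.isnan(self.train_sse) else self.train_sse,
        }
        s = json.dumps(d, indent=1)
        if path is not None:
            with open(path, "w") as f:
                f.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "MLPModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as f:
                d = json.load(f)
        return cls(
            w1=np.array(d["w1"]), b1=np.array(d["b1"]),
            w2=np.array(d["w2"]), b2=np.array(d["b2"]),
            in_lo=np.array(d["in_lo"]), in_hi=np.array(d["in_hi"]),
            out_lo=np.array(d["out_lo"]), out_hi=np.array(d["out_hi"]),
            train_sse=d["train_sse"] if d["train_sse"] is not None else np.nan,
        )


def _pack(w1, b1, w2, b2) -> np.ndarray:
    return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])


def _unpack(w: np.ndarray, n_in: int, n_h: int, n_out: int):
    i = 0
    w1 = w[i : i + n_h * n_in].reshape(n_h, n_in); i += n_h * n_in
    b1 = w[i : i + n_h]; i += n_h
    w2 = w[i : i + n_out * n_h].reshape(n_out, n_h); i += n_out * n_h
    b2 = w[i : i + n_out]
    return w1, b1, w2, b2


def _residual_jacobian(w, xs, ys, n_in, n_h, n_out):
    """Residuals r = pred - target (flattened) and the analytic Jacobian."""
    w1, b1, w2, b2 = _unpack(w, n_in, n_h, n_out)
    n = len(xs)
    z1 = xs @ w1.T + b1
    a1 = _sigmoid(z1)
    pred = a1 @ w2.T + b2
    r = (pred - ys).ravel()

    sp = a1 * (1.0 - a1)  # sigmoid'
    J = np.zeros((n * n_out, len(w)))
    # d pred[s,o] / d w1[h,i] = w2[o,h] sp[s,h] x[s,i]
    dW1 = np.einsum("oh,sh,si->sohi", w2, sp, xs)
    J[:, : n_h * n_in] = dW1.reshape(n * n_out, n_h * n_in)
    # d/d b1[h] = w2[o,h] sp[s,h]
    J[:, n_h * n_in : n_h * n_in + n_h] = np.einsum("oh,sh->soh", w2, sp).reshape(
        n * n_out, n_h
    )
    # d/d w2[o,h] = a1[s,h] (only for matching o)
    off = n_h * n_in + n_h
    eye_o = np.eye(n_out)
    dW2 = np.einsum("po,sh->spoh", eye_o, a1).reshape(n * n_out, n_out * n_h)
    J[:, off : off + n_out * n_h] = dW2
    # d/d b2[o]
    off += n_out * n_h
    J[:, off:] = np.tile(eye_o, (n, 1))
    return r, J


@dataclass(frozen=True)
class LMSettings:
    """Levenberg-Marquardt knobs: initial damping, adaptation factor,
    stopping tolerances and epoch cap; validation early stopping applies
    only when the training set is large enough to spare rows."""

    lambda0: float = 1e-3
    factor: float = 10.0
    gtol: float = 1e-9
    lambda_max: float = 1e10
    max_epochs: int = 200
    val_fraction: float = 0.15  # 0 disables validation early stopping
    patience: int = 6
    min_rows_for_validation: int = 10


def train_mlp(
    ts: GainTrainingSet,
    hidden: int = 20,
    lm: LMSettings | None = None,
    seed: int = 0,
) -> MLPModel:
    """Fit the gain-scheduling MLP to ``ts`` by Levenberg-Marquardt.

    Deterministic under ``seed`` (weight initialisation and the optional
    train/validation split).  Accepted LM steps never increase the training
    sum of squares, so the final SSE is <= the initial one.
    """
    lm = lm or LMSettings()
    rng = np.random.default_rng(seed)
    X = np.atleast_2d(np.asarray(ts.inputs, dtype=float))
    Y = np.atleast_2d(np.asarray(ts.targets, dtype=float))
    n, n_in = X.shape
    n_out = Y.shape[1]

    in_lo, in_hi = X.min(axis=0), X.max(axis=0)
    out_lo, out_hi = Y.min(axis=0), Y.max(axis=0)
    span_in = np.where(in_hi > in_lo, in_hi - in_lo, 1.0)
    span_out = np.where(out_hi > out_lo, out_hi - out_lo, 1.0)
    Xs = 2.0 * (X - in_lo) / span_in - 1.0
    Ys = 2.0 * (Y - out_lo) / span_out - 1.0

    # train/validation split (only when enabled and the set can spare rows)
    use_val = lm.val_fraction > 0 and n >= lm.min_rows_for_validation
    if use_val:
        perm = rng.permutation(n)
        n_val = max(1, int(round(lm.val_fraction * n)))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
    else:
        tr_idx = np.arange(n)
        val_idx = np.array([], dtype=int)
    Xt, Yt = Xs[tr_idx], Ys[tr_idx]

    w = rng.uniform(-0.5, 0.5, size=hidden * n_in + hidden + n_out * hidden + n_out)
    lam = lm.lambda0
    r, J = _residual_jacobian(w, Xt, Yt, n_in, hidden, n_out)
    sse = float(r @ r)
    best_val, best_w, stale = np.inf, w.copy(), 0

    for _ in range(lm.max_epochs):
        g = J.T @ r
        if np.max(np.abs(g)) < lm.gtol:
            break
        JtJ = J.T @ J
        accepted = False
        while lam <= lm.lambda_max:
            try:
                dw = np.linalg.solve(JtJ + lam * np.eye(len(w)), -g)
            except np.linalg.LinAlgError:
                lam *= lm.factor
                continue
            w_try = w + dw
            r_try, J_try = _residual_jacobian(w_try, Xt, Yt, n_in, hidden, n_out)
            sse_try = float(r_try @ r_try)
            if np.isfinite(sse_try) and sse_try < sse:
                w, r, J, sse = w_try, r_try, J_try, sse_try
                lam = max(lam / lm.factor, 1e-15)
                accepted = True
                break
            lam *= lm.factor
        if not accepted:
            break
        if use_val:
            w1, b1, w2, b2 = _unpack(w, n_in, hidden, n_out)
            pv = _sigmoid(Xs[val_idx] @ w1.T + b1) @ w2.T + b2
            val_sse = float(np.sum((pv - Ys[val_idx]) ** 2))
            if val_sse < best_val - 1e-12:
                best_val, best_w, stale = val_sse, w.copy(), 0
            else:
                stale += 1
                if stale >= lm.patience:
                    w = best_w
                    break

    w1, b1, w2, b2 = _unpack(w, n_in, hidden, n_out)
    # report SSE over the full (scaled) set for the returned weights
    pred = _sigmoid(Xs @ w1.T + b1) @ w2.T + b2
    final_sse = float(np.sum((pred - Ys) ** 2))
    return MLPModel(
        w1=w1, b1=b1, w2=w2, b2=b2,
        in_lo=in_lo, in_hi=in_hi, out_lo=out_lo, out_hi=out_hi,
        train_sse=final_sse,
    )


def predict_gains(
    model: MLPModel,
    params: PlantCondition | np.ndarray,
    bounds=DEFAULT_GAIN_BOUNDS,
) -> PIDGains:
    """Scheduled gains for one plant condition.

    The raw network output is clamped first to the envelope of gains seen
    during training (the scheduler interpolates between tuned optima and is
    never trusted to extrapolate beyond them — an exactly-interpolating
    network can swing far outside the target range between grid points) and
    then to the tuner's search box.
    """
    x = params.as_array() if isinstance(params, PlantCondition) else np.asarray(params, float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite scheduler inputs: {x!r}")
    y = model.predict(x)[:3]
    y = np.clip(y, model.out_lo[:3], model.out_hi[:3])
    b = np.asarray(bounds, dtype=float)
    y = np.clip(y, b[:, 0], b[:, 1])
    return PIDGains(kp=float(y[0]), ki=float(y[1]), kd=float(y[2]))
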