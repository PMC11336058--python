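"""Imperialist Competitive Algorithm (ICA) for PID gain tuning.

Standard Atashpaz-Gargari formulation: an initial population of "countries"
(candidate gain vectors) is split into empires — the best countries become
imperialists, the rest are distributed as colonies in proportion to
normalised imperialist power.  Each iteration colonies move toward their
imperialist (assimilation, with random angular deviation), a fraction are
re-drawn uniformly (revolution), a colony that beats its imperialist swaps
roles, and the weakest empire loses its weakest colony to a
roulette-selected winner (competition); empires with no colonies collapse.

Positions are kept inside the search box by reflection; non-finite costs
are treated as +inf.  Everything is reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

#: Default PID gain search box: kp, ki, kd.  The integral gain carries a
#: floor because the therapy requires steady tracking against the slow
#: background drift of poorly perfused tissue (multi-thousand-second
#: modes): the quasi-static tracking lag is drift-rate/(ki * plant gain),
#: and ki >= 200 keeps it below ~1 mK over the whole uncertainty box.  The
#: tuning cost alone cannot impose this — it contains near-optimal plateau
#: solutions with tiny ki whose residual lag it barely penalises.
DEFAULT_GAIN_BOUNDS = ((0.0, 2000.0), (200.0, 5000.0), (0.0, 500.0))


@dataclass(frozen=True)
class ICAConfig:
    """ICA hyperparameters — conventional values for the standard
    Atashpaz-Gargari formulation."""

    n_countries: int = 50
    n_imperialists: int = 8
    beta: float = 2.0  # assimilation coefficient
    gamma: float = np.pi / 4  # assimilation angular deviation (radians)
    revolution_rate: float = 0.3
    zeta: float = 0.1  # colony weight in empire total cost
    max_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_imperialists < self.n_countries:
            raise ValueError(
                f"need 1 <= n_imperialists < n_countries, got "
                f"{self.n_imperialists} / {self.n_countries}"
            )
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not 0.0 <= self.revolution_rate <= 1.0:
            raise ValueError(f"revolution rate must be in [0,1], got {self.revolution_rate}")
        if not 0.0 <= self.zeta <= 1.0:
            raise ValueError(f"zeta must be in [0,1], got {self.zeta}")


@dataclass
class Empire:
    """One empire: imperialist + colonies (positions are rows)."""

    imperialist: np.ndarray
    imperialist_cost: float
    colonies: np.ndarray  # (n_col, dim)
    colony_costs: np.ndarray

    def total_cost(self, zeta: float) -> float:
        if len(self.colony_costs) == 0:
            return float(self.imperialist_cost)
        finite = self.colony_costs[np.isfinite(self.colony_costs)]
        mean_col = float(finite.mean()) if len(finite) else self.imperialist_cost
        return float(self.imperialist_cost + zeta * mean_col)

    @property
    def size(self) -> int:
        return 1 + len(self.colony_costs)


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect out-of-box coordinates back inside [lo, hi]."""
    span = hi - lo
    y = np.where(span > 0, (x - lo) % (2 * span), 0.0)
    return lo + np.where(y > span, 2 * span - y, y)


def _safe_cost(cost_fn: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    v = cost_fn(x)
    return float(v) if np.isfinite(v) else np.inf


class ImperialistCompetitiveOptimizer:
    """Minimise ``cost_fn`` over a box via the imperialist competitive algorithm.

    The phase operations (:meth:`assimilate`, :meth:`revolve`,
    :meth:`compete`) mutate ``self.empires`` in place and are exposed so
    their contracts can be exercised directly.
    """

    def __init__(
        self,
        cost_fn: Callable[[np.ndarray], float],
        bounds: Sequence[tuple[float, float]] = DEFAULT_GAIN_BOUNDS,
        cfg: ICAConfig | None = None,
    ):
        self.cfg = cfg or ICAConfig()
        self.cost_fn = cost_fn
        b = np.asarray(bounds, dtype=float)
        if b.ndim != 2 or b.shape[1] != 2 or not np.all(np.isfinite(b)):
            raise ValueError("bounds must be a finite sequence of (lo, hi) pairs")
        if (b[:, 0] > b[:, 1]).any():
            raise ValueError("bounds with lo > hi")
        self.lo, self.hi = b[:, 0], b[:, 1]
        self.dim = len(b)
        self.rng = np.random.default_rng(self.cfg.seed)
        self.empires: list[Empire] = []
        self.best_position: np.ndarray | None = None
        self.best_cost = np.inf
        self.history: list[float] = []
        self._init_empires()

    # -- initialisation ------------------------------------------------------

    def _init_empires(self) -> None:
        cfg = self.cfg
        pos = self.rng.uniform(self.lo, self.hi, size=(cfg.n_countries, self.dim))
        costs = np.array([_safe_cost(self.cost_fn, p) for p in pos])
        order = np.argsort(costs, kind="stable")
        pos, costs = pos[order], costs[order]
        n_imp = cfg.n_imperialists
        imp_costs = costs[:n_imp]
        # normalised power: share of colonies per imperialist
        ref = imp_costs.max()
        finite = imp_costs[np.isfinite(imp_costs)]
        span = ref - imp_costs if np.isfinite(ref) else np.ones(n_imp)
        power = span + 1e-12
        power = power / power.sum()
        n_col_total = cfg.n_countries - n_imp
        counts = np.floor(power * n_col_total).astype(int)
        while counts.sum() < n_col_total:  # distribute the remainder to the strongest
            counts[np.argmax(power - counts / max(n_col_total, 1))] += 1
        idx = n_imp
        self.empires = []
        for i in range(n_imp):
            c = counts[i]
            self.empires.append(
                Empire(
                    imperialist=pos[i].copy(),
                    imperialist_cost=float(costs[i]),
                    colonies=pos[idx : idx + c].copy(),
                    colony_costs=costs[idx : idx + c].copy(),
                )
            )
            idx += c
        self._update_best()
        self.history.append(self.best_cost)

    def _update_best(self) -> None:
        for e in self.empires:
            if e.imperialist_cost < self.best_cost:
                self.best_cost = float(e.imperialist_cost)
                self.best_position = e.imperialist.copy()

    @property
    def population_size(self) -> int:
        return sum(e.size for e in self.empires)

    # -- phase operations ----------------------------------------------------

    def assimilate(self) -> None:
        """Move every colony a uniform(0, beta) fraction of the way to its
        imperialist, with a random deviation orthogonal in expectation."""
        cfg = self.cfg
        for e in self.empires:
            if len(e.colony_costs) == 0:
                continue
            d = e.imperialist - e.colonies
            lam = self.rng.uniform(0.0, cfg.beta, size=(len(d), 1))
            move = lam * d
            if cfg.gamma > 0 and self.dim > 1:
                # rotate each step by a random angle in (-gamma, gamma):
                # add an orthogonal component of magnitude ||move|| tan(theta)
                theta = self.rng.uniform(-cfg.gamma, cfg.gamma, size=(len(d), 1))
                u = self.rng.normal(size=d.shape)
                norm_m = np.linalg.norm(move, axis=1, keepdims=True)
                unit_m = np.divide(move, norm_m, out=np.zeros_like(move), where=norm_m > 0)
                u -= np.sum(u * unit_m, axis=1, keepdims=True) * unit_m
                norm_u = np.linalg.norm(u, axis=1, keepdims=True)
                u = np.divide(u, norm_u, out=np.zeros_like(u), where=norm_u > 0)
                move = move + np.tan(theta) * norm_m * u
            e.colonies = _reflect(e.colonies + move, self.lo, self.hi)
            e.colony_costs = np.array([_safe_cost(self.cost_fn, p) for p in e.colonies])

    def revolve(self) -> None:
        """Re-draw a ``revolution_rate`` fraction of each empire's colonies
        uniformly inside the bounds."""
        rate = self.cfg.revolution_rate
        if rate == 0:
            return
        for e in self.empires:
            n = len(e.colony_costs)
            if n == 0:
                continue
            n_rev = int(np.ceil(rate * n)) if rate > 0 else 0
            which = self.rng.choice(n, size=min(n_rev, n), replace=False)
            e.colonies[which] = self.rng.uniform(self.lo, self.hi, size=(len(which), self.dim))
            for i in which:
                e.colony_costs[i] = _safe_cost(self.cost_fn, e.colonies[i])

    def _swap_best_colonies(self) -> None:
        for e in self.empires:
            if len(e.colony_costs) == 0:
                continue
            i = int(np.argmin(e.colony_costs))
            if e.colony_costs[i] < e.imperialist_cost:
                e.colonies[i], e.imperialist = e.imperialist.copy(), e.colonies[i].copy()
                e.colony_costs[i], e.imperialist_cost = (
                    e.imperialist_cost,
                    float(e.colony_costs[i]),
                )

    def compete(self) -> None:
        """Transfer the weakest colony of the weakest empire to a winner
        drawn by normalised-power roulette; empty empires collapse."""
        if len(self.empires) < 2:
            return
        totals = np.array([e.total_cost(self.cfg.zeta) for e in self.empires])
        totals = np.where(np.isfinite(totals), totals, np.nanmax(totals[np.isfinite(totals)], initial=1.0) * 10)
        weakest = int(np.argmax(totals))
        w = self.empires[weakest]
        if len(w.colony_costs) == 0:
            # the whole empire collapses: its imperialist becomes a colony
            item, item_cost = w.imperialist, w.imperialist_cost
            self.empires.pop(weakest)
            totals = np.delete(totals, weakest)
        else:
            i = int(np.argmax(w.colony_costs))
            item, item_cost = w.colonies[i].copy(), float(w.colony_costs[i])
            keep = np.arange(len(w.colony_costs)) != i
            w.colonies, w.colony_costs = w.colonies[keep], w.colony_costs[keep]
        # roulette over normalised powers; ties broken toward the lower index
        power = totals.max() - totals + 1e-12
        p = power / power.sum()
        winner = int(self.rng.choice(len(self.empires), p=p))
        tgt = self.empires[winner]
        tgt.colonies = np.vstack([tgt.colonies, item]) if tgt.colonies.size else item[None, :]
        tgt.colony_costs = np.append(tgt.colony_costs, item_cost)

    # -- main loop -----------------------------------------------------------

    def run(self) -> tuple[np.ndarray, float, list[float]]:
        for _ in range(self.cfg.max_iterations):
            self.assimilate()
            self.revolve()
            self._swap_best_colonies()
            self.compete()
            self._update_best()
            self.history.append(self.best_cost)
            if len(self.empires) == 1 and len(self.empires[0].colony_costs) == 0:
                break
        assert self.best_position is not None
        return self.best_position.copy(), self.best_cost, list(self.history)


def optimize(
    cost_fn: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]] = DEFAULT_GAIN_BOUNDS,
    cfg: ICAConfig | None = None,
) -> tuple[np.ndarray, float, list[float]]:
    """Convenience wrapper: run the ICA and return (best x, best cost, history).

    The best-cost history is the running minimum and therefore
    non-increasing; identical seeds give identical runs.
    """
    return ImperialistCompetitiveOptimizer(cost_fn, bounds, cfg).run()
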