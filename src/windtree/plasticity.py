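"""Growth-strategy optimization: thigmomorphogenesis as constrained fitness
maximization.

The tree's reaction to wind is modelled as the choice of a single
secondary-growth sink parameter ``S_layer`` maximizing two objectives -
final tree height H_tree and standing stem biomass Q_stem - subject to the
trunk never breaking over the growth horizon.  The bi-objective problem is
solved with NSGA-II (real-coded SBX crossover, polynomial mutation,
constraint-domination: feasible individuals always dominate infeasible
ones).  Because the simulator is deterministic, fitness evaluations are
cached; the optimizer's seed is the only source of randomness.

From the resulting Pareto front three strategies are read off: I - the
shortest/heaviest tree (max Q_stem), III - the tallest/lightest (max
H_tree), and II - the front member closest to the front's mean objective
vector (a height/weight compromise).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import harness


@dataclass
class PlasticityProblem:
    wind_speed: float  # m/s
    horizon: int = 8
    s_layer_bounds: tuple[float, float] = (0.1, 20.0)
    base_config: harness.SimConfig | None = None

    def __post_init__(self) -> None:
        lo, hi = self.s_layer_bounds
        if not (0 < lo < hi):
            raise ValueError("s_layer bounds must be positive and ordered")
        if self.base_config is None:
            self.base_config = harness.make_fixtures("poplar_preset")


@dataclass
class Nsga2Settings:
    pop_size: int = 100
    generations: int = 100
    crossover_prob: float = 0.7
    mutation_prob: float = 0.4
    eta_crossover: float = 15.0
    eta_mutation: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class ParetoPoint:
    s_layer: float
    H_tree: float  # m
    Q_stem: float  # kg
    feasible: bool


# ---------------------------------------------------------------------------
# candidate evaluation


def evaluate_candidate(
    s_layer: float,
    problem: PlasticityProblem,
    cache: dict | None = None,
) -> tuple[float, float, bool]:
    """Grow a tree with the given ``S_layer`` under the problem's wind.

    Returns (H_tree m, Q_stem kg, feasible); feasible is False as soon as the
    trunk breaks in any cycle, regardless of later regrowth.  A numerical
    failure of the simulation marks the candidate infeasible.
    """
    key = (round(float(s_layer), 9), problem.wind_speed, problem.horizon)
    if cache is not None and key in cache:
        return cache[key]
    cfg = problem.base_config.with_wind(problem.wind_speed).with_s_layer(float(s_layer))
    cfg.horizon = problem.horizon
    try:
        traj = harness.run_simulation(cfg)
        feasible = not any(rep.trunk_broken for rep in traj.cycles)
        final = traj.final
        h = final.H_tree if final else 0.0
        q = final.Q_stem if final else 0.0
        result = (h, q, feasible)
    except Exception as exc:  # noqa: BLE001 - diagnostic, not fatal
        warnings.warn(f"simulation failed for S_layer={s_layer}: {exc}")
        result = (0.0, 0.0, False)
    if cache is not None:
        cache[key] = result
    return result


# ---------------------------------------------------------------------------
# generic real-coded NSGA-II (minimization)


def _dominates(f_a, cv_a, f_b, cv_b) -> bool:
    """Constraint-domination: feasible beats infeasible; among infeasible the
    smaller violation wins; among feasible, Pareto dominance."""
    if cv_a == 0.0 and cv_b > 0.0:
        return True
    if cv_a > 0.0 and cv_b == 0.0:
        return False
    if cv_a > 0.0 and cv_b > 0.0:
        return cv_a < cv_b
    return all(a <= b for a, b in zip(f_a, f_b)) and any(a < b for a, b in zip(f_a, f_b))


def _fast_nondominated_sort(objs, cvs) -> list[list[int]]:
    n = len(objs)
    S = [[] for _ in range(n)]
    counts = [0] * n
    fronts: list[list[int]] = [[]]
    for p in range(n):
        for q in range(n):
            if p == q:
                continue
            if _dominates(objs[p], cvs[p], objs[q], cvs[q]):
                S[p].append(q)
            elif _dominates(objs[q], cvs[q], objs[p], cvs[p]):
                counts[p] += 1
        if counts[p] == 0:
            fronts[0].append(p)
    i = 0
    while fronts[i]:
        nxt: list[int] = []
        for p in fronts[i]:
            for q in S[p]:
                counts[q] -= 1
                if counts[q] == 0:
                    nxt.append(q)
        i += 1
        fronts.append(nxt)
    return fronts[:-1]


def _crowding_distance(objs: np.ndarray, front: list[int]) -> np.ndarray:
    dist = np.zeros(len(front))
    if len(front) <= 2:
        dist[:] = np.inf
        return dist
    f = objs[front]
    for m in range(f.shape[1]):
        order = np.argsort(f[:, m], kind="stable")
        span = f[order[-1], m] - f[order[0], m]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span <= 0:
            continue
        for k in range(1, len(front) - 1):
            dist[order[k]] += (f[order[k + 1], m] - f[order[k - 1], m]) / span
    return dist


def _sbx_pair(a, b, lo, hi, eta, rng):
    if abs(a - b) < 1e-14:
        return a, b
    x1, x2 = min(a, b), max(a, b)
    u = rng.random()
    beta = 1.0 + 2.0 * (x1 - lo) / (x2 - x1)
    alpha = 2.0 - beta ** (-(eta + 1.0))
    beta_q = (u * alpha) ** (1.0 / (eta + 1.0)) if u <= 1.0 / alpha else (
        1.0 / (2.0 - u * alpha)
    ) ** (1.0 / (eta + 1.0))
    c1 = 0.5 * ((x1 + x2) - beta_q * (x2 - x1))
    beta = 1.0 + 2.0 * (hi - x2) / (x2 - x1)
    alpha = 2.0 - beta ** (-(eta + 1.0))
    beta_q = (u * alpha) ** (1.0 / (eta + 1.0)) if u <= 1.0 / alpha else (
        1.0 / (2.0 - u * alpha)
    ) ** (1.0 / (eta + 1.0))
    c2 = 0.5 * ((x1 + x2) + beta_q * (x2 - x1))
    c1 = min(max(c1, lo), hi)
    c2 = min(max(c2, lo), hi)
    if rng.random() < 0.5:
        c1, c2 = c2, c1
    return c1, c2


def _poly_mutate(x, lo, hi, eta, rng):
    u = rng.random()
    if u < 0.5:
        delta = (2.0 * u) ** (1.0 / (eta + 1.0)) - 1.0
        return min(max(x + delta * (x - lo), lo), hi)
    delta = 1.0 - (2.0 * (1.0 - u)) ** (1.0 / (eta + 1.0))
    return min(max(x + delta * (hi - x), lo), hi)


def nsga2_minimize(
    evaluate: Callable[[float], tuple[Sequence[float], float]],
    bounds: tuple[float, float],
    settings: Nsga2Settings,
) -> list[tuple[float, tuple[float, ...], float]]:
    """NSGA-II over one real decision variable.

    ``evaluate(x)`` returns (objective tuple to minimize, constraint
    violation >= 0).  Returns the final population's first non-dominated
    front as (x, objectives, violation) tuples, reproducible given the seed.
    """
    rng = np.random.default_rng(settings.seed)
    lo, hi = bounds
    xs = list(rng.uniform(lo, hi, settings.pop_size))
    evals = [evaluate(x) for x in xs]

    def rank_and_crowd(xs_all, evals_all):
        objs = np.array([tuple(f) for f, _ in evals_all], dtype=float)
        cvs = [cv for _, cv in evals_all]
        fronts = _fast_nondominated_sort(objs, cvs)
        rank = np.empty(len(xs_all), dtype=int)
        crowd = np.empty(len(xs_all))
        for r, front in enumerate(fronts):
            rank[front] = r
            crowd[front] = _crowding_distance(objs, front)
        return fronts, rank, crowd

    fronts, rank, crowd = rank_and_crowd(xs, evals)
    for _ in range(settings.generations):
        # binary tournaments -> mating pool
        def pick() -> int:
            i, j = rng.integers(0, len(xs), 2)
            if rank[i] != rank[j]:
                return i if rank[i] < rank[j] else j
            if crowd[i] != crowd[j]:
                return i if crowd[i] > crowd[j] else j
            return i
        children: list[float] = []
        while len(children) < settings.pop_size:
            p1, p2 = xs[pick()], xs[pick()]
            if rng.random() < settings.crossover_prob:
                c1, c2 = _sbx_pair(p1, p2, lo, hi, settings.eta_crossover, rng)
            else:
                c1, c2 = p1, p2
            for c in (c1, c2):
                if rng.random() < settings.mutation_prob:
                    c = _poly_mutate(c, lo, hi, settings.eta_mutation, rng)
                children.append(c)
        children = children[: settings.pop_size]
        child_evals = [evaluate(x) for x in children]
        xs_all = xs + children
        evals_all = evals + child_evals
        fronts, rank_all, crowd_all = rank_and_crowd(xs_all, evals_all)
        # environmental selection
        chosen: list[int] = []
        for front in fronts:
            if len(chosen) + len(front) <= settings.pop_size:
                chosen.extend(front)
            else:
                by_crowd = sorted(front, key=lambda i: -crowd_all[i])
                chosen.extend(by_crowd[: settings.pop_size - len(chosen)])
                break
        xs = [xs_all[i] for i in chosen]
        evals = [evals_all[i] for i in chosen]
        fronts, rank, crowd = rank_and_crowd(xs, evals)
    first = fronts[0] if fronts else []
    return [(xs[i], tuple(evals[i][0]), evals[i][1]) for i in first]


# ---------------------------------------------------------------------------
# the plasticity problem proper


def nsga2_optimize(
    problem: PlasticityProblem,
    settings: Nsga2Settings,
    cache: dict | None = None,
) -> list[ParetoPoint]:
    """Maximize (H_tree, Q_stem) over S_layer under the no-trunk-breakage
    constraint; returns the feasible non-dominated set (may be empty).

    The decision variable is searched on a log scale: S_layer is a
    sink-strength ratio spanning two decades, and biologically relevant
    optima sit in its lowest decade.
    """
    if cache is None:
        cache = {}

    def evaluate(x: float):
        h, q, feasible = evaluate_candidate(math.exp(x), problem, cache)
        return (-h, -q), 0.0 if feasible else 1.0

    lo, hi = problem.s_layer_bounds
    raw = nsga2_minimize(evaluate, (math.log(lo), math.log(hi)), settings)
    front = [
        ParetoPoint(s_layer=math.exp(x), H_tree=-f[0], Q_stem=-f[1], feasible=cv == 0.0)
        for x, f, cv in raw
        if cv == 0.0
    ]
    if not front:
        warnings.warn("no feasible individual survived; empty Pareto front")
        return []
    # deduplicate identical decision values
    seen: dict[float, ParetoPoint] = {}
    for pt in front:
        seen.setdefault(round(pt.s_layer, 9), pt)
    return sorted(seen.values(), key=lambda p: p.s_layer)


def select_strategies(front: list[ParetoPoint]) -> dict[str, ParetoPoint]:
    """Read strategies I (max Q_stem), II (nearest the front mean), III
    (max H_tree) off a Pareto front; ties favour the smaller s_layer."""
    if not front:
        raise ValueError("empty Pareto front")
    s1 = max(front, key=lambda p: (p.Q_stem, -p.s_layer))
    s3 = max(front, key=lambda p: (p.H_tree, -p.s_layer))
    h = np.array([p.H_tree for p in front])
    q = np.array([p.Q_stem for p in front])
    h_span = h.max() - h.min()
    q_span = q.max() - q.min()
    hn = (h - h.min()) / h_span if h_span > 0 else np.zeros_like(h)
    qn = (q - q.min()) / q_span if q_span > 0 else np.zeros_like(q)
    d2 = (hn - hn.mean()) ** 2 + (qn - qn.mean()) ** 2
    order = sorted(range(len(front)), key=lambda i: (d2[i], front[i].s_layer))
    s2 = front[order[0]]
    return {"I": s1, "II": s2, "III": s3}


def front_percentiles(front: list[ParetoPoint]) -> dict[str, float]:
    """Box-plot summary of the front's s_layer values."""
    s = np.array([p.s_layer for p in front])
    return {
        "min": float(s.min()),
        "p10": float(np.percentile(s, 10)),
        "p25": float(np.percentile(s, 25)),
        "p50": float(np.percentile(s, 50)),
        "p75": float(np.percentile(s, 75)),
        "p90": float(np.percentile(s, 90)),
        "max": float(s.max()),
    }


def hypervolume_2d(points: np.ndarray, ref: tuple[float, float]) -> float:
    """Hypervolume (minimization, 2 objectives) dominated by ``points``
    relative to the reference point."""
    pts = np.asarray(points, dtype=float)
    pts = pts[(pts[:, 0] <= ref[0]) & (pts[:, 1] <= ref[1])]
    if len(pts) == 0:
        return 0.0
    pts = pts[np.argsort(pts[:, 0], kind="stable")]
    # keep the non-dominated staircase, then integrate rectangle by rectangle
    stairs: list[tuple[float, float]] = []
    best = math.inf
    for x, y in pts:
        if y < best:
            stairs.append((float(x), float(y)))
            best = y
    hv = 0.0
    for i, (x, y) in enumerate(stairs):
        x_next = stairs[i + 1][0] if i + 1 < len(stairs) else ref[0]
        hv += (x_next - x) * (ref[1] - y)
    return hv
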