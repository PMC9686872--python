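"""Longitudinal stress, stem breakage and the critical wind speed.

Breakage follows a brittle criterion: an internode fails as soon as the
peripheral longitudinal stress of its section,

    stress = 32 |M| / (pi d^3),

exceeds the modulus of rupture (MOR) of green wood, where M is the
resultant bending moment in the section plane and d the internode
diameter.  The most basal failing internode of an axis severs everything
distal to it (itself included).  Trunk breakage is treated as fatal for
the optimization constraint; branch breakage merely prunes the crown.

The critical wind speed (CWS) of a parameter set is the smallest steady
wind under which the trunk breaks at some point of the growth horizon,
found by a coarse scan refined by bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import structure
from .biomech import FlatTree, MechSolution
from .structure import Axis, Phytomer, Tree


class SingularSectionError(ValueError):
    pass


def longitudinal_stress(M: float, d: float) -> float:
    """Peripheral longitudinal stress (Pa) of a circular section.

    ``M`` is the resultant bending moment (N m) in the section plane and
    ``d`` the stem diameter (m).
    """
    if d <= 0:
        raise SingularSectionError("diameter must be positive")
    return 32.0 * abs(M) / (math.pi * d**3)


def segment_stresses(solution: MechSolution, include_solution_loads: bool = True) -> np.ndarray:
    """Stress (Pa) at the base section of every standing internode.

    Total internal moment = committed permanent state + (optionally) the
    current solve's increment; only the component perpendicular to the
    internode axis bends the section.
    """
    flat = solution.flat
    n = flat.n
    out = np.zeros(n)
    dirs = flat.rest_dir
    for i, ph in enumerate(flat.phytomers):
        m_tot = ph.perm_moment.copy()
        if include_solution_loads:
            m_tot = m_tot + solution.M_base[i]
        e = dirs[i]
        m_bend = m_tot - float(np.dot(m_tot, e)) * e
        d = 2.0 * flat.radius[i]
        if d > 0:
            out[i] = longitudinal_stress(float(np.linalg.norm(m_bend)), d)
    return out


@dataclass
class SafetyReport:
    stresses: np.ndarray  # Pa, per standing internode (flat order)
    POT: int | None  # 1-based rank (base->top) of the max-stress trunk internode
    stress_trunk: float  # Pa
    stress_tree: float  # Pa
    broken: list[int] = field(default_factory=list)  # flat indices that failed
    trunk_broken: bool = False
    top_deflection: float = 0.0  # deg
    pruned_biomass_g: float = 0.0
    # (id of the phytomer just below each cut, or None at an axis base;
    #  severed weight g) - consumed by the wind-off removal pass
    removals: list[tuple[int | None, float]] = field(default_factory=list)


def _sever(axis: Axis, index: int, cycle: int) -> tuple[float, float]:
    """Remove phytomers ``index..`` of an axis (with their subtrees).

    Returns (stem biomass removed, living leaf biomass removed) in grams.
    """
    stem_g = 0.0
    leaf_g = 0.0

    def collect(ph: Phytomer) -> None:
        nonlocal stem_g, leaf_g
        ph.broken = True
        stem_g += ph.stem_biomass
        leaf_g += sum(lf.blade_biomass for lf in ph.leaves if lf.alive)
        for child in ph.children:
            for cph in child.phytomers:
                collect(cph)

    for ph in axis.phytomers[index:]:
        collect(ph)
    axis.phytomers = axis.phytomers[:index]
    axis.apical_alive = False
    return stem_g, leaf_g


def detect_and_prune(
    tree: Tree,
    solution: MechSolution,
    MOR: float,
    include_solution_loads: bool = True,
) -> tuple[SafetyReport, Tree]:
    """Mark internodes whose stress exceeds the MOR and sever their distal parts.

    The most basal failing internode of each axis takes its whole distal
    substructure with it; severed biomass leaves the tree (and therefore all
    weight aggregates).  Returns the report and the pruned tree.
    """
    flat = solution.flat
    stresses = segment_stresses(solution, include_solution_loads)
    trunk_mask = flat.is_trunk
    stress_tree = float(stresses.max()) if flat.n else 0.0
    pot = None
    stress_trunk = 0.0
    if trunk_mask.any():
        trunk_stresses = stresses[trunk_mask]
        stress_trunk = float(trunk_stresses.max())
        pot = int(np.argmax(trunk_stresses)) + 1  # trunk internodes are flat-ordered base->top
    over = np.nonzero(stresses > MOR)[0]
    report = SafetyReport(
        stresses=stresses,
        POT=pot,
        stress_trunk=stress_trunk,
        stress_tree=stress_tree,
        broken=[int(i) for i in over],
        top_deflection=solution.top_deflection_deg(),
    )
    if len(over) == 0:
        return report, tree

    # group failing internodes by axis; sever at the most basal one
    fail_ids = {id(flat.phytomers[i]) for i in over}
    pruned_g = 0.0
    for ax in list(structure.iter_axes(tree)):
        for idx, ph in enumerate(ax.phytomers):
            if id(ph) in fail_ids:
                if ax.pa == 1:
                    report.trunk_broken = True
                if idx > 0:
                    insertion = id(ax.phytomers[idx - 1])
                elif ax.parent_attachment is not None:
                    insertion = id(ax.parent_attachment[0])
                else:
                    insertion = None
                stem_g, leaf_g = _sever(ax, idx, tree.age)
                pruned_g += stem_g + leaf_g
                report.removals.append((insertion, stem_g + leaf_g))
                break
    report.pruned_biomass_g = pruned_g
    return report, tree


def top_deflection(obj: Tree | MechSolution) -> float:
    """Angle (deg) between the trunk's tip segment and vertical, in [0, 180]."""
    if isinstance(obj, MechSolution):
        return obj.top_deflection_deg()
    tree = obj
    if not tree.trunk.phytomers:
        raise ValueError("trunk is empty")
    d = tree.trunk.phytomers[-1].rest_dir
    d = d / np.linalg.norm(d)
    return math.degrees(math.acos(min(1.0, max(-1.0, float(d[2])))))


@dataclass
class CwsResult:
    value: float | None  # m/s; None when the trunk never breaks below u_max
    status: str  # 'ok' | 'unbroken' | 'floor'

    def __float__(self) -> float:
        return math.inf if self.value is None else self.value


def critical_wind_speed(
    config=None,
    u_min: float = 0.0,
    u_max: float = 50.0,
    step: float = 1.0,
    resolution: float = 0.1,
    breaks_at: Callable[[float], bool] | None = None,
) -> CwsResult:
    """Smallest steady wind speed (m/s) that breaks the trunk.

    Each candidate regrows the tree from seed under that wind (the scenario
    in ``config``); ``breaks_at`` may be supplied directly for testing.
    Coarse scan with ``step``, then bisection to ``resolution``.  Returns a
    'floor' result when even ``u_min`` breaks the trunk and an 'unbroken'
    sentinel when ``u_max`` never does.
    """
    if u_max <= u_min:
        raise ValueError("u_max must exceed u_min")
    if breaks_at is None:
        if config is None:
            raise ValueError("need a simulation config or a breaks_at callable")
        from . import harness  # deferred: harness orchestrates full simulations

        def breaks_at(u: float) -> bool:
            cfg = config.with_wind(u)
            traj = harness.run_simulation(cfg)
            return any(rep.trunk_broken for rep in traj.cycles)

    if breaks_at(u_min):
        return CwsResult(u_min, "floor")
    lo = u_min
    hi = None
    u = u_min + step
    while u <= u_max + 1e-9:
        if breaks_at(u):
            hi = u
            break
        lo = u
        u += step
    if hi is None:
        return CwsResult(None, "unbroken")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if breaks_at(mid):
            hi = mid
        else:
            lo = mid
    return CwsResult(round(hi / resolution) * resolution, "ok")


def safety_table(solution: MechSolution, include_solution_loads: bool = True):
    """Per-internode mechanical summary (axis, height, diameter, forces,
    moments, stress) as a DataFrame."""
    import pandas as pd

    flat = solution.flat
    stresses = segment_stresses(solution, include_solution_loads)
    pb, pt = solution.deformed_positions()
    rows = []
    for i, ph in enumerate(flat.phytomers):
        f_tot = ph.perm_force + (solution.R_base[i] if include_solution_loads else 0.0)
        m_tot = ph.perm_moment + (solution.M_base[i] if include_solution_loads else 0.0)
        rows.append(
            {
                "segment": i,
                "pa": ph.pa,
                "is_trunk": bool(flat.is_trunk[i]),
                "height_m": pb[i][2],
                "diameter_cm": 2.0 * flat.radius[i] * 100.0,
                "Fx": f_tot[0], "Fy": f_tot[1], "Fz": f_tot[2],
                "Mx": m_tot[0], "My": m_tot[1], "Mz": m_tot[2],
                "stress_MPa": stresses[i] / 1e6,
            }
        )
    return pd.DataFrame(rows)
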