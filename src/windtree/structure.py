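"""Tree topology and per-internode state.

A tree is a hierarchy of axes; an axis is an ordered list of phytomers
(internode + axillary leaves), grouped into growth units (GU), one GU per
growth cycle.  Each axis carries a physiological age (PA): 1 for the trunk,
increasing for higher branching orders, up to the species maximum ``P_m``.

Geometry convention: z up, origin at the stem base, wind blows along +x.
Rest-pose directions (after committed permanent deformation) are stored per
phytomer as world-frame unit vectors; positions are derived by walking the
tree from the base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np

from .units import G_GRAVITY, cm_to_m, grams_to_newtons


class InvalidRulesError(ValueError):
    """Topology rules that violate the PA ordering (child PA must exceed parent PA)."""


class StructureError(RuntimeError):
    """Structurally inconsistent tree (e.g. cyclic axis references)."""


@dataclass
class Ring:
    """One annual layer of secondary growth on an internode.

    Areas are cross-section areas in cm^2, biomass in grams, density in
    g cm^-3, length (the parent internode length) in cm; the defining
    relation is ``biomass = density * area * length``.
    """

    cycle_formed: int
    area: float
    density: float
    biomass: float
    length: float


@dataclass
class LeafOrgan:
    blade_biomass: float  # g
    blade_area: float  # cm^2
    birth_cycle: int
    alive: bool = True
    shed_cycle: int | None = None


@dataclass
class Phytomer:
    pa: int
    birth_cycle: int
    pith_length: float = 0.0  # cm
    pith_area: float = 0.0  # cm^2
    pith_biomass: float = 0.0  # g
    rings: list[Ring] = field(default_factory=list)
    leaves: list[LeafOrgan] = field(default_factory=list)
    # rest-pose direction of the internode axis, world frame, unit vector
    rest_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    azimuth: float = 0.0  # phyllotaxy azimuth (deg), bookkeeping for laterals
    broken: bool = False
    # lateral axes attached at this phytomer's tip node
    children: list["Axis"] = field(default_factory=list)
    # accumulated (committed) internal load state at the base section,
    # world frame: force in N, moment in N*m
    perm_force: np.ndarray = field(default_factory=lambda: np.zeros(3))
    perm_moment: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def stem_biomass(self) -> float:
        """Internode weight (g): pith plus all accumulated rings."""
        return self.pith_biomass + sum(r.biomass for r in self.rings)

    @property
    def section_area(self) -> float:
        """Total cross-section area (cm^2): pith plus rings."""
        return self.pith_area + sum(r.area for r in self.rings)

    @property
    def radius_cm(self) -> float:
        """Internode radius (cm) from accumulated layer areas."""
        return math.sqrt(self.section_area / math.pi)

    @property
    def length_m(self) -> float:
        return cm_to_m(self.pith_length)

    def leaf_biomass(self, alive_only: bool = True) -> float:
        return sum(lf.blade_biomass for lf in self.leaves if lf.alive or not alive_only)


@dataclass
class Axis:
    pa: int
    phytomers: list[Phytomer] = field(default_factory=list)
    # (bearing phytomer, insertion angle deg, azimuth deg); None for the trunk
    parent_attachment: tuple[Phytomer, float, float] | None = None
    birth_cycle: int = 0
    apical_alive: bool = True  # False once the tip has been severed
    phyllo_counter: int = 0

    def gu_sizes(self) -> dict[int, int]:
        """Phytomer count per birth cycle (growth-unit sizes)."""
        out: dict[int, int] = {}
        for ph in self.phytomers:
            out[ph.birth_cycle] = out.get(ph.birth_cycle, 0) + 1
        return out

    @property
    def tip_dir(self) -> np.ndarray:
        if self.phytomers:
            return self.phytomers[-1].rest_dir
        raise StructureError("axis has no phytomers yet")


@dataclass
class TopologyRules:
    """Deterministic organogenesis rules.

    ``laterals_per_phytomer[pa]`` lists the PAs of child axes borne by a
    lateral-bearing phytomer of an axis of age-class ``pa``;
    ``lateral_period[pa]`` spaces lateral-bearing phytomers within a GU
    (period equal to the GU size means one lateral-bearing phytomer per GU).
    """

    phytomers_per_gu: dict[int, int]
    laterals_per_phytomer: dict[int, list[int]]
    insertion_angle: dict[int, float]  # deg, per child PA
    phyllotaxy_step: float = 137.5  # deg
    lateral_period: dict[int, int] | None = None
    leaves_per_phytomer: int = 1

    def validate(self, p_max: int) -> None:
        for pa, children in self.laterals_per_phytomer.items():
            for cpa in children:
                if cpa <= pa:
                    raise InvalidRulesError(
                        f"child PA {cpa} must exceed parent PA {pa}"
                    )
        for pa, cnt in self.phytomers_per_gu.items():
            if cnt < 0:
                raise InvalidRulesError("phytomer counts must be >= 0")

    def period_for(self, pa: int) -> int:
        if self.lateral_period and pa in self.lateral_period:
            return max(1, self.lateral_period[pa])
        return max(1, self.phytomers_per_gu.get(pa, 1))


@dataclass
class Tree:
    trunk: Axis
    age: int = 0
    rules: TopologyRules | None = None

    @classmethod
    def seed(cls, rules: TopologyRules | None = None) -> "Tree":
        return cls(trunk=Axis(pa=1), age=0, rules=rules)


# ---------------------------------------------------------------------------
# traversal helpers


def iter_axes(tree: Tree) -> Iterator[Axis]:
    """All axes in preorder (trunk first)."""
    stack = [tree.trunk]
    seen: set[int] = set()
    while stack:
        ax = stack.pop()
        if id(ax) in seen:
            raise StructureError("cyclic axis topology")
        seen.add(id(ax))
        yield ax
        for ph in reversed(ax.phytomers):
            for child in reversed(ph.children):
                stack.append(child)


def iter_phytomers(tree: Tree) -> Iterator[tuple[Axis, int, Phytomer]]:
    for ax in iter_axes(tree):
        for i, ph in enumerate(ax.phytomers):
            yield ax, i, ph


def living_leaves(tree: Tree) -> Iterator[tuple[Phytomer, LeafOrgan]]:
    for _, _, ph in iter_phytomers(tree):
        for lf in ph.leaves:
            if lf.alive:
                yield ph, lf


def living_blade_area_cm2(tree: Tree) -> float:
    return sum(lf.blade_area for _, lf in living_leaves(tree))


def leaf_counts_by_pa(tree: Tree, p_max: int) -> np.ndarray:
    """Living leaf counts indexed by PA-1 (Eq-2 style census)."""
    counts = np.zeros(p_max, dtype=int)
    for ph, _ in living_leaves(tree):
        counts[ph.pa - 1] += 1
    return counts


# ---------------------------------------------------------------------------
# geometry


def _perp_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to d (deterministic convention)."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(float(np.dot(ref, d))) > 0.95:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - np.dot(ref, d) * d
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def tilted_direction(parent_dir: np.ndarray, insertion_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector at ``insertion_deg`` from ``parent_dir``, rolled by azimuth."""
    d = parent_dir / np.linalg.norm(parent_dir)
    u, v = _perp_frame(d)
    psi = math.radians(insertion_deg)
    phi = math.radians(azimuth_deg)
    out = math.cos(psi) * d + math.sin(psi) * (math.cos(phi) * u + math.sin(phi) * v)
    return out / np.linalg.norm(out)


def rest_positions(tree: Tree) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Base and tip positions (m, world frame) per phytomer id, rest pose."""
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def walk(axis: Axis, base: np.ndarray) -> None:
        pos = base
        for ph in axis.phytomers:
            tip = pos + ph.rest_dir * ph.length_m
            out[id(ph)] = (pos, tip)
            for child in ph.children:
                if child.phytomers:
                    walk(child, tip)
            pos = tip

    walk(tree.trunk, np.zeros(3))
    return out


def tree_height(tree: Tree) -> float:
    """Trunk tip height (m) in the rest pose."""
    if not tree.trunk.phytomers:
        return 0.0
    pos = rest_positions(tree)
    tip = pos[id(tree.trunk.phytomers[-1])][1]
    return float(tip[2])


def trunk_dbh_cm(tree: Tree, breast_height: float = 1.3) -> float | None:
    """Trunk diameter (cm) at breast height, rest pose; None if too short."""
    pos = rest_positions(tree)
    for ph in tree.trunk.phytomers:
        base, tip = pos[id(ph)]
        if base[2] <= breast_height <= tip[2]:
            return 2.0 * ph.radius_cm
    return None


# ---------------------------------------------------------------------------
# organogenesis


def develop(tree: Tree, rules: TopologyRules, n: int, p_max: int) -> list[Phytomer]:
    """Append one growth unit to every living axis tip (cycle ``n``).

    New phytomers are created with zero dimensions; their size is set by the
    primary allocation of the same cycle.  New lateral axes are created as
    buds (empty axes) which produce their first GU the following cycle.
    Returns the list of phytomers created (so a zero-production cycle can be
    rolled back by the caller).
    """
    if n != tree.age + 1:
        raise ValueError(f"develop expects cycle {tree.age + 1}, got {n}")
    rules.validate(p_max)

    new_phytomers: list[Phytomer] = []
    for ax in list(iter_axes(tree)):
        if not ax.apical_alive:
            continue
        if ax.pa > p_max:  # pragma: no cover - rules.validate rejects these
            continue
        if ax.parent_attachment is not None and not ax.phytomers and ax.birth_cycle >= n:
            # a bud created this very cycle waits one cycle
            continue
        count = rules.phytomers_per_gu.get(ax.pa, 0)
        period = rules.period_for(ax.pa)
        if ax.phytomers:
            tip_dir = ax.tip_dir
        elif ax.parent_attachment is not None:
            bearer, angle, azim = ax.parent_attachment
            tip_dir = tilted_direction(bearer.rest_dir, angle, azim)
        else:
            tip_dir = np.array([0.0, 0.0, 1.0])
        for i in range(count):
            ax.phyllo_counter += 1
            azim = (ax.phyllo_counter * rules.phyllotaxy_step) % 360.0
            ph = Phytomer(pa=ax.pa, birth_cycle=n, rest_dir=tip_dir.copy(), azimuth=azim)
            for _ in range(rules.leaves_per_phytomer):
                ph.leaves.append(LeafOrgan(0.0, 0.0, birth_cycle=n))
            if i % period == 0:
                for child_pa in rules.laterals_per_phytomer.get(ax.pa, []):
                    if child_pa <= p_max:
                        ang = rules.insertion_angle.get(child_pa, 45.0)
                        ph.children.append(
                            Axis(pa=child_pa, parent_attachment=(ph, ang, azim), birth_cycle=n)
                        )
            ax.phytomers.append(ph)
            new_phytomers.append(ph)
    tree.age = n
    return new_phytomers


def rollback_develop(tree: Tree, new_phytomers: list[Phytomer]) -> None:
    """Remove the phytomers created by the last ``develop`` (zero-production cycle)."""
    doomed = {id(ph) for ph in new_phytomers}
    for ax in iter_axes(tree):
        ax.phytomers = [ph for ph in ax.phytomers if id(ph) not in doomed]
    tree.age -= 1


# ---------------------------------------------------------------------------
# weights


@dataclass
class AxisAggregate:
    total_weight_n: float  # N, stems + living leaves of the whole substructure
    increment_weight_n: float  # N, biomass added this cycle (net of shed leaves)
    gravity_center: np.ndarray  # m, biomass-weighted mean position


def substructure_weights(tree: Tree, cycle: int | None = None) -> dict[int, AxisAggregate]:
    """Per-axis substructure aggregates, summed highest PA first.

    Each axis aggregate combines its own internode weights, its living leaf
    weights and the aggregates of all child axes.  The increment counts
    organs and rings added at ``cycle`` (default: the tree's age) minus
    leaves shed that cycle.
    """
    if cycle is None:
        cycle = tree.age
    pos = rest_positions(tree)
    out: dict[int, AxisAggregate] = {}

    ordered = sorted(iter_axes(tree), key=lambda ax: ax.pa, reverse=True)
    for ax in ordered:
        mass_g = 0.0
        inc_g = 0.0
        moment = np.zeros(3)  # g * m
        for ph in ax.phytomers:
            base, tip = pos[id(ph)]
            mid = 0.5 * (base + tip)
            m_ph = ph.stem_biomass
            mass_g += m_ph
            moment += m_ph * mid
            if ph.birth_cycle == cycle:
                inc_g += ph.pith_biomass
            inc_g += sum(r.biomass for r in ph.rings if r.cycle_formed == cycle)
            for lf in ph.leaves:
                if lf.alive:
                    mass_g += lf.blade_biomass
                    moment += lf.blade_biomass * tip
                    if lf.birth_cycle == cycle:
                        inc_g += lf.blade_biomass
                elif lf.shed_cycle == cycle:
                    inc_g -= lf.blade_biomass  # shed at the start of this cycle
            for child in ph.children:
                if id(child) in out:
                    agg = out[id(child)]
                    child_g = agg.total_weight_n / G_GRAVITY * 1000.0
                    mass_g += child_g
                    inc_g += agg.increment_weight_n / G_GRAVITY * 1000.0
                    moment += child_g * agg.gravity_center
        center = moment / mass_g if mass_g > 0 else np.zeros(3)
        out[id(ax)] = AxisAggregate(
            total_weight_n=grams_to_newtons(mass_g),
            increment_weight_n=grams_to_newtons(inc_g),
            gravity_center=center,
        )
    return out


def total_stem_weight(tree: Tree) -> float:
    """Q_stem (g): summed internode weights of trunk and all branches.

    Leaves are excluded; internodes severed by breakage are no longer part of
    the tree and therefore no longer counted.
    """
    return sum(ph.stem_biomass for _, _, ph in iter_phytomers(tree))


def export_internodes(tree: Tree):
    """One record per internode (for CSV export)."""
    import pandas as pd

    pos = rest_positions(tree)
    rows = []
    for ax_idx, ax in enumerate(iter_axes(tree)):
        for i, ph in enumerate(ax.phytomers):
            base, tip = pos[id(ph)]
            rows.append(
                {
                    "axis_id": ax_idx,
                    "pa": ph.pa,
                    "rank": i,
                    "birth_cycle": ph.birth_cycle,
                    "base_x": base[0], "base_y": base[1], "base_z": base[2],
                    "tip_x": tip[0], "tip_y": tip[1], "tip_z": tip[2],
                    "radius_cm": ph.radius_cm,
                    "biomass_g": ph.stem_biomass,
                    "broken": ph.broken,
                }
            )
    return pd.DataFrame(rows)


def export_obj(tree: Tree, path: str) -> None:
    """Write the rest-pose geometry as OBJ line segments."""
    pos = rest_positions(tree)
    verts: list[np.ndarray] = []
    lines: list[tuple[int, int]] = []
    for _, _, ph in iter_phytomers(tree):
        base, tip = pos[id(ph)]
        verts.append(base)
        verts.append(tip)
        lines.append((len(verts) - 1, len(verts)))
    with open(path, "w") as fh:
        for v in verts:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for a, b in lines:
            fh.write(f"l {a} {b}\n")
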