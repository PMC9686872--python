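"""Incremental transfer-matrix beam mechanics for branched trees.

Each internode is a straight multilayer beam segment (pith plus annual
rings).  A solve propagates a 6-component state (3 translations, 3
rotations; 3 forces, 3 moments) through the branched structure in two
passes:

* an upward pass (highest branching order first) accumulates the internal
  load resultants ``S`` at every section from the distributed loads ``F``
  (self-weight increments, wind drag) and concentrated loads ``C`` (leaves,
  branch insertions), with moment arms taken on the *deformed* geometry;
* a downward pass integrates small-deflection Euler-Bernoulli transfer
  relations segment by segment from the clamped base to the free tips,
  giving translations and rotations at every node.

Because loads recomputed on the deformed shape change the next solve, the
two passes are iterated until the displacement field stabilizes - the tree
visibly "sways" toward its equilibrium.  Growth-induced (gravity-increment)
deformation is committed into the rest pose; wind deformation is elastic
and never committed, so removing the wind restores the rest pose exactly.

The closed-form per-segment integration (for a linearly varying internal
moment plus a uniform distributed load) makes a single segment reproduce
the textbook cantilever results PL^3/3EI, PL^2/2EI and qL^4/8EI to machine
precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import structure
from .structure import Tree
from .units import G_GRAVITY, grams_to_newtons
from .wind import WindField, drag_forces, leaf_drag_forces

Z_UP = np.array([0.0, 0.0, 1.0])


class SingularSectionError(ValueError):
    pass


class ContractViolationError(RuntimeError):
    pass


@dataclass
class MaterialParams:
    E_ref: float = 7.0e9  # elastic modulus of green wood (Pa)
    density_link: bool = False  # scale layer modulus with layer density
    rho_ref: float = 0.40  # reference density for the modulus scaling (g cm^-3)
    rho_pith: float = 0.36  # pith density used when density_link is on
    torsion_ratio: float = 1.0 / 16.0  # G/E for green wood
    Ma_strain: float = 0.0  # maturation-strain hook (0 = off)

    def __post_init__(self) -> None:
        if self.E_ref <= 0:
            raise ValueError("E_ref must be positive")


@dataclass
class MechState:
    """Displacement and internal load state at one beam node."""

    D: np.ndarray = field(default_factory=lambda: np.zeros(6))  # tx ty tz rx ry rz
    S: np.ndarray = field(default_factory=lambda: np.zeros(6))  # Fx Fy Fz Mx My Mz

    @property
    def translation(self) -> np.ndarray:
        return self.D[:3]

    @property
    def rotation(self) -> np.ndarray:
        return self.D[3:]

    @property
    def force(self) -> np.ndarray:
        return self.S[:3]

    @property
    def moment(self) -> np.ndarray:
        return self.S[3:]


@dataclass
class BeamSegment:
    """One beam element: geometry, layered section and its loads."""

    length: float  # m
    layers: list[tuple[float, float]]  # (outer radius m, elastic modulus Pa), increasing
    direction: np.ndarray = field(default_factory=lambda: Z_UP.copy())
    weight_increment: np.ndarray = field(default_factory=lambda: np.zeros(3))  # N/m
    wind_load: np.ndarray = field(default_factory=lambda: np.zeros(3))  # N/m
    C: np.ndarray = field(default_factory=lambda: np.zeros(6))  # concentrated at distal node
    torsion_ratio: float = 1.0 / 16.0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("segment length must be positive")
        radii = [r for r, _ in self.layers]
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("layer outer radii must be strictly increasing")
        d = np.asarray(self.direction, dtype=float)
        self.direction = d / np.linalg.norm(d)

    @property
    def distributed(self) -> np.ndarray:
        return self.weight_increment + self.wind_load


def composite_stiffness(segment: BeamSegment) -> tuple[float, float]:
    """Bending and axial stiffness (EI, EA) of a layered circular section."""
    r_in = 0.0
    ei = 0.0
    ea = 0.0
    for r_out, e_mod in segment.layers:
        if r_out <= 0:
            raise SingularSectionError("zero-radius layer")
        ei += e_mod * math.pi * (r_out**4 - r_in**4) / 4.0
        ea += e_mod * math.pi * (r_out**2 - r_in**2)
        r_in = r_out
    if ei == 0.0:
        raise SingularSectionError("section has no layers")
    return ei, ea


def _torsional_stiffness(segment: BeamSegment) -> float:
    r_in = 0.0
    gj = 0.0
    for r_out, e_mod in segment.layers:
        gj += segment.torsion_ratio * e_mod * math.pi * (r_out**4 - r_in**4) / 2.0
        r_in = r_out
    return gj


def transfer_step(state: MechState, segment: BeamSegment) -> MechState:
    """Propagate the mechanical state from the base to the tip of one segment.

    ``state.S`` holds the internal load resultant at the base section (all
    loads distal to it).  The returned state carries the resultant just
    beyond the distal node, so at a free, unloaded tip it vanishes.
    """
    if not np.all(np.isfinite(state.D)) or not np.all(np.isfinite(state.S)):
        raise FloatingPointError("non-finite mechanical state")
    ei, ea = composite_stiffness(segment)
    gj = _torsional_stiffness(segment)
    e = segment.direction
    L = segment.length
    w = segment.distributed
    # resultants at the tip section (distal node included)
    r_t = state.force - w * L
    m_t = state.moment - np.cross(L * e, r_t) - (L * L / 2.0) * np.cross(e, w)
    m_ax = float(np.dot(m_t, e))
    m_perp = m_t - m_ax * e
    a_vec = np.cross(e, r_t)
    b_vec = np.cross(e, w)
    theta_b = state.rotation
    t_b = state.translation
    theta_t = theta_b + (L * m_perp + (L**2 / 2.0) * a_vec + (L**3 / 6.0) * b_vec) / ei
    if gj > 0:
        theta_t = theta_t + (L * m_ax / gj) * e
    t_t = (
        t_b
        + np.cross(theta_b, L * e)
        + np.cross((L**2 / 2.0) * m_perp + (L**3 / 3.0) * a_vec + (L**4 / 8.0) * b_vec, e) / ei
        + e * (L * float(np.dot(r_t, e)) + (L**2 / 2.0) * float(np.dot(w, e))) / ea
    )
    s_tip = np.concatenate([r_t - segment.C[:3], m_t - segment.C[3:]])
    return MechState(D=np.concatenate([t_t, theta_t]), S=s_tip)


# ---------------------------------------------------------------------------
# flattened tree representation


@dataclass
class FlatTree:
    """Array view of the standing internodes, ordered parent-before-child."""

    phytomers: list  # Phytomer refs, aligned with the arrays
    parent: np.ndarray  # (n,) parent segment index, -1 at the trunk base
    length: np.ndarray  # (n,) m
    rest_base: np.ndarray  # (n,3) m
    rest_tip: np.ndarray  # (n,3) m
    radius: np.ndarray  # (n,) m
    EI: np.ndarray
    EA: np.ndarray
    GJ: np.ndarray
    is_trunk: np.ndarray  # (n,) bool
    leaf_area: np.ndarray | None = None  # (n,) m^2 living blades at the tip node
    levels: list[np.ndarray] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.phytomers)

    @property
    def rest_dir(self) -> np.ndarray:
        d = self.rest_tip - self.rest_base
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def trunk_tip_index(self) -> int:
        idx = np.nonzero(self.is_trunk)[0]
        return int(idx[-1])

    def tips(self) -> np.ndarray:
        has_child = np.zeros(self.n, dtype=bool)
        has_child[self.parent[self.parent >= 0]] = True
        return np.nonzero(~has_child)[0]


def _segment_stiffness(ph, material: MaterialParams) -> tuple[float, float, float]:
    """(EI, EA, GJ) of one internode's layered section (SI units)."""
    radii_cm = []
    mods = []
    area = ph.pith_area
    radii_cm.append(math.sqrt(area / math.pi))
    mods.append(
        material.E_ref * (material.rho_pith / material.rho_ref if material.density_link else 1.0)
    )
    for ring in ph.rings:
        area += ring.area
        radii_cm.append(math.sqrt(area / math.pi))
        mods.append(
            material.E_ref * (ring.density / material.rho_ref if material.density_link else 1.0)
        )
    ei = ea = gj = 0.0
    r_in = 0.0
    for r_cm, e_mod in zip(radii_cm, mods):
        r_out = r_cm / 100.0
        ei += e_mod * math.pi * (r_out**4 - r_in**4) / 4.0
        ea += e_mod * math.pi * (r_out**2 - r_in**2)
        gj += material.torsion_ratio * e_mod * math.pi * (r_out**4 - r_in**4) / 2.0
        r_in = r_out
    return ei, ea, gj


def flatten(tree: Tree, material: MaterialParams) -> FlatTree:
    """Build the array representation of the current standing structure."""
    phyt: list = []
    parent: list[int] = []
    is_trunk: list[bool] = []

    def walk(axis: structure.Axis, parent_idx: int, trunk: bool) -> None:
        prev = parent_idx
        for ph in axis.phytomers:
            if ph.pith_length <= 0:
                continue
            idx = len(phyt)
            phyt.append(ph)
            parent.append(prev)
            is_trunk.append(trunk)
            for child in ph.children:
                if child.phytomers:
                    walk(child, idx, False)
            prev = idx

    walk(tree.trunk, -1, True)
    n = len(phyt)
    pos = structure.rest_positions(tree)
    rest_base = np.zeros((n, 3))
    rest_tip = np.zeros((n, 3))
    length = np.zeros(n)
    radius = np.zeros(n)
    ei = np.zeros(n)
    ea = np.zeros(n)
    gj = np.zeros(n)
    leaf_area = np.zeros(n)
    for i, ph in enumerate(phyt):
        b, t = pos[id(ph)]
        rest_base[i] = b
        rest_tip[i] = t
        length[i] = ph.length_m
        radius[i] = ph.radius_cm / 100.0
        ei[i], ea[i], gj[i] = _segment_stiffness(ph, material)
        leaf_area[i] = sum(lf.blade_area for lf in ph.leaves if lf.alive) / 1.0e4
    parent_arr = np.asarray(parent, dtype=int)
    depth = np.zeros(n, dtype=int)
    for i in range(n):
        depth[i] = 0 if parent_arr[i] < 0 else depth[parent_arr[i]] + 1
    levels = [np.nonzero(depth == d)[0] for d in range(int(depth.max()) + 1 if n else 0)]
    return FlatTree(
        phytomers=phyt,
        parent=parent_arr,
        length=length,
        rest_base=rest_base,
        rest_tip=rest_tip,
        radius=radius,
        EI=ei,
        EA=ea,
        GJ=gj,
        is_trunk=np.asarray(is_trunk, dtype=bool),
        leaf_area=leaf_area,
        levels=levels,
    )


# ---------------------------------------------------------------------------
# linear solve (two passes over the levels)


def solve_linear(
    flat: FlatTree,
    dist_w: np.ndarray,
    conc_f: np.ndarray,
    p_base: np.ndarray | None = None,
    p_tip: np.ndarray | None = None,
    geo_dist_w: np.ndarray | None = None,
    geo_conc_f: np.ndarray | None = None,
    t_base_prev: np.ndarray | None = None,
    t_tip_prev: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """One linear beam solve: loads -> resultants and displacements.

    ``dist_w`` (n,3) N/m acts along each segment, ``conc_f`` (n,3) N acts at
    each segment's distal node.  Moment arms are taken on the supplied
    (possibly deformed) positions; elastic integration uses the rest axes.

    ``geo_dist_w``/``geo_conc_f`` carry loads already balanced in the rest
    pose (the standing self-weight): only the *moment increment* caused by
    the displacement field of the previous iteration (``t_base_prev``,
    ``t_tip_prev``) is applied - the mechanism by which a swaying tree's
    gravity center shifts and feeds back on the bending.
    """
    n = flat.n
    if p_base is None:
        p_base = flat.rest_base
    if p_tip is None:
        p_tip = flat.rest_tip
    L = flat.length[:, None]
    w_tot = dist_w * L  # total distributed force per segment
    geo = geo_dist_w is not None
    if geo:
        gw_tot = geo_dist_w * L
        if geo_conc_f is None:
            geo_conc_f = np.zeros((n, 3))
        if t_base_prev is None:
            t_base_prev = np.zeros((n, 3))
        if t_tip_prev is None:
            t_tip_prev = np.zeros((n, 3))
        t_mid_prev = 0.5 * (t_base_prev + t_tip_prev)
    acc_f = np.zeros((n, 3))
    acc_m = np.zeros((n, 3))
    acc_gw = np.zeros((n, 3))  # summed geometric-load forces distal to the node
    acc_tw = np.zeros((n, 3))  # summed (displacement x force) of geometric loads
    r_tipnode = np.zeros((n, 3))
    m_tipnode = np.zeros((n, 3))
    r_base = np.zeros((n, 3))
    m_base = np.zeros((n, 3))
    dp = p_tip - p_base
    for level in reversed(flat.levels):
        idx = level
        rt = acc_f[idx] + conc_f[idx]
        mt = acc_m[idx]
        r_tipnode[idx] = rt
        r_base[idx] = rt + w_tot[idx]
        mb = mt + np.cross(dp[idx], rt) + 0.5 * np.cross(dp[idx], w_tot[idx])
        m_base[idx] = mb
        m_tipnode[idx] = mt
        par = flat.parent[idx]
        ok = par >= 0
        if ok.any():
            np.add.at(acc_f, par[ok], r_base[idx][ok])
            np.add.at(acc_m, par[ok], m_base[idx][ok])
        if geo:
            # running sums of the rest-balanced loads and their
            # displacement moments, distal to each node
            gw_node = acc_gw[idx] + geo_conc_f[idx]
            tw_node = acc_tw[idx] + np.cross(t_tip_prev[idx], geo_conc_f[idx])
            gw_base = gw_node + gw_tot[idx]
            tw_base = tw_node + np.cross(t_mid_prev[idx], gw_tot[idx])
            # moment increment at a section s: sum_distal (t_i - t_s) x W_i
            m_tipnode[idx] += tw_node - np.cross(t_tip_prev[idx], gw_node)
            m_base[idx] += tw_base - np.cross(t_base_prev[idx], gw_base)
            if ok.any():
                np.add.at(acc_gw, par[ok], gw_base[ok])
                np.add.at(acc_tw, par[ok], tw_base[ok])

    # downward: integrate displacements from the clamped base
    e = dp / np.linalg.norm(dp, axis=1, keepdims=True)
    t_tip = np.zeros((n, 3))
    th_tip = np.zeros((n, 3))
    ei = flat.EI[:, None]
    ea = flat.EA[:, None]
    gj = flat.GJ
    Ls = flat.length
    for level in flat.levels:
        idx = level
        par = flat.parent[idx]
        t_b = np.where((par >= 0)[:, None], t_tip[np.maximum(par, 0)], 0.0)
        th_b = np.where((par >= 0)[:, None], th_tip[np.maximum(par, 0)], 0.0)
        ee = e[idx]
        Lc = Ls[idx][:, None]
        rt = r_tipnode[idx]
        mt = m_tipnode[idx]
        m_ax = np.sum(mt * ee, axis=1, keepdims=True)
        m_perp = mt - m_ax * ee
        a_vec = np.cross(ee, rt)
        b_vec = np.cross(ee, dist_w[idx])
        th = (
            th_b
            + (Lc * m_perp + Lc**2 / 2.0 * a_vec + Lc**3 / 6.0 * b_vec) / ei[idx]
        )
        gj_c = gj[idx]
        tors = np.zeros_like(th)
        ok = gj_c > 0
        if ok.any():
            tors[ok] = (Ls[idx][ok, None] * m_ax[ok] / gj_c[ok, None]) * ee[ok]
        th = th + tors
        tt = (
            t_b
            + np.cross(th_b, Lc * ee)
            + np.cross(Lc**2 / 2.0 * m_perp + Lc**3 / 3.0 * a_vec + Lc**4 / 8.0 * b_vec, ee)
            / ei[idx]
            + ee
            * (Lc * np.sum(rt * ee, axis=1, keepdims=True) + Lc**2 / 2.0 * np.sum(dist_w[idx] * ee, axis=1, keepdims=True))
            / ea[idx]
        )
        t_tip[idx] = tt
        th_tip[idx] = th
    if not (np.all(np.isfinite(t_tip)) and np.all(np.isfinite(th_tip))):
        bad = np.nonzero(~np.isfinite(t_tip).all(axis=1))[0]
        raise FloatingPointError(f"non-finite displacement at segments {bad[:5]}")
    return {
        "t_tip": t_tip,
        "theta_tip": th_tip,
        "R_base": r_base,
        "M_base": m_base,
        "R_tipnode": r_tipnode,
        "M_tipnode": m_tipnode,
    }


# ---------------------------------------------------------------------------
# load assembly


@dataclass
class LoadCase:
    mode: str
    dist_w: np.ndarray  # (n,3) N/m
    conc_f: np.ndarray  # (n,3) N at distal nodes
    wf: WindField | None = None


def assemble_loads(
    tree: Tree,
    mode: str,
    flat: FlatTree,
    cycle: int | None = None,
    wf: WindField | None = None,
    previous: LoadCase | None = None,
    removals: list[tuple[int, float]] | None = None,
) -> LoadCase:
    """Per-segment loads for one solve stage.

    ``gravity_increment`` loads each segment with the self-weight added this
    cycle (new pith, new ring) as a distributed load, plus new leaf weights
    (minus shed leaves) concentrated at the bearing nodes.  ``wind_on``
    carries the drag computed on the rest geometry (the equilibrium loop
    recomputes it on the deformed one).  ``wind_off`` negates a previous
    wind case.  ``removal`` applies severed substructures as one-time
    negative concentrated loads at their insertion segments
    (``removals`` = list of (segment index, severed weight g)).
    """
    n = flat.n
    dist_w = np.zeros((n, 3))
    conc_f = np.zeros((n, 3))
    if mode == "gravity_increment":
        if cycle is None:
            cycle = tree.age
        for i, ph in enumerate(flat.phytomers):
            inc_g = ph.pith_biomass if ph.birth_cycle == cycle else 0.0
            inc_g += sum(r.biomass for r in ph.rings if r.cycle_formed == cycle)
            if inc_g > 0:
                dist_w[i, 2] = -grams_to_newtons(inc_g) / flat.length[i]
            leaf_g = sum(lf.blade_biomass for lf in ph.leaves if lf.birth_cycle == cycle)
            leaf_g -= sum(lf.blade_biomass for lf in ph.leaves if lf.shed_cycle == cycle)
            if leaf_g != 0.0:
                conc_f[i, 2] = -grams_to_newtons(leaf_g)
    elif mode == "wind_on":
        if wf is None:
            raise ValueError("wind_on requires a WindField")
        mid_z = 0.5 * (flat.rest_base[:, 2] + flat.rest_tip[:, 2])
        dist_f = drag_forces(flat.length, flat.radius, flat.rest_dir, mid_z, wf)
        dist_w = dist_f / flat.length[:, None]
        if flat.leaf_area is not None and wf.Cd_leaf > 0:
            conc_f = conc_f + leaf_drag_forces(flat.leaf_area, flat.rest_tip[:, 2], wf)
        return LoadCase("wind_on", dist_w, conc_f, wf=wf)
    elif mode == "wind_off":
        if previous is None:
            raise ValueError("wind_off requires the preceding wind_on case")
        return LoadCase("wind_off", -previous.dist_w, -previous.conc_f)
    elif mode == "removal":
        for seg_idx, weight_g in removals or []:
            conc_f[seg_idx, 2] += grams_to_newtons(weight_g)  # upward = weight removed
    else:
        raise ValueError(f"unknown load mode {mode!r}")
    return LoadCase(mode, dist_w, conc_f, wf=wf)


# ---------------------------------------------------------------------------
# equilibrium iteration


@dataclass
class MechSolution:
    kind: str
    flat: FlatTree
    t_tip: np.ndarray
    theta_tip: np.ndarray
    R_base: np.ndarray
    M_base: np.ndarray
    R_tipnode: np.ndarray
    M_tipnode: np.ndarray
    dist_w: np.ndarray
    conc_f: np.ndarray
    converged: bool
    unstable: bool
    iterations: int
    trace: list[dict] = field(default_factory=list)

    def theta_base(self) -> np.ndarray:
        par = self.flat.parent
        out = np.where((par >= 0)[:, None], self.theta_tip[np.maximum(par, 0)], 0.0)
        return out

    def deformed_positions(self) -> tuple[np.ndarray, np.ndarray]:
        par = self.flat.parent
        t_base = np.where((par >= 0)[:, None], self.t_tip[np.maximum(par, 0)], 0.0)
        return self.flat.rest_base + t_base, self.flat.rest_tip + self.t_tip

    def top_deflection_deg(self) -> float:
        """Angle (deg) between the trunk's tip segment and vertical."""
        if self.flat.n == 0:
            return 0.0
        i = self.flat.trunk_tip_index()
        pb, pt = self.deformed_positions()
        d = pt[i] - pb[i]
        d = d / np.linalg.norm(d)
        return math.degrees(math.acos(min(1.0, max(-1.0, float(d[2])))))


def _empty_solution(kind: str, flat: FlatTree) -> MechSolution:
    z = np.zeros((flat.n, 3))
    return MechSolution(kind, flat, z, z.copy(), z.copy(), z.copy(), z.copy(), z.copy(),
                        z.copy(), z.copy(), True, False, 0)


def solve_equilibrium(
    tree: Tree,
    load_case: LoadCase | None,
    material: MaterialParams,
    max_iter: int = 10,
    tol: float = 1.0e-4,
    flat: FlatTree | None = None,
    on_iteration: Callable[["FlatTree", "MechSolution"], bool] | None = None,
) -> MechSolution:
    """Iterate linear solves with geometric load updates to equilibrium.

    For a wind case the drag is recomputed on the deformed geometry at every
    iteration; for gravity the (fixed) loads keep their magnitudes but the
    moment arms follow the structure.  ``on_iteration`` may inspect each
    intermediate solution (e.g. for breakage); returning True signals that
    the structure changed and the solver must re-flatten and restart the
    displacement history.  Divergence (displacement change growing for
    three consecutive iterations) is reported, not raised.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if flat is None:
        flat = flatten(tree, material)
    if flat.n == 0:
        return _empty_solution(load_case.mode if load_case else "empty", flat)
    mode = load_case.mode if load_case is not None else "wind_on"
    dist_w = load_case.dist_w if load_case is not None else None
    conc_f = load_case.conc_f if load_case is not None else None
    wf = load_case.wf if load_case is not None else None
    if conc_f is not None and conc_f.shape != (flat.n, 3):
        conc_f = np.zeros((flat.n, 3))

    def standing_weight_loads(fl: FlatTree) -> tuple[np.ndarray, np.ndarray]:
        """Distributed stem weight (N/m) and concentrated living-leaf weight
        (N) per segment - the loads whose gravity centers shift with sway."""
        gw = np.zeros((fl.n, 3))
        gc = np.zeros((fl.n, 3))
        for i, ph in enumerate(fl.phytomers):
            gw[i, 2] = -grams_to_newtons(ph.stem_biomass) / fl.length[i]
            leaf_g = sum(lf.blade_biomass for lf in ph.leaves if lf.alive)
            gc[i, 2] = -grams_to_newtons(leaf_g)
        return gw, gc

    def committed_weight_loads(fl: FlatTree) -> tuple[np.ndarray, np.ndarray]:
        """Self-weight committed in earlier cycles (standing stems minus this
        cycle's additions); its moment arms shift as the structure deforms,
        and that shift is part of the gravity increment."""
        cyc = tree.age
        gw = np.zeros((fl.n, 3))
        gc = np.zeros((fl.n, 3))
        for i, ph in enumerate(fl.phytomers):
            old_g = ph.stem_biomass
            if ph.birth_cycle == cyc:
                old_g -= ph.pith_biomass
            old_g -= sum(r.biomass for r in ph.rings if r.cycle_formed == cyc)
            if old_g > 0:
                gw[i, 2] = -grams_to_newtons(old_g) / fl.length[i]
        return gw, gc

    geo_w = geo_c = None
    if mode == "wind_on":
        geo_w, geo_c = standing_weight_loads(flat)
    elif mode == "gravity_increment":
        geo_w, geo_c = committed_weight_loads(flat)

    t_prev = np.zeros((flat.n, 3))
    th_prev = np.zeros((flat.n, 3))
    trace: list[dict] = []
    converged = False
    unstable = False
    deltas: list[float] = []
    it = 0
    sol_fields = None
    while it < max_iter:
        it += 1
        par = flat.parent
        t_base = np.where((par >= 0)[:, None], t_prev[np.maximum(par, 0)], 0.0)
        p_base = flat.rest_base + t_base
        p_tip = flat.rest_tip + t_prev
        if mode == "wind_on":
            dp = p_tip - p_base
            dirs = dp / np.linalg.norm(dp, axis=1, keepdims=True)
            mid_z = 0.5 * (p_base[:, 2] + p_tip[:, 2])
            dist_f = drag_forces(flat.length, flat.radius, dirs, mid_z, wf)
            dist_w = dist_f / flat.length[:, None]
            conc_f = np.zeros((flat.n, 3))
            if flat.leaf_area is not None and wf.Cd_leaf > 0:
                conc_f = conc_f + leaf_drag_forces(flat.leaf_area, p_tip[:, 2], wf)
        sol_fields = solve_linear(
            flat, dist_w, conc_f, p_base, p_tip,
            geo_dist_w=geo_w, geo_conc_f=geo_c,
            t_base_prev=t_base, t_tip_prev=t_prev,
        )
        t_new = sol_fields["t_tip"]
        delta = float(np.max(np.linalg.norm(t_new - t_prev, axis=1))) if flat.n else 0.0
        tmp = MechSolution(
            mode, flat, t_new, sol_fields["theta_tip"],
            sol_fields["R_base"], sol_fields["M_base"],
            sol_fields["R_tipnode"], sol_fields["M_tipnode"],
            dist_w, conc_f, False, False, it, trace,
        )
        trace.append({"iteration": it, "delta_m": delta,
                      "top_deflection_deg": tmp.top_deflection_deg()})
        if on_iteration is not None and on_iteration(flat, tmp):
            # structure changed (breakage): re-flatten and restart
            flat = flatten(tree, material)
            if flat.n == 0:
                return _empty_solution(mode, flat)
            t_prev = np.zeros((flat.n, 3))
            th_prev = np.zeros((flat.n, 3))
            if mode != "wind_on":
                raise ContractViolationError(
                    "structural changes during a non-wind solve require reassembled loads"
                )
            conc_f = np.zeros((flat.n, 3))
            geo_w, geo_c = standing_weight_loads(flat)
            deltas = []
            continue
        t_prev, th_prev = t_new, sol_fields["theta_tip"]
        deltas.append(delta)
        if delta < tol:
            converged = True
            break
        if len(deltas) >= 4 and all(
            deltas[-k] > deltas[-k - 1] for k in range(1, 4)
        ):
            unstable = True
            break
    return MechSolution(
        mode, flat, t_prev, th_prev,
        sol_fields["R_base"], sol_fields["M_base"],
        sol_fields["R_tipnode"], sol_fields["M_tipnode"],
        dist_w, conc_f if conc_f is not None else np.zeros((flat.n, 3)),
        converged, unstable, it, trace,
    )


def check_tip_boundary(
    solution: MechSolution, tol_force: float = 1.0e-3, tol_moment: float = 1.0e-3
) -> dict[int, bool]:
    """Verify the free-tip boundary condition of a solution.

    Propagates the internal load past each tip node (base resultant minus
    the segment's own loads) and checks that hardly any force or moment
    remains; returns per-tip pass/fail keyed by segment index.
    """
    flat = solution.flat
    out: dict[int, bool] = {}
    w_tot = solution.dist_w * flat.length[:, None]
    pb, pt = solution.deformed_positions()
    dp = pt - pb
    for i in flat.tips():
        r_tip = solution.R_base[i] - w_tot[i] - solution.conc_f[i]
        m_tip = (
            solution.M_base[i]
            - np.cross(dp[i], solution.R_base[i] - w_tot[i])
            - 0.5 * np.cross(dp[i], w_tot[i])
        )
        out[int(i)] = bool(
            np.linalg.norm(r_tip) < tol_force and np.linalg.norm(m_tip) < tol_moment
        )
    return out


def commit_permanent(tree: Tree, solution: MechSolution) -> Tree:
    """Fold a converged gravity-increment solution into the rest pose.

    Rotates every internode's rest direction by its mid-segment rotation and
    accumulates the internal load increments; wind deformation is temporary
    by definition and committing it is a contract violation.
    """
    if solution.kind not in ("gravity_increment", "removal"):
        raise ContractViolationError(
            f"only gravity-increment solutions may be committed, got {solution.kind!r}"
        )
    flat = solution.flat
    th_base = solution.theta_base()
    th_mid = 0.5 * (th_base + solution.theta_tip)
    for i, ph in enumerate(flat.phytomers):
        d = ph.rest_dir + np.cross(th_mid[i], ph.rest_dir)
        ph.rest_dir = d / np.linalg.norm(d)
        ph.perm_force = ph.perm_force + solution.R_base[i]
        ph.perm_moment = ph.perm_moment + solution.M_base[i]
    return tree
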