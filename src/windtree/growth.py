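"""Per-cycle biomass production and source-sink allocation.

Each growth cycle the tree produces a biomass pool Q(n) from its leaf area
(a Beer-law saturating production rule), which is split between *primary*
growth (new leaf blades and internode piths, competing through per-PA sink
strengths) and *secondary* growth (a new wood ring on every standing
internode).  The secondary demand follows the pipe model: it is proportional
to the number of leaves borne in the previous cycle, with one sink unit
``S_layer`` per leaf.  The ring pool is then spread over internodes by a
mixture rule with parameter ``lambda``:

* lambda = 0 - biomass per unit length, weighted by the per-PA layer sink,
  i.e. uniform over internodes of the same PA;
* lambda = 1 - additionally proportional to the number of living leaves
  distal to the internode (pipe-model taper, stronger near the base).

Ring area follows from biomass, wood density and internode length; the
internode radius is the result of layer accumulation over the pith.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import structure
from .structure import Phytomer, Ring, Tree


class AllocationError(ValueError):
    pass


@dataclass
class GrowthParams:
    """Species parameters for the growth model (poplar preset in harness).

    Per-PA sequences are indexed PA 1..P_m.  Units: areas m^2 (ground) and
    cm^2 (organs), biomass g, lengths cm, densities g cm^-3, MOR Pa.
    """

    S_p: float = 12.0  # ground projection area of the crown (m^2)
    P_m: int = 4  # maximum physiological age
    e: float = 0.023  # specific leaf weight (g cm^-2)
    P_b: tuple[float, ...] = (1.0, 0.66, 0.32, 0.2)  # blade sink per PA
    P_i: tuple[float, ...] = (0.875, 0.5, 0.3, 0.1)  # pith sink per PA
    P_r: tuple[float, ...] = (0.8, 0.05, 0.05, 0.05)  # relative layer sink per PA
    alpha: tuple[float, ...] = (-0.28, -0.36, -0.26, -0.06)  # allometry exponent per PA
    beta: tuple[float, ...] = (6.51, 4.22, 3.77, 5.20)  # allometry scale per PA
    rho_pith: float = 0.36  # pith density (g cm^-3)
    rho_layer_range: tuple[float, float] = (0.36, 0.48)  # ring density bounds
    rho_layer_rings: int = 8  # ring index at which the density schedule saturates
    rho_layer_const: float | None = None  # constant density override
    MOR: float = 45.0e6  # modulus of rupture (Pa)
    S_layer: float = 1.0  # layer sink strength per leaf (control parameter)
    lam: float = 0.1  # ring allocation mode parameter, in [0, 1]
    E_pot: float = 5500.0  # potential production rate (g m^-2 per cycle)
    k_beer: float = 0.8  # production saturation coefficient
    leaf_lifespan: int = 1  # cycles
    Q_seed: float = 100.0  # seed reserve fuelling the first cycle (g)

    def validate(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise AllocationError("lambda must lie in [0, 1]")
        for name in ("P_b", "P_i", "P_r"):
            if any(v < 0 for v in getattr(self, name)):
                raise AllocationError(f"{name} sink strengths must be >= 0")
        if self.S_layer < 0:
            raise AllocationError("S_layer must be >= 0")

    def ring_density(self, ring_index: int) -> float:
        """Density of the ``ring_index``-th cambial ring (1-based).

        Linear from the lower to the upper bound of the configured range over
        ``rho_layer_rings`` rings, then constant (wood stiffens and densifies
        over the first years of ring formation).
        """
        if self.rho_layer_const is not None:
            return self.rho_layer_const
        lo, hi = self.rho_layer_range
        frac = min(max(ring_index - 1, 0) / max(self.rho_layer_rings - 1, 1), 1.0)
        return lo + (hi - lo) * frac


@dataclass
class AllocationReport:
    cycle: int
    Q_n: float  # production this cycle (g)
    D_total: float
    D_pri: float
    D_sec: float
    Q_pri: float
    Q_sec: float
    ring_allocations: dict[int, float] = field(default_factory=dict)  # id(phytomer) -> g


# ---------------------------------------------------------------------------
# production


def production(tree: Tree, params: GrowthParams, n: int) -> float:
    """Biomass pool Q(n) (g) produced at cycle ``n``.

    Saturating Beer-law form driven by the blade area active during the
    previous cycle; the first cycle runs on the seed reserve.
    """
    if n <= 1:
        return params.Q_seed
    a_leaf_m2 = blade_area_of_cycle(tree, n - 1)
    if a_leaf_m2 < 0:
        raise AllocationError("negative leaf area")
    return params.E_pot * params.S_p * (1.0 - math.exp(-params.k_beer * a_leaf_m2 / params.S_p))


def production_from_area(a_leaf_m2: float, params: GrowthParams) -> float:
    """Q(n) for a given living blade area (m^2)."""
    if a_leaf_m2 < 0:
        raise AllocationError("negative leaf area")
    return params.E_pot * params.S_p * (1.0 - math.exp(-params.k_beer * a_leaf_m2 / params.S_p))


def leaf_count_of_cycle(tree: Tree, cycle: int) -> int:
    """Number of leaves alive during ``cycle`` (the Eq-2 style census)."""
    count = 0
    for _, _, ph in structure.iter_phytomers(tree):
        for lf in ph.leaves:
            if lf.birth_cycle <= cycle and (lf.shed_cycle is None or lf.shed_cycle > cycle):
                count += 1
    return count


def blade_area_of_cycle(tree: Tree, cycle: int) -> float:
    """Total blade area (m^2) of leaves alive during ``cycle``."""
    total = 0.0
    for _, _, ph in structure.iter_phytomers(tree):
        for lf in ph.leaves:
            if lf.birth_cycle <= cycle and (lf.shed_cycle is None or lf.shed_cycle > cycle):
                total += lf.blade_area
    return total / 1.0e4  # cm^2 -> m^2


# ---------------------------------------------------------------------------
# demand and secondary pool


def primary_demand(tree: Tree, params: GrowthParams, n: int) -> float:
    """Sink demand of the organs created at cycle ``n`` (blades + piths)."""
    d = 0.0
    for _, _, ph in structure.iter_phytomers(tree):
        if ph.birth_cycle == n:
            d += params.P_i[ph.pa - 1] + len(ph.leaves) * params.P_b[ph.pa - 1]
    return d


def secondary_pool(
    params: GrowthParams,
    leaf_count_prev: np.ndarray | list[int],
    Q_n: float,
    D_total: float,
) -> tuple[float, float]:
    """Secondary-growth demand and pool: D_sec = S_layer * sum_p N_b(n-1);
    Q_sec = D_sec * Q_n / D_total."""
    n_leaves = float(np.sum(np.asarray(leaf_count_prev)))
    d_sec = params.S_layer * n_leaves
    if d_sec == 0.0:
        return 0.0, 0.0
    if D_total <= 0.0:
        if Q_n > 0.0:
            raise AllocationError("zero total demand with positive production")
        return d_sec, 0.0
    return d_sec, d_sec * Q_n / D_total


# ---------------------------------------------------------------------------
# ring distribution


def _living_leaf_counts_above(tree: Tree) -> dict[int, int]:
    """spa(j, n): living leaves borne by each internode's distal subtree
    (the internode's own leaves included)."""
    counts: dict[int, int] = {}

    def walk_axis(axis: structure.Axis) -> int:
        distal = 0
        for ph in reversed(axis.phytomers):
            distal += sum(1 for lf in ph.leaves if lf.alive)
            for child in ph.children:
                distal += walk_axis(child)
            counts[id(ph)] = distal
        return distal

    walk_axis(tree.trunk)
    return counts


def distribute_rings(
    tree: Tree, Q_sec: float, params: GrowthParams, n: int
) -> dict[int, float]:
    """Split the secondary pool over internodes (mixture rule, parameter lambda).

    Eligible internodes are all standing internodes created before cycle
    ``n``.  Returns ``{id(phytomer): ring biomass (g)}`` summing exactly to
    ``Q_sec``.
    """
    if Q_sec < 0:
        raise AllocationError("Q_sec must be >= 0")
    eligible = [
        ph
        for _, _, ph in structure.iter_phytomers(tree)
        if ph.birth_cycle < n and ph.pith_length > 0
    ]
    if not eligible:
        if Q_sec > 0:
            raise AllocationError("no eligible internode for ring allocation")
        return {}
    lam = params.lam
    spa = _living_leaf_counts_above(tree)
    w_len = np.array([ph.pith_length * params.P_r[ph.pa - 1] for ph in eligible])
    s = np.array([float(spa.get(id(ph), 0)) for ph in eligible])
    d1 = float(w_len.sum())
    d2 = float((w_len * s).sum())
    if d1 <= 0:
        raise AllocationError("zero length-weighted demand D1")
    if lam > 0 and d2 <= 0:
        warnings.warn("no living leaves above any internode; falling back to lambda=0")
        lam = 0.0
    share = (1.0 - lam) / d1 * w_len
    if lam > 0:
        share = share + lam * s / d2 * w_len
    q = share * Q_sec
    return {id(ph): float(qi) for ph, qi in zip(eligible, q)}


# ---------------------------------------------------------------------------
# primary allocation and ring geometry


def pith_dimensions(q: float, pa: int, params: GrowthParams) -> tuple[float, float]:
    """Length (cm) and section area (cm^2) of a pith of biomass ``q`` (g),
    from the allometric rule l = beta * q^((1+alpha)/2)."""
    if q <= 0:
        return 0.0, 0.0
    expo = (1.0 + params.alpha[pa - 1]) / 2.0
    length = params.beta[pa - 1] * q**expo
    area = q / (params.rho_pith * length)
    return length, area


def primary_allocation(tree: Tree, params: GrowthParams, Q_pri: float, n: int) -> float:
    """Size the organs created at cycle ``n`` from the primary pool.

    The pool is split proportionally to blade/pith sink strengths; blade
    area follows from the specific leaf weight, pith dimensions from the
    allometric rule.  Returns the biomass actually allocated (== Q_pri when
    there are new organs).
    """
    if Q_pri < 0:
        raise AllocationError("Q_pri must be >= 0")
    new = [ph for _, _, ph in structure.iter_phytomers(tree) if ph.birth_cycle == n]
    d_pri = sum(
        params.P_i[ph.pa - 1] + len(ph.leaves) * params.P_b[ph.pa - 1] for ph in new
    )
    if d_pri == 0:
        return 0.0
    unit = Q_pri / d_pri
    for ph in new:
        q_pith = params.P_i[ph.pa - 1] * unit
        ph.pith_biomass = q_pith
        ph.pith_length, ph.pith_area = pith_dimensions(q_pith, ph.pa, params)
        for lf in ph.leaves:
            lf.blade_biomass = params.P_b[ph.pa - 1] * unit
            lf.blade_area = lf.blade_biomass / params.e
    return Q_pri


def update_ring_geometry(
    phytomer: Phytomer, q_ring: float, density: float, n: int, params: GrowthParams | None = None
) -> float:
    """Append this cycle's ring to an internode and return the new radius (cm).

    Ring area = biomass / (density * length); radius accumulates layer areas
    over the pith.  A zero-biomass ring leaves the radius unchanged.
    """
    if q_ring < 0:
        raise AllocationError("ring biomass must be >= 0")
    if params is not None:
        lo, hi = params.rho_layer_range
        if not (lo - 1e-12 <= density <= hi + 1e-12):
            warnings.warn(
                f"ring density {density} outside configured range [{lo}, {hi}]"
            )
    if q_ring == 0:
        return phytomer.radius_cm
    if phytomer.pith_length <= 0:
        raise AllocationError("cannot add a ring to a zero-length internode")
    area = q_ring / (density * phytomer.pith_length)
    phytomer.rings.append(
        Ring(
            cycle_formed=n,
            area=area,
            density=density,
            biomass=q_ring,
            length=phytomer.pith_length,
        )
    )
    return phytomer.radius_cm


def allocate_cycle(tree: Tree, params: GrowthParams, n: int) -> AllocationReport:
    """Full source-sink step for cycle ``n`` (after organogenesis).

    Computes production, splits it between primary and secondary growth,
    sizes the new organs and lays down this cycle's rings.  Conserves the
    produced biomass exactly.
    """
    params.validate()
    # secondary demand is driven by the number of leaves of the last cycle
    n_leaves_prev = leaf_count_of_cycle(tree, n - 1)
    q_n = production(tree, params, n)
    d_pri = primary_demand(tree, params, n)
    d_sec = params.S_layer * float(n_leaves_prev) if n > 1 else 0.0
    d_total = d_pri + d_sec
    if d_total <= 0:
        return AllocationReport(n, q_n, 0.0, 0.0, 0.0, 0.0, 0.0)
    q_pri = q_n * d_pri / d_total
    q_sec = q_n * d_sec / d_total
    primary_allocation(tree, params, q_pri, n)
    rings = distribute_rings(tree, q_sec, params, n) if q_sec > 0 else {}
    by_id = {id(ph): ph for _, _, ph in structure.iter_phytomers(tree)}
    for pid, q_ring in rings.items():
        ph = by_id[pid]
        density = params.ring_density(len(ph.rings) + 1)
        update_ring_geometry(ph, q_ring, density, n, params)
    return AllocationReport(n, q_n, d_total, d_pri, d_sec, q_pri, q_sec, rings)


def shed_leaves(tree: Tree, params: GrowthParams, n: int) -> float:
    """Retire leaves older than the leaf lifespan at the start of cycle ``n``.
    Returns the shed biomass (g)."""
    shed = 0.0
    for _, _, ph in structure.iter_phytomers(tree):
        for lf in ph.leaves:
            if lf.alive and n - lf.birth_cycle >= params.leaf_lifespan:
                lf.alive = False
                lf.shed_cycle = n
                shed += lf.blade_biomass
    return shed
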