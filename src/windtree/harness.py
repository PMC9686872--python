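"""Growth-cycle orchestration, configuration and fixture presets.

One growth cycle runs four stages in a fixed order:

1. organogenesis + primary growth + ring allocation (the source-sink step);
2. gravity-increment equilibrium, committed as permanent deformation;
3. wind-on equilibrium with breakage checks at every iteration (temporary,
   elastic deformation);
4. wind-off consolidation - the elastic wind deformation is released, and
   if wind tore branches off, the lost weight is applied as a one-time
   negative load and the resulting spring-back is committed.

Everything is deterministic: two runs of the same configuration produce
identical trajectories.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import biomech, growth, safety, structure
from .biomech import MaterialParams
from .growth import GrowthParams
from .structure import TopologyRules, Tree
from .wind import WindField

log = logging.getLogger("windtree")


@dataclass
class MechSettings:
    material: MaterialParams = field(default_factory=MaterialParams)
    max_iter: int = 10  # equilibrium iterations per stage (N_p)
    tol: float = 1.0e-4  # displacement tolerance (m)
    tol_force: float = 1.0e-3  # free-tip force residual (N)
    tol_moment: float = 1.0e-3  # free-tip moment residual (N m)


@dataclass
class WindSettings:
    u_ref: float = 0.0  # speed at the reference height (m/s)
    azimuth_deg: float = 0.0
    h0: float = 10.0
    z0_ratio: float = 0.06
    rho_air: float = 1.226
    Cd: float = 0.25
    Cd_leaf: float = 0.2

    def field_(self) -> WindField:
        return WindField.from_azimuth(
            self.u_ref, self.azimuth_deg,
            h0=self.h0, z0_ratio=self.z0_ratio, rho_air=self.rho_air,
            Cd=self.Cd, Cd_leaf=self.Cd_leaf,
        )


@dataclass
class SimConfig:
    growth: GrowthParams = field(default_factory=GrowthParams)
    rules: TopologyRules | None = None
    wind: WindSettings = field(default_factory=WindSettings)
    mech: MechSettings = field(default_factory=MechSettings)
    horizon: int = 8
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rules is None:
            self.rules = default_rules(self.growth.P_m)
        self.growth.validate()
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")

    def with_wind(self, u_ref: float) -> "SimConfig":
        cfg = copy_config(self)
        cfg.wind.u_ref = u_ref
        cfg.out_dir = None
        return cfg

    def with_s_layer(self, s_layer: float) -> "SimConfig":
        cfg = copy_config(self)
        cfg.growth.S_layer = s_layer
        cfg.out_dir = None
        return cfg

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rules"]["phytomers_per_gu"] = dict(self.rules.phytomers_per_gu)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        gp = GrowthParams(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d.get("growth", {}).items()
        })
        rules_d = d.get("rules")
        rules = None
        if rules_d is not None:
            rules = TopologyRules(
                phytomers_per_gu={int(k): int(v) for k, v in rules_d["phytomers_per_gu"].items()},
                laterals_per_phytomer={int(k): list(v) for k, v in rules_d["laterals_per_phytomer"].items()},
                insertion_angle={int(k): float(v) for k, v in rules_d["insertion_angle"].items()},
                phyllotaxy_step=float(rules_d.get("phyllotaxy_step", 137.5)),
                lateral_period=(
                    {int(k): int(v) for k, v in rules_d["lateral_period"].items()}
                    if rules_d.get("lateral_period") else None
                ),
                leaves_per_phytomer=int(rules_d.get("leaves_per_phytomer", 1)),
            )
        wind = WindSettings(**d.get("wind", {}))
        mech_d = dict(d.get("mech", {}))
        mat = MaterialParams(**mech_d.pop("material", {}))
        mech = MechSettings(material=mat, **mech_d)
        return cls(
            growth=gp, rules=rules, wind=wind, mech=mech,
            horizon=int(d.get("horizon", 8)),
            out_dir=d.get("out_dir"),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(text))


def copy_config(cfg: SimConfig) -> SimConfig:
    return SimConfig.from_dict(cfg.to_dict())


def default_rules(p_max: int = 4) -> TopologyRules:
    """Default crown architecture: GU sizes (5,4,3,2) for PA 1..4, one
    lateral of PA p+1 per GU, insertion 45 deg, phyllotaxy 137.5 deg."""
    sizes = {1: 5, 2: 4, 3: 3, 4: 2}
    return TopologyRules(
        phytomers_per_gu={p: sizes.get(p, 2) for p in range(1, p_max + 1)},
        laterals_per_phytomer={p: [p + 1] for p in range(1, p_max)},
        insertion_angle={p: 45.0 for p in range(2, p_max + 1)},
        phyllotaxy_step=137.5,
    )


# ---------------------------------------------------------------------------
# per-cycle reporting


@dataclass
class CycleReport:
    cycle: int
    Q_n: float  # g, biomass produced
    Q_pri: float  # g
    Q_sec: float  # g
    Q_stem: float  # kg, standing stem biomass after the cycle
    H_tree: float  # m, trunk tip height (rest pose)
    leaf_area: float  # m^2, living blades
    dbh_cm: float | None  # trunk diameter at 1.3 m, rest pose
    top_deflection: float  # deg, wind-on
    broken_count: int
    trunk_broken: bool
    D_pri: float = 0.0  # primary sink demand
    D_sec: float = 0.0  # secondary (ring) sink demand
    pith_new_g: float = 0.0
    rings_new_g: float = 0.0
    blades_new_g: float = 0.0
    shed_g: float = 0.0
    severed_g: float = 0.0  # stems + leaves lost to breakage this cycle
    severed_stem_g: float = 0.0
    gravity_converged: bool = True
    wind_converged: bool = True
    wind_iterations: int = 0
    wind_trace: list = field(default_factory=list)


class CycleError(RuntimeError):
    def __init__(self, stage: str, cycle: int, cause: Exception):
        super().__init__(f"cycle {cycle}, stage {stage}: {cause}")
        self.stage = stage
        self.cycle = cycle


def _removal_commit(tree: Tree, removals: list[tuple[int, float]], mech: MechSettings) -> None:
    """Apply severed substructures as negative concentrated loads and commit
    the spring-back."""
    if not removals:
        return
    flat = biomech.flatten(tree, mech.material)
    if flat.n == 0:
        return
    index_of = {id(ph): i for i, ph in enumerate(flat.phytomers)}
    mapped = []
    for ph_id, weight_g in removals:
        if ph_id in index_of:
            mapped.append((index_of[ph_id], weight_g))
    if not mapped:
        return
    lc = biomech.assemble_loads(tree, "removal", flat, removals=mapped)
    sol = biomech.solve_equilibrium(tree, lc, mech.material, max_iter=mech.max_iter,
                                    tol=mech.tol, flat=flat)
    biomech.commit_permanent(tree, sol)


def run_growth_cycle(tree: Tree, config: SimConfig, n: int) -> tuple[Tree, CycleReport]:
    """Advance the tree by one growth cycle (see module docstring)."""
    gp = config.growth
    mech = config.mech
    stem_before = structure.total_stem_weight(tree)

    # -- stage 1: organogenesis and source-sink allocation --------------
    try:
        new_phs = structure.develop(tree, config.rules, n, gp.P_m)
        shed_g = growth.shed_leaves(tree, gp, n)
        alloc = growth.allocate_cycle(tree, gp, n)
        if alloc.Q_n <= 0.0 and new_phs:
            structure.rollback_develop(tree, new_phs)
            new_phs = []
    except Exception as exc:  # noqa: BLE001 - re-tag with stage diagnostics
        raise CycleError("growth", n, exc) from exc

    pith_new = sum(ph.pith_biomass for ph in new_phs)
    blades_new = sum(lf.blade_biomass for ph in new_phs for lf in ph.leaves)

    broken_count = 0
    trunk_broken = False
    severed_g = 0.0
    severed_stem_g = 0.0
    removals: list[tuple[int, float]] = []

    # -- stage 2: gravity increment, committed --------------------------
    try:
        flat = biomech.flatten(tree, mech.material)
        gsol_converged = True
        if flat.n:
            lc = biomech.assemble_loads(tree, "gravity_increment", flat, cycle=n)
            gsol = biomech.solve_equilibrium(
                tree, lc, mech.material, max_iter=mech.max_iter, tol=mech.tol, flat=flat
            )
            biomech.commit_permanent(tree, gsol)
            gsol_converged = gsol.converged
            # self-weight alone may already exceed the MOR on slender stems
            rep, _ = safety.detect_and_prune(tree, gsol, gp.MOR, include_solution_loads=False)
            if rep.broken:
                broken_count += len(rep.broken)
                trunk_broken = trunk_broken or rep.trunk_broken
                severed_g += rep.pruned_biomass_g
                removals.extend(rep.removals)
    except CycleError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise CycleError("gravity", n, exc) from exc

    # -- stage 3: wind-on equilibrium with breakage ----------------------
    top_deflection = 0.0
    wind_converged = True
    wind_iters = 0
    wind_trace: list = []
    if config.wind.u_ref > 0.0:
        try:
            wf = config.wind.field_()
            events: list[safety.SafetyReport] = []

            def on_iteration(flat_now, sol) -> bool:
                rep, _ = safety.detect_and_prune(tree, sol, gp.MOR)
                if rep.broken:
                    events.append(rep)
                    removals.extend(rep.removals)
                    return True
                return False

            wsol = biomech.solve_equilibrium(
                tree,
                biomech.LoadCase("wind_on", np.zeros((0, 3)), np.zeros((0, 3)), wf=wf),
                mech.material,
                max_iter=mech.max_iter,
                tol=mech.tol,
                on_iteration=on_iteration,
            )
            wind_converged = wsol.converged
            wind_iters = wsol.iterations
            wind_trace = wsol.trace
            top_deflection = wsol.top_deflection_deg()
            for rep in events:
                broken_count += len(rep.broken)
                trunk_broken = trunk_broken or rep.trunk_broken
                severed_g += rep.pruned_biomass_g
        except CycleError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise CycleError("wind", n, exc) from exc

    # -- stage 4: wind-off consolidation ---------------------------------
    # Elastic wind deformation is discarded with the wind; if branches were
    # severed, their weight leaves the structure permanently.
    try:
        stem_after = structure.total_stem_weight(tree)
        lost_stem = stem_before + pith_new + alloc.Q_sec - stem_after
        severed_stem_g = max(lost_stem, 0.0)
        if severed_g > 0:
            _removal_commit(tree, removals, mech)
    except CycleError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise CycleError("wind_off", n, exc) from exc

    report = CycleReport(
        cycle=n,
        Q_n=alloc.Q_n,
        Q_pri=alloc.Q_pri,
        Q_sec=alloc.Q_sec,
        Q_stem=structure.total_stem_weight(tree) / 1000.0,
        H_tree=structure.tree_height(tree),
        leaf_area=growth.blade_area_of_cycle(tree, n),
        dbh_cm=structure.trunk_dbh_cm(tree),
        top_deflection=top_deflection,
        broken_count=broken_count,
        trunk_broken=trunk_broken,
        D_pri=alloc.D_pri,
        D_sec=alloc.D_sec,
        pith_new_g=pith_new,
        rings_new_g=alloc.Q_sec,
        blades_new_g=blades_new,
        shed_g=shed_g,
        severed_g=severed_g,
        severed_stem_g=severed_stem_g,
        gravity_converged=gsol_converged,
        wind_converged=wind_converged,
        wind_iterations=wind_iters,
        wind_trace=wind_trace,
    )
    log.debug("cycle %d: Q=%.1f g, H=%.2f m, Q_stem=%.2f kg, broken=%d",
              n, report.Q_n, report.H_tree, report.Q_stem, broken_count)
    return tree, report


@dataclass
class Trajectory:
    cycles: list[CycleReport]
    tree: Tree

    @property
    def final(self) -> CycleReport | None:
        return self.cycles[-1] if self.cycles else None

    def to_frame(self):
        import pandas as pd

        rows = []
        for rep in self.cycles:
            d = dataclasses.asdict(rep)
            d.pop("wind_trace")
            rows.append(d)
        return pd.DataFrame(rows)


def run_simulation(config: SimConfig) -> Trajectory:
    """Run ``horizon`` growth cycles from seed; optionally export CSV/OBJ."""
    tree = Tree.seed(config.rules)
    reports: list[CycleReport] = []
    for n in range(1, config.horizon + 1):
        tree, rep = run_growth_cycle(tree, config, n)
        reports.append(rep)
    traj = Trajectory(reports, tree)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        traj.to_frame().to_csv(out / "cycles.csv", index=False)
        structure.export_internodes(tree).to_csv(out / "internodes.csv", index=False)
        structure.export_obj(tree, str(out / "tree.obj"))
        if reports and reports[-1].wind_trace:
            import pandas as pd

            pd.DataFrame(reports[-1].wind_trace).to_csv(out / "solver_trace.csv", index=False)
    return traj


# ---------------------------------------------------------------------------
# fixtures


def poplar_params(**overrides) -> GrowthParams:
    """Poplar parameter preset (crown area 12 m^2, P_m 4, MOR 45 MPa, ...)."""
    return GrowthParams(**overrides)


def make_fixtures(kind: str):
    """Canonical test/analysis scenarios.

    * ``cantilever`` - a vertical homogeneous beam (known EI) as a Tree,
      for analytic beam oracles;
    * ``single_stem`` - an unbranched tree configuration;
    * ``toy_tree`` - a small 2-PA branched configuration (<= 30 internodes);
    * ``poplar_preset`` - the full poplar parameter set.
    """
    if kind == "cantilever":
        return cantilever_fixture()
    if kind == "single_stem":
        gp = poplar_params()
        rules = TopologyRules(
            phytomers_per_gu={1: 4},
            laterals_per_phytomer={},
            insertion_angle={},
        )
        return SimConfig(growth=gp, rules=rules, horizon=6)
    if kind == "toy_tree":
        gp = poplar_params(P_m=2, P_b=(1.0, 0.66), P_i=(0.875, 0.5), P_r=(0.8, 0.05),
                           alpha=(-0.28, -0.36), beta=(6.51, 4.22), S_p=4.0)
        rules = TopologyRules(
            phytomers_per_gu={1: 3, 2: 2},
            laterals_per_phytomer={1: [2]},
            insertion_angle={2: 45.0},
            lateral_period={1: 3},
        )
        return SimConfig(growth=gp, rules=rules, horizon=4)
    if kind == "poplar_preset":
        return SimConfig(growth=poplar_params(), horizon=8)
    raise ValueError(f"unknown fixture kind {kind!r}")


def cantilever_fixture(
    n_segments: int = 8, total_length: float = 2.0, radius_m: float = 0.02,
    E: float = 7.0e9,
):
    """Vertical homogeneous cantilever as a Tree; EI = E pi r^4 / 4."""
    import math

    tree = Tree.seed()
    area_cm2 = math.pi * (radius_m * 100.0) ** 2
    seg_cm = total_length * 100.0 / n_segments
    for i in range(n_segments):
        ph = structure.Phytomer(
            pa=1, birth_cycle=1,
            pith_length=seg_cm,
            pith_area=area_cm2,
            pith_biomass=0.0,
        )
        tree.trunk.phytomers.append(ph)
    tree.age = 1
    material = MaterialParams(E_ref=E)
    ei = E * math.pi * radius_m**4 / 4.0
    return {"tree": tree, "material": material, "EI": ei,
            "length": total_length, "radius": radius_m}
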