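"""Production and source-sink allocation: worked values and conservation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from windtree import growth, harness, structure
from windtree.growth import (
    AllocationError,
    GrowthParams,
    distribute_rings,
    pith_dimensions,
    primary_allocation,
    production_from_area,
    secondary_pool,
    update_ring_geometry,
)
from windtree.structure import Axis, LeafOrgan, Phytomer, Tree


class TestProduction:
    def test_zero_leaf_area_zero_production(self):
        p = GrowthParams(E_pot=200.0, S_p=12.0, k_beer=1.0)
        assert production_from_area(0.0, p) == 0.0

    def test_saturates_at_potential(self):
        p = GrowthParams(E_pot=200.0, S_p=12.0, k_beer=1.0)
        q = production_from_area(100.0 * p.S_p, p)
        assert q == pytest.approx(p.E_pot * p.S_p, rel=1e-4)

    def test_worked_value(self):
        # E_pot=200, S_p=12, k=1, A=6 m^2 -> 2400 (1 - e^-0.5)
        p = GrowthParams(E_pot=200.0, S_p=12.0, k_beer=1.0)
        assert production_from_area(6.0, p) == pytest.approx(944.3264, abs=1e-3)

    def test_monotone_in_leaf_area(self):
        p = GrowthParams()
        areas = np.linspace(0, 50, 20)
        q = [production_from_area(a, p) for a in areas]
        assert all(b >= a for a, b in zip(q, q[1:]))

    def test_negative_area_rejected(self):
        with pytest.raises(AllocationError):
            production_from_area(-1.0, GrowthParams())


class TestSecondaryPool:
    def test_no_leaves_no_pool(self):
        d_sec, q_sec = secondary_pool(GrowthParams(S_layer=4.0), [0, 0], 500.0, 250.0)
        assert (d_sec, q_sec) == (0.0, 0.0)

    def test_worked_value(self):
        d_sec, q_sec = secondary_pool(GrowthParams(S_layer=4.0), [25], 500.0, 250.0)
        assert d_sec == pytest.approx(100.0)
        assert q_sec == pytest.approx(200.0)

    def test_monotone_in_s_layer(self):
        q1 = secondary_pool(GrowthParams(S_layer=2.0), [10], 500.0, 250.0)[1]
        q2 = secondary_pool(GrowthParams(S_layer=4.0), [10], 500.0, 250.0)[1]
        assert q2 > q1

    def test_zero_demand_with_production_raises(self):
        with pytest.raises(AllocationError):
            secondary_pool(GrowthParams(S_layer=1.0), [5], 100.0, 0.0)


def two_internode_tree(lengths_cm=(100.0, 200.0), leaves=(3, 1)):
    """Single-axis tree, two existing internodes with living leaves."""
    tree = Tree.seed()
    for length, n_leaf in zip(lengths_cm, leaves):
        ph = Phytomer(pa=1, birth_cycle=1, pith_length=length, pith_area=1.0,
                      pith_biomass=10.0)
        for _ in range(n_leaf):
            ph.leaves.append(LeafOrgan(1.0, 40.0, birth_cycle=1))
        tree.trunk.phytomers.append(ph)
    tree.age = 1
    return tree


class TestRingDistribution:
    def test_lambda0_proportional_to_length(self):
        tree = two_internode_tree()
        p = GrowthParams(lam=0.0)
        alloc = distribute_rings(tree, 30.0, p, n=2)
        lo, hi = tree.trunk.phytomers
        assert alloc[id(lo)] == pytest.approx(10.0)
        assert alloc[id(hi)] == pytest.approx(20.0)

    def test_lambda1_pipe_model(self):
        tree = two_internode_tree()
        p = GrowthParams(lam=1.0)
        alloc = distribute_rings(tree, 30.0, p, n=2)
        lo, hi = tree.trunk.phytomers
        # distal leaf counts: lower internode sees 4, upper 1; D2 = l*Pr*spa
        # with the lower bearing 3 own leaves: spa = (4, 1)
        d2 = 100 * 0.8 * 4 + 200 * 0.8 * 1
        assert alloc[id(lo)] == pytest.approx(100 * 0.8 * 4 / d2 * 30.0)
        assert alloc[id(hi)] == pytest.approx(200 * 0.8 * 1 / d2 * 30.0)

    def test_lambda1_hand_worked_split(self):
        # leaves counted strictly above give the textbook 18/12 split
        tree = two_internode_tree(leaves=(3, 1))
        # move the lower internode's leaves up so that spa = (3+1, 1) -> (4,1)
        # the hand-worked case with spa=(3,1), D2=4.0 (lengths in m):
        lo, hi = tree.trunk.phytomers
        lo.leaves = lo.leaves[:2]  # spa becomes (3, 1)
        alloc = distribute_rings(tree, 30.0, GrowthParams(lam=1.0), n=2)
        assert alloc[id(lo)] == pytest.approx(18.0)
        assert alloc[id(hi)] == pytest.approx(12.0)

    def test_no_leaves_falls_back_to_uniform(self):
        tree = two_internode_tree(leaves=(0, 0))
        with pytest.warns(UserWarning):
            alloc = distribute_rings(tree, 30.0, GrowthParams(lam=0.5), n=2)
        assert sum(alloc.values()) == pytest.approx(30.0)

    @given(lam=st.floats(0.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_partition_of_unity(self, lam):
        tree = two_internode_tree()
        alloc = distribute_rings(tree, 77.7, GrowthParams(lam=lam), n=2)
        assert sum(alloc.values()) == pytest.approx(77.7, rel=1e-9)

    def test_pruned_internodes_receive_nothing(self):
        tree = two_internode_tree()
        tree.trunk.phytomers[1].pith_length = 0.0  # degenerate/severed stub
        alloc = distribute_rings(tree, 30.0, GrowthParams(lam=0.0), n=2)
        assert len(alloc) == 1


class TestPrimaryAllocation:
    def test_worked_split(self):
        tree = Tree.seed()
        ph = Phytomer(pa=1, birth_cycle=1)
        ph.leaves.append(LeafOrgan(0.0, 0.0, 1))
        tree.trunk.phytomers.append(ph)
        tree.age = 1
        p = GrowthParams()  # P_b[0]=1, P_i[0]=0.875
        primary_allocation(tree, p, 15.0, n=1)
        assert ph.leaves[0].blade_biomass == pytest.approx(8.0)
        assert ph.pith_biomass == pytest.approx(7.0)
        assert ph.leaves[0].blade_area == pytest.approx(8.0 / 0.023, rel=1e-9)

    def test_zero_pool_zero_organs(self):
        tree = Tree.seed()
        ph = Phytomer(pa=1, birth_cycle=1)
        tree.trunk.phytomers.append(ph)
        tree.age = 1
        primary_allocation(tree, GrowthParams(), 0.0, n=1)
        assert ph.pith_biomass == 0.0

    def test_allometry_relation(self):
        p = GrowthParams()
        q = 20.0
        length, area = pith_dimensions(q, 1, p)
        assert length == pytest.approx(p.beta[0] * q ** ((1 + p.alpha[0]) / 2))
        assert area * length * p.rho_pith == pytest.approx(q, rel=1e-12)


class TestRingGeometry:
    def test_worked_area(self):
        ph = Phytomer(pa=1, birth_cycle=1, pith_length=100.0, pith_area=1.0)
        update_ring_geometry(ph, 20.0, 0.4, n=2)
        assert ph.rings[-1].area == pytest.approx(0.5)

    def test_worked_radius(self):
        ph = Phytomer(pa=1, birth_cycle=1, pith_length=100.0, pith_area=1.0)
        update_ring_geometry(ph, 20.0, 0.4, n=2)
        assert ph.radius_cm == pytest.approx(math.sqrt(1.5 / math.pi), abs=1e-4)
        assert ph.radius_cm == pytest.approx(0.6910, abs=1e-4)

    def test_zero_ring_keeps_radius(self):
        ph = Phytomer(pa=1, birth_cycle=1, pith_length=100.0, pith_area=1.0)
        r0 = ph.radius_cm
        update_ring_geometry(ph, 0.0, 0.4, n=2)
        assert ph.radius_cm == r0

    def test_density_outside_range_warns(self):
        ph = Phytomer(pa=1, birth_cycle=1, pith_length=100.0, pith_area=1.0)
        with pytest.warns(UserWarning):
            update_ring_geometry(ph, 1.0, 0.9, n=2, params=GrowthParams())


class TestFullCycleConservation:
    @pytest.mark.parametrize("lam", [0.0, 0.3, 1.0])
    @pytest.mark.parametrize("seed", [1, 2])
    def test_production_equals_allocation(self, lam, seed):
        rng = np.random.default_rng(seed)
        cfg = harness.make_fixtures("toy_tree")
        cfg.growth.lam = lam
        cfg.growth.S_layer = float(rng.uniform(0.3, 3.0))
        tree = Tree.seed(cfg.rules)
        for n in range(1, 4):
            structure.develop(tree, cfg.rules, n, cfg.growth.P_m)
            growth.shed_leaves(tree, cfg.growth, n)
            rep = growth.allocate_cycle(tree, cfg.growth, n)
            new_organs = sum(
                ph.pith_biomass + sum(lf.blade_biomass for lf in ph.leaves)
                for _, _, ph in structure.iter_phytomers(tree)
                if ph.birth_cycle == n
            )
            new_rings = sum(
                r.biomass
                for _, _, ph in structure.iter_phytomers(tree)
                for r in ph.rings
                if r.cycle_formed == n
            )
            assert new_organs + new_rings == pytest.approx(rep.Q_n, rel=1e-6)
            assert new_rings == pytest.approx(rep.Q_sec, rel=1e-6)

    def test_trunk_taper_with_lambda1(self):
        # pipe-model taper needs leaves distributed along the stem (lifespan
        # > 1) and a uniform ring density to isolate the allocation effect
        cfg = harness.make_fixtures("single_stem")
        cfg.growth.lam = 1.0
        cfg.growth.leaf_lifespan = 2
        cfg.growth.rho_layer_const = 0.40
        traj = harness.run_simulation(cfg)
        trunk = traj.tree.trunk.phytomers
        last = traj.tree.age
        # newest ring is thicker at the base (every living leaf is distal)
        # than on the highest ringed internode (only the newest GU distal)
        basal = next(r.area for r in trunk[0].rings if r.cycle_formed == last)
        apical_ph = [ph for ph in trunk if ph.birth_cycle == last - 1][-1]
        apical = next(r.area for r in apical_ph.rings if r.cycle_formed == last)
        assert basal >= apical
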