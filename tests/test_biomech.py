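"""Beam mechanics against Euler-Bernoulli closed forms and invariants."""

import math

import numpy as np
import pytest

from windtree import biomech, structure
from windtree.biomech import (
    BeamSegment,
    ContractViolationError,
    MaterialParams,
    MechState,
    SingularSectionError,
    composite_stiffness,
    transfer_step,
)
from windtree.harness import cantilever_fixture


def tip_point_load_solution(fx, load, axis=0):
    """Solve the cantilever fixture under a point load at the tip."""
    flat = biomech.flatten(fx["tree"], fx["material"])
    conc = np.zeros((flat.n, 3))
    conc[-1, axis] = load
    return flat, biomech.solve_linear(flat, np.zeros((flat.n, 3)), conc)


class TestCompositeStiffness:
    def test_homogeneous_disc(self):
        seg = BeamSegment(length=1.0, layers=[(0.02, 7.0e9)])
        ei, ea = composite_stiffness(seg)
        assert ei == pytest.approx(7e9 * math.pi * 0.02**4 / 4.0, rel=1e-12)
        assert ei == pytest.approx(879.65, abs=0.01)
        assert ea == pytest.approx(7e9 * math.pi * 0.02**2, rel=1e-12)

    def test_two_layers_match_quadrature(self):
        layers = [(0.015, 5.0e9), (0.025, 8.0e9)]
        seg = BeamSegment(length=1.0, layers=layers)
        ei, ea = composite_stiffness(seg)
        # independent oracle: radial quadrature, layer by layer
        # (I about a diameter is half the polar moment: dI = pi r^3 dr)
        ei_num = ea_num = 0.0
        r_in = 0.0
        for r_out, e_mod in layers:
            r = np.linspace(r_in, r_out, 100001)
            ei_num += np.trapezoid(e_mod * math.pi * r**3, r)
            ea_num += np.trapezoid(e_mod * 2 * math.pi * r, r)
            r_in = r_out
        assert ei == pytest.approx(ei_num, rel=1e-9)
        assert ea == pytest.approx(ea_num, rel=1e-9)

    def test_linear_in_modulus(self):
        ei1, _ = composite_stiffness(BeamSegment(1.0, [(0.02, 7e9)]))
        ei2, _ = composite_stiffness(BeamSegment(1.0, [(0.02, 14e9)]))
        assert ei2 == pytest.approx(2 * ei1)

    def test_outer_layer_strictly_increases(self):
        ei1, ea1 = composite_stiffness(BeamSegment(1.0, [(0.02, 7e9)]))
        ei2, ea2 = composite_stiffness(BeamSegment(1.0, [(0.02, 7e9), (0.022, 7e9)]))
        assert ei2 > ei1 and ea2 > ea1

    def test_empty_section_rejected(self):
        with pytest.raises(SingularSectionError):
            composite_stiffness(BeamSegment(1.0, []))


class TestTransferStep:
    def test_zero_state_zero_loads(self):
        seg = BeamSegment(length=2.0, layers=[(0.02, 7e9)])
        out = transfer_step(MechState(), seg)
        assert np.allclose(out.D, 0.0) and np.allclose(out.S, 0.0)

    def test_tip_point_load_closed_form(self):
        ei = 7e9 * math.pi * 0.02**4 / 4.0
        seg = BeamSegment(length=2.0, layers=[(0.02, 7e9)])
        # base resultant of a 10 N transverse tip load
        base = MechState(
            S=np.array([10.0, 0.0, 0.0, 0.0, 2.0 * 10.0, 0.0])
        )
        out = transfer_step(base, seg)
        assert out.translation[0] == pytest.approx(10 * 2**3 / (3 * ei), rel=1e-9)
        assert out.translation[0] == pytest.approx(0.030316, abs=1e-6)
        assert out.rotation[1] == pytest.approx(10 * 2**2 / (2 * ei), rel=1e-9)
        assert out.rotation[1] == pytest.approx(0.022737, abs=1e-6)

    def test_uniform_load_closed_form(self):
        ei = 7e9 * math.pi * 0.02**4 / 4.0
        q = 5.0
        seg = BeamSegment(
            length=2.0, layers=[(0.02, 7e9)],
            weight_increment=np.array([q, 0.0, 0.0]),
        )
        base = MechState(
            S=np.array([q * 2.0, 0.0, 0.0, 0.0, q * 2.0**2 / 2.0, 0.0])
        )
        out = transfer_step(base, seg)
        assert out.translation[0] == pytest.approx(q * 2**4 / (8 * ei), rel=1e-9)
        assert out.translation[0] == pytest.approx(0.011369, abs=1e-6)
        # tip resultant vanishes on a free tip
        assert np.linalg.norm(out.S) < 1e-9

    def test_non_finite_state_rejected(self):
        seg = BeamSegment(length=1.0, layers=[(0.02, 7e9)])
        bad = MechState(S=np.array([np.nan] * 6))
        with pytest.raises(FloatingPointError):
            transfer_step(bad, seg)


class TestTreeSolver:
    def test_cantilever_matches_closed_form(self, cantilever):
        flat, sol = tip_point_load_solution(cantilever, 10.0)
        ei = cantilever["EI"]
        L = cantilever["length"]
        assert sol["t_tip"][-1, 0] == pytest.approx(10 * L**3 / (3 * ei), rel=1e-9)
        assert sol["theta_tip"][-1, 1] == pytest.approx(10 * L**2 / (2 * ei), rel=1e-9)

    def test_uniform_load_matches_closed_form(self, cantilever):
        flat = biomech.flatten(cantilever["tree"], cantilever["material"])
        q = 5.0
        w = np.zeros((flat.n, 3))
        w[:, 0] = q
        sol = biomech.solve_linear(flat, w, np.zeros((flat.n, 3)))
        ei, L = cantilever["EI"], cantilever["length"]
        assert sol["t_tip"][-1, 0] == pytest.approx(q * L**4 / (8 * ei), rel=1e-9)

    def test_base_reaction_equals_total_load(self, cantilever):
        flat = biomech.flatten(cantilever["tree"], cantilever["material"])
        rng = np.random.default_rng(7)
        w = rng.normal(size=(flat.n, 3))
        c = rng.normal(size=(flat.n, 3))
        sol = biomech.solve_linear(flat, w, c)
        total = (w * flat.length[:, None]).sum(axis=0) + c.sum(axis=0)
        assert np.allclose(sol["R_base"][0], total, rtol=1e-9)

    def test_linearity_in_loads(self, cantilever):
        flat = biomech.flatten(cantilever["tree"], cantilever["material"])
        c = np.zeros((flat.n, 3))
        c[-1, 0] = 3.0
        s1 = biomech.solve_linear(flat, np.zeros((flat.n, 3)), c)
        s2 = biomech.solve_linear(flat, np.zeros((flat.n, 3)), 2 * c)
        assert np.allclose(2 * s1["t_tip"], s2["t_tip"], rtol=1e-12)

    def test_mesh_refinement_stable(self):
        coarse = cantilever_fixture(n_segments=8)
        fine = cantilever_fixture(n_segments=16)
        d = []
        for fx in (coarse, fine):
            _, sol = tip_point_load_solution(fx, 10.0)
            d.append(sol["t_tip"][-1, 0])
        assert abs(d[1] - d[0]) / d[0] < 0.005

    def test_branched_tree_reaction(self, toy_tree):
        mat = MaterialParams()
        flat = biomech.flatten(toy_tree, mat)
        rng = np.random.default_rng(11)
        w = rng.normal(size=(flat.n, 3)) * 0.01
        c = rng.normal(size=(flat.n, 3)) * 0.01
        sol = biomech.solve_linear(flat, w, c)
        total = (w * flat.length[:, None]).sum(axis=0) + c.sum(axis=0)
        assert np.allclose(sol["R_base"][0], total, rtol=1e-8)


class TestEquilibrium:
    def test_zero_load_converges_immediately(self, toy_tree):
        mat = MaterialParams()
        flat = biomech.flatten(toy_tree, mat)
        lc = biomech.LoadCase(
            "removal", np.zeros((flat.n, 3)), np.zeros((flat.n, 3))
        )
        sol = biomech.solve_equilibrium(toy_tree, lc, mat, flat=flat)
        assert sol.converged and sol.iterations == 1
        assert np.allclose(sol.t_tip, 0.0)

    def test_tip_boundary_check(self, cantilever):
        tree, mat = cantilever["tree"], cantilever["material"]
        flat = biomech.flatten(tree, mat)
        lc = biomech.assemble_loads(tree, "gravity_increment", flat, cycle=1)
        sol = biomech.solve_equilibrium(tree, lc, mat, flat=flat)
        checks = biomech.check_tip_boundary(sol, 1e-6, 1e-6)
        assert all(checks.values())
        # corrupting an internal resultant must break the tip condition
        sol.R_base[-1] += np.array([1.0, 0.0, 0.0])
        checks = biomech.check_tip_boundary(sol, 1e-6, 1e-6)
        assert not all(checks.values())

    def test_tolerance_scaling(self, cantilever):
        flat = biomech.flatten(cantilever["tree"], cantilever["material"])
        lc = biomech.LoadCase("removal", np.zeros((flat.n, 3)), np.zeros((flat.n, 3)))
        sol = biomech.solve_equilibrium(cantilever["tree"], lc, cantilever["material"], flat=flat)
        tight = biomech.check_tip_boundary(sol, 1e-9, 1e-9)
        loose = biomech.check_tip_boundary(sol, 1e-8, 1e-8)
        for k in tight:
            assert (not tight[k]) or loose[k]

    def test_commit_wind_solution_forbidden(self, toy_tree):
        mat = MaterialParams()
        flat = biomech.flatten(toy_tree, mat)
        sol = biomech.solve_equilibrium(
            toy_tree,
            biomech.LoadCase("removal", np.zeros((flat.n, 3)), np.zeros((flat.n, 3))),
            mat, flat=flat,
        )
        sol_bad = biomech.MechSolution(
            "wind_on", sol.flat, sol.t_tip, sol.theta_tip, sol.R_base,
            sol.M_base, sol.R_tipnode, sol.M_tipnode, sol.dist_w, sol.conc_f,
            True, False, 1,
        )
        with pytest.raises(ContractViolationError):
            biomech.commit_permanent(toy_tree, sol_bad)

    def test_commit_zero_solution_idempotent(self, toy_tree):
        mat = MaterialParams()
        dirs_before = [
            ph.rest_dir.copy() for _, _, ph in structure.iter_phytomers(toy_tree)
        ]
        flat = biomech.flatten(toy_tree, mat)
        lc = biomech.LoadCase("removal", np.zeros((flat.n, 3)), np.zeros((flat.n, 3)))
        sol = biomech.solve_equilibrium(toy_tree, lc, mat, flat=flat)
        biomech.commit_permanent(toy_tree, sol)
        dirs_after = [
            ph.rest_dir for _, _, ph in structure.iter_phytomers(toy_tree)
        ]
        for a, b in zip(dirs_before, dirs_after):
            assert np.allclose(a, b)

    def test_two_small_increments_superpose(self, cantilever):
        """Committing two half-loads approximates one full load (first order)."""
        import copy

        ei, L = cantilever["EI"], cantilever["length"]
        mat = cantilever["material"]

        def tip_after(loads):
            tree = copy.deepcopy(cantilever["tree"])
            for f in loads:
                flat = biomech.flatten(tree, mat)
                c = np.zeros((flat.n, 3))
                c[-1, 0] = f
                lc = biomech.LoadCase("removal", np.zeros((flat.n, 3)), c)
                sol = biomech.solve_equilibrium(tree, lc, mat, flat=flat)
                biomech.commit_permanent(tree, sol)
            pos = structure.rest_positions(tree)
            return pos[id(tree.trunk.phytomers[-1])][1][0]

        one = tip_after([10.0])
        two = tip_after([5.0, 5.0])
        assert two == pytest.approx(one, rel=0.05)
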