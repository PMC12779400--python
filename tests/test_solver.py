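"""FE solver: patch tests against the scalar free-swelling oracle,
objectivity, domain volumes, constraints."""

from __future__ import annotations

import numpy as np
import pytest

from craniogrowth.fe.materials import CellGrowth, NeoHookean, free_swelling_equilibrium
from craniogrowth.fe.solver import GrowthSchedule, SolverParams, scenario_schedule, solve_growth
from craniogrowth.mesh import TetMesh, tet_volumes
from craniogrowth.synthetic.head import voxel_tet_mesh

BALL_MATS = {"brain": CellGrowth()}


class TestSchedules:
    def test_scenario_ramps_match_published_endpoints(self):
        br = scenario_schedule("Br")
        assert br.ramps["brain"]["phir"] == (0.3, 1.35)
        assert br.ramps["brain"]["cr"] == (210.0, 945.0)
        m = scenario_schedule("M")
        assert m.ramps["muscle_L1"]["phir"] == (0.3, 0.9)
        assert m.ramps["muscle_L1"]["cr"] == (210.0, 630.0)
        assert scenario_schedule("N").ramps == {}
        both = scenario_schedule("Br+M")
        assert "brain" in both.ramps and "muscle_R2" in both.ramps

    def test_scaling_interpolates_endpoints(self):
        br = scenario_schedule("Br").scaled({"brain": 0.5})
        assert br.ramps["brain"]["phir"] == (0.3, pytest.approx(0.825))
        assert br.ramps["brain"]["cr"] == (210.0, pytest.approx(577.5))

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            scenario_schedule("X")


class TestFlatScenario:
    def test_baseline_has_zero_displacement_and_unit_ratios(self, ball_mesh):
        mesh, fixed = ball_mesh
        res = solve_growth(mesh, BALL_MATS, GrowthSchedule(scenario="N"), fixed_dofs=fixed)
        assert np.abs(res.displacement).max() < 1e-8
        assert res.volume_ratios["brain"] == pytest.approx(1.0, abs=1e-10)


class TestFreeSwellingPatch:
    @pytest.mark.parametrize("phir_end,cr_end", [(0.5, 350.0), (0.9, 630.0)])
    def test_unconstrained_body_matches_scalar_oracle(self, ball_mesh, phir_end, cr_end):
        """Homogeneous free swelling: the FE volume ratio equals the scalar
        equilibrium J within 0.5 % and the J field is uniform."""
        mesh, fixed = ball_mesh
        sched = GrowthSchedule(
            ramps={"brain": {"phir": (0.3, phir_end), "cr": (210.0, cr_end)}},
            n_steps=5,
            scenario="Br",
        )
        res = solve_growth(mesh, BALL_MATS, sched, fixed_dofs=fixed)
        j_oracle = free_swelling_equilibrium(CellGrowth(), phir=phir_end, cr=cr_end)
        assert res.volume_ratios["brain"] == pytest.approx(j_oracle, rel=5e-3)
        jel = tet_volumes(mesh.nodes + res.displacement, mesh.tets) / tet_volumes(
            mesh.nodes, mesh.tets
        )
        assert np.ptp(jel) / j_oracle < 5e-3

    def test_confined_ball_swells_less_and_is_pressurised(self):
        """The same tissue inside a rigid fully-fixed bone shell reaches a
        smaller J than in free swelling, with positive (compressive)
        pressure."""
        def classify(p):
            r2 = (p**2).sum(axis=1)
            out = np.full(len(p), -1)
            out[r2 <= 14.0**2] = 0  # bone shell
            out[r2 <= 10.0**2] = 1  # brain core
            return out

        nodes, tets, dom = voxel_tet_mesh(classify, ((-16, 16),) * 3, 2.5)
        mesh = TetMesh(nodes=nodes, tets=tets, domain=dom)
        bone_nodes = np.unique(tets[dom == 0])
        fixed = (3 * bone_nodes[:, None] + np.arange(3)).ravel()
        mats = {"brain": CellGrowth(), "bone": NeoHookean()}
        sched = GrowthSchedule(
            ramps={"brain": {"phir": (0.3, 0.5), "cr": (210.0, 350.0)}}, n_steps=5
        )
        res = solve_growth(mesh, mats, sched, fixed_dofs=fixed)
        j_free = free_swelling_equilibrium(CellGrowth(), phir=0.5, cr=350.0)
        assert res.volume_ratios["brain"] < j_free
        # pressure = RT (cr/(J - phir) - ce) > 0 when confined below free J
        mat = CellGrowth()
        pi = mat.osmotic_pressure(res.volume_ratios["brain"], phir=0.5, cr=350.0)
        assert pi > 0

    def test_newton_is_quadratic_near_solution(self, ball_mesh):
        """Iteration counts stay small (consistent-tangent Newton) across
        the load steps of the patch test."""
        mesh, fixed = ball_mesh
        sched = GrowthSchedule(
            ramps={"brain": {"phir": (0.3, 0.5), "cr": (210.0, 350.0)}}, n_steps=5
        )
        res = solve_growth(mesh, BALL_MATS, sched, fixed_dofs=fixed)
        iters = [rec["iterations"] for rec in res.log]
        assert max(iters) <= 8

    def test_residuals_below_tolerance_each_accepted_step(self, ball_mesh):
        mesh, fixed = ball_mesh
        sp = SolverParams()
        sched = GrowthSchedule(
            ramps={"brain": {"phir": (0.3, 0.45), "cr": (210.0, 320.0)}}, n_steps=4
        )
        res = solve_growth(mesh, BALL_MATS, sched, sp, fixed_dofs=fixed)
        for rec in res.log:
            assert rec["residual"] <= sp.rtol * max(rec["r0"], 1e-30) + sp.atol


class TestObjectivity:
    def test_rotating_the_problem_rotates_the_solution(self, rng):
        """Zero-displacement constraints are frame-invariant when whole
        nodes are fixed, so rotating the reference mesh must rotate the
        converged displacement field."""

        def classify(p):
            r2 = (p**2).sum(axis=1)
            out = np.full(len(p), -1)
            out[r2 <= 13.0**2] = 0  # bone shell
            out[r2 <= 9.0**2] = 1  # growing core
            return out

        nodes, tets, dom = voxel_tet_mesh(classify, ((-15, 15),) * 3, 3.0)
        bone_nodes = np.unique(tets[dom == 0])
        fixed = (3 * bone_nodes[:, None] + np.arange(3)).ravel()
        mats = {"brain": CellGrowth(), "bone": NeoHookean()}
        sched = GrowthSchedule(
            ramps={"brain": {"phir": (0.3, 0.42), "cr": (210.0, 300.0)}}, n_steps=3
        )
        mesh = TetMesh(nodes=nodes, tets=tets, domain=dom)
        res = solve_growth(mesh, mats, sched, fixed_dofs=fixed)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        rotated = TetMesh(nodes=mesh.nodes @ q.T, tets=mesh.tets, domain=mesh.domain)
        res_rot = solve_growth(rotated, mats, sched, fixed_dofs=fixed)
        err = np.abs(res_rot.displacement - res.displacement @ q.T).max()
        scale = max(np.abs(res.displacement).max(), 1.0)
        assert err / scale < 1e-6


class TestDomainVolume:
    def test_zero_displacement_gives_reference_volume(self, small_head_mesh):
        u = np.zeros((small_head_mesh.n_nodes, 3))
        assert small_head_mesh.domain_volume("brain", u) == small_head_mesh.domain_volume("brain")

    def test_uniform_stretch_scales_volume_by_determinant(self, small_head_mesh):
        d = np.array([1.1, 0.9, 1.25])
        u = small_head_mesh.nodes * (d - 1.0)
        v0 = small_head_mesh.domain_volume("bone")
        v1 = small_head_mesh.domain_volume("bone", u)
        assert v1 == pytest.approx(v0 * d.prod(), rel=1e-12)

    def test_matches_per_element_determinant_oracle(self, small_head_mesh, rng):
        u = rng.normal(size=(small_head_mesh.n_nodes, 3)) * 0.01
        idx = small_head_mesh.tets_of("brain")
        tets = small_head_mesh.tets[idx]
        x0 = small_head_mesh.nodes
        x1 = x0 + u
        # oracle: integrate det F over each element (constant on linear tets)
        total = 0.0
        for t in tets[:400]:
            d0 = np.column_stack([x0[t[1]] - x0[t[0]], x0[t[2]] - x0[t[0]], x0[t[3]] - x0[t[0]]])
            d1 = np.column_stack([x1[t[1]] - x1[t[0]], x1[t[2]] - x1[t[0]], x1[t[3]] - x1[t[0]]])
            v_ref = np.linalg.det(d0) / 6.0
            total += v_ref * np.linalg.det(d1 @ np.linalg.inv(d0))
        partial = tet_volumes(x1, tets[:400]).sum()
        assert partial == pytest.approx(total, rel=1e-10)

    def test_inverted_element_reported(self, small_head_mesh):
        u = -0.9 * small_head_mesh.nodes  # crush towards origin, inverting nothing
        u[:, 0] = -1.5 * small_head_mesh.nodes[:, 0]  # flip x: inversion
        with pytest.raises(ValueError, match="inverted"):
            small_head_mesh.domain_volume("brain", u)


class TestConstraints:
    def test_constrained_nodes_do_not_move(self, small_head_mesh):
        res = solve_growth(small_head_mesh, schedule=GrowthSchedule(scenario="N"))
        for name in ("condyle_L", "condyle_R", "anchor"):
            idx = small_head_mesh.node_sets[name]
            assert np.abs(res.displacement[idx]).max() < 1e-12

    def test_missing_material_rejected(self, small_head_mesh):
        with pytest.raises(ValueError, match="no material"):
            solve_growth(small_head_mesh, {"bone": NeoHookean()}, GrowthSchedule())
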