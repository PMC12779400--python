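"""Quasi-static total-Lagrangian finite-element solver on linear tetrahedra.

Growth is applied in pseudo-time: at each load step the cell-growth state
(phir, cr) of every growing domain is moved along its ramp and static
equilibrium is re-solved by Newton iteration with a consistent tangent,
optional backtracking line search, and automatic step bisection on failure.
Displacements are fixed to zero on the condylar and anchor node sets.  There
is no unloading: the retained deformed configuration is the model's
"plastic" shape change.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import splu

from ..mesh import DOMAIN_NAMES, MUSCLE_DOMAINS, TetMesh, tet_volumes
from ..morpho.config import LandmarkConfiguration
from ..scheme import default_scheme
from .materials import CellGrowth, MaterialSpec, NeoHookean, StepFailure, pk1_stress

__all__ = ["GrowthSchedule", "SolverParams", "SimulationResult", "solve_growth", "scenario_schedule"]

#: Paper-anchored ramp endpoints for the two growing tissues.
BRAIN_RAMP = {"phir": (0.3, 1.35), "cr": (210.0, 945.0)}
MUSCLE_RAMP = {"phir": (0.3, 0.9), "cr": (210.0, 630.0)}


@dataclass(frozen=True)
class GrowthSchedule:
    """Piecewise-linear (phir, cr) ramps per growing domain over pseudo-time.

    ``ramps`` maps domain name -> {"phir": (start, end), "cr": (start, end)}.
    Domains not listed keep their reference state.  The scenario id is one
    of N (flat), Br (brain), M (muscles), Br+M (both).
    """

    ramps: dict = field(default_factory=dict)
    n_steps: int = 10
    scenario: str = "N"

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    def state_at(self, domain: str, t: float, material: CellGrowth) -> tuple[float, float]:
        """Growth state (phir, cr) of a domain at pseudo-time t in [0, 1]."""
        ramp = self.ramps.get(domain)
        if ramp is None:
            return material.phir, material.cr
        p0, p1 = ramp["phir"]
        c0, c1 = ramp["cr"]
        return p0 + t * (p1 - p0), c0 + t * (c1 - c0)

    def scaled(self, factors: dict[str, float]) -> "GrowthSchedule":
        """Scale ramp endpoints toward/beyond the baseline by a multiplier
        per domain: end' = start + factor * (end - start)."""
        ramps = {}
        for dom, ramp in self.ramps.items():
            f = factors.get(dom, 1.0)
            ramps[dom] = {
                k: (v[0], v[0] + f * (v[1] - v[0])) for k, v in ramp.items()
            }
        return replace(self, ramps=ramps)


def scenario_schedule(scenario: str, n_steps: int = 10) -> GrowthSchedule:
    """Build the N / Br / M / Br+M growth schedule."""
    ramps: dict = {}
    if scenario in ("Br", "Br+M", "BrM"):
        ramps["brain"] = {k: v for k, v in BRAIN_RAMP.items()}
    if scenario in ("M", "Br+M", "BrM"):
        for m in MUSCLE_DOMAINS:
            ramps[m] = {k: v for k, v in MUSCLE_RAMP.items()}
    if scenario not in ("N", "Br", "M", "Br+M", "BrM"):
        raise ValueError(f"unknown scenario {scenario!r}")
    return GrowthSchedule(ramps=ramps, n_steps=n_steps, scenario="Br+M" if scenario == "BrM" else scenario)


@dataclass(frozen=True)
class SolverParams:
    """Newton/continuation controls."""

    rtol: float = 1e-6
    atol: float = 1e-8
    max_newton: int = 25
    line_search: bool = True
    max_bisections: int = 4
    min_step: float = 1.0 / 160.0
    #: trust-region-like cap on the Newton increment (mm); guards against
    #: huge steps through near-singular (buckling) tangents
    max_increment: float = 25.0

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class SimulationResult:
    """Converged growth simulation."""

    mesh: TetMesh
    displacement: np.ndarray  # (N, 3) mm
    volume_ratios: dict[str, float]  # per-domain deformed/reference volume
    log: list  # per accepted step: dict(step, t, iterations, residual)
    scenario: str

    @property
    def deformed_nodes(self) -> np.ndarray:
        return self.mesh.nodes + self.displacement

    def deformed_landmarks(self, specimen_id: str = "") -> LandmarkConfiguration:
        coords = self.mesh.landmark_coords(self.displacement)
        return LandmarkConfiguration(coords, default_scheme(), specimen_id=specimen_id or self.scenario)

    def volume_change_percent(self, domain: str | list[str]) -> float:
        ref = self.mesh.domain_volume(domain)
        cur = self.mesh.domain_volume(domain, self.displacement)
        return 100.0 * (cur - ref) / ref


class _Assembler:
    """Precomputed element data + vectorised residual/stiffness assembly."""

    def __init__(self, mesh: TetMesh, materials: MaterialSpec):
        self.mesh = mesh
        nodes, tets = mesh.nodes, mesh.tets
        d = np.stack(
            [nodes[tets[:, 1]] - nodes[tets[:, 0]],
             nodes[tets[:, 2]] - nodes[tets[:, 0]],
             nodes[tets[:, 3]] - nodes[tets[:, 0]]], axis=1
        )  # (M,3,3) rows are edge vectors
        self.V0 = np.linalg.det(d) / 6.0
        dinv = np.linalg.inv(d)  # columns of dinv are grad lambda_a
        grad = np.transpose(dinv, (0, 2, 1))  # (M, 3(a=1..3), 3)
        g0 = -grad.sum(axis=1, keepdims=True)
        self.gradN = np.concatenate([g0, grad], axis=1)  # (M,4,3)
        self.materials = materials
        # group elements by domain for material evaluation
        self.groups = {
            name: mesh.tets_of(name) for name in DOMAIN_NAMES if mesh.tets_of(name).size
        }
        # sparse assembly indices (M*12 x 12 pattern)
        dof = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
        self.rows = np.repeat(dof, 12, axis=1).ravel()
        self.cols = np.tile(dof, (1, 12)).ravel()
        self.ndof = 3 * mesh.n_nodes

    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        ue = u.reshape(-1, 3)[self.mesh.tets]  # (M,4,3)
        return np.einsum("mai,maJ->miJ", ue, self.gradN) + np.eye(3)

    def total_energy(self, u: np.ndarray, growth_state: dict) -> float:
        """Total strain energy (line-search merit function)."""
        from .materials import strain_energy_density

        F = self.deformation_gradients(u)
        w = np.empty(len(F))
        for name, idx in self.groups.items():
            mat = self.materials[name]
            if isinstance(mat, CellGrowth):
                phir, cr = growth_state.get(name, (mat.phir, mat.cr))
                w[idx] = strain_energy_density(F[idx], mat, phir=phir, cr=cr)
            else:
                w[idx] = strain_energy_density(F[idx], mat)
        return float(self.V0 @ w)

    def assemble(self, u: np.ndarray, growth_state: dict, need_K: bool = True):
        """Internal force vector (ndof,) and optional tangent CSC matrix."""
        F = self.deformation_gradients(u)
        M = len(F)
        P = np.empty((M, 3, 3))
        A = np.empty((M, 3, 3, 3, 3)) if need_K else None
        for name, idx in self.groups.items():
            mat = self.materials[name]
            if isinstance(mat, CellGrowth):
                phir, cr = growth_state.get(name, (mat.phir, mat.cr))
                p, a = pk1_stress(F[idx], mat, phir=phir, cr=cr, tangent=need_K, strict=False)
            else:
                p, a = pk1_stress(F[idx], mat, tangent=need_K)
            P[idx] = p
            if need_K:
                A[idx] = a
        fel = np.einsum("m,miJ,maJ->mai", self.V0, P, self.gradN)
        fint = np.zeros(self.ndof)
        np.add.at(fint, (3 * self.mesh.tets[:, :, None] + np.arange(3)).ravel(), fel.ravel())
        if not need_K:
            return fint, None
        t1 = np.einsum("miJkL,maJ->maikL", A, self.gradN)
        kel = np.einsum("m,maikL,mbL->maibk", self.V0, t1, self.gradN).reshape(-1)
        K = csc_matrix((kel, (self.rows, self.cols)), shape=(self.ndof, self.ndof))
        return fint, K


def _growth_state(schedule: GrowthSchedule, materials: MaterialSpec, t: float) -> dict:
    state = {}
    for name, mat in materials.items():
        if isinstance(mat, CellGrowth):
            state[name] = schedule.state_at(name, t, mat)
    return state


def newton_equilibrate(
    asm: _Assembler,
    free: np.ndarray,
    state: dict,
    u: np.ndarray,
    solver: SolverParams,
) -> tuple[np.ndarray, int, float, float, bool]:
    """Newton iteration to static equilibrium at a fixed growth state.

    Returns (u, iterations, residual, initial residual, converged).
    Raises StepFailure if the constitutive response fails irrecoverably.
    """
    u_trial = u.copy()
    r0 = np.nan
    res = np.nan
    energy = asm.total_energy(u_trial, state)
    for it in range(1, solver.max_newton + 1):
        fint, K = asm.assemble(u_trial, state)
        res = float(np.linalg.norm(fint[free]))
        if it == 1:
            r0 = res
        if res <= solver.rtol * max(r0, 1e-30) + solver.atol:
            return u_trial, it, res, r0, True
        lu = splu(K[free][:, free].tocsc())
        du = lu.solve(-fint[free])
        big = np.abs(du).max()
        if big > solver.max_increment:
            du *= solver.max_increment / big
        # backtracking on the total strain energy (both materials are
        # hyperelastic, so the energy is the natural merit function and is
        # far more robust than the residual norm near instabilities)
        slope = float(fint[free] @ du)  # directional derivative of energy
        step = 1.0
        best = None  # (energy, displacement)
        while step >= 1.0 / 64.0:
            u_new = u_trial.copy()
            u_new[free] += step * du
            try:
                e_new = asm.total_energy(u_new, state)
            except StepFailure:
                step *= 0.5
                continue
            if best is None or e_new < best[0]:
                best = (e_new, u_new)
            if e_new <= energy + 1e-4 * step * slope or not solver.line_search:
                break
            step *= 0.5
        if best is None:
            raise StepFailure("line search failed")
        energy, u_trial = best
    return u_trial, solver.max_newton, res, r0, False


def solve_growth(
    mesh: TetMesh,
    materials: MaterialSpec | None = None,
    schedule: GrowthSchedule | None = None,
    solver: SolverParams | None = None,
    fixed_sets: tuple[str, ...] = ("condyle_L", "condyle_R", "anchor"),
    fixed_dofs: np.ndarray | None = None,
    initial_displacement: np.ndarray | None = None,
) -> SimulationResult:
    """Run the load-stepped Newton solve of a growth schedule.

    Parameters
    ----------
    mesh : TetMesh
    materials : per-domain MaterialSpec (defaults: 300 MPa bone, baseline
        cell-growth soft tissues)
    schedule : GrowthSchedule (default: scenario N, flat ramps)
    solver : SolverParams
    fixed_sets : node-set names receiving zero-displacement constraints
    fixed_dofs : explicit dof indices to fix instead of ``fixed_sets``
        (used by patch tests on meshes without condyles)
    initial_displacement : optional warm start for the displacement field
        (path independence makes the final state independent of it)

    Returns
    -------
    SimulationResult

    Raises
    ------
    RuntimeError
        If bisections are exhausted before reaching pseudo-time 1.
    """
    from .materials import default_materials

    materials = default_materials() if materials is None else materials
    schedule = GrowthSchedule() if schedule is None else schedule
    solver = SolverParams() if solver is None else solver
    for name in DOMAIN_NAMES:
        if np.any(mesh.domain == DOMAIN_NAMES.index(name)) and name not in materials:
            raise ValueError(f"no material for domain {name}")

    asm = _Assembler(mesh, materials)
    if fixed_dofs is None:
        fixed_nodes = np.unique(np.concatenate([mesh.node_sets[s] for s in fixed_sets]))
        fixed_dofs = (3 * fixed_nodes[:, None] + np.arange(3)).ravel()
    free = np.setdiff1d(np.arange(asm.ndof), fixed_dofs)
    if free.size == asm.ndof:
        raise ValueError("no constrained dofs; the system would be singular")

    u = np.zeros(asm.ndof) if initial_displacement is None else initial_displacement.ravel().copy()
    t = 0.0
    dt = 1.0 / schedule.n_steps
    log: list[dict] = []
    n_bisect = 0
    while t < 1.0 - 1e-12:
        dt = min(dt, 1.0 - t)
        t_try = t + dt
        state = _growth_state(schedule, materials, t_try)
        res = np.nan
        try:
            u_trial, it, res, r0, ok = newton_equilibrate(asm, free, state, u, solver)
        except StepFailure:
            ok = False
        if ok:
            u = u_trial
            t = t_try
            log.append({"step": len(log) + 1, "t": t, "iterations": it, "residual": res, "r0": r0})
            dt = min(2.0 * dt, 1.0 / schedule.n_steps)
        else:
            dt *= 0.5
            n_bisect += 1
            if dt < solver.min_step or n_bisect > 8 * solver.max_bisections:
                raise RuntimeError(
                    f"growth solve failed at t={t:.4f}: bisection exhausted "
                    f"(last residual {res}); {len(log)} accepted steps"
                )

    ratios = {}
    for name in DOMAIN_NAMES:
        idx = mesh.tets_of(name)
        if idx.size:
            ref = tet_volumes(mesh.nodes, mesh.tets[idx]).sum()
            cur = tet_volumes(mesh.nodes + u.reshape(-1, 3), mesh.tets[idx]).sum()
            ratios[name] = float(cur / ref)
    return SimulationResult(
        mesh=mesh,
        displacement=u.reshape(-1, 3),
        volume_ratios=ratios,
        log=log,
        scenario=schedule.scenario,
    )
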