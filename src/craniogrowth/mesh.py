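"""Labeled tetrahedral multi-domain mesh.

The container used by the growth simulation: node coordinates in mm,
tetrahedra with one domain label each (bone, brain, four masticatory-muscle
bodies, mandible), named node sets for boundary conditions, and landmarks
embedded as (tet, barycentric-weight) anchors so they track any deformation
linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical domain order; indices are the labels stored per tet.
DOMAIN_NAMES = (
    "bone",
    "brain",
    "muscle_L1",
    "muscle_R1",
    "muscle_L2",
    "muscle_R2",
    "mandible",
)

MUSCLE_DOMAINS = ("muscle_L1", "muscle_R1", "muscle_L2", "muscle_R2")


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for correctly oriented tets)."""
    a = nodes[tets[:, 0]]
    e1 = nodes[tets[:, 1]] - a
    e2 = nodes[tets[:, 2]] - a
    e3 = nodes[tets[:, 3]] - a
    return np.einsum("ij,ij->i", np.cross(e1, e2), e3) / 6.0


@dataclass
class LandmarkAnchor:
    """A landmark tied to a tetrahedron by barycentric weights."""

    name: str
    tet: int
    weights: np.ndarray  # (4,) non-negative, sums to 1


@dataclass
class TetMesh:
    """Multi-domain tetrahedral mesh.

    Attributes
    ----------
    nodes : (N, 3) float array, mm
    tets : (M, 4) int array
        Positively oriented.
    domain : (M,) int array
        Index into DOMAIN_NAMES.
    node_sets : dict of name -> int array
        At least ``condyle_L``, ``condyle_R`` and ``anchor`` for simulation.
    landmark_anchors : list of LandmarkAnchor
    diagnostics : dict
        Generator-reported quality figures (min dihedral angle, cell size...).
    region_params : dict
        Parametric values used to label surface regions (vault/face/base).
    """

    nodes: np.ndarray
    tets: np.ndarray
    domain: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    landmark_anchors: list[LandmarkAnchor] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    region_params: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]

    def domain_index(self, name: str) -> int:
        return DOMAIN_NAMES.index(name)

    def tets_of(self, domains: str | list[str]) -> np.ndarray:
        """Indices of tets belonging to the named domain(s)."""
        if isinstance(domains, str):
            domains = [domains]
        codes = [self.domain_index(d) for d in domains]
        return np.flatnonzero(np.isin(self.domain, codes))

    def domain_volume(self, domain: str | list[str], displacement: np.ndarray | None = None) -> float:
        """Sum of signed tet volumes over a domain, optionally deformed.

        Raises if any deformed element is inverted.
        """
        nodes = self.nodes if displacement is None else self.nodes + displacement
        idx = self.tets_of(domain)
        vols = tet_volumes(nodes, self.tets[idx])
        if np.any(vols <= 0):
            bad = idx[np.argmin(vols)]
            raise ValueError(f"inverted element {bad} (volume {vols.min():.3e})")
        return float(vols.sum())

    def landmark_coords(self, displacement: np.ndarray | None = None) -> np.ndarray:
        """Evaluate landmark anchors, optionally under a displacement field.

        Barycentric evaluation is linear, so deforming the nodes and
        re-evaluating equals deforming the anchor points directly.
        """
        nodes = self.nodes if displacement is None else self.nodes + displacement
        out = np.empty((len(self.landmark_anchors), 3))
        for i, anc in enumerate(self.landmark_anchors):
            out[i] = anc.weights @ nodes[self.tets[anc.tet]]
        return out

    def boundary_facets(self, domains: str | list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Boundary triangles of the union of ``domains`` (default: all).

        Returns ``(facets, owner_tet)`` with facets outward-oriented with
        respect to the owning tetrahedron.
        """
        idx = np.arange(self.n_tets) if domains is None else self.tets_of(domains)
        if idx.size == 0:
            raise ValueError("empty domain selection")
        tets = self.tets[idx]
        # local faces opposite each vertex, ordered so normals point outward
        # for a positively oriented tet
        face_local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
        faces = tets[:, face_local].reshape(-1, 3)
        owners = np.repeat(idx, 4)
        key = np.sort(faces, axis=1)
        order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
        key_sorted = key[order]
        uniq_mask = np.ones(len(key_sorted), dtype=bool)
        same_as_prev = np.all(key_sorted[1:] == key_sorted[:-1], axis=1)
        uniq_mask[1:] &= ~same_as_prev
        uniq_mask[:-1] &= ~same_as_prev
        sel = order[uniq_mask]
        return faces[sel], owners[sel]

    def check_valid(self) -> None:
        """Raise if any tet is non-positive or mandatory invariants fail."""
        vols = tet_volumes(self.nodes, self.tets)
        if np.any(vols <= 0):
            raise ValueError(f"{np.count_nonzero(vols <= 0)} non-positive tetrahedra")
        for name in ("condyle_L", "condyle_R"):
            if name in self.node_sets and self.node_sets[name].size == 0:
                raise ValueError(f"node set {name} is empty")
        for anc in self.landmark_anchors:
            w = anc.weights
            if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"bad barycentric weights for landmark {anc.name}")


def min_dihedral_angle(nodes: np.ndarray, tets: np.ndarray) -> float:
    """Minimum dihedral angle (degrees) over the mesh."""
    edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    opp = {e: tuple(set(range(4)) - set(e)) for e in edges}
    x = nodes[tets]  # (M,4,3)
    min_ang = np.inf
    for e in edges:
        i, j = e
        k, l = opp[e]
        # face normals of the two faces sharing edge (i,j)
        n1 = np.cross(x[:, j] - x[:, i], x[:, k] - x[:, i])
        n2 = np.cross(x[:, l] - x[:, i], x[:, j] - x[:, i])
        n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
        n2 /= np.linalg.norm(n2, axis=1, keepdims=True)
        cosang = np.clip(-(n1 * n2).sum(axis=1), -1.0, 1.0)
        min_ang = min(min_ang, float(np.degrees(np.arccos(cosang)).min()))
    return min_ang
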