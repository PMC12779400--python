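"""Surface extraction and model-to-model distance fields.

The growth heatmaps compare the baseline and deformed cranial surfaces: for
every vertex of the source surface, the exact minimum Euclidean distance to
the target surface (point-to-triangle, accelerated by a KD-tree over
triangle centroids but exact by construction).  Optionally signed by the
target's outward normal: positive = source vertex outside the target =
outward growth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TetMesh

__all__ = [
    "TriangleSurface",
    "DistanceField",
    "extract_surface",
    "model_to_model_distance",
    "closest_point_on_triangles",
]

REGION_NAMES = ("vault", "face", "base", "other")


@dataclass
class TriangleSurface:
    """Oriented triangle surface with optional per-vertex region labels."""

    vertices: np.ndarray  # (V, 3) mm
    triangles: np.ndarray  # (T, 3) int
    regions: np.ndarray | None = None  # (V,) int index into REGION_NAMES

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.triangles = np.asarray(self.triangles, int)
        if self.triangles.size:
            areas = 0.5 * np.linalg.norm(
                np.cross(
                    self.vertices[self.triangles[:, 1]] - self.vertices[self.triangles[:, 0]],
                    self.vertices[self.triangles[:, 2]] - self.vertices[self.triangles[:, 0]],
                ),
                axis=1,
            )
            if np.any(areas <= 0):
                raise ValueError("degenerate (zero-area) triangle in surface")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def face_normals(self) -> np.ndarray:
        n = np.cross(
            self.vertices[self.triangles[:, 1]] - self.vertices[self.triangles[:, 0]],
            self.vertices[self.triangles[:, 2]] - self.vertices[self.triangles[:, 0]],
        )
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def enclosed_volume(self) -> float:
        """Divergence-theorem volume (valid for closed, outward surfaces)."""
        v = self.vertices
        t = self.triangles
        return float(
            np.einsum("ij,ij->", np.cross(v[t[:, 0]], v[t[:, 1]]), v[t[:, 2]]) / 6.0
        )


@dataclass
class DistanceField:
    """Per-source-vertex distances to a target surface."""

    distances: np.ndarray  # (V,) >= 0, or signed if requested
    signed: bool
    source: TriangleSurface

    def region_mean(self, region: str) -> float:
        if self.source.regions is None:
            raise ValueError("source surface has no region labels")
        idx = REGION_NAMES.index(region)
        mask = self.source.regions == idx
        if not mask.any():
            raise ValueError(f"no vertices in region {region!r}")
        return float(np.abs(self.distances[mask]).mean())

    def region_summary(self) -> dict[str, dict[str, float]]:
        out = {}
        if self.source.regions is None:
            return out
        for i, name in enumerate(REGION_NAMES):
            mask = self.source.regions == i
            if mask.any():
                d = self.distances[mask]
                out[name] = {
                    "n": int(mask.sum()),
                    "mean_abs": float(np.abs(d).mean()),
                    "mean": float(d.mean()),
                    "max_abs": float(np.abs(d).max()),
                }
        return out


def extract_surface(
    mesh: TetMesh,
    domains: str | list[str],
    displacement: np.ndarray | None = None,
    region_labeler=None,
) -> TriangleSurface:
    """Boundary surface of the union of the named domains.

    Facets are outward-oriented.  ``region_labeler`` maps reference vertex
    positions to region indices (vault/face/base/other); the generator's
    parametric labeler is used by the pipeline.

    Raises ``ValueError`` on an empty domain selection.
    """
    facets, _ = mesh.boundary_facets(domains)
    used = np.unique(facets)
    remap = -np.ones(mesh.n_nodes, dtype=int)
    remap[used] = np.arange(used.size)
    nodes = mesh.nodes if displacement is None else mesh.nodes + displacement
    regions = None
    if region_labeler is not None:
        regions = np.asarray(region_labeler(mesh.nodes[used]), dtype=int)
    return TriangleSurface(
        vertices=nodes[used], triangles=remap[facets], regions=regions
    )


def closest_point_on_triangles(points: np.ndarray, tri_verts: np.ndarray) -> np.ndarray:
    """Exact closest point on each triangle for each (point, triangle) pair.

    points : (n, 3); tri_verts : (n, 3, 3) one triangle per point row.
    Vectorised region-based clamp of the barycentric solution.
    """
    a = tri_verts[:, 0]
    b = tri_verts[:, 1]
    c = tri_verts[:, 2]
    ab = b - a
    ac = c - a
    ap = points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m
    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    t = (d1 / (d1 - d3))[m]
    out[m] = a[m] + t[:, None] * ab[m]
    done |= m
    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    t = (d2 / (d2 - d6))[m]
    out[m] = a[m] + t[:, None] * ac[m]
    done |= m
    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    t = ((d4 - d3) / ((d4 - d3) + (d5 - d6)))[m]
    out[m] = b[m] + t[:, None] * (c[m] - b[m])
    done |= m
    # interior
    m = ~done
    denom = (va + vb + vc)[m]
    v = (vb[m] / denom)[:, None]
    w = (vc[m] / denom)[:, None]
    out[m] = a[m] + v * ab[m] + w * ac[m]
    return out


def model_to_model_distance(
    source: TriangleSurface,
    target: TriangleSurface,
    signed: bool = False,
    chunk: int = 2048,
) -> DistanceField:
    """Exact per-vertex closest distance from source vertices to the target.

    A KD-tree over target triangle centroids supplies an upper bound per
    vertex; all triangles whose centroid could possibly beat that bound are
    then tested exactly, so acceleration never changes the result.
    """
    if source.n_vertices == 0 or len(target.triangles) == 0:
        raise ValueError("surfaces must be non-empty")
    tv = target.vertices[target.triangles]  # (T,3,3)
    centroids = tv.mean(axis=1)
    radii = np.linalg.norm(tv - centroids[:, None, :], axis=2).max(axis=1)
    rmax = float(radii.max())
    tree = cKDTree(centroids)
    normals = target.face_normals() if signed else None

    pts = source.vertices
    dist = np.empty(len(pts))
    sign = np.ones(len(pts))
    k0 = min(8, len(centroids))
    for start in range(0, len(pts), chunk):
        p = pts[start : start + chunk]
        dcen, icen = tree.query(p, k=k0)
        dcen = np.atleast_2d(dcen)
        icen = np.atleast_2d(icen)
        # exact distances to the k nearest-centroid triangles -> upper bound
        flat_idx = icen.ravel()
        rep_pts = np.repeat(p, icen.shape[1], axis=0)
        cp = closest_point_on_triangles(rep_pts, tv[flat_idx])
        d0 = np.linalg.norm(rep_pts - cp, axis=1).reshape(len(p), -1)
        upper = d0.min(axis=1)
        best_local = d0.argmin(axis=1)
        best_tri = icen[np.arange(len(p)), best_local]
        best_cp = cp.reshape(len(p), -1, 3)[np.arange(len(p)), best_local]
        # any triangle with centroid farther than upper + its radius cannot win
        cand = tree.query_ball_point(p, upper + rmax + 1e-12)
        for i, cands in enumerate(cand):
            cands = np.asarray(cands)
            if cands.size:
                keep = np.linalg.norm(centroids[cands] - p[i], axis=1) <= upper[i] + radii[cands] + 1e-12
                cands = cands[keep]
            if cands.size:
                cps = closest_point_on_triangles(
                    np.broadcast_to(p[i], (cands.size, 3)), tv[cands]
                )
                ds = np.linalg.norm(cps - p[i], axis=1)
                j = int(ds.argmin())
                if ds[j] < upper[i]:
                    upper[i] = ds[j]
                    best_tri[i] = cands[j]
                    best_cp[i] = cps[j]
            dist[start + i] = upper[i]
            if signed:
                sign[start + i] = 1.0 if (p[i] - best_cp[i]) @ normals[best_tri[i]] >= 0 else -1.0
    return DistanceField(
        distances=dist * sign if signed else dist, signed=signed, source=source
    )
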