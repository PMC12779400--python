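"""Idealized multi-domain head mesh generator.

The head is a constructive solid: an ellipsoidal skull shell enclosing an
ellipsoidal brain, with a circular basal opening (foramen-magnum analogue),
a facial block fused to the anterior shell, a mandible block below, and four
masticatory-muscle bodies (a masseter-like and a temporalis-like pair)
bridging the lateral skull wall and the mandible.  Geometry is meshed on a
uniform voxel grid (cells classified at their centres, then split into six
tetrahedra each by the Freudenthal subdivision), which makes domain
interfaces conforming by construction and the output a pure function of the
parameters.

Coordinates are right-handed, in mm: x lateral (midsagittal plane x = 0,
left negative), y posterior-to-anterior, z inferior-to-superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from ..mesh import DOMAIN_NAMES, LandmarkAnchor, TetMesh, min_dihedral_angle, tet_volumes
from ..scheme import LandmarkScheme, default_scheme

__all__ = ["HeadGeometryParams", "generate_head_mesh", "parametric_landmarks"]


@dataclass(frozen=True)
class HeadGeometryParams:
    """Parameters of the constructive head geometry (all lengths in mm).

    Defaults approximate a neonatal head: endocranial volume ~390 cm^3,
    facial block and mandible sized to carry the orbital and condylar
    landmarks, muscle bodies of ~13 cm^3 each.
    """

    endocranial_semiaxes: tuple[float, float, float] = (40.0, 55.0, 42.0)
    skull_thickness: float = 7.0
    face_block_extent: tuple[float, float, float] = (56.0, 28.0, 40.0)
    muscle_semiaxes: tuple[float, float, float] = (10.0, 14.0, 22.0)
    mandible_extent: tuple[float, float, float] = (80.0, 67.0, 12.0)
    target_edge_length: float = 7.0
    seed: int = 1

    def __post_init__(self) -> None:
        lengths = (
            list(self.endocranial_semiaxes)
            + [self.skull_thickness]
            + list(self.face_block_extent)
            + list(self.muscle_semiaxes)
            + list(self.mandible_extent)
            + [self.target_edge_length]
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all lengths must be positive")
        if self.skull_thickness >= min(self.endocranial_semiaxes) / 5.0:
            raise ValueError("skull_thickness must be < min(endocranial_semiaxes)/5")
        if self.skull_thickness < 0.8 * self.target_edge_length:
            raise ValueError(
                "skull_thickness too small for target_edge_length; the shell "
                "would not be resolved (need thickness >= 0.8 x edge length)"
            )

    # ---- derived geometry ------------------------------------------------
    @property
    def outer_semiaxes(self) -> tuple[float, float, float]:
        t = self.skull_thickness
        a, b, c = self.endocranial_semiaxes
        return (a + t, b + t, c + t)

    @property
    def foramen_radius(self) -> float:
        return 0.15 * self.endocranial_semiaxes[0]

    @property
    def foramen_center_y(self) -> float:
        return -0.45 * self.endocranial_semiaxes[1]

    @property
    def face_origin_y(self) -> float:
        """Anterior face block starts slightly inside the outer shell."""
        return self.outer_semiaxes[1] - 6.0

    @property
    def face_center_z(self) -> float:
        return -10.0

    @property
    def mandible_top_z(self) -> float:
        return -(self.outer_semiaxes[2] + self.skull_thickness)

    @property
    def mandible_center(self) -> tuple[float, float, float]:
        w, d, h = self.mandible_extent
        ay = self.endocranial_semiaxes[1]
        # body spans from behind the condylar rami to the chin region
        return (0.0, -0.38 * ay + d / 2.0, self.mandible_top_z - h / 2.0)

    @property
    def ramus_centers(self) -> tuple[tuple[float, float, float], ...]:
        """Condylar ramus columns articulating the mandible with the skull
        base (temporomandibular-joint analogue).  Placed posterior-laterally,
        adjacent to the fixed occipital-condyle patches, where the shell is
        effectively immobile — the jaw is anchored without confining the
        expanding parts of the basicranium."""
        ax, ay, az = self.endocranial_semiaxes
        x = 0.50 * ax
        y = -0.27 * ay
        z_top = -0.88 * az
        z_bot = self.mandible_top_z
        return ((-x, y, (z_top + z_bot) / 2.0), (x, y, (z_top + z_bot) / 2.0))

    @property
    def ramus_extent(self) -> tuple[float, float, float]:
        az = self.endocranial_semiaxes[2]
        return (10.0, 12.0, -0.88 * az - self.mandible_top_z)

    def elevator_region(self) -> tuple[np.ndarray, np.ndarray]:
        """Interior of the masticatory compartment (|x| box) that the
        elevator muscle pair fills exactly."""
        ax, ay, az = self.endocranial_semiaxes
        # spans the midline: the left/right bodies meet at x = 0, sealing
        # the sub-basal space between mandible floor and cranial-base
        # ceiling (tongue/pharyngeal-mass analogue)
        x0, x1 = -0.75 * ax, 0.75 * ax
        y0, y1 = -0.11 * ay, 0.47 * ay
        z0, z1 = self.mandible_top_z - 2.0, -0.5 * az
        return (
            np.array([(x0 + x1) / 2, (y0 + y1) / 2, (z0 + z1) / 2]),
            np.array([x1 - x0, y1 - y0, z1 - z0]),
        )

    def compartment_walls(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Bone walls (mandible domain) enclosing each elevator-muscle
        compartment between skull base and mandible body (masticatory-fossa
        analogue).  Returned as (center, extent) boxes in |x| coordinates;
        both sides are mirrored.  Sealing the compartment is what lets
        muscle growth pressurise the cranial base: a muscle with a free
        surface equilibrates at zero osmotic pressure and cannot interact
        with the expanding brain."""
        ax, ay, az = self.endocranial_semiaxes
        zb = self.mandible_top_z
        y0, y1 = -0.11 * ay, 0.47 * ay
        # walls ~12 mm thick: thin walls bulge and vent the compartment
        # pressure that carries the muscle-brain interaction
        walls = [
            # lateral wall
            ((0.75 * ax + 1.05 * ax) / 2, (y0 + y1) / 2, (zb + -0.62 * az) / 2,
             0.30 * ax, y1 - y0, -0.62 * az - zb),
            # anterior wall (spans the midline)
            (0.525 * ax, (0.47 * ay + 0.67 * ay) / 2, (zb + -0.71 * az) / 2,
             1.05 * ax, 0.20 * ay, -0.71 * az - zb),
            # posterior wall (spans the midline)
            (0.525 * ax, (-0.25 * ay + -0.11 * ay) / 2, (zb + -0.71 * az) / 2,
             1.05 * ax, 0.14 * ay, -0.71 * az - zb),
        ]
        return [
            (np.array([cx, cy, cz]), np.array([ex, ey, ez]))
            for cx, cy, cz, ex, ey, ez in walls
        ]

    def muscle_centers(self) -> dict[str, np.ndarray]:
        """Two muscle bodies per side: an elevator pair (masseter/pterygoid
        analogue) filling the space between the basicranial shell and the
        articulated mandible — the load path through which expanding
        tissues compete for space — and a temporalis-like pair against the
        lateral vault wall."""
        ax, ay, az = self.endocranial_semiaxes
        t = self.skull_thickness
        mz = self.muscle_semiaxes[2]
        elevator = np.array([0.60 * ax, 0.18 * ay, self.mandible_top_z + 0.55 * mz])
        temporalis = np.array([ax + t + 1.0, -5.0, 6.0])
        return {
            "muscle_L1": elevator * np.array([-1, 1, 1]),
            "muscle_R1": elevator,
            "muscle_L2": temporalis * np.array([-1, 1, 1]),
            "muscle_R2": temporalis,
        }


def _inside_ellipsoid(p: np.ndarray, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    q = (p - center) / semi
    return (q**2).sum(axis=1) <= 1.0


def _inside_box(p: np.ndarray, center: np.ndarray, extent: np.ndarray) -> np.ndarray:
    return np.all(np.abs(p - center) <= np.asarray(extent) / 2.0, axis=1)


def classify_points(points: np.ndarray, params: HeadGeometryParams) -> np.ndarray:
    """Domain code per point (-1 = outside), by the constructive-solid rules.

    Priority: bone (shell minus basal opening, plus facial block), brain
    (endocranial cavity), mandible, then the four muscle bodies.
    """
    p = np.asarray(points, dtype=float)
    zero = np.zeros(3)
    inner = _inside_ellipsoid(p, zero, np.array(params.endocranial_semiaxes))
    outer = _inside_ellipsoid(p, zero, np.array(params.outer_semiaxes))
    shell = outer & ~inner
    foramen = (
        (p[:, 0] ** 2 + (p[:, 1] - params.foramen_center_y) ** 2 <= params.foramen_radius**2)
        & (p[:, 2] < 0)
    )
    w, d, h = params.face_block_extent
    face = _inside_box(
        p,
        np.array([0.0, params.face_origin_y + d / 2.0, params.face_center_z]),
        np.array([w, d, h]),
    )
    bone = (shell & ~foramen) | face
    mandible = _inside_box(p, np.array(params.mandible_center), np.array(params.mandible_extent))
    for rc in params.ramus_centers:
        mandible |= _inside_box(p, np.array(rc), np.array(params.ramus_extent))
    p_abs = np.column_stack([np.abs(p[:, 0]), p[:, 1], p[:, 2]])
    for center, extent in params.compartment_walls():
        mandible |= _inside_box(p_abs, center, extent)
    code = np.full(len(p), -1, dtype=np.int32)
    msemi = np.array(params.muscle_semiaxes)
    for name, center in params.muscle_centers().items():
        if name in ("muscle_L2", "muscle_R2"):
            inside = _inside_ellipsoid(p, center, msemi)
        else:
            # elevator pair fills its bone-bounded compartment exactly
            # (no free surface); the box is clipped by the bone/brain/
            # mandible priorities below
            cc, ee = params.elevator_region()
            inside = _inside_box(p_abs, cc, ee) & (
                (p[:, 0] > 0) if center[0] > 0 else (p[:, 0] < 0)
            )
        code[inside] = DOMAIN_NAMES.index(name)
    code[mandible] = DOMAIN_NAMES.index("mandible")
    code[inner] = DOMAIN_NAMES.index("brain")
    code[bone] = DOMAIN_NAMES.index("bone")
    return code


# Freudenthal subdivision: six tets per cube, one per permutation of the
# axes; all cubes split identically so shared faces are conforming.
def _freudenthal_tets() -> np.ndarray:
    def corner_id(d):
        return d[0] + 2 * d[1] + 4 * d[2]

    tets = []
    for perm in permutations(range(3)):
        v = np.zeros(3, dtype=int)
        ids = [corner_id(v)]
        for ax in perm:
            v = v.copy()
            v[ax] = 1
            ids.append(corner_id(v))
        # fix orientation: odd permutations give negative volume
        e = np.eye(3, dtype=int)
        m = np.stack([e[perm[0]], e[perm[0]] + e[perm[1]], np.ones(3, dtype=int)])
        if np.linalg.det(m) < 0:
            ids[2], ids[3] = ids[3], ids[2]
        tets.append(ids)
    return np.array(tets, dtype=np.int64)


_FREUDENTHAL = _freudenthal_tets()


def parametric_landmarks(params: HeadGeometryParams, scheme: LandmarkScheme | None = None) -> np.ndarray:
    """The 18 landmark target positions on the constructive geometry (mm).

    Midline landmarks sit on the basal-opening rim (Ba, Op), the interior
    cranial base (S, Ts, Ds) and the facial block (Na, Ans, Pns); paired
    landmarks mark the orbital rims on the facial block front (Io, Lo, Mo,
    So) and the mandibular condyles (Cd).  Returned in scheme order; exactly
    symmetric about x = 0.
    """
    if scheme is None:
        scheme = default_scheme()
    ax, ay, az = params.endocranial_semiaxes
    t = params.skull_thickness
    bx, by, bz = params.outer_semiaxes
    mid_c = az + t / 2.0  # mid-shell z semiaxis
    mid_b = ay + t / 2.0

    def midshell_z(y: float) -> float:
        return -mid_c * np.sqrt(max(0.0, 1.0 - (y / mid_b) ** 2))

    def innerbase_z(y: float) -> float:
        return -az * np.sqrt(max(0.0, 1.0 - (y / ay) ** 2)) - t / 2.0

    rf, yf = params.foramen_radius, params.foramen_center_y
    w, d, h = params.face_block_extent
    y_front = params.face_origin_y + d - 1.0
    zc = params.face_center_z
    mw, md, mh = params.mandible_extent
    mc = params.mandible_center

    pos = {
        "Ba": (0.0, yf + rf + 2.0, midshell_z(yf + rf + 2.0)),
        "Op": (0.0, yf - rf - 2.0, midshell_z(yf - rf - 2.0)),
        "S": (0.0, 0.16 * ay, innerbase_z(0.16 * ay)),
        "Ts": (0.0, 0.25 * ay, innerbase_z(0.25 * ay)),
        "Ds": (0.0, 0.07 * ay, innerbase_z(0.07 * ay)),
        "Na": (0.0, by - 1.0, zc + h / 2.0 - 2.0),
        "Ans": (0.0, y_front, zc - 0.1 * h),
        "Pns": (0.0, params.face_origin_y + 2.0, zc - h / 2.0 + 2.0),
        "So": (0.25 * w, y_front, zc + 0.30 * h),
        "Io": (0.25 * w, y_front, zc - 0.30 * h),
        "Lo": (0.40 * w, y_front, zc),
        "Mo": (0.10 * w, y_front, zc),
        "Cd": (
            params.ramus_centers[1][0],
            params.ramus_centers[1][1],
            params.mandible_top_z + 2.0,
        ),
    }
    out = np.zeros((scheme.n_landmarks, 3))
    for i, name in enumerate(scheme.names):
        if name.endswith("_L"):
            x, y, z = pos[name[:-2]]
            out[i] = (-x, y, z)
        elif name.endswith("_R"):
            out[i] = pos[name[:-2]]
        else:
            out[i] = pos[name]
    return out


def _anchor_landmarks(
    mesh_nodes: np.ndarray,
    tets: np.ndarray,
    domain: np.ndarray,
    targets: np.ndarray,
    scheme: LandmarkScheme,
) -> list[LandmarkAnchor]:
    """Tie each landmark to the best nearby tet of an appropriate domain."""
    anchors: list[LandmarkAnchor] = []
    centroids = mesh_nodes[tets].mean(axis=1)
    bone_code = DOMAIN_NAMES.index("bone")
    mand_code = DOMAIN_NAMES.index("mandible")
    trees = {
        bone_code: cKDTree(centroids[domain == bone_code]),
        mand_code: cKDTree(centroids[domain == mand_code]),
    }
    maps = {
        bone_code: np.flatnonzero(domain == bone_code),
        mand_code: np.flatnonzero(domain == mand_code),
    }
    for i, name in enumerate(scheme.names):
        code = mand_code if name.startswith("Cd") else bone_code
        k = min(40, len(maps[code]))
        _, nn = trees[code].query(targets[i], k=k)
        best = None
        for local in np.atleast_1d(nn):
            tet = maps[code][local]
            verts = mesh_nodes[tets[tet]]
            mat = np.column_stack([verts[1] - verts[0], verts[2] - verts[0], verts[3] - verts[0]])
            lam = np.linalg.solve(mat, targets[i] - verts[0])
            w = np.concatenate([[1.0 - lam.sum()], lam])
            score = w.min()
            if best is None or score > best[0]:
                best = (score, tet, w)
            if score >= 0:
                break
        _, tet, w = best
        w = np.clip(w, 0.0, None)
        w /= w.sum()
        anchors.append(LandmarkAnchor(name=name, tet=int(tet), weights=w))
    return anchors


def voxel_tet_mesh(
    classify,
    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]],
    edge_length: float,
    symmetric_x: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mesh an implicit multi-domain solid on a uniform voxel grid.

    ``classify(points) -> int codes`` labels cell centres (-1 = outside);
    kept cells are split into six conforming tets each (Freudenthal).

    Returns ``(nodes, tets, domain_codes)``.  Used by the head generator and
    by simple test solids (balls, shells, blocks).
    """
    h = edge_length
    (x0, x1), (y0, y1), (z0, z1) = bounds
    if symmetric_x:
        nx = int(np.ceil(max(abs(x0), abs(x1)) / h))
        xs = np.arange(-nx, nx + 1) * h
    else:
        xs = np.arange(int(np.floor(x0 / h)), int(np.ceil(x1 / h)) + 1) * h
    ys = np.arange(int(np.floor(y0 / h)), int(np.ceil(y1 / h)) + 1) * h
    zs = np.arange(int(np.floor(z0 / h)), int(np.ceil(z1 / h)) + 1) * h
    cx, cy, cz = (0.5 * (a[:-1] + a[1:]) for a in (xs, ys, zs))
    gx, gy, gz = np.meshgrid(cx, cy, cz, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    codes = np.asarray(classify(centers), dtype=np.int32)
    keep = np.flatnonzero(codes >= 0)
    if keep.size == 0:
        raise ValueError("no cells classified inside the geometry")
    ncx, ncy, ncz = len(cx), len(cy), len(cz)
    ci, cj, ck = np.unravel_index(keep, (ncx, ncy, ncz))
    nyn, nzn = len(ys), len(zs)

    def node_id(i, j, k):
        return (i * nyn + j) * nzn + k

    corner_ids = np.empty((keep.size, 8), dtype=np.int64)
    for c, (dx, dy, dz) in enumerate(
        [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0), (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
    ):
        corner_ids[:, c] = node_id(ci + dx, cj + dy, ck + dz)
    used, inverse = np.unique(corner_ids, return_inverse=True)
    local_corner = inverse.reshape(corner_ids.shape)
    ui, uj, uk = np.unravel_index(used, (len(xs), nyn, nzn))
    nodes = np.column_stack([xs[ui], ys[uj], zs[uk]]).astype(float)
    tets = local_corner[:, _FREUDENTHAL].reshape(-1, 4)
    domain = np.repeat(codes[keep], 6).astype(np.int32)
    return nodes, tets, domain


def generate_head_mesh(params: HeadGeometryParams | None = None) -> TetMesh:
    """Build the conforming multi-domain head mesh.

    Deterministic: identical parameters give a bitwise-identical mesh.

    Raises
    ------
    ValueError
        If any domain ends up empty, a tet is non-positive, or the mesh is
        mechanically disconnected.
    """
    if params is None:
        params = HeadGeometryParams()
    h = params.target_edge_length
    bx, by, bz = params.outer_semiaxes
    centers = params.muscle_centers()
    msemi = np.array(params.muscle_semiaxes)
    xmax = max(bx, max(abs(c[0]) for c in centers.values()) + msemi[0]) + h
    ymin = -by - h
    ymax = max(by, params.face_origin_y + params.face_block_extent[1]) + h
    zmin = params.mandible_top_z - params.mandible_extent[2] - h
    zmax = bz + h

    nodes, tets, domain = voxel_tet_mesh(
        lambda pts: classify_points(pts, params),
        ((-xmax, xmax), (ymin, ymax), (zmin, zmax)),
        h,
        symmetric_x=True,
    )
    vols = tet_volumes(nodes, tets)
    if np.any(vols <= 0):
        raise ValueError("meshing failure: non-positive tetrahedron produced")

    # mechanical connectivity: every domain must hang together through
    # shared faces (one component), otherwise the stiffness matrix is singular
    faces = np.sort(tets[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]].reshape(-1, 3), axis=1)
    owners = np.repeat(np.arange(len(tets)), 4)
    order = np.lexsort((faces[:, 2], faces[:, 1], faces[:, 0]))
    fs, os_ = faces[order], owners[order]
    shared = np.all(fs[1:] == fs[:-1], axis=1)
    a, b = os_[:-1][shared], os_[1:][shared]
    adj = coo_matrix((np.ones(len(a)), (a, b)), shape=(len(tets), len(tets)))
    ncomp, _ = connected_components(adj, directed=False)
    if ncomp != 1:
        raise ValueError(f"mesh is disconnected ({ncomp} face-connected components)")

    for name in DOMAIN_NAMES:
        if not np.any(domain == DOMAIN_NAMES.index(name)):
            raise ValueError(f"domain {name} has no elements")

    # ---- node sets -------------------------------------------------------
    bone_nodes = np.unique(tets[domain == DOMAIN_NAMES.index("bone")])
    brain_nodes = np.unique(tets[domain == DOMAIN_NAMES.index("brain")])
    # keep constraint sets off growing tissue: a fully pinned cell-growth tet
    # cannot satisfy J > phir once phir ramps past 1
    growing = np.isin(
        domain, [DOMAIN_NAMES.index(d) for d in ("brain",) + tuple(m for m in DOMAIN_NAMES if m.startswith("muscle"))]
    )
    growing_nodes = np.unique(tets[growing])
    bone_nodes = np.setdiff1d(bone_nodes, growing_nodes)
    p = nodes[bone_nodes]
    rho = np.sqrt(p[:, 0] ** 2 + (p[:, 1] - params.foramen_center_y) ** 2)
    rf = params.foramen_radius
    az = params.endocranial_semiaxes[2]
    near_rim = (
        (rho >= rf - 0.1 * h)
        & (rho <= rf + 1.1 * h)
        & (p[:, 2] < -0.75 * az)
        & (np.abs(p[:, 0]) > 0.3 * rf)
    )
    condyle_L = bone_nodes[near_rim & (p[:, 0] < 0)]
    condyle_R = bone_nodes[near_rim & (p[:, 0] > 0)]
    # single interior brain node: a point anchor cannot over-constrain any
    # growing tet (the brain is already tied to bone at the cavity interface)
    q = nodes[brain_nodes]
    anchor_target = np.array([0.0, -5.0, -0.25 * az])
    danch = np.linalg.norm(q - anchor_target, axis=1)
    anchor = brain_nodes[[int(np.argmin(danch))]]
    if condyle_L.size == 0 or condyle_R.size == 0 or anchor.size == 0:
        raise ValueError("empty constraint node set; geometry/edge-length mismatch")

    targets = parametric_landmarks(params)
    scheme = default_scheme()
    anchors = _anchor_landmarks(nodes, tets, domain, targets, scheme)

    mesh = TetMesh(
        nodes=nodes,
        tets=tets,
        domain=domain,
        node_sets={"condyle_L": condyle_L, "condyle_R": condyle_R, "anchor": anchor},
        landmark_anchors=anchors,
        diagnostics={
            "n_cells": int(len(tets) // 6),
            "edge_length": h,
            "min_dihedral_deg": min_dihedral_angle(nodes, tets[:64]),
            "min_tet_volume": float(vols.min()),
        },
        region_params={
            "endocranial_semiaxes": params.endocranial_semiaxes,
            "outer_semiaxes": params.outer_semiaxes,
            "face_origin_y": params.face_origin_y,
            "vault_z": 0.25 * params.endocranial_semiaxes[2],
            "base_z": -0.55 * params.endocranial_semiaxes[2],
        },
    )
    mesh.check_valid()
    return mesh


def label_surface_regions(points: np.ndarray, region_params: dict) -> np.ndarray:
    """Region label per point: 0=vault, 1=face, 2=base, 3=other.

    Parametric rules on the undeformed geometry: the facial block region is
    'face', the superior skull cap 'vault', the inferior region 'base'.
    """
    p = np.asarray(points, dtype=float)
    labels = np.full(len(p), 3, dtype=np.int32)
    labels[p[:, 2] > region_params["vault_z"]] = 0
    labels[p[:, 2] < region_params["base_z"]] = 2
    labels[p[:, 1] > region_params["face_origin_y"]] = 1
    return labels
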