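"""File formats: VTU meshes, PLY surfaces, landmark CSV / Slicer markups
JSON, NIfTI label images.

The VTU writer/reader handles exactly the subset this package produces
(ASCII UnstructuredGrid of tetrahedra with point/cell data) so meshes and
displacement fields can be inspected in ParaView; surfaces go through
trimesh, images through nibabel.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import DOMAIN_NAMES, TetMesh
from .morpho.config import LandmarkConfiguration
from .scheme import LandmarkScheme, default_scheme
from .surfaces import TriangleSurface

__all__ = [
    "write_vtu",
    "read_vtu",
    "write_ply",
    "read_ply",
    "landmarks_to_csv",
    "landmarks_from_csv",
    "write_markups_json",
    "read_markups_json",
    "write_label_image",
    "read_label_image",
]


def _fmt(a: np.ndarray) -> str:
    return " ".join(f"{x:.17g}" for x in np.asarray(a).ravel())


def write_vtu(
    path: str | Path,
    mesh: TetMesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """ASCII VTU (UnstructuredGrid) with the domain label as cell data."""
    cell_data = dict(cell_data or {})
    cell_data.setdefault("domain", mesh.domain)
    point_data = dict(point_data or {})
    n, m = mesh.n_nodes, mesh.n_tets
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">',
        "<Points>",
        f'<DataArray type="Float64" NumberOfComponents="3" format="ascii">{_fmt(mesh.nodes)}</DataArray>',
        "</Points>",
        "<Cells>",
        f'<DataArray type="Int64" Name="connectivity" format="ascii">{_fmt(mesh.tets)}</DataArray>',
        f'<DataArray type="Int64" Name="offsets" format="ascii">{_fmt(4 * np.arange(1, m + 1))}</DataArray>',
        f'<DataArray type="UInt8" Name="types" format="ascii">{_fmt(np.full(m, 10))}</DataArray>',
        "</Cells>",
    ]
    if point_data:
        parts.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            comp = 1 if arr.ndim == 1 else arr.shape[1]
            parts.append(
                f'<DataArray type="Float64" Name="{name}" NumberOfComponents="{comp}" '
                f'format="ascii">{_fmt(arr)}</DataArray>'
            )
        parts.append("</PointData>")
    parts.append("<CellData>")
    for name, arr in cell_data.items():
        parts.append(
            f'<DataArray type="Int32" Name="{name}" format="ascii">{_fmt(np.asarray(arr, int))}</DataArray>'
        )
    parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(parts))


def read_vtu(path: str | Path) -> TetMesh:
    """Read a VTU written by :func:`write_vtu` back into a TetMesh."""
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    pts = piece.find("Points/DataArray")
    nodes = np.fromstring(pts.text, sep=" ").reshape(-1, 3)
    conn = None
    for da in piece.findall("Cells/DataArray"):
        if da.get("Name") == "connectivity":
            conn = np.fromstring(da.text, sep=" ", dtype=np.int64).reshape(-1, 4)
    domain = np.zeros(len(conn), dtype=np.int32)
    cd = piece.find("CellData")
    if cd is not None:
        for da in cd.findall("DataArray"):
            if da.get("Name") == "domain":
                domain = np.fromstring(da.text, sep=" ", dtype=np.int32)
    return TetMesh(nodes=nodes, tets=conn, domain=domain)


def write_ply(path: str | Path, surface: TriangleSurface) -> None:
    import trimesh

    trimesh.Trimesh(
        vertices=surface.vertices, faces=surface.triangles, process=False
    ).export(str(path), encoding="ascii")


def read_ply(path: str | Path) -> TriangleSurface:
    import trimesh

    t = trimesh.load(str(path), process=False)
    return TriangleSurface(vertices=np.asarray(t.vertices), triangles=np.asarray(t.faces))


# ---- landmarks -----------------------------------------------------------

def landmarks_to_csv(path: str | Path, configs: list[LandmarkConfiguration]) -> None:
    rows = []
    for c in configs:
        for name, xyz in zip(c.scheme.names, c.coords):
            rows.append(
                {
                    "name": name,
                    "x": xyz[0],
                    "y": xyz[1],
                    "z": xyz[2],
                    "specimen": c.specimen_id,
                    "age": c.age,
                    "replicate": c.replicate,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def landmarks_from_csv(
    path: str | Path, scheme: LandmarkScheme | None = None
) -> list[LandmarkConfiguration]:
    scheme = scheme or default_scheme()
    df = pd.read_csv(path)
    configs = []
    for (spec, rep), grp in df.groupby(["specimen", "replicate"], sort=True):
        grp = grp.set_index("name").loc[list(scheme.names)]
        age = grp["age"].iloc[0]
        configs.append(
            LandmarkConfiguration(
                grp[["x", "y", "z"]].to_numpy(float),
                scheme,
                specimen_id=str(spec),
                age=None if pd.isna(age) else float(age),
                replicate=int(rep),
            )
        )
    return configs


def write_markups_json(path: str | Path, config: LandmarkConfiguration) -> None:
    """3D Slicer fiducial markups (.mrk.json), LPS coordinates as exported
    by recent Slicer versions (our coordinates are written verbatim)."""
    points = [
        {
            "id": str(i + 1),
            "label": name,
            "position": [float(v) for v in xyz],
            "locked": False,
            "visibility": True,
        }
        for i, (name, xyz) in enumerate(zip(config.scheme.names, config.coords))
    ]
    doc = {
        "@schema": "https://raw.githubusercontent.com/slicer/slicer/master/Modules/Loadable/Markups/Resources/Schema/markups-schema-v1.0.3.json",
        "markups": [
            {
                "type": "Fiducial",
                "coordinateSystem": "LPS",
                "controlPoints": points,
            }
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_markups_json(
    path: str | Path, scheme: LandmarkScheme | None = None, **covariates
) -> LandmarkConfiguration:
    scheme = scheme or default_scheme()
    doc = json.loads(Path(path).read_text())
    pts = {p["label"]: p["position"] for p in doc["markups"][0]["controlPoints"]}
    coords = np.array([pts[name] for name in scheme.names], dtype=float)
    return LandmarkConfiguration(coords, scheme, **covariates)


# ---- label images --------------------------------------------------------

def write_label_image(path: str | Path, image) -> None:
    """NIfTI-1 with the voxel spacing on the affine diagonal."""
    import nibabel as nib

    affine = np.diag([*image.spacing, 1.0])
    nib.save(nib.Nifti1Image(image.data.astype(np.uint8), affine), str(path))


def read_label_image(path: str | Path, age_days: float | None = None):
    import nibabel as nib

    from .synthetic.images import LabelImage

    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelImage(
        data=np.asarray(img.dataobj).astype(np.uint8),
        spacing=spacing,
        age_days=age_days if age_days is not None else np.nan,
        ground_truth={},
    )
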