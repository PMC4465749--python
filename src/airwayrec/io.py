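"""Readers and writers: image stacks (DICOM or TIFF/PNG + JSON geometry
sidecar), the contour text format, NURBS JSON, and mesh export.

The contour text format mirrors the study workflow of exporting level-set
boundary coordinates to plain text: '#'-prefixed header lines carry the
orientation, frame fields and registration flag; each contour block starts
with ``slice=<i> region=<id> label=<tag> closed=<0|1>`` followed by one
``x_mm<TAB>y_mm`` pair per line; blocks are separated by blank lines.
Write -> read round-trips are lossless to well below 1e-9 mm.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import Contour, ContourSet, InvalidInputError, PlaneFrame
from .nurbs import NurbsCurve, NurbsSurface
from .phantom import ImageStack
from .reconstruction import TriMesh

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "write_contours",
    "read_contours",
    "write_nurbs_json",
    "read_nurbs_json",
    "write_mesh",
    "ParseError",
    "MissingMetadataError",
]

SIDECAR_NAME = "geometry.json"


class ParseError(ValueError):
    pass


class MissingMetadataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# image stacks


def write_image_stack(stack: ImageStack, path) -> None:
    """Write one stack as per-slice float32 TIFFs plus a geometry sidecar."""
    import tifffile

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for k in range(stack.n_slices):
        tifffile.imwrite(path / f"slice_{k:04d}.tif", stack.data[k])
    sidecar = {
        "frame": stack.frame.to_dict(),
        "n_slices": stack.n_slices,
        "provenance": stack.provenance,
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))


def _read_sidecar_stack(path: Path) -> ImageStack:
    import tifffile
    from PIL import Image

    meta = json.loads((path / SIDECAR_NAME).read_text())
    if "frame" not in meta:
        raise MissingMetadataError("sidecar missing 'frame'")
    frame = PlaneFrame.from_dict(meta["frame"])
    files = sorted(
        [p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png")]
    )
    if not files:
        raise InvalidInputError(f"no image slices found in {path}")
    slices = []
    for f in files:
        if f.suffix.lower() in (".tif", ".tiff"):
            slices.append(np.asarray(tifffile.imread(f), np.float32))
        else:
            slices.append(np.asarray(Image.open(f), np.float32))
    data = np.stack(slices)
    return ImageStack(data, frame, meta.get("provenance", {}))


def _read_dicom_stack(path: Path, orientation: str) -> ImageStack:
    import pydicom

    files = sorted(path.glob("*.dcm")) or sorted(
        p for p in path.iterdir() if p.is_file() and p.suffix.lower() != ".json"
    )
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:  # not a DICOM file
            continue
    if not datasets:
        raise InvalidInputError(f"no readable DICOM files in {path}")
    required = ("ImagePositionPatient", "ImageOrientationPatient", "PixelSpacing")
    for ds in datasets:
        for tag in required:
            if not hasattr(ds, tag):
                raise MissingMetadataError(f"DICOM file missing {tag}")
    iop0 = np.asarray(datasets[0].ImageOrientationPatient, float)
    for ds in datasets[1:]:
        if not np.allclose(np.asarray(ds.ImageOrientationPatient, float), iop0, atol=1e-6):
            raise InvalidInputError("mixed orientations in one DICOM series")
    axis_u = iop0[:3]  # row direction: along increasing column
    axis_v = iop0[3:]  # column direction: along increasing row
    normal = np.cross(axis_u, axis_v)
    positions = [float(np.asarray(ds.ImagePositionPatient, float) @ normal) for ds in datasets]
    order = np.argsort(positions)
    datasets = [datasets[i] for i in order]
    pos_sorted = np.sort(positions)
    thickness = float(getattr(datasets[0], "SliceThickness", 0.0) or 0.0)
    if len(pos_sorted) > 1:
        spacing = float(np.mean(np.diff(pos_sorted)))
    else:
        spacing = float(getattr(datasets[0], "SpacingBetweenSlices", thickness) or thickness)
    if thickness <= 0:
        raise MissingMetadataError("DICOM file missing SliceThickness")
    gap = max(spacing - thickness, 0.0)
    ps = np.asarray(datasets[0].PixelSpacing, float)  # (row, col) mm
    data = np.stack([ds.pixel_array.astype(np.float32) for ds in datasets])
    frame = PlaneFrame(
        orientation=orientation,
        origin=np.asarray(datasets[0].ImagePositionPatient, float),
        axis_u=axis_u / np.linalg.norm(axis_u),
        axis_v=axis_v / np.linalg.norm(axis_v),
        pixel_spacing=(float(ps[1]), float(ps[0])),
        slice_thickness=thickness,
        slice_gap=gap,
        matrix=data.shape[1:],
    )
    return ImageStack(data, frame, {"source": str(path), "format": "dicom"})


def read_image_stack(path, orientation: str | None = None) -> ImageStack:
    """Read a stack from a directory: DICOM series, or TIFF/PNG slices plus
    a ``geometry.json`` sidecar.  Slices are sorted by position along the
    stack normal."""
    path = Path(path)
    if not path.is_dir():
        raise InvalidInputError(f"{path} is not a directory")
    if (path / SIDECAR_NAME).exists():
        return _read_sidecar_stack(path)
    if orientation is None:
        raise MissingMetadataError("DICOM reading requires the stack orientation")
    return _read_dicom_stack(path, orientation)


# ---------------------------------------------------------------------------
# contour text format


def write_contours(cset: ContourSet, path) -> None:
    lines = ["# airwayrec contour file v1"]
    lines.append(f"# orientation={cset.orientation}")
    lines.append(f"# registered={int(cset.registered)}")
    lines.append("# frame=" + json.dumps(cset.frame.to_dict()))
    for c in cset:
        lines.append("")
        label = c.label if c.label is not None else "-"
        lines.append(
            f"slice={c.slice_index} region={c.region_id} label={label} "
            f"closed={int(c.closed)}"
        )
        for x, y in c.points:
            lines.append(f"{float(x)!r}\t{float(y)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_contours(path) -> ContourSet:
    path = Path(path)
    orientation = None
    frame = None
    registered = False
    cset: ContourSet | None = None
    pending: dict | None = None
    points: list[tuple[float, float]] = []

    def flush():
        nonlocal pending, points
        if pending is None:
            return
        if len(points) < (3 if pending["closed"] else 2):
            raise ParseError(
                f"{path}: contour starting near line {pending['line']} has too few points"
            )
        c = Contour(
            np.asarray(points, float),
            pending["slice"],
            frame,
            closed=pending["closed"],
            label=pending["label"],
            region_id=pending["region"],
        )
        cset.add(c)
        pending, points = None, []

    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            flush()
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("orientation="):
                orientation = body.split("=", 1)[1]
            elif body.startswith("registered="):
                registered = bool(int(body.split("=", 1)[1]))
            elif body.startswith("frame="):
                frame = PlaneFrame.from_dict(json.loads(body.split("=", 1)[1]))
            continue
        if cset is None:
            if orientation is None or frame is None:
                raise ParseError(f"{path}:{ln}: contour data before header")
            cset = ContourSet(orientation, frame, registered=registered)
        if line.startswith("slice="):
            flush()
            try:
                kv = dict(tok.split("=", 1) for tok in line.split())
                pending = {
                    "slice": int(kv["slice"]),
                    "region": int(kv.get("region", 0)),
                    "label": None if kv.get("label", "-") == "-" else kv["label"],
                    "closed": bool(int(kv.get("closed", 1))),
                    "line": ln,
                }
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{ln}: bad contour header: {exc}") from exc
            continue
        if pending is None:
            raise ParseError(f"{path}:{ln}: coordinates outside a contour block")
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{ln}: expected 'x<TAB>y'")
        try:
            points.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: bad coordinate: {exc}") from exc
    flush()
    if cset is None:
        if orientation is None or frame is None:
            raise ParseError(f"{path}: missing header")
        cset = ContourSet(orientation, frame, registered=registered)
    return cset


# ---------------------------------------------------------------------------
# NURBS JSON and meshes


def _curve_dict(c: NurbsCurve) -> dict:
    return {
        "degree": c.degree,
        "control_points": c.control_points.tolist(),
        "weights": c.weights.tolist(),
        "knots": c.knots.tolist(),
        "closed": bool(c.closed),
    }


def write_nurbs_json(obj: NurbsCurve | NurbsSurface | dict, path) -> None:
    """Documented JSON schema for NURBS geometry (degrees, knots, weights,
    control net); no proprietary CAD formats."""
    if isinstance(obj, NurbsCurve):
        doc = {"type": "curve", **_curve_dict(obj)}
    elif isinstance(obj, NurbsSurface):
        doc = {
            "type": "surface",
            "degree_u": obj.degree_u,
            "degree_v": obj.degree_v,
            "control_points": obj.control_points.tolist(),
            "weights": obj.weights.tolist(),
            "knots_u": obj.knots_u.tolist(),
            "knots_v": obj.knots_v.tolist(),
            "closed_u": bool(obj.closed_u),
        }
    elif isinstance(obj, dict):
        items = {}
        for k, v in obj.items():
            if isinstance(v, NurbsCurve):
                items[k] = {"type": "curve", **_curve_dict(v)}
            elif isinstance(v, NurbsSurface):
                items[k] = {
                    "type": "surface",
                    "degree_u": v.degree_u,
                    "degree_v": v.degree_v,
                    "control_points": v.control_points.tolist(),
                    "weights": v.weights.tolist(),
                    "knots_u": v.knots_u.tolist(),
                    "knots_v": v.knots_v.tolist(),
                    "closed_u": bool(v.closed_u),
                }
            else:
                raise InvalidInputError("collection items must be NURBS objects")
        doc = {"type": "collection", "items": items}
    else:
        raise InvalidInputError("unsupported NURBS object")
    Path(path).write_text(json.dumps(doc, indent=1))


def read_nurbs_json(path) -> NurbsCurve | NurbsSurface:
    doc = json.loads(Path(path).read_text())
    if doc["type"] == "curve":
        return NurbsCurve(
            doc["degree"],
            np.asarray(doc["control_points"], float),
            np.asarray(doc["weights"], float),
            np.asarray(doc["knots"], float),
            closed=doc.get("closed", False),
        )
    if doc["type"] == "surface":
        return NurbsSurface(
            doc["degree_u"],
            doc["degree_v"],
            np.asarray(doc["control_points"], float),
            np.asarray(doc["weights"], float),
            np.asarray(doc["knots_u"], float),
            np.asarray(doc["knots_v"], float),
            closed_u=doc.get("closed_u", False),
        )
    raise ParseError(f"{path}: unknown NURBS document type {doc['type']!r}")


def write_mesh(mesh: TriMesh, path) -> None:
    """Export a mesh as binary STL or OBJ, by file extension."""
    tm = mesh.to_trimesh() if isinstance(mesh, TriMesh) else mesh
    path = Path(path)
    if path.suffix.lower() not in (".stl", ".obj"):
        raise InvalidInputError("mesh export supports .stl and .obj")
    tm.export(str(path))
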