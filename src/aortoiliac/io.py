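"""Readers and writers for the three centerline dialects and the report CSV.

Dialects
--------
* CSV: ``branch_id,point_index,x,y,z[,radius][,parent_id][,label]``.
* VTK XML PolyData (``.vtp``): ASCII polyline cells, radius as a named
  point-data array (default ``MaximumInscribedSphereRadius``).
* JSON tree: explicit ``parent`` / ``label`` per branch.

Coordinates are written with enough digits to round-trip float64 in the CSV
and JSON dialects; the VTP writer uses a 17-significant-digit ASCII encoding.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, StructureError
from .model import (
    ATTACH_TOL_MM,
    LABELS,
    UNLABELED,
    BifurcationMetrics,
    Centerline,
    CenterlineTree,
    ElongationMetrics,
    SubjectReport,
    metric_field_names,
)

DEFAULT_RADIUS_ARRAY = "MaximumInscribedSphereRadius"

_CSV_REQUIRED = ("branch_id", "point_index", "x", "y", "z")


# ---------------------------------------------------------------------------
# connectivity inference (shared by CSV-without-parent and VTP readers)
# ---------------------------------------------------------------------------

def infer_parents(branches: dict[str, Centerline]) -> dict[str, str | None]:
    """Infer a rooted tree from shared endpoints within the attachment tolerance.

    A branch ``b`` attaches to the branch holding the point nearest to
    ``b``'s first point, preferring candidates whose nearest point is not
    their own first point (those are siblings sharing the junction).
    """
    ids = sorted(branches)
    parent: dict[str, str | None] = {}
    for b in ids:
        first = branches[b].points[0]
        best = None  # (is_sibling_like, distance, id)
        for p in ids:
            if p == b:
                continue
            d = np.linalg.norm(branches[p].points - first, axis=1)
            i = int(np.argmin(d))
            if d[i] > ATTACH_TOL_MM:
                continue
            sibling_like = i == 0 and np.linalg.norm(
                branches[p].points[0] - first
            ) <= ATTACH_TOL_MM
            key = (bool(sibling_like), float(d[i]), p)
            if best is None or key < best:
                best = key
        if best is None:
            parent[b] = None
        elif best[0]:
            # only sibling-like candidates: no true parent found
            parent[b] = None
        else:
            parent[b] = best[2]
    roots = [b for b, p in parent.items() if p is None]
    if len(roots) != 1:
        raise StructureError(
            f"endpoint-proximity connectivity yields {len(roots)} roots "
            f"({roots}); supply explicit parent ids"
        )
    return parent


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_centerline_csv(path, coordinate_frame: str = "LPS") -> CenterlineTree:
    """Read a flat-CSV centerline tree.

    Parameters
    ----------
    path : path-like
        CSV file with header columns ``branch_id, point_index, x, y, z`` and
        optional ``radius``, ``parent_id``, ``label``.
    coordinate_frame : {"LPS", "RAS"}
        Frame the coordinates are declared in (no conversion is applied).
    """
    try:
        df = pd.read_csv(path, dtype={"branch_id": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise FormatError(f"cannot parse CSV {path}: {e}") from e
    for col in _CSV_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    if df.duplicated(subset=["branch_id", "point_index"]).any():
        dup = df[df.duplicated(subset=["branch_id", "point_index"])].iloc[0]
        raise FormatError(
            f"duplicate (branch_id, point_index) = "
            f"({dup['branch_id']!r}, {dup['point_index']})"
        )
    has_radius = "radius" in df.columns
    has_parent = "parent_id" in df.columns
    has_label = "label" in df.columns

    branches: dict[str, Centerline] = {}
    parent: dict[str, str | None] = {}
    label: dict[str, str] = {}
    for bid, grp in df.groupby("branch_id", sort=True):
        grp = grp.sort_values("point_index")
        pts = grp[["x", "y", "z"]].to_numpy(dtype=float)
        rad = None
        if has_radius and grp["radius"].notna().all():
            rad = grp["radius"].to_numpy(dtype=float)
        branches[str(bid)] = Centerline(pts, rad)
        if has_parent:
            pvals = grp["parent_id"].dropna().unique()
            if len(pvals) > 1:
                raise FormatError(f"branch {bid!r} has conflicting parent_id values")
            parent[str(bid)] = str(pvals[0]) if len(pvals) else None
        if has_label:
            lvals = grp["label"].dropna().unique()
            if len(lvals) > 1:
                raise FormatError(f"branch {bid!r} has conflicting label values")
            if len(lvals):
                label[str(bid)] = str(lvals[0])
    if not has_parent:
        parent = infer_parents(branches)
    return CenterlineTree(branches, parent, label, coordinate_frame)


def write_centerline_csv(tree: CenterlineTree, path) -> None:
    """Write a tree in the flat-CSV dialect (full float64 precision)."""
    rows = []
    for bid in sorted(tree.branches):
        cl = tree.branches[bid]
        for i, p in enumerate(cl.points):
            row = {
                "branch_id": bid,
                "point_index": i,
                "x": p[0],
                "y": p[1],
                "z": p[2],
            }
            if cl.radius is not None:
                row["radius"] = cl.radius[i]
            row["parent_id"] = tree.parent[bid] if tree.parent[bid] else ""
            lab = tree.label[bid]
            row["label"] = "" if lab == UNLABELED else lab
            rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


# ---------------------------------------------------------------------------
# VTK XML PolyData dialect (ASCII only; no VTK runtime dependency)
# ---------------------------------------------------------------------------

def _parse_ascii_array(elem: ET.Element, dtype=float) -> np.ndarray:
    fmt = elem.get("format", "ascii")
    if fmt != "ascii":
        raise FormatError(f"only ascii-format VTP DataArrays are supported, got {fmt!r}")
    tokens = (elem.text or "").split()
    if not tokens:
        return np.empty(0, dtype)
    try:
        return np.array(tokens, dtype=dtype)
    except ValueError as e:
        raise FormatError(f"malformed numeric DataArray: {e}") from e


def read_centerline_vtp(
    path,
    coordinate_frame: str = "LPS",
    radius_array: str = DEFAULT_RADIUS_ARRAY,
) -> CenterlineTree:
    """Read polyline cells from a VTK XML PolyData file.

    One branch is created per polyline cell (named ``branch_0``, ``branch_1``,
    ... in cell order); connectivity is inferred from shared endpoints within
    1 mm. A per-point radius array is attached when ``radius_array`` exists.
    """
    try:
        root = ET.parse(path).getroot()
    except (ET.ParseError, OSError) as e:
        raise FormatError(f"cannot parse VTP {path}: {e}") from e
    piece = root.find("./PolyData/Piece")
    if piece is None:
        raise FormatError(f"{path} is not a VTK PolyData file")
    pts_elem = piece.find("./Points/DataArray")
    if pts_elem is None:
        raise FormatError(f"{path} has no Points array")
    coords = _parse_ascii_array(pts_elem).reshape(-1, 3)

    lines = piece.find("Lines")
    if lines is None:
        raise FormatError(f"{path} contains no polyline cells")
    conn = offs = None
    for arr in lines.findall("DataArray"):
        if arr.get("Name") == "connectivity":
            conn = _parse_ascii_array(arr, int)
        elif arr.get("Name") == "offsets":
            offs = _parse_ascii_array(arr, int)
    if conn is None or offs is None or len(offs) == 0:
        raise FormatError(f"{path} contains no polyline cells")

    radius = None
    pdata = piece.find("PointData")
    if pdata is not None:
        for arr in pdata.findall("DataArray"):
            if arr.get("Name") == radius_array:
                radius = _parse_ascii_array(arr)
                if radius.shape[0] != coords.shape[0]:
                    raise FormatError(
                        f"radius array {radius_array!r} has {radius.shape[0]} values "
                        f"for {coords.shape[0]} points"
                    )

    branches: dict[str, Centerline] = {}
    start = 0
    for i, end in enumerate(offs):
        idx = conn[start:end]
        start = int(end)
        rad = radius[idx] if radius is not None else None
        branches[f"branch_{i}"] = Centerline(coords[idx], rad)
    parent = infer_parents(branches) if len(branches) > 1 else {next(iter(branches)): None}
    return CenterlineTree(branches, parent, {}, coordinate_frame)


def write_centerline_vtp(
    tree: CenterlineTree, path, radius_array: str = DEFAULT_RADIUS_ARRAY
) -> None:
    """Write the tree as ASCII VTK XML PolyData (one polyline per branch)."""
    order = sorted(tree.branches)
    coords, radii, conn, offs = [], [], [], []
    n = 0
    all_radius = all(tree.branches[b].radius is not None for b in order)
    for b in order:
        cl = tree.branches[b]
        coords.append(cl.points)
        if all_radius:
            radii.append(cl.radius)
        conn.extend(range(n, n + len(cl)))
        n += len(cl)
        offs.append(n)
    pts = np.vstack(coords)

    def fmt(a, spec="%.17g"):
        return "\n".join(" ".join(spec % v for v in np.atleast_1d(row)) for row in a)

    vtk = ET.Element("VTKFile", type="PolyData", version="1.0", byte_order="LittleEndian")
    poly = ET.SubElement(vtk, "PolyData")
    piece = ET.SubElement(
        poly,
        "Piece",
        NumberOfPoints=str(n),
        NumberOfVerts="0",
        NumberOfLines=str(len(order)),
        NumberOfStrips="0",
        NumberOfPolys="0",
    )
    if all_radius:
        pdata = ET.SubElement(piece, "PointData", Scalars=radius_array)
        arr = ET.SubElement(
            pdata, "DataArray", type="Float64", Name=radius_array, format="ascii"
        )
        arr.text = fmt(np.concatenate(radii))
    points = ET.SubElement(piece, "Points")
    parr = ET.SubElement(
        points,
        "DataArray",
        type="Float64",
        NumberOfComponents="3",
        format="ascii",
    )
    parr.text = fmt(pts)
    lines = ET.SubElement(piece, "Lines")
    carr = ET.SubElement(lines, "DataArray", type="Int64", Name="connectivity", format="ascii")
    carr.text = " ".join(str(i) for i in conn)
    oarr = ET.SubElement(lines, "DataArray", type="Int64", Name="offsets", format="ascii")
    oarr.text = " ".join(str(i) for i in offs)
    ET.indent(vtk)
    ET.ElementTree(vtk).write(path, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# JSON tree dialect
# ---------------------------------------------------------------------------

def read_centerline_json(path, coordinate_frame: str | None = None) -> CenterlineTree:
    """Read the JSON tree dialect (explicit parent/child connectivity)."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as e:
        raise FormatError(f"cannot parse JSON {path}: {e}") from e
    if "branches" not in doc:
        raise FormatError(f"{path}: missing 'branches' object")
    frame = coordinate_frame or doc.get("coordinate_frame", "LPS")
    branches, parent, label = {}, {}, {}
    for bid, spec in doc["branches"].items():
        if "points" not in spec:
            raise FormatError(f"{path}: branch {bid!r} has no 'points'")
        branches[bid] = Centerline(spec["points"], spec.get("radius"))
        parent[bid] = spec.get("parent")
        if spec.get("label"):
            label[bid] = spec["label"]
    return CenterlineTree(branches, parent, label, frame)


def write_centerline_json(tree: CenterlineTree, path) -> None:
    doc = {"coordinate_frame": tree.coordinate_frame, "branches": {}}
    for bid in sorted(tree.branches):
        cl = tree.branches[bid]
        entry = {
            "points": cl.points.tolist(),
            "parent": tree.parent[bid],
            "label": None if tree.label[bid] == UNLABELED else tree.label[bid],
        }
        if cl.radius is not None:
            entry["radius"] = cl.radius.tolist()
        doc["branches"][bid] = entry
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# report CSV
# ---------------------------------------------------------------------------

_ELONG_COLS = [f.replace("segment_label", "") for f in metric_field_names(ElongationMetrics)]


def report_columns() -> list[str]:
    """Fixed, documented column order of the report CSV."""
    cols = ["subject_id"]
    for label in LABELS:
        for f in metric_field_names(ElongationMetrics):
            if f == "segment_label":
                continue
            cols.append(f"{label}.{f}")
    cols.extend(f"bifurcation.{f}" for f in metric_field_names(BifurcationMetrics))
    cols.append("provenance")
    return cols


def _fmt_value(v) -> str:
    if v is None:
        return ""
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return format(float(v), ".9g")


def write_report_csv(reports: list[SubjectReport], path) -> None:
    """Write one row per subject with the fixed column schema.

    Floats carry 9 significant digits; output is deterministic for identical
    input (dict-free ordering, sorted provenance keys).
    """
    if not reports:
        raise ValueError("report list is empty")
    cols = report_columns()
    lines = [",".join(cols)]
    for rep in reports:
        row = [rep.subject_id]
        for label in LABELS:
            em = rep.elongation.get(label)
            for f in metric_field_names(ElongationMetrics):
                if f == "segment_label":
                    continue
                row.append(_fmt_value(getattr(em, f)) if em is not None else "")
        bm = rep.bifurcation
        for f in metric_field_names(BifurcationMetrics):
            row.append(_fmt_value(getattr(bm, f)) if bm is not None else "")
        prov = json.dumps(rep.provenance, sort_keys=True).replace('"', "'")
        row.append(f'"{prov}"')
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


READERS = {
    "csv": read_centerline_csv,
    "vtp": read_centerline_vtp,
    "json": read_centerline_json,
}

WRITERS = {
    "csv": write_centerline_csv,
    "vtp": write_centerline_vtp,
    "json": write_centerline_json,
}
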