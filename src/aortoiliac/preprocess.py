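"""Centerline smoothing, arc-length resampling and anatomical labeling."""

from __future__ import annotations

import warnings

import numpy as np

from .errors import AmbiguityError, ParameterError, StructureError
from .model import UNLABELED, Centerline, CenterlineTree

#: Lateral-centroid separation below which left/right assignment is refused.
LATERALITY_TIE_MM = 0.5


def laplacian_smooth(
    centerline: Centerline, factor: float = 0.1, iterations: int = 100
) -> Centerline:
    """Endpoint-pinned umbrella Laplacian smoothing of a polyline.

    Each iteration replaces every interior point ``p`` by
    ``p + factor * ((p_prev + p_next) / 2 - p)``; the two endpoints never
    move and radii pass through unchanged.
    """
    if not 0 < factor < 1:
        raise ParameterError(f"smoothing factor must lie in (0, 1), got {factor}")
    if iterations < 0:
        raise ParameterError("iterations must be non-negative")
    if len(centerline) < 3:
        warnings.warn("2-point centerline returned unsmoothed", stacklevel=2)
        return centerline.copy()
    pts = centerline.points.copy()
    for _ in range(iterations):
        mid = 0.5 * (pts[:-2] + pts[2:])
        pts[1:-1] += factor * (mid - pts[1:-1])
    rad = None if centerline.radius is None else centerline.radius.copy()
    return Centerline(pts, rad)


def resample_arclength(centerline: Centerline, spacing_mm: float = 5.0) -> Centerline:
    """Resample at arc-length positions ``0, s, 2s, ...`` plus the exact endpoint.

    Positions are linearly interpolated along the polyline; radii are
    interpolated the same way. Total arc length is preserved within 0.1 %
    for inputs whose native spacing is at most ``spacing_mm / 2``.
    """
    if spacing_mm <= 0:
        raise ParameterError(f"spacing must be positive, got {spacing_mm}")
    pos = centerline.arc_positions()
    total = pos[-1]
    if spacing_mm >= total:
        raise ParameterError(
            f"spacing {spacing_mm} mm is not below the arc length {total:.3f} mm"
        )
    targets = np.arange(0.0, total, spacing_mm)
    # exact original endpoint always terminates the output
    if total - targets[-1] <= 1e-9 * max(total, 1.0):
        targets = targets[:-1]
    pts = np.empty((len(targets) + 1, 3))
    for k in range(3):
        pts[:-1, k] = np.interp(targets, pos, centerline.points[:, k])
    pts[-1] = centerline.points[-1]
    rad = None
    if centerline.radius is not None:
        rad = np.empty(len(targets) + 1)
        rad[:-1] = np.interp(targets, pos, centerline.radius)
        rad[-1] = centerline.radius[-1]
    return Centerline(pts, rad)


def _initial_direction(cl: Centerline) -> np.ndarray:
    d = cl.points[-1] - cl.points[0]
    return d / np.linalg.norm(d)


def identify_segments(tree: CenterlineTree) -> CenterlineTree:
    """Label the aortoiliac tree: root aorta, children CIAs, continuations EIAs.

    Left/right CIA assignment uses the mean lateral (x) coordinate in the
    declared frame: in LPS the larger-x child is the patient's left, in RAS
    the smaller-x child. When a CIA has two children the EIA is the child
    with the larger mean radius (the internal iliac being the smaller),
    falling back to the child deviating least from the CIA end direction
    when radii are absent. Pre-existing labels are preserved and validated.
    """
    tree = tree.copy()
    root = tree.root()
    kids = tree.children(root)
    if len(kids) != 2:
        raise StructureError(
            f"root branch must have exactly two children, found {len(kids)}"
        )

    def assign(branch: str, label: str) -> None:
        existing = tree.label[branch]
        if existing != UNLABELED and existing != label:
            raise StructureError(
                f"branch {branch!r} already labeled {existing!r}, expected {label!r}"
            )
        tree.label[branch] = label

    assign(root, "aorta")
    mx = {b: float(tree.branches[b].points[:, 0].mean()) for b in kids}
    if abs(mx[kids[0]] - mx[kids[1]]) < LATERALITY_TIE_MM:
        pre = {tree.label[b] for b in kids}
        if pre == {"cia_left", "cia_right"}:
            pass  # explicit labels resolve the tie
        else:
            raise AmbiguityError(
                "CIA lateral centroids differ by < 0.5 mm; supply explicit labels"
            )
    # LPS: +x toward patient left; RAS: +x toward patient right
    ordered = sorted(kids, key=lambda b: mx[b], reverse=tree.coordinate_frame == "LPS")
    if {tree.label[b] for b in kids} != {"cia_left", "cia_right"}:
        assign(ordered[0], "cia_left")
        assign(ordered[1], "cia_right")

    for cia in kids:
        side = tree.label[cia].removeprefix("cia_")
        gkids = tree.children(cia)
        if not gkids:
            continue
        if len(gkids) == 1:
            eia = gkids[0]
        elif len(gkids) == 2:
            radii = {
                g: tree.branches[g].radius.mean()
                for g in gkids
                if tree.branches[g].radius is not None
            }
            if len(radii) == 2:
                eia = max(gkids, key=lambda g: radii[g])
            else:
                cia_dir = _initial_direction(tree.branches[cia])
                eia = min(
                    gkids,
                    key=lambda g: float(
                        np.arccos(
                            np.clip(
                                np.dot(_initial_direction(tree.branches[g]), cia_dir),
                                -1.0,
                                1.0,
                            )
                        )
                    ),
                )
        else:
            raise StructureError(
                f"CIA branch {cia!r} has {len(gkids)} children; at most two supported"
            )
        assign(eia, f"eia_{side}")
    tree.validate()
    return tree


def smooth_tree(
    tree: CenterlineTree, factor: float = 0.1, iterations: int = 100
) -> CenterlineTree:
    """Apply endpoint-pinned smoothing to every branch (junctions stay put)."""
    out = tree.copy()
    for b in out.branches:
        out.branches[b] = laplacian_smooth(out.branches[b], factor, iterations)
    return out


def resample_tree(tree: CenterlineTree, spacing_mm: float = 5.0) -> CenterlineTree:
    """Resample every branch; branches shorter than the spacing pass through."""
    out = tree.copy()
    for b in out.branches:
        cl = out.branches[b]
        if cl.arc_positions()[-1] > spacing_mm:
            out.branches[b] = resample_arclength(cl, spacing_mm)
    return out
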