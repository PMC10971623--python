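"""Domain types: centerlines, vessel trees, and per-subject metric containers.

All coordinates and radii are millimeters; angles are degrees. Readers never
convert units — the unit system is declared, not inferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from .errors import AortoiliacError, StructureError

#: Recognized anatomical labels for aortoiliac segments.
LABELS = ("aorta", "cia_left", "cia_right", "eia_left", "eia_right")
UNLABELED = "unlabeled"

#: Supported patient coordinate frames (DICOM LPS is the default; +x points
#: toward the patient's left in LPS and toward the right in RAS).
FRAMES = ("LPS", "RAS")

#: Children attach to their parent within this Euclidean tolerance (mm).
ATTACH_TOL_MM = 1.0

_MIN_SEPARATION_MM = 1e-9


class Centerline:
    """An ordered 3-D polyline with optional per-point inscribed-sphere radii.

    Parameters
    ----------
    points : array-like, shape (n, 3)
        Ordered vertex coordinates in mm; ``n >= 2`` and consecutive points
        must be distinct.
    radius : array-like, shape (n,), optional
        Maximal-inscribed-sphere radius at each point, strictly positive.
    """

    __slots__ = ("points", "radius")

    def __init__(self, points, radius=None):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise AortoiliacError(f"points must have shape (n, 3), got {pts.shape}")
        if pts.shape[0] < 2:
            raise AortoiliacError("a centerline needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise AortoiliacError("centerline coordinates must be finite")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps <= _MIN_SEPARATION_MM):
            raise AortoiliacError("consecutive centerline points must be distinct")
        self.points = pts
        if radius is not None:
            rad = np.asarray(radius, dtype=float)
            if rad.shape != (pts.shape[0],):
                raise AortoiliacError(
                    f"radius length {rad.shape} does not match {pts.shape[0]} points"
                )
            if not np.all(np.isfinite(rad)) or np.any(rad <= 0):
                raise AortoiliacError("radii must be finite and strictly positive")
            self.radius = rad
        else:
            self.radius = None

    def __len__(self) -> int:
        return self.points.shape[0]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        r = "with radii" if self.radius is not None else "no radii"
        return f"Centerline({len(self)} points, {r})"

    @property
    def has_radius(self) -> bool:
        return self.radius is not None

    def arc_positions(self) -> np.ndarray:
        """Cumulative arc-length position of each vertex (mm), starting at 0."""
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    def copy(self) -> "Centerline":
        rad = None if self.radius is None else self.radius.copy()
        return Centerline(self.points.copy(), rad)

    def reversed(self) -> "Centerline":
        rad = None if self.radius is None else self.radius[::-1].copy()
        return Centerline(self.points[::-1].copy(), rad)


class CenterlineTree:
    """Named vessel branches with rooted connectivity and anatomical labels.

    Parameters
    ----------
    branches : dict[str, Centerline]
        Branch identifier to centerline.
    parent : dict[str, str | None]
        Parent branch per branch; exactly one branch has parent ``None``.
    label : dict[str, str], optional
        Anatomical label per branch, one of :data:`LABELS` or ``"unlabeled"``.
    coordinate_frame : {"LPS", "RAS"}
        Patient frame the coordinates are expressed in.
    """

    __slots__ = ("branches", "parent", "label", "coordinate_frame")

    def __init__(self, branches, parent, label=None, coordinate_frame="LPS"):
        if not branches:
            raise StructureError("tree has no branches")
        if coordinate_frame not in FRAMES:
            raise AortoiliacError(f"coordinate_frame must be one of {FRAMES}")
        self.branches = dict(branches)
        self.parent = {b: parent.get(b) for b in self.branches}
        lab = dict(label or {})
        self.label = {b: lab.get(b, UNLABELED) for b in self.branches}
        self.coordinate_frame = coordinate_frame
        self.validate()

    # -- structure ---------------------------------------------------------

    def root(self) -> str:
        roots = [b for b, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise StructureError(f"tree must have exactly one root, found {roots}")
        return roots[0]

    def children(self, branch: str) -> list[str]:
        return sorted(b for b, p in self.parent.items() if p == branch)

    def validate(self) -> None:
        """Check the rooted-tree, attachment and label-uniqueness invariants."""
        root = self.root()
        for b, p in self.parent.items():
            if p is not None and p not in self.branches:
                raise StructureError(f"branch {b!r} references unknown parent {p!r}")
        # no cycles: walk each branch to the root
        for b in self.branches:
            seen = set()
            node = b
            while node is not None:
                if node in seen:
                    raise StructureError(f"connectivity cycle involving {b!r}")
                seen.add(node)
                node = self.parent[node]
            if root not in seen:
                raise StructureError(f"branch {b!r} is not connected to the root")
        for b, p in self.parent.items():
            if p is None:
                continue
            first = self.branches[b].points[0]
            d = np.linalg.norm(self.branches[p].points - first, axis=1).min()
            if d > ATTACH_TOL_MM:
                raise StructureError(
                    f"branch {b!r} starts {d:.3f} mm from parent {p!r} "
                    f"(tolerance {ATTACH_TOL_MM} mm)"
                )
        used = [l for l in self.label.values() if l != UNLABELED]
        for l in used:
            if l not in LABELS:
                raise StructureError(f"unknown anatomical label {l!r}")
        dup = {l for l in used if used.count(l) > 1}
        if dup:
            raise StructureError(f"anatomical labels used more than once: {sorted(dup)}")

    # -- labels ------------------------------------------------------------

    def branch_with_label(self, label: str) -> str:
        for b, l in self.label.items():
            if l == label:
                return b
        raise StructureError(f"no branch labeled {label!r}")

    def has_label(self, label: str) -> bool:
        return label in self.label.values()

    def copy(self) -> "CenterlineTree":
        return CenterlineTree(
            {b: c.copy() for b, c in self.branches.items()},
            dict(self.parent),
            dict(self.label),
            self.coordinate_frame,
        )


@dataclass
class ElongationMetrics:
    """Length, chord, tortuosity index and average absolute curvature of a segment."""

    segment_label: str
    centerline_length_mm: float
    chord_length_mm: float
    tortuosity_index_pct: float
    aac_per_mm_x1000: float
    n_curvature_samples: int

    def __post_init__(self):
        if not self.chord_length_mm > 0:
            raise AortoiliacError("chord length must be positive")
        if self.centerline_length_mm < self.chord_length_mm - 1e-9:
            raise AortoiliacError("centerline length cannot be below chord length")
        if self.tortuosity_index_pct < -1e-9 or self.aac_per_mm_x1000 < 0:
            raise AortoiliacError("TI and AAC must be non-negative")
        if self.n_curvature_samples < 1:
            raise AortoiliacError("need at least one curvature sample")


@dataclass
class BifurcationMetrics:
    """Aortic-bifurcation angles, near-bifurcation areas and Murray's-law radii."""

    takeoff_left_deg: float
    takeoff_right_deg: float
    bifurcation_angle_deg: float
    planarity_left_deg: float
    planarity_right_deg: float
    asymmetry: float
    area_aorta_mm2: float
    area_cia_left_mm2: float
    area_cia_right_mm2: float
    r_aorta_mm: float
    r_cia_left_mm: float
    r_cia_right_mm: float
    r_ideal_mm: float
    r_discrepancy_mm: float

    def __post_init__(self):
        angles = (
            self.takeoff_left_deg,
            self.takeoff_right_deg,
            self.bifurcation_angle_deg,
            self.planarity_left_deg,
            self.planarity_right_deg,
        )
        if any(a < -1e-9 for a in angles):
            raise AortoiliacError("angles must be non-negative")
        if not -1.0 <= self.asymmetry <= 1.0:
            raise AortoiliacError("asymmetry must lie in [-1, 1]")
        positives = (
            self.area_aorta_mm2,
            self.area_cia_left_mm2,
            self.area_cia_right_mm2,
            self.r_aorta_mm,
            self.r_cia_left_mm,
            self.r_cia_right_mm,
            self.r_ideal_mm,
        )
        if any(v <= 0 for v in positives):
            raise AortoiliacError("areas and radii must be strictly positive")
        if self.r_discrepancy_mm < 0:
            raise AortoiliacError("radius discrepancy must be non-negative")
        for r, a in (
            (self.r_aorta_mm, self.area_aorta_mm2),
            (self.r_cia_left_mm, self.area_cia_left_mm2),
            (self.r_cia_right_mm, self.area_cia_right_mm2),
        ):
            if not math.isclose(r, math.sqrt(a / math.pi), rel_tol=1e-9):
                raise AortoiliacError("r_measured must equal sqrt(A/pi)")


@dataclass
class SubjectReport:
    """All metrics for one subject plus provenance of how they were computed."""

    subject_id: str
    elongation: dict[str, ElongationMetrics | None] = field(default_factory=dict)
    bifurcation: BifurcationMetrics | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for label in LABELS:
            self.elongation.setdefault(label, None)
        extra = set(self.elongation) - set(LABELS)
        if extra:
            raise AortoiliacError(f"unknown segment labels in report: {sorted(extra)}")


def metric_field_names(cls) -> list[str]:
    """Dataclass field names in declaration order (report column helper)."""
    return [f.name for f in fields(cls)]
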