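"""Aortic-bifurcation reference frame, angles and Murray's-law conformance.

The frame places three unit vectors at the junction: the aorta flow
direction ``f`` and the two daughter directions ``v_left`` / ``v_right``.
The bifurcation plane contains ``f`` by construction, with normal
``n = unit(f x (v_left - v_right))``, so the aorta's own out-of-plane angle
is identically zero and daughter planarity is measured relative to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    GeometryError,
    MissingDataError,
    ParameterError,
    StructureError,
    UndefinedMetricError,
)
from .model import BifurcationMetrics, Centerline, CenterlineTree

DEFAULT_WINDOW_MM = 15.0
DEFAULT_AREA_SPACING_MM = 5.0

_UNIT_TOL = 1e-9


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("cannot normalize a (near-)zero vector")
    return v / n


@dataclass(frozen=True)
class BifurcationFrame:
    """Junction origin plus unit vectors f, v_left, v_right and plane normal n."""

    origin: np.ndarray
    f: np.ndarray
    v_left: np.ndarray
    v_right: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        for name in ("f", "v_left", "v_right", "n"):
            v = getattr(self, name)
            if abs(np.linalg.norm(v) - 1.0) > _UNIT_TOL:
                raise GeometryError(f"frame vector {name} is not unit length")
        if abs(float(np.dot(self.n, self.f))) > 1e-6:
            raise GeometryError("plane normal must be orthogonal to the aorta axis")


def branch_vector(
    centerline: Centerline,
    origin: np.ndarray,
    window_mm: float = DEFAULT_WINDOW_MM,
    orientation: str = "away",
) -> np.ndarray:
    """Unit direction of a branch near the junction, oriented along flow.

    A least-squares line (first principal axis) is fitted to the centerline
    points within ``window_mm`` arc length of the point nearest ``origin``.
    ``orientation="away"`` points from the junction into the branch
    (daughters); ``orientation="toward"`` points into the junction (parent).
    """
    if orientation not in ("away", "toward"):
        raise ParameterError(f"orientation must be 'away' or 'toward', got {orientation!r}")
    origin = np.asarray(origin, dtype=float)
    pos = centerline.arc_positions()
    i_near = int(np.argmin(np.linalg.norm(centerline.points - origin, axis=1)))
    dist = np.abs(pos - pos[i_near])
    mask = dist <= window_mm
    if mask.sum() < 2:
        raise GeometryError(
            f"fewer than 2 centerline points within {window_mm} mm of the junction"
        )
    pts = centerline.points[mask]
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    # orient: 'away' runs from the junction-side point to the far point
    far = pts[int(np.argmax(dist[mask]))]
    near = centerline.points[i_near]
    ref = far - near if orientation == "away" else near - far
    if float(np.dot(d, ref)) < 0:
        d = -d
    return _unit(d)


def build_frame(tree: CenterlineTree, window_mm: float = DEFAULT_WINDOW_MM) -> BifurcationFrame:
    """Construct the bifurcation frame of a labeled aortoiliac tree."""
    for label in ("aorta", "cia_left", "cia_right"):
        if not tree.has_label(label):
            raise StructureError(f"tree is missing a branch labeled {label!r}")
    aorta = tree.branches[tree.branch_with_label("aorta")]
    left = tree.branches[tree.branch_with_label("cia_left")]
    right = tree.branches[tree.branch_with_label("cia_right")]
    origin = aorta.points[-1]
    f = branch_vector(aorta, origin, window_mm, orientation="toward")
    v_left = branch_vector(left, origin, window_mm, orientation="away")
    v_right = branch_vector(right, origin, window_mm, orientation="away")
    if np.linalg.norm(np.cross(v_left, v_right)) < 1e-6:
        raise GeometryError("degenerate bifurcation: daughter vectors are parallel")
    n = _unit(np.cross(f, v_left - v_right))
    return BifurcationFrame(origin=origin, f=f, v_left=v_left, v_right=v_right, n=n)


def _in_plane(frame: BifurcationFrame, v: np.ndarray) -> np.ndarray:
    proj = v - float(np.dot(v, frame.n)) * frame.n
    norm = np.linalg.norm(proj)
    if norm < 1e-9:
        raise GeometryError("daughter vector is orthogonal to the bifurcation plane")
    return proj / norm


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return math.degrees(math.acos(c))


def take_off_angle(frame: BifurcationFrame, side: str) -> float:
    """In-plane angle between a daughter vector and the aorta axis, degrees."""
    v = {"left": frame.v_left, "right": frame.v_right}[side]
    return _angle_deg(_in_plane(frame, v), frame.f)


def bifurcation_angle(frame: BifurcationFrame) -> float:
    """In-plane angle between the two daughter vectors, degrees."""
    return _angle_deg(_in_plane(frame, frame.v_left), _in_plane(frame, frame.v_right))


def planarity_angle(frame: BifurcationFrame, side: str) -> float:
    """Out-of-plane tilt of a daughter vector, |arcsin(v . n)| in degrees."""
    v = {"left": frame.v_left, "right": frame.v_right}[side]
    s = float(np.clip(np.dot(v, frame.n), -1.0, 1.0))
    return abs(math.degrees(math.asin(s)))


def bifurcation_asymmetry(theta_left_deg: float, theta_right_deg: float) -> float:
    """Normalized signed take-off difference (L - R)/(L + R), in (-1, 1)."""
    total = theta_left_deg + theta_right_deg
    if total <= 0:
        raise UndefinedMetricError("asymmetry undefined when take-off angles sum to zero")
    return (theta_left_deg - theta_right_deg) / total


def mean_cross_sectional_area(
    centerline: Centerline,
    origin: np.ndarray,
    window_mm: float = DEFAULT_WINDOW_MM,
    spacing_mm: float = DEFAULT_AREA_SPACING_MM,
) -> float:
    """Mean of pi * r^2 sampled every ``spacing_mm`` within ``window_mm`` of the junction.

    Samples sit at arc distances ``spacing, 2*spacing, ... <= window`` from
    the branch end nearest ``origin`` (the junction point itself is excluded);
    radii are linearly interpolated between centerline points.
    """
    if centerline.radius is None:
        raise MissingDataError("cross-sectional areas require per-point radii")
    origin = np.asarray(origin, dtype=float)
    pos = centerline.arc_positions()
    total = pos[-1]
    d_first = np.linalg.norm(centerline.points[0] - origin)
    d_last = np.linalg.norm(centerline.points[-1] - origin)
    # arc distance from the junction-side end of the branch
    dist = pos if d_first <= d_last else total - pos
    n_samples = int(math.floor(min(window_mm, dist.max()) / spacing_mm))
    if n_samples < 1:
        raise GeometryError(
            f"no area sample at {spacing_mm} mm intervals fits within "
            f"{window_mm} mm of the junction"
        )
    targets = spacing_mm * np.arange(1, n_samples + 1)
    order = np.argsort(dist)
    radii = np.interp(targets, dist[order], centerline.radius[order])
    return float(np.mean(math.pi * radii**2))


def murray_ideal_radius(r_parent_mm: float) -> float:
    """Ideal symmetric daughter radius r_parent * 2**(-1/3) from Murray's law."""
    if r_parent_mm <= 0:
        raise ParameterError("parent radius must be positive")
    return r_parent_mm * 2.0 ** (-1.0 / 3.0)


def radius_discrepancy(
    r_cia_left_mm: float, r_cia_right_mm: float, r_ideal_mm: float
) -> float:
    """Mean absolute deviation of the two daughter radii from the ideal radius."""
    if min(r_cia_left_mm, r_cia_right_mm, r_ideal_mm) <= 0:
        raise ParameterError("all radii must be positive")
    return 0.5 * (abs(r_cia_left_mm - r_ideal_mm) + abs(r_cia_right_mm - r_ideal_mm))


def compute_bifurcation_metrics(
    tree: CenterlineTree,
    window_mm: float = DEFAULT_WINDOW_MM,
    area_spacing_mm: float = DEFAULT_AREA_SPACING_MM,
) -> BifurcationMetrics:
    """All bifurcation metrics of a labeled tree with radii on aorta and CIAs.

    Aorta areas are averaged on the parent side of the junction, CIA areas
    on the daughter side; measured radii derive from the averaged areas and
    feed the Murray's-law ideal radius and discrepancy.
    """
    frame = build_frame(tree, window_mm)
    t_left = take_off_angle(frame, "left")
    t_right = take_off_angle(frame, "right")
    aorta = tree.branches[tree.branch_with_label("aorta")]
    left = tree.branches[tree.branch_with_label("cia_left")]
    right = tree.branches[tree.branch_with_label("cia_right")]
    a_aorta = mean_cross_sectional_area(aorta, frame.origin, window_mm, area_spacing_mm)
    a_left = mean_cross_sectional_area(left, frame.origin, window_mm, area_spacing_mm)
    a_right = mean_cross_sectional_area(right, frame.origin, window_mm, area_spacing_mm)
    r_aorta = math.sqrt(a_aorta / math.pi)
    r_left = math.sqrt(a_left / math.pi)
    r_right = math.sqrt(a_right / math.pi)
    r_ideal = murray_ideal_radius(r_aorta)
    return BifurcationMetrics(
        takeoff_left_deg=t_left,
        takeoff_right_deg=t_right,
        bifurcation_angle_deg=bifurcation_angle(frame),
        planarity_left_deg=planarity_angle(frame, "left"),
        planarity_right_deg=planarity_angle(frame, "right"),
        asymmetry=bifurcation_asymmetry(t_left, t_right),
        area_aorta_mm2=a_aorta,
        area_cia_left_mm2=a_left,
        area_cia_right_mm2=a_right,
        r_aorta_mm=r_aorta,
        r_cia_left_mm=r_left,
        r_cia_right_mm=r_right,
        r_ideal_mm=r_ideal,
        r_discrepancy_mm=radius_discrepancy(r_left, r_right, r_ideal),
    )
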