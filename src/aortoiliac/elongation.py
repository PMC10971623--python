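"""Arc length, tortuosity index and discrete osculating-circle curvature.

The tortuosity index (TI) is the percentage excess of centerline length over
the straight endpoint distance, ``(L/D - 1) * 100``. Curvature is estimated
at fixed arc-length samples as the reciprocal circumradius of each sample
and its two neighbours; the average absolute curvature (AAC) is the mean of
those samples, reported in 1/mm scaled by 1000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError
from .model import Centerline, ElongationMetrics
from .preprocess import resample_arclength

#: Relative collinearity tolerance below which curvature is reported as zero.
_COLLINEAR_RTOL = 1e-12

_MIN_CHORD_MM = 1e-6


@dataclass
class CurvatureProfile:
    """Unsigned curvature samples along a centerline.

    Attributes
    ----------
    arc_position_mm : ndarray
        Strictly increasing arc-length position of each sample.
    kappa_per_mm : ndarray
        Non-negative curvature (1/mm) at each sample.
    """

    arc_position_mm: np.ndarray
    kappa_per_mm: np.ndarray

    def __post_init__(self):
        self.arc_position_mm = np.asarray(self.arc_position_mm, dtype=float)
        self.kappa_per_mm = np.asarray(self.kappa_per_mm, dtype=float)
        if self.arc_position_mm.shape != self.kappa_per_mm.shape:
            raise ValueError("positions and curvatures must have equal length")
        if np.any(np.diff(self.arc_position_mm) <= 0):
            raise ValueError("arc positions must be strictly increasing")
        if np.any(self.kappa_per_mm < 0):
            raise ValueError("curvature samples must be non-negative")


def arc_length(centerline: Centerline) -> float:
    """Total polyline length in mm (sum of consecutive Euclidean distances)."""
    return float(np.linalg.norm(np.diff(centerline.points, axis=0), axis=1).sum())


def chord_length(centerline: Centerline) -> float:
    """Straight distance between the two endpoints in mm."""
    return float(np.linalg.norm(centerline.points[-1] - centerline.points[0]))


def tortuosity_index(centerline: Centerline) -> float:
    """TI = (L/D - 1) x 100, the percentage excess length over the chord."""
    d = chord_length(centerline)
    if d <= _MIN_CHORD_MM:
        raise UndefinedMetricError(
            "tortuosity index is undefined for (nearly) closed centerlines"
        )
    return (arc_length(centerline) / d - 1.0) * 100.0


def _circumcircle_curvature(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Reciprocal circumradius of the triangle (p0, p1, p2).

    kappa = 4 * Area / (|a| |b| |c|); returns 0 when the points are collinear
    within the relative tolerance.
    """
    a = np.linalg.norm(p1 - p0)
    b = np.linalg.norm(p2 - p1)
    c = np.linalg.norm(p2 - p0)
    cross = np.cross(p1 - p0, p2 - p0)
    area2 = np.linalg.norm(cross)  # twice the triangle area
    if area2 <= _COLLINEAR_RTOL * a * b * c or area2 == 0.0:
        return 0.0
    return float(2.0 * area2 / (a * b * c))


def pointwise_curvature(
    centerline: Centerline, spacing_mm: float | None = 5.0
) -> CurvatureProfile:
    """Discrete osculating-circle curvature at fixed arc-length samples.

    Parameters
    ----------
    centerline : Centerline
        Input polyline.
    spacing_mm : float or None
        Sample spacing; the centerline is resampled internally at this
        spacing. Pass ``None`` to use the points exactly as given (e.g. when
        the input is already sampled at the desired interval).

    Endpoints carry no curvature sample; at each interior sample the
    curvature is the reciprocal circumradius of the sample and its two
    neighbours (zero for collinear triples).
    """
    cl = centerline
    if spacing_mm is not None:
        cl = resample_arclength(cl, spacing_mm)
    if len(cl) < 3:
        raise UndefinedMetricError("curvature needs at least 3 samples")
    pts = cl.points
    pos = cl.arc_positions()
    kappa = np.array(
        [_circumcircle_curvature(pts[i - 1], pts[i], pts[i + 1]) for i in range(1, len(cl) - 1)]
    )
    return CurvatureProfile(pos[1:-1], kappa)


def average_absolute_curvature(
    centerline: Centerline, spacing_mm: float | None = 5.0
) -> float:
    """Mean unsigned curvature sample, reported as 1/mm x 1000."""
    profile = pointwise_curvature(centerline, spacing_mm)
    return float(profile.kappa_per_mm.mean() * 1000.0)


def compute_elongation_metrics(
    centerline: Centerline, segment_label: str, spacing_mm: float | None = 5.0
) -> ElongationMetrics:
    """Bundle L, D, TI and AAC for one labeled segment."""
    profile = pointwise_curvature(centerline, spacing_mm)
    return ElongationMetrics(
        segment_label=segment_label,
        centerline_length_mm=arc_length(centerline),
        chord_length_mm=chord_length(centerline),
        tortuosity_index_pct=tortuosity_index(centerline),
        aac_per_mm_x1000=float(profile.kappa_per_mm.mean() * 1000.0),
        n_curvature_samples=int(profile.kappa_per_mm.size),
    )
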