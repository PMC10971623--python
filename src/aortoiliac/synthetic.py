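"""Seeded synthetic centerlines and aortoiliac trees with ground-truth metrics.

Analytic curves (lines, arcs, helices) carry closed-form tortuosity and
curvature truths; parameterized bifurcation trees carry the angle, asymmetry
and radius-discrepancy values implied by their construction. These objects
stand in for patient scans in every test and acceptance check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import bifurcation as bif
from .errors import ParameterError
from .model import Centerline, CenterlineTree

_Y = np.array([0.0, 1.0, 0.0])
_F_AORTA = np.array([0.0, 0.0, -1.0])  # flow direction: superior -> inferior


@dataclass
class SyntheticTruth:
    """Generator parameters plus the metric values they imply.

    ``expected`` maps metric keys to analytic values; every expected value
    carries an entry in ``tolerance``. Stochastic fixtures record their seed
    so they can be regenerated bit-exactly.
    """

    name: str
    params: dict = field(default_factory=dict)
    seed: int | None = None
    expected: dict = field(default_factory=dict)
    tolerance: dict = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self):
        missing = [k for k, v in self.expected.items() if v is not None and k not in self.tolerance]
        if missing:
            raise ParameterError(f"expected values without tolerances: {missing}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "params": self.params,
            "seed": self.seed,
            "expected": self.expected,
            "tolerance": self.tolerance,
            "notes": self.notes,
        }


# ---------------------------------------------------------------------------
# analytic curves
# ---------------------------------------------------------------------------

def _line(length: float, spacing: float) -> np.ndarray:
    s = np.arange(0.0, length, spacing)
    if length - s[-1] > 1e-9:
        s = np.append(s, length)
    return np.column_stack([s, np.zeros_like(s), np.zeros_like(s)])


def _arc(radius: float, sweep_deg: float, spacing: float) -> np.ndarray:
    phi = math.radians(sweep_deg)
    total = radius * phi
    s = np.arange(0.0, total, spacing)
    if total - s[-1] > 1e-9:
        s = np.append(s, total)
    theta = s / radius
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros_like(theta)]
    )


def _helix(r: float, c: float, turns: float, spacing: float) -> np.ndarray:
    speed = math.hypot(r, c)  # |dp/dt| for p(t) = (r cos t, r sin t, c t)
    t_end = 2.0 * math.pi * turns
    total = speed * t_end
    s = np.arange(0.0, total, spacing)
    if total - s[-1] > 1e-9:
        s = np.append(s, total)
    t = s / speed
    return np.column_stack([r * np.cos(t), r * np.sin(t), c * t])


def make_curve(
    kind: str, params: dict | None = None, spacing_mm: float = 5.0, seed: int = 0
) -> tuple[Centerline, SyntheticTruth]:
    """Generate an analytic test curve with its closed-form metric truth.

    Kinds and parameters
    --------------------
    ``line``            : length (default 100)
    ``arc``             : R (radius, default 100), sweep_deg (default 90)
    ``helix``           : r (default 10), c (pitch/2pi, default 5), turns (default 1)
    ``perturbed_line``  : length, amplitude, wavelength, jitter_sd (truth is
    bounds-only; the jitter stream is seeded and reproducible)
    """
    params = dict(params or {})
    if spacing_mm <= 0:
        raise ParameterError("spacing_mm must be positive")
    tol = {"ti_pct": 1e-9, "aac_x1000": 1e-9}
    if kind == "line":
        length = float(params.setdefault("length", 100.0))
        if length <= spacing_mm:
            raise ParameterError("line length must exceed the spacing")
        pts = _line(length, spacing_mm)
        expected = {"ti_pct": 0.0, "aac_x1000": 0.0}
    elif kind == "arc":
        R = float(params.setdefault("R", 100.0))
        sweep = float(params.setdefault("sweep_deg", 90.0))
        if R <= 0 or not 0 < sweep <= 359:
            raise ParameterError("arc needs R > 0 and sweep_deg in (0, 359]")
        pts = _arc(R, sweep, spacing_mm)
        phi = math.radians(sweep)
        expected = {
            "ti_pct": ((phi / 2.0) / math.sin(phi / 2.0) - 1.0) * 100.0,
            "aac_x1000": 1000.0 / R,
        }
        tol = {"ti_pct": 0.1, "aac_x1000": 1e-6}
    elif kind == "helix":
        r = float(params.setdefault("r", 10.0))
        c = float(params.setdefault("c", 5.0))
        turns = float(params.setdefault("turns", 1.0))
        if min(r, c, turns) <= 0:
            raise ParameterError("helix needs r, c, turns > 0")
        pts = _helix(r, c, turns, spacing_mm)
        expected = {
            "ti_pct": (math.hypot(r, c) / c - 1.0) * 100.0,
            "aac_x1000": 1000.0 * r / (r * r + c * c),
        }
        tol = {"ti_pct": 0.5, "aac_x1000": 0.01 * expected["aac_x1000"]}
        if turns != round(turns):
            expected["ti_pct"] = None  # chord formula holds for whole turns only
    elif kind == "perturbed_line":
        length = float(params.setdefault("length", 100.0))
        amplitude = float(params.setdefault("amplitude", 2.0))
        wavelength = float(params.setdefault("wavelength", 40.0))
        jitter_sd = float(params.setdefault("jitter_sd", 0.0))
        if length <= spacing_mm or wavelength <= 0:
            raise ParameterError("perturbed_line needs length > spacing and wavelength > 0")
        pts = _line(length, spacing_mm)
        pts[:, 1] += amplitude * np.sin(2.0 * math.pi * pts[:, 0] / wavelength)
        if jitter_sd > 0:
            rng = np.random.default_rng(seed)
            pts[1:-1] += rng.normal(0.0, jitter_sd, size=pts[1:-1].shape)
        expected = {"ti_pct": None, "aac_x1000": None}
        tol = {}
    else:
        raise ParameterError(f"unknown curve kind {kind!r}")
    truth = SyntheticTruth(
        name=f"curve:{kind}",
        params={"kind": kind, "spacing_mm": spacing_mm, **params},
        seed=seed,
        expected=expected,
        tolerance=tol,
        notes="bounds only" if kind == "perturbed_line" else "",
    )
    return Centerline(pts), truth


# ---------------------------------------------------------------------------
# aortoiliac trees
# ---------------------------------------------------------------------------

def _daughter_direction(takeoff_deg: float, tilt_deg: float, lateral_sign: float) -> np.ndarray:
    """Unit daughter vector: in-plane take-off then out-of-plane tilt toward +y.

    The in-plane part lies in the x-z construction plane at ``takeoff_deg``
    from the aorta axis; tilting by ``tilt_deg`` rotates the vector toward +y
    while leaving its in-plane projection direction unchanged.
    """
    th = math.radians(takeoff_deg)
    al = math.radians(tilt_deg)
    in_plane = np.array([lateral_sign * math.sin(th), 0.0, -math.cos(th)])
    return math.cos(al) * in_plane + math.sin(al) * _Y


def _sample_segment(start: np.ndarray, direction: np.ndarray, length: float, step: float) -> np.ndarray:
    s = np.arange(0.0, length, step)
    if length - s[-1] > 1e-9:
        s = np.append(s, length)
    return start + np.outer(s, direction)


def make_aortoiliac_tree(
    takeoff_left_deg: float = 26.0,
    takeoff_right_deg: float = 26.0,
    tilt_left_deg: float = 0.0,
    tilt_right_deg: float = 0.0,
    r_aorta_mm: float = 8.0,
    murray_conforming: bool = True,
    r_cia_left_mm: float | None = None,
    r_cia_right_mm: float | None = None,
    segment_lengths_mm: dict | None = None,
    jitter_sd_mm: float = 0.0,
    seed: int = 0,
    step_mm: float = 2.0,
) -> tuple[CenterlineTree, SyntheticTruth]:
    """Build a five-branch aortoiliac tree with known bifurcation truth.

    The aorta runs down the -z axis into the origin; the daughters leave the
    origin at the requested in-plane take-off angles (LPS frame: left toward
    +x) and are tilted out of the construction plane toward +y by the
    requested amounts. EIAs continue each CIA in a straight line. Radii are
    constant per branch; ``murray_conforming`` overrides explicit CIA radii
    with ``r_aorta * 2**(-1/3)``. Truth angles are the values implied by the
    construction vectors under the bifurcation-frame definition (exact when
    the two tilts are equal). Gaussian jitter, when requested, displaces
    interior points only and is fully seeded.
    """
    for name, a in (
        ("takeoff_left_deg", takeoff_left_deg),
        ("takeoff_right_deg", takeoff_right_deg),
    ):
        if not 0 < a < 90:
            raise ParameterError(f"{name} must lie in (0, 90), got {a}")
    for name, a in (("tilt_left_deg", tilt_left_deg), ("tilt_right_deg", tilt_right_deg)):
        if not -90 < a < 90:
            raise ParameterError(f"{name} must lie in (-90, 90), got {a}")
    if r_aorta_mm <= 0:
        raise ParameterError("r_aorta_mm must be positive")
    if jitter_sd_mm < 0:
        raise ParameterError("jitter_sd_mm must be non-negative")

    lengths = {"aorta": 90.0, "cia": 60.0, "eia": 100.0}
    lengths.update(segment_lengths_mm or {})

    if murray_conforming:
        r_left = r_right = bif.murray_ideal_radius(r_aorta_mm)
    else:
        if r_cia_left_mm is None or r_cia_right_mm is None:
            raise ParameterError(
                "explicit CIA radii are required when murray_conforming is False"
            )
        r_left, r_right = float(r_cia_left_mm), float(r_cia_right_mm)
    if min(r_left, r_right) <= 0:
        raise ParameterError("CIA radii must be positive")

    v_left = _daughter_direction(takeoff_left_deg, tilt_left_deg, +1.0)
    v_right = _daughter_direction(takeoff_right_deg, tilt_right_deg, -1.0)

    origin = np.zeros(3)
    top = np.array([0.0, 0.0, lengths["aorta"]])
    aorta_pts = _sample_segment(top, _F_AORTA, lengths["aorta"], step_mm)
    cia_l_pts = _sample_segment(origin, v_left, lengths["cia"], step_mm)
    cia_r_pts = _sample_segment(origin, v_right, lengths["cia"], step_mm)
    eia_l_pts = _sample_segment(cia_l_pts[-1], v_left, lengths["eia"], step_mm)
    eia_r_pts = _sample_segment(cia_r_pts[-1], v_right, lengths["eia"], step_mm)

    if jitter_sd_mm > 0:
        rng = np.random.default_rng(seed)
        for pts in (aorta_pts, cia_l_pts, cia_r_pts, eia_l_pts, eia_r_pts):
            pts[1:-1] += rng.normal(0.0, jitter_sd_mm, size=pts[1:-1].shape)

    def branch(pts: np.ndarray, r: float) -> Centerline:
        return Centerline(pts, np.full(len(pts), r))

    branches = {
        "aorta": branch(aorta_pts, r_aorta_mm),
        "cia_left": branch(cia_l_pts, r_left),
        "cia_right": branch(cia_r_pts, r_right),
        "eia_left": branch(eia_l_pts, 0.8 * r_left),
        "eia_right": branch(eia_r_pts, 0.8 * r_right),
    }
    parent = {
        "aorta": None,
        "cia_left": "aorta",
        "cia_right": "aorta",
        "eia_left": "cia_left",
        "eia_right": "cia_right",
    }
    label = {b: b for b in branches}
    tree = CenterlineTree(branches, parent, label, "LPS")

    # truth: evaluate the frame definition on the exact construction vectors
    n = np.cross(_F_AORTA, v_left - v_right)
    n /= np.linalg.norm(n)
    frame = bif.BifurcationFrame(
        origin=origin, f=_F_AORTA, v_left=v_left, v_right=v_right, n=n
    )
    t_left = bif.take_off_angle(frame, "left")
    t_right = bif.take_off_angle(frame, "right")
    r_ideal = bif.murray_ideal_radius(r_aorta_mm)
    angle_tol = 0.5 if jitter_sd_mm == 0 else 3.0
    truth = SyntheticTruth(
        name="aortoiliac_tree",
        params={
            "takeoff_left_deg": takeoff_left_deg,
            "takeoff_right_deg": takeoff_right_deg,
            "tilt_left_deg": tilt_left_deg,
            "tilt_right_deg": tilt_right_deg,
            "r_aorta_mm": r_aorta_mm,
            "murray_conforming": murray_conforming,
            "r_cia_left_mm": r_left,
            "r_cia_right_mm": r_right,
            "segment_lengths_mm": lengths,
            "jitter_sd_mm": jitter_sd_mm,
            "step_mm": step_mm,
        },
        seed=seed,
        expected={
            "takeoff_left_deg": t_left,
            "takeoff_right_deg": t_right,
            "bifurcation_angle_deg": bif.bifurcation_angle(frame),
            "planarity_left_deg": bif.planarity_angle(frame, "left"),
            "planarity_right_deg": bif.planarity_angle(frame, "right"),
            "asymmetry": bif.bifurcation_asymmetry(t_left, t_right),
            "r_discrepancy_mm": bif.radius_discrepancy(r_left, r_right, r_ideal),
        },
        tolerance={
            "takeoff_left_deg": angle_tol,
            "takeoff_right_deg": angle_tol,
            "bifurcation_angle_deg": angle_tol,
            "planarity_left_deg": angle_tol,
            "planarity_right_deg": angle_tol,
            "asymmetry": 0.01 if jitter_sd_mm == 0 else 0.05,
            "r_discrepancy_mm": 0.01 if jitter_sd_mm == 0 else 0.1,
        },
    )
    return tree, truth


# ---------------------------------------------------------------------------
# preset registry
# ---------------------------------------------------------------------------

def _preset_murray_symmetric_52deg():
    return make_aortoiliac_tree(takeoff_left_deg=26.0, takeoff_right_deg=26.0)


def _preset_tilted_left_10deg():
    # both daughters hinge 10 degrees out of the construction plane, so the
    # left daughter's out-of-plane angle is exactly 10 under the frame normal
    return make_aortoiliac_tree(tilt_left_deg=10.0, tilt_right_deg=10.0)


def _preset_asymmetric_30_20():
    return make_aortoiliac_tree(takeoff_left_deg=30.0, takeoff_right_deg=20.0)


def _preset_elderly_tortuous():
    return make_curve(
        "perturbed_line",
        {"length": 120.0, "amplitude": 8.0, "wavelength": 35.0, "jitter_sd": 0.0},
        spacing_mm=2.0,
    )


PRESETS = {
    "murray_symmetric_52deg": _preset_murray_symmetric_52deg,
    "tilted_left_10deg": _preset_tilted_left_10deg,
    "asymmetric_30_20": _preset_asymmetric_30_20,
    "elderly_tortuous": _preset_elderly_tortuous,
}


def preset(name: str):
    """Return a deterministic (object, truth) pair from the preset registry."""
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    obj, truth = PRESETS[name]()
    truth.name = f"preset:{name}"
    return obj, truth
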