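"""End-to-end analysis: smooth -> resample -> label -> elongation + bifurcation."""

from __future__ import annotations

import logging
from pathlib import Path

from . import __version__
from .bifurcation import compute_bifurcation_metrics
from .config import AnalysisConfig
from .elongation import compute_elongation_metrics
from .errors import AortoiliacError
from .io import READERS
from .model import LABELS, CenterlineTree, SubjectReport
from .preprocess import identify_segments, resample_tree, smooth_tree

log = logging.getLogger("aortoiliac")


def analyze_tree(
    tree: CenterlineTree, subject_id: str, config: AnalysisConfig | None = None
) -> SubjectReport:
    """Run the full pipeline on an in-memory tree and return its report.

    Branches are smoothed with endpoints pinned, resampled at the configured
    arc-length spacing, anatomically labeled when unlabeled, and measured.
    Segments absent from the tree are reported as missing; bifurcation
    metrics require radii on the aorta and both CIAs and are reported as
    missing otherwise (with the reason logged).
    """
    cfg = config or AnalysisConfig()
    work = smooth_tree(tree, cfg.smoothing_factor, cfg.smoothing_iterations)
    work = resample_tree(work, cfg.resample_spacing_mm)
    if not all(work.has_label(l) for l in ("aorta", "cia_left", "cia_right")):
        work = identify_segments(work)

    report = SubjectReport(subject_id=subject_id, provenance=_provenance(cfg))
    for label in LABELS:
        if not work.has_label(label):
            log.info("subject %s: segment %s missing from input", subject_id, label)
            continue
        cl = work.branches[work.branch_with_label(label)]
        # already resampled at the curvature spacing when spacings coincide
        spacing = None if cfg.curvature_spacing_mm == cfg.resample_spacing_mm else cfg.curvature_spacing_mm
        report.elongation[label] = compute_elongation_metrics(cl, label, spacing)
    try:
        report.bifurcation = compute_bifurcation_metrics(
            work, cfg.bifurcation_window_mm, cfg.bifurcation_area_spacing_mm
        )
    except AortoiliacError as e:
        log.warning("subject %s: bifurcation metrics unavailable: %s", subject_id, e)
        report.bifurcation = None
    return report


def analyze_file(path, fmt: str, config: AnalysisConfig | None = None) -> SubjectReport:
    """Read one centerline file in the given dialect and analyze it."""
    cfg = config or AnalysisConfig()
    reader = READERS[fmt]
    kwargs = {"coordinate_frame": cfg.frame}
    if fmt == "vtp":
        kwargs["radius_array"] = cfg.radius_array
    tree = reader(path, **kwargs)
    report = analyze_tree(tree, subject_id=Path(path).stem, config=cfg)
    report.provenance["input"] = Path(path).name
    return report


def _provenance(cfg: AnalysisConfig) -> dict:
    return {"software": "aortoiliac", "version": __version__, "config": cfg.to_dict()}
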