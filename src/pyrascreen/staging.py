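"""TNM-style slide staging from tissue-level RoIs and cell-level evidence.

A slide is assigned one of four node-lesion classes following the clinical
TNM size conventions: macrometastasis (largest lesion extent > 2.0 mm),
micrometastasis (0.2-2.0 mm, or more than 200 tumor cells), isolated tumor
cells (ITC: <= 0.2 mm and <= 200 cells) and negative.  Extents are maximum
Feret (caliper) diameters in millimetres; all cut-offs are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

SLIDE_LABELS = ("negative", "itc", "micro", "macro")
LABEL_ORDER = {lab: i for i, lab in enumerate(SLIDE_LABELS)}


@dataclass
class StagingThresholds:
    """Clinical TNM node-lesion cut-offs (config-overridable)."""

    macro_min_mm: float = 2.0
    micro_min_mm: float = 0.2
    itc_max_cells: int = 200
    negative_break_level: int = 2

    def __post_init__(self):
        if not (self.macro_min_mm > self.micro_min_mm > 0):
            raise ValueError("need macro_min_mm > micro_min_mm > 0")
        if self.itc_max_cells <= 0:
            raise ValueError("itc_max_cells must be positive")


@dataclass
class SlideDecision:
    """Staging output: the class label plus its supporting evidence."""

    label: str
    largest_extent_mm: float = 0.0
    max_cell_count: int = 0
    evidence: dict = field(default_factory=dict)


def region_extent_mm(points, pixel_size_um=1.0, level=0):
    """Maximum Feret diameter of a region in millimetres.

    ``points`` is either an (n, 2) array of (row, col) pixel coordinates at
    the given level or a 2-D binary mask (its True pixels are used).  The
    pixel size is scaled by ``2**level``.
    """
    pts = np.asarray(points)
    if pts.ndim == 2 and pts.dtype == bool:
        pts = np.argwhere(pts)
    pts = np.asarray(pts, dtype=float)
    if pts.size == 0:
        raise ValueError("empty region")
    px_mm = pixel_size_um * (2 ** level) * 1e-3
    if len(pts) == 1:
        return px_mm
    return _max_pairwise(pts) * px_mm


def _max_pairwise(pts):
    """Maximum pairwise distance; convex-hull reduction for large sets."""
    pts = np.asarray(pts, dtype=float)
    if len(pts) > 64:
        from scipy.spatial import ConvexHull, QhullError

        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:  # degenerate (collinear) sets
            pass
    return float(pdist(pts).max())


def _component_extent_mm(component, pyramid, patch_size):
    """Feret diameter of a connected RoI component from its patch corners."""
    px_mm = pyramid.level_pixel_size_um(component[0].level) * 1e-3
    corners = []
    for roi in component:
        r, c = roi.origin
        h, w = roi.size
        corners.extend([(r, c), (r, c + w), (r + h, c), (r + h, c + w)])
    pts = np.asarray(corners, dtype=float) * px_mm
    return float(pdist(pts).max())


def classify_slide(rois_by_level, cell_regions, thresholds, pyramid, patch_size=32):
    """Stage a slide from search RoIs and cell-level regions.

    Decision chain (larger class wins when regions disagree):

    1. no RoI at any level finer than ``negative_break_level`` -> negative
       (the search broke off before reaching the decision level);
    2. any 4-connected RoI component at ``negative_break_level`` with Feret
       extent >= ``macro_min_mm`` -> macro;
    3. any cell region with diameter >= ``micro_min_mm`` or more than
       ``itc_max_cells`` cells -> micro;
    4. any cancer cells detected at all -> itc;
    5. otherwise negative.

    ``cell_regions`` may be ``None`` only when step 2 already decides macro
    or step 1 decides negative; otherwise cell-level evidence is required
    and a ``ValueError`` instructs to run cell detection.
    """
    from .search import connected_roi_area

    brk = thresholds.negative_break_level
    fine_rois = [roi for lvl, rois in rois_by_level.items() if lvl < brk for roi in rois]
    if not fine_rois:
        return SlideDecision(label="negative",
                             evidence={"reason": f"no RoI below level {brk}"})

    decision_rois = rois_by_level.get(brk, [])
    largest = 0.0
    n_comp = 0
    if decision_rois:
        comps = connected_roi_area(decision_rois, pyramid, patch_size=patch_size)
        n_comp = len(comps)
        for comp, _area in comps:
            largest = max(largest, _component_extent_mm(comp, pyramid, patch_size))
    if largest >= thresholds.macro_min_mm:
        return SlideDecision(label="macro", largest_extent_mm=largest,
                             evidence={"roi_components_at_break_level": n_comp})

    if cell_regions is None:
        raise ValueError(
            "sub-macro candidate regions present but no cell-level results; "
            "run cell detection (cell_detect) on the candidate regions first"
        )

    max_cells = max((reg.cell_count for reg in cell_regions), default=0)
    max_diam_mm = max((reg.diameter_um * 1e-3 for reg in cell_regions), default=0.0)
    evidence = {"roi_components_at_break_level": n_comp,
                "largest_roi_extent_mm": largest,
                "n_cell_regions": len(cell_regions)}
    if any(reg.diameter_um * 1e-3 >= thresholds.micro_min_mm
           or reg.cell_count > thresholds.itc_max_cells for reg in cell_regions):
        return SlideDecision(label="micro", largest_extent_mm=max(largest, max_diam_mm),
                             max_cell_count=max_cells, evidence=evidence)
    if max_cells > 0:
        return SlideDecision(label="itc", largest_extent_mm=max_diam_mm,
                             max_cell_count=max_cells, evidence=evidence)
    return SlideDecision(label="negative", largest_extent_mm=largest,
                         evidence=evidence)


def label_from_lesions(lesions, thresholds=None):
    """Staging oracle on planted lesion specs: the largest class wins.

    Each lesion contributes macro when its diameter reaches ``macro_min_mm``,
    micro when it reaches ``micro_min_mm`` (or exceeds ``itc_max_cells``
    cells), else ITC; a slide with no lesions is negative.
    """
    thresholds = thresholds or StagingThresholds()
    label = "negative"
    for lesion in lesions:
        d_mm = lesion.diameter_um * 1e-3
        cells = getattr(lesion, "cell_count", None)
        if d_mm >= thresholds.macro_min_mm:
            cand = "macro"
        elif d_mm >= thresholds.micro_min_mm or (cells is not None
                                                 and cells > thresholds.itc_max_cells):
            cand = "micro"
        else:
            cand = "itc"
        if LABEL_ORDER[cand] > LABEL_ORDER[label]:
            label = cand
    return label
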