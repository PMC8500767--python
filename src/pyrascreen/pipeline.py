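"""End-to-end slide screening: pyramid search -> cell detection -> staging.

Wires the modules into the screening order a pathology workflow follows:
coarse-to-fine RoI search over the pyramid, cell-level detection on the
surviving sub-macro candidate regions, then TNM-style staging.  Oracle
detectors (classifier from ground-truth masks, cell points from the planted
nuclei) provide the reference path used for validation on synthetic slides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .cells import cluster_points, nms_peaks
from .pyramid import extract_patch, map_coords
from .search import mask_fraction_classifier, search
from .staging import StagingThresholds, classify_slide


@dataclass
class ScreenConfig:
    """Screening pipeline settings."""

    patch_size: int = 32
    start_level: int | None = None
    stop_level: int = 1
    threshold: float = 0.5
    tissue_only: bool = False
    safety_margin: float = 0.0
    cluster_cutoff_um: float = 50.0
    nms_sigma: float = 3.0
    nms_smooth_sigma: float = 1.5
    thresholds: StagingThresholds = field(default_factory=StagingThresholds)


def candidate_footprints_level0(result, pyramid, thresholds):
    """Level-0 bounding boxes of the RoI components at the decision level."""
    from .search import connected_roi_area

    brk = thresholds.negative_break_level
    rois = result.rois_by_level.get(brk, [])
    if not rois:
        return []
    boxes = []
    for comp, _area in connected_roi_area(rois, pyramid, result.patch_size):
        rows = [roi.origin[0] for roi in comp]
        cols = [roi.origin[1] for roi in comp]
        ps = result.patch_size
        r0, c0 = map_coords((min(rows), min(cols)), brk, 0)
        r1, c1 = map_coords((max(rows) + ps, max(cols) + ps), brk, 0)
        boxes.append((r0, c0, r1, c1))
    return boxes


def oracle_cell_points(slide, footprints):
    """Planted tumor-cell points falling inside the candidate footprints."""
    pts = slide.tumor_points
    if len(pts) == 0:
        return np.empty((0, 2))
    keep = np.zeros(len(pts), dtype=bool)
    for (r0, c0, r1, c1) in footprints:
        keep |= ((pts[:, 0] >= r0) & (pts[:, 0] < r1)
                 & (pts[:, 1] >= c0) & (pts[:, 1] < c1))
    return pts[keep]


def detect_cells_in_footprints(pyramid, regressor, footprints, cfg,
                               tile=64, max_side=512):
    """Run the cell-level density model over candidate level-0 footprints.

    Each footprint is tiled, densities predicted, peaks extracted by NMS
    and mapped back to level-0 coordinates.  Footprints are clipped to
    ``max_side`` to bound desk-scale compute.
    """
    from .cells import GaussianKernelSpec

    spec = GaussianKernelSpec(sigma=cfg.nms_sigma)
    min_height = 0.1 * spec.peak_value()
    h, w = pyramid.level_dims(0)
    points = []
    for (r0, c0, r1, c1) in footprints:
        r0, c0 = max(0, r0), max(0, c0)
        r1, c1 = min(h, min(r1, r0 + max_side)), min(w, min(c1, c0 + max_side))
        for rr in range(r0, r1, tile):
            for cc in range(c0, c1, tile):
                patch = extract_patch(pyramid, 0, (rr, cc), (tile, tile))
                dens = regressor.predict(patch.image[None])[0]
                for (pr, pc) in nms_peaks(dens, radius=cfg.nms_sigma,
                                          min_height=min_height,
                                          smooth_sigma=cfg.nms_smooth_sigma):
                    points.append((rr + pr, cc + pc))
    return np.asarray(points, dtype=float).reshape(-1, 2)


def screen_slide(pyramid, classifier, cfg=None, cell_regressor=None,
                 slide=None, oracle=False):
    """Screen one slide and return (decision, search_result, cell_regions).

    With ``oracle=True`` the classifier defaults to the ground-truth-mask
    patch oracle and cell points come from the slide's planted tumor nuclei
    (requires ``slide``); otherwise a trained :class:`PatchClassifier`-style
    callable and a :class:`DensityRegressor` drive both stages.
    """
    cfg = cfg or ScreenConfig()
    if oracle:
        classifier = mask_fraction_classifier(pyramid)
    elif classifier is None:
        raise ValueError("a patch classifier is required unless oracle=True")
    clf = classifier if callable(classifier) else classifier.confidence

    result = search(pyramid, clf, t=cfg.threshold, start_level=cfg.start_level,
                    stop_level=cfg.stop_level, patch_size=cfg.patch_size,
                    tissue_only=cfg.tissue_only, safety_margin=cfg.safety_margin)

    # tissue-level evidence may already settle the slide (negative or macro);
    # only surviving sub-macro candidates go to the cell-level detector
    try:
        decision = classify_slide(result.rois_by_level, None, cfg.thresholds,
                                  pyramid, patch_size=cfg.patch_size)
        return decision, result, None
    except ValueError:
        pass

    footprints = candidate_footprints_level0(result, pyramid, cfg.thresholds)
    if oracle:
        if slide is None:
            raise ValueError("oracle screening needs the synthetic slide ground truth")
        points = oracle_cell_points(slide, footprints)
    elif cell_regressor is not None:
        points = detect_cells_in_footprints(pyramid, cell_regressor, footprints, cfg)
    else:
        raise ValueError("sub-macro candidates present: a cell_regressor is required")

    cell_regions = cluster_points(points, cfg.cluster_cutoff_um,
                                  pixel_size_um=pyramid.pixel_size_um)
    decision = classify_slide(result.rois_by_level, cell_regions, cfg.thresholds,
                              pyramid, patch_size=cfg.patch_size)
    return decision, result, cell_regions


def decision_report(decision, result, cell_regions, runtime_s=None, extra=None):
    """Assemble the YAML-serializable slide report."""
    report = {
        "label": decision.label,
        "evidence": {
            "largest_extent_mm": round(float(decision.largest_extent_mm), 4),
            "max_cell_count": int(decision.max_cell_count),
            **{k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
               for k, v in decision.evidence.items()},
        },
        "search": {
            "n_evaluations": int(result.n_evaluations),
            "rois_per_level": {int(l): len(r)
                               for l, r in sorted(result.rois_by_level.items())},
            "start_level": int(result.start_level),
            "stop_level": int(result.stop_level),
        },
        "cell_regions": ([] if cell_regions is None else
                         [{"cell_count": int(r.cell_count),
                           "diameter_um": round(float(r.diameter_um), 2)}
                          for r in cell_regions]),
    }
    if runtime_s is not None:
        report["runtime_s"] = round(float(runtime_s), 3)
    if extra:
        report.update(extra)
    return report


def write_report(report, path):
    with open(path, "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)
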