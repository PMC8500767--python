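"""Tree-like coarse-to-fine RoI search over the image pyramid.

The search starts from a dense grid of fixed-size patches at a coarse level.
Each patch is scored by a per-level classifier; patches whose cancer
confidence C(x) reaches the threshold t become regions of interest (RoIs)
and their four quadrant children at the next finer level are queued, while
sub-threshold patches are pruned together with their whole subtree.  Patch
positions are addressed by location-code information (LCI): a quadtree path
string over {0,1,2,3} (0=NW, 1=NE, 2=SW, 3=SE), one symbol per descended
level, anchored at a root patch of the start level.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pyramid import Patch, extract_patch, tile_level

QUADRANTS = "0123"
QUADRANT_OFFSETS = {"0": (0, 0), "1": (0, 1), "2": (1, 0), "3": (1, 1)}


@dataclass(frozen=True)
class LocationCode:
    """Quadtree path addressing one patch at one level.

    ``code`` holds one quadrant symbol per level descended below
    ``start_level``; ``root`` is the pixel origin of the ancestral root patch
    at the start level (multiple roots arise when the start level holds more
    than one patch).
    """

    code: str
    start_level: int
    root: tuple = (0, 0)

    def __post_init__(self):
        if any(s not in QUADRANTS for s in self.code):
            raise ValueError(f"malformed LCI symbol in {self.code!r}")

    @property
    def level(self):
        return self.start_level - len(self.code)


def lci_children(lci):
    """The four quadrant children of an LCI at the next finer level."""
    if lci.level <= 0:
        raise ValueError("cannot descend below level 0")
    return [LocationCode(code=lci.code + q, start_level=lci.start_level, root=lci.root)
            for q in QUADRANTS]


def lci_to_coords(lci, patch_size):
    """Decode an LCI into ``(level, (row, col))`` for a given patch size.

    Each descent doubles resolution: a parent at origin ``o`` maps to a
    footprint at ``2 o`` at the next finer level, and its quadrant child
    adds an offset of 0 or ``patch_size`` per axis.
    """
    depth = len(lci.code)
    r = lci.root[0] * (2 ** depth)
    c = lci.root[1] * (2 ** depth)
    for k, sym in enumerate(lci.code):
        dr, dc = QUADRANT_OFFSETS[sym]
        scale = 2 ** (depth - 1 - k)
        r += dr * patch_size * scale
        c += dc * patch_size * scale
    return lci.level, (r, c)


def lci_from_coords(level, origin, patch_size, start_level, root=(0, 0)):
    """Encode patch coordinates into an LCI (inverse of :func:`lci_to_coords`)."""
    depth = start_level - level
    if depth < 0:
        raise ValueError("level above start_level")
    r, c = origin
    r -= root[0] * (2 ** depth)
    c -= root[1] * (2 ** depth)
    symbols = []
    for k in range(depth):
        scale = 2 ** (depth - 1 - k)
        dr, rem_r = divmod(r, patch_size * scale)
        dc, rem_c = divmod(c, patch_size * scale)
        if dr not in (0, 1) or dc not in (0, 1):
            raise ValueError(f"origin {origin} not addressable from root {root}")
        symbols.append({(0, 0): "0", (0, 1): "1", (1, 0): "2", (1, 1): "3"}[(dr, dc)])
        r, c = rem_r, rem_c
    if (r, c) != (0, 0):
        raise ValueError(f"origin {origin} not aligned to the patch grid")
    return LocationCode(code="".join(symbols), start_level=start_level, root=root)


@dataclass
class RoI:
    """A patch flagged cancer-positive at one level."""

    lci: LocationCode
    level: int
    origin: tuple
    size: tuple
    confidence: float


@dataclass
class SearchResult:
    rois_by_level: dict
    n_evaluations: int
    start_level: int
    stop_level: int
    patch_size: int

    def rois(self, level):
        return self.rois_by_level.get(level, [])


def _resolve_classifier(models, level):
    if callable(models):
        return models
    try:
        return models[level]
    except (KeyError, TypeError, IndexError):
        raise KeyError(f"no classifier model for level {level}")


def mask_fraction_classifier(pyramid, positive_fraction=0.0):
    """Oracle classifier from the pyramid's ground-truth masks.

    Returns a callable scoring a patch 1.0 when the fraction of ground-truth
    positive pixels under its footprint exceeds ``positive_fraction``
    (default: any positive pixel), else 0.0.  Monotone under the any-positive
    mask-coarsening rule, which makes quadtree pruning lossless.
    """
    if pyramid.masks is None:
        raise ValueError("pyramid carries no ground-truth masks")

    def classify(patch):
        mask = pyramid.masks[patch.level]
        r, c = patch.origin
        h, w = patch.size
        crop = mask[max(r, 0):r + h, max(c, 0):c + w]
        frac = crop.sum() / (h * w) if crop.size else 0.0
        return 1.0 if frac > positive_fraction else 0.0

    return classify


def search(pyramid, models, t=0.5, start_level=None, stop_level=1, patch_size=32,
           tissue_only=False, safety_margin=0.0):
    """Coarse-to-fine quadtree RoI search (location-code guided).

    Parameters
    ----------
    models : callable or mapping level -> callable
        Patch classifier(s) returning a confidence in [0, 1] for a
        :class:`~pyrascreen.pyramid.Patch`.
    t : float
        Confidence threshold; at levels above ``stop_level`` it is lowered
        by ``safety_margin`` to mitigate non-monotone classifiers missing
        lesions that look benign when coarse.
    tissue_only : bool
        Restrict the start-level grid to patches with tissue content.

    Returns a :class:`SearchResult` with RoIs grouped by level and the number
    of classifier evaluations performed (for pruning-bound instrumentation).
    """
    if start_level is None:
        start_level = pyramid.n_levels - 1
    if not (start_level > stop_level >= 0):
        raise ValueError("need start_level > stop_level >= 0")
    if start_level >= pyramid.n_levels:
        raise ValueError("start_level outside the pyramid")
    _resolve_classifier(models, start_level)  # fail fast on missing model

    queue = deque()
    if tissue_only:
        start_patches = tile_level(pyramid, start_level, patch_size, patch_size,
                                   tissue_only=True)
        for p in start_patches:
            queue.append(LocationCode("", start_level, root=p.origin))
    else:
        h, w = pyramid.level_dims(start_level)
        for r in range(0, h, patch_size):
            for c in range(0, w, patch_size):
                queue.append(LocationCode("", start_level, root=(r, c)))

    rois_by_level = {}
    n_evals = 0
    while queue:
        lci = queue.popleft()
        level, origin = lci_to_coords(lci, patch_size)
        clf = _resolve_classifier(models, level)
        patch = extract_patch(pyramid, level, origin, (patch_size, patch_size))
        patch.lci = lci
        conf = float(clf(patch))
        n_evals += 1
        eff_t = t - safety_margin if level > stop_level else t
        if conf >= eff_t:
            rois_by_level.setdefault(level, []).append(
                RoI(lci=lci, level=level, origin=origin,
                    size=(patch_size, patch_size), confidence=conf))
            if level > stop_level:
                queue.extend(lci_children(lci))
    return SearchResult(rois_by_level=rois_by_level, n_evaluations=n_evals,
                        start_level=start_level, stop_level=stop_level,
                        patch_size=patch_size)


def exhaustive_scan(pyramid, models, t, level, patch_size=32):
    """Brute-force full tiling scan of one level (no pruning).

    Scores every grid patch of the level and returns the positive set; the
    reference against which the quadtree search is validated.
    """
    clf = _resolve_classifier(models, level)
    h, w = pyramid.level_dims(level)
    rois = []
    for r in range(0, h, patch_size):
        for c in range(0, w, patch_size):
            patch = extract_patch(pyramid, level, (r, c), (patch_size, patch_size))
            conf = float(clf(patch))
            if conf >= t:
                rois.append(RoI(lci=None, level=level, origin=(r, c),
                                size=(patch_size, patch_size), confidence=conf))
    return rois


def connected_roi_area(rois, pyramid, patch_size=None):
    """Group same-level RoIs into 4-connected components with physical areas.

    Connectivity is on the patch grid; each component's area is
    ``patch_count * (patch_size * pixel_size_at_level)**2`` in mm².
    Returns a list of ``(component_rois, area_mm2)`` pairs.
    """
    if not rois:
        return []
    levels = {r.level for r in rois}
    if len(levels) > 1:
        raise ValueError(f"RoIs span multiple levels: {sorted(levels)}")
    level = levels.pop()
    if patch_size is None:
        patch_size = rois[0].size[0]
    cells = {}
    for roi in rois:
        cells[(roi.origin[0] // patch_size, roi.origin[1] // patch_size)] = roi
    seen = set()
    components = []
    px_um = pyramid.level_pixel_size_um(level)
    patch_area_mm2 = (patch_size * px_um * 1e-3) ** 2
    for cell in sorted(cells):
        if cell in seen:
            continue
        comp = []
        stack = [cell]
        seen.add(cell)
        while stack:
            cur = stack.pop()
            comp.append(cells[cur])
            for d in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nb = (cur[0] + d[0], cur[1] + d[1])
                if nb in cells and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        components.append((comp, len(comp) * patch_area_mm2))
    return components


def rois_to_dataframe(result):
    """Flatten a SearchResult into a ``level,lci,row,col,size,confidence`` frame."""
    rows = []
    for level in sorted(result.rois_by_level, reverse=True):
        for roi in result.rois_by_level[level]:
            rows.append({
                "level": level,
                "lci": roi.lci.code if roi.lci is not None else "",
                "root_row": roi.lci.root[0] if roi.lci is not None else -1,
                "root_col": roi.lci.root[1] if roi.lci is not None else -1,
                "row": roi.origin[0],
                "col": roi.origin[1],
                "size": roi.size[0],
                "confidence": roi.confidence,
            })
    return pd.DataFrame(rows, columns=["level", "lci", "root_row", "root_col",
                                       "row", "col", "size", "confidence"])


def roi_heatmap(pyramid, rois, level, out_png=None, alpha=0.45):
    """Render RoIs as a red overlay heat map on one level (screening report style)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = pyramid.levels[level].astype(float) / 255.0
    overlay = np.zeros(img.shape[:2])
    for roi in rois:
        if roi.level != level:
            continue
        r, c = roi.origin
        h, w = roi.size
        overlay[r:r + h, c:c + w] = np.maximum(overlay[r:r + h, c:c + w],
                                               roi.confidence)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(img)
    ax.imshow(overlay, cmap="Reds", alpha=alpha * (overlay > 0), vmin=0, vmax=1)
    ax.set_axis_off()
    if out_png is not None:
        fig.savefig(out_png, bbox_inches="tight", dpi=120)
        plt.close(fig)
        return None
    return fig
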