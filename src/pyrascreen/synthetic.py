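"""Fully labelled synthetic pyramidal slides and patch datasets.

The generator emulates the structure of scanned H&E lymph-node slides at
desk scale: a chromatic pink tissue blob on a near-white glass background,
planted lesions of the three TNM size classes (macro / micro / ITC) rendered
as darker, denser-textured regions, and nuclei rendered as small dark
ellipses with point labels and bounding boxes.  Every slide carries per-level
ground-truth lesion masks (coarsened with the any-positive rule) and a true
staging label derived from the planted lesions, so every downstream module is
trainable and testable without external data.

It does not attempt photorealism: no stain physics, no scanner artefacts,
no real nuclear morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import cells as _cells
from .pyramid import Pyramid, build_pyramid, write_pyramid, read_pyramid
from .staging import StagingThresholds, label_from_lesions

TISSUE_RGB = np.array([217.0, 166.0, 191.0])
LESION_RGB = np.array([150.0, 110.0, 170.0])
NUCLEUS_RGB = np.array([90.0, 60.0, 120.0])
BACKGROUND_GRAY = 250.0


@dataclass
class LesionSpec:
    """One planted lesion: a darker, denser disk-like region.

    ``cell_count`` fixes the number of planted tumor nuclei (used for
    ITC-scale lesions, which the TNM convention counts by cells); when
    ``None`` the lesion is populated at three times the background nuclei
    density.
    """

    center: tuple
    diameter_um: float
    shape_irregularity: float = 0.0
    cell_count: int | None = None

    def __post_init__(self):
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be positive")
        if not (0 <= self.shape_irregularity <= 1):
            raise ValueError("shape_irregularity must be in [0, 1]")


@dataclass
class SlideSpec:
    """Parameters of one synthetic slide."""

    base_height: int
    base_width: int
    n_levels: int = 6
    pixel_size_um: float = 0.25
    lesions: list = field(default_factory=list)
    nuclei_density: float = 1000.0  # nuclei per mm^2 of tissue
    background_seed: int = 0
    tissue_radius_frac: float = 0.42

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        div = 2 ** (self.n_levels - 1)
        if self.base_height % div or self.base_width % div:
            raise ValueError(
                f"base dims {(self.base_height, self.base_width)} must be divisible "
                f"by 2**(n_levels-1) = {div}")
        if not (0.1 <= self.pixel_size_um <= 1.0):
            raise ValueError("pixel_size_um must lie in [0.1, 1.0]")


@dataclass
class SyntheticSlide:
    """A generated slide with its full ground truth."""

    pyramid: Pyramid
    lesion_masks: list
    tissue_mask: np.ndarray
    nuclei_points: np.ndarray
    nuclei_bboxes: np.ndarray
    nuclei_tumor: np.ndarray
    true_label: str
    spec: SlideSpec

    @property
    def tumor_points(self):
        return self.nuclei_points[self.nuclei_tumor]


def bbox_to_point(bbox):
    """Center of a bounding box: the average of its four coordinates."""
    r0, c0, r1, c1 = bbox
    if r0 > r1 or c0 > c1:
        raise ValueError(f"inverted bbox {bbox}")
    return ((r0 + r1) / 2.0, (c0 + c1) / 2.0)


def _multiscale_noise(shape, rng, scales=(16, 64), amplitude=1.0):
    """Smooth Perlin-like texture: sum of bilinearly upsampled noise octaves."""
    h, w = shape
    out = np.zeros((h, w), dtype=np.float32)
    for s in scales:
        coarse = rng.standard_normal((max(h // s, 1) + 1, max(w // s, 1) + 1))
        out += resize(coarse, (h, w), order=1, preserve_range=True,
                      anti_aliasing=False).astype(np.float32)
    return out * (amplitude / len(scales))


def _blob_mask(shape, center, radius_px, irregularity, rng, coarse=1):
    """Disk with a smooth low-order radial boundary perturbation.

    Evaluated only inside the blob's bounding window; ``coarse`` > 1
    evaluates the radial test on a coarse grid and replicates it (used for
    the large tissue blob, where a few-pixel boundary step is irrelevant).
    """
    h, w = shape
    cy, cx = center
    margin = 1.35 * radius_px + coarse
    r0 = max(int(cy - margin), 0)
    r1 = min(int(np.ceil(cy + margin)) + 1, h)
    c0 = max(int(cx - margin), 0)
    c1 = min(int(np.ceil(cx + margin)) + 1, w)
    mask = np.zeros((h, w), dtype=bool)
    if r1 <= r0 or c1 <= c0:
        return mask
    rows = np.arange(r0, r1, coarse, dtype=np.float32) + (coarse - 1) / 2.0
    cols = np.arange(c0, c1, coarse, dtype=np.float32) + (coarse - 1) / 2.0
    dy = (rows - cy)[:, None]
    dx = (cols - cx)[None, :]
    dist = np.sqrt(dy * dy + dx * dx)
    if irregularity > 0:
        theta = np.arctan2(dy, dx)
        amp = 0.2 * irregularity
        phases = rng.uniform(0, 2 * np.pi, size=3)
        bound = radius_px * (1.0
                             + amp * 0.5 * np.cos(2 * theta + phases[0])
                             + amp * 0.3 * np.cos(3 * theta + phases[1])
                             + amp * 0.2 * np.cos(5 * theta + phases[2]))
    else:
        bound = radius_px
    win = dist <= bound
    if coarse > 1:
        win = win.repeat(coarse, axis=0).repeat(coarse, axis=1)
    mask[r0:r1, c0:c1] = win[:r1 - r0, :c1 - c0]
    return mask


def _stamp_nuclei(image, points, radii, color, rng):
    """Draw axis-aligned dark ellipses (radius 3-5 px) at the given points."""
    h, w = image.shape[:2]
    for (pr, pc), (a, b) in zip(points, radii):
        ir, ic = int(round(pr)), int(round(pc))
        ra, rb = int(np.ceil(a)), int(np.ceil(b))
        r0, r1 = max(ir - ra, 0), min(ir + ra + 1, h)
        c0, c1 = max(ic - rb, 0), min(ic + rb + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        yy = (np.arange(r0, r1) - pr)[:, None] / a
        xx = (np.arange(c0, c1) - pc)[None, :] / b
        m = yy * yy + xx * xx <= 1.0
        jitter = rng.uniform(-10, 10)
        for ch in range(3):
            image[r0:r1, c0:c1, ch][m] = color[ch] + jitter
    return image


def _sample_in_mask(mask, n, rng):
    """Uniform points inside a boolean mask (exact count)."""
    flat = np.flatnonzero(mask)
    if len(flat) == 0 or n <= 0:
        return np.empty((0, 2))
    idx = rng.choice(flat, size=n, replace=True)
    rows, cols = np.unravel_index(idx, mask.shape)
    jitter = rng.uniform(0.0, 1.0, size=(n, 2))
    return np.column_stack([rows, cols]) + jitter


def generate_slide(spec, seed=0, thresholds=None):
    """Generate one fully labelled synthetic slide.

    Deterministic: the same ``(spec, seed)`` yields bit-identical output.
    The tissue shape and texture depend only on ``spec.background_seed``;
    nuclei placement and shading jitter on ``(background_seed, seed)``.
    The slide's true label is the staging oracle applied to the planted
    lesions.  A lesion whose disk leaves the canvas or the tissue region is
    rejected with an explicit error.
    """
    thresholds = thresholds or StagingThresholds()
    h, w = spec.base_height, spec.base_width
    px = spec.pixel_size_um
    shape_rng = np.random.default_rng(spec.background_seed)
    rng = np.random.default_rng([spec.background_seed, seed])

    # --- tissue blob on glass background
    tissue_r = spec.tissue_radius_frac * min(h, w)
    coarse = 4 if min(h, w) >= 1024 else 1
    tissue = _blob_mask((h, w), (h / 2.0, w / 2.0), tissue_r, 0.4, shape_rng,
                        coarse=coarse)
    image = np.empty((h, w, 3), dtype=np.float32)
    # texture/noise fields computed at reduced resolution for big canvases
    bg_noise = _multiscale_noise((h // coarse, w // coarse), shape_rng,
                                 scales=(max(32 // coarse, 4),), amplitude=2.0)
    texture = _multiscale_noise((h // coarse, w // coarse), shape_rng,
                                scales=(max(16 // coarse, 4), max(64 // coarse, 8)),
                                amplitude=12.0)
    if coarse > 1:
        bg_noise = bg_noise.repeat(coarse, axis=0).repeat(coarse, axis=1)
        texture = texture.repeat(coarse, axis=0).repeat(coarse, axis=1)
    image[:] = (BACKGROUND_GRAY + bg_noise)[:, :, None]
    tex_t = texture[tissue]
    for ch in range(3):
        image[:, :, ch][tissue] = TISSUE_RGB[ch] + tex_t

    # --- lesions
    lesion_mask = np.zeros((h, w), dtype=bool)
    lesion_masks_individual = []
    for k, lesion in enumerate(spec.lesions):
        radius_px = lesion.diameter_um / (2.0 * px)
        cy, cx = lesion.center
        if not (radius_px <= cy <= h - radius_px and radius_px <= cx <= w - radius_px):
            raise ValueError(
                f"lesion {k} (center {lesion.center}, diameter {lesion.diameter_um} um "
                f"= {2 * radius_px:.0f} px) does not fit inside the {h}x{w} canvas")
        lrng = np.random.default_rng([spec.background_seed, seed, 1000 + k])
        lcoarse = 2 if radius_px > 256 else 1
        lmask = _blob_mask((h, w), (cy, cx), radius_px, lesion.shape_irregularity,
                           lrng, coarse=lcoarse)
        inside = tissue[lmask].mean() if lmask.any() else 0.0
        if inside < 0.98:
            raise ValueError(
                f"lesion {k} at {lesion.center} lies outside the tissue region "
                f"({100 * (1 - inside):.1f}% of its disk is on glass)")
        # blend within the lesion's bounding window only
        rows = np.flatnonzero(lmask.any(axis=1))
        cols = np.flatnonzero(lmask.any(axis=0))
        r0, r1, c0, c1 = rows[0], rows[-1] + 1, cols[0], cols[-1] + 1
        msub = lmask[r0:r1, c0:c1]
        blend = 0.55
        tex_l = texture[r0:r1, c0:c1][msub] * 0.7
        for ch in range(3):
            sub = image[r0:r1, c0:c1, ch]
            sub[msub] = (1 - blend) * sub[msub] + blend * (LESION_RGB[ch] + tex_l)
        lesion_mask |= lmask
        lesion_masks_individual.append(lmask)

    # --- nuclei: background density in tissue, 3x density inside lesions
    area_mm2 = tissue.sum() * (px * 1e-3) ** 2
    n_bg = int(rng.poisson(spec.nuclei_density * area_mm2))
    pts = [_sample_in_mask(tissue, n_bg, rng)] if n_bg else [np.empty((0, 2))]
    for lesion, lmask in zip(spec.lesions, lesion_masks_individual):
        l_area_mm2 = lmask.sum() * (px * 1e-3) ** 2
        if lesion.cell_count is not None:
            n_extra = lesion.cell_count
        else:
            n_extra = int(round(2.0 * spec.nuclei_density * l_area_mm2))
        n_extra = max(n_extra, 3)  # every lesion carries at least a few cells
        pts.append(_sample_in_mask(lmask, n_extra, rng))
    points = np.vstack(pts)
    radii = rng.uniform(3.0, 5.0, size=(len(points), 2))
    order = np.lexsort((points[:, 1], points[:, 0]))
    points, radii = points[order], radii[order]
    _stamp_nuclei(image, points, radii, NUCLEUS_RGB, rng)
    tumor_flags = (lesion_mask[points[:, 0].astype(int), points[:, 1].astype(int)]
                   if len(points) else np.zeros(0, dtype=bool))
    bboxes = np.column_stack([points[:, 0] - radii[:, 0], points[:, 1] - radii[:, 1],
                              points[:, 0] + radii[:, 0], points[:, 1] + radii[:, 1]]) \
        if len(points) else np.empty((0, 4))

    base = np.clip(np.round(image), 0, 255).astype(np.uint8)
    pyramid = build_pyramid(base, spec.n_levels, pixel_size_um=px,
                            base_mask=lesion_mask)
    true_label = label_from_lesions(spec.lesions, thresholds)
    return SyntheticSlide(pyramid=pyramid, lesion_masks=pyramid.masks,
                          tissue_mask=tissue, nuclei_points=points,
                          nuclei_bboxes=bboxes, nuclei_tumor=tumor_flags,
                          true_label=true_label, spec=spec)


# ---------------------------------------------------------------------------
# Desk-scale slide specs per staging class


def make_staging_spec(label, rng, base=3072, n_levels=6, pixel_size_um=1.0):
    """A randomized SlideSpec whose planted lesion realizes the given class.

    Uses the top of the allowed pixel-size range (1.0 um/px) so that
    millimetre-scale TNM lesions fit a desk-scale canvas: a 3072 px base is
    ~3.1 mm across.  Lesion diameters keep a safety margin from the TNM
    cut-offs so patch-grid quantization cannot flip the class.
    """
    center_jitter = 0.08 * base
    cy = base / 2 + rng.uniform(-center_jitter, center_jitter)
    cx = base / 2 + rng.uniform(-center_jitter, center_jitter)
    lesions = []
    if label == "macro":
        d_um = rng.uniform(2200, 2500)
        lesions = [LesionSpec(center=(base / 2, base / 2), diameter_um=d_um,
                              shape_irregularity=0.2)]
    elif label == "micro":
        d_um = rng.uniform(350, 1200)
        lesions = [LesionSpec(center=(cy, cx), diameter_um=d_um,
                              shape_irregularity=0.3)]
    elif label == "itc":
        d_um = rng.uniform(80, 150)
        cells = int(rng.integers(60, 170))
        lesions = [LesionSpec(center=(cy, cx), diameter_um=d_um,
                              shape_irregularity=0.2, cell_count=cells)]
    elif label != "negative":
        raise ValueError(f"unknown staging class {label!r}")
    # radius fraction 0.46 keeps the largest macro lesion inside the tissue
    # blob for every boundary-wobble draw
    return SlideSpec(base_height=base, base_width=base, n_levels=n_levels,
                     pixel_size_um=pixel_size_um, lesions=lesions,
                     background_seed=int(rng.integers(0, 2 ** 31)),
                     tissue_radius_frac=0.46)


# ---------------------------------------------------------------------------
# Patch-level datasets for desk-scale training


def _render_patch(size, rng, tumor, nuclei_lambda=(4.0, 12.0)):
    img = np.empty((size, size, 3), dtype=np.float32)
    texture = _multiscale_noise((size, size), rng, scales=(8, 24), amplitude=12.0)
    base_color = TISSUE_RGB.copy()
    if tumor:
        base_color = 0.45 * base_color + 0.55 * LESION_RGB
    brightness = rng.uniform(-8, 8)
    for ch in range(3):
        img[:, :, ch] = base_color[ch] + texture + brightness
    lam = nuclei_lambda[1] if tumor else nuclei_lambda[0]
    n = int(rng.poisson(lam))
    pts = np.column_stack([rng.uniform(3, size - 3, n), rng.uniform(3, size - 3, n)])
    radii = rng.uniform(3.0, 5.0, size=(n, 2))
    _stamp_nuclei(img, pts, radii, NUCLEUS_RGB, rng)
    return np.clip(np.round(img), 0, 255).astype(np.uint8), pts


def generate_tissue_patches(n, size=64, seed=0):
    """Balanced tumor/normal patch set for the tissue-level classifier.

    Tumor patches are darker/more purple with ~3x nuclei density, matching
    the slide generator's lesion rendering.  Returns ``(X, y)`` with X of
    shape (n, size, size, 3) uint8 and y in {0, 1}.
    """
    rng = np.random.default_rng(seed)
    X = np.empty((n, size, size, 3), dtype=np.uint8)
    y = np.zeros(n, dtype=np.int64)
    for i in range(n):
        tumor = i % 2 == 1
        X[i], _ = _render_patch(size, rng, tumor)
        y[i] = int(tumor)
    return X, y


def generate_nuclei_patches(n, size=64, seed=0, k_range=(6, 13), min_sep=14,
                            sigma=3.0):
    """Nuclei patches with point labels and Gaussian density targets.

    Each patch holds ``k`` nuclei with pairwise separation >= ``min_sep``
    pixels (at least 4 sigma, so NMS can resolve every cell); targets come
    from :func:`pyrascreen.cells.points_to_density`.  Returns
    ``(X, point_lists, Y)``.
    """
    rng = np.random.default_rng(seed)
    spec = _cells.GaussianKernelSpec(sigma=sigma)
    X = np.empty((n, size, size, 3), dtype=np.uint8)
    Y = np.empty((n, size, size), dtype=np.float64)
    point_lists = []
    # keep the full truncated kernel inside the patch so mass is conserved
    margin = int(np.ceil(spec.truncate * sigma)) + 1
    for i in range(n):
        k = int(rng.integers(*k_range))
        pts = []
        tries = 0
        while len(pts) < k and tries < 2000:
            cand = rng.uniform(margin, size - margin, size=2)
            if all(np.hypot(cand[0] - p[0], cand[1] - p[1]) >= min_sep for p in pts):
                pts.append(tuple(cand))
            tries += 1
        pts = np.asarray(pts)
        img = np.empty((size, size, 3), dtype=np.float32)
        texture = _multiscale_noise((size, size), rng, scales=(8, 24), amplitude=8.0)
        for ch in range(3):
            img[:, :, ch] = TISSUE_RGB[ch] + texture
        radii = rng.uniform(3.0, 4.5, size=(len(pts), 2))
        _stamp_nuclei(img, pts, radii, NUCLEUS_RGB, rng)
        X[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)
        Y[i] = _cells.points_to_density(pts, (size, size), spec)
        point_lists.append(pts)
    return X, point_lists, Y


def generate_sequence_dataset(n_sequences, seq_len=4, size=64, seed=0):
    """Row-major patch sequences with tumor-mass ground truth for the
    LSTM-fused counter.

    Each patch may contain one irregular tumor blob; the ground-truth
    density ``F0`` is its 0/1 mask and the per-patch mass ``T0 = sum(F0)``.
    Returns a list of ``(patches, gt_maps, gt_counts)`` triples.
    """
    rng = np.random.default_rng(seed)
    sequences = []
    for _ in range(n_sequences):
        patches = np.empty((seq_len, size, size, 3), dtype=np.uint8)
        gt_maps = np.zeros((seq_len, size, size), dtype=np.float64)
        for i in range(seq_len):
            img, _ = _render_patch(size, rng, tumor=False)
            imgf = img.astype(np.float32)
            if rng.uniform() < 0.7:
                radius = rng.uniform(0.125, 0.34) * size
                cy = rng.uniform(radius, size - radius)
                cx = rng.uniform(radius, size - radius)
                mask = _blob_mask((size, size), (cy, cx), radius, 0.3, rng)
                for ch in range(3):
                    vals = imgf[:, :, ch][mask]
                    imgf[:, :, ch][mask] = 0.45 * vals + 0.55 * LESION_RGB[ch]
                gt_maps[i] = mask.astype(np.float64)
            patches[i] = np.clip(np.round(imgf), 0, 255).astype(np.uint8)
        gt_counts = gt_maps.sum(axis=(1, 2))
        sequences.append((patches, gt_maps, gt_counts))
    return sequences


# ---------------------------------------------------------------------------
# On-disk format


def write_slide(slide, outdir):
    """Write a slide in the pyramid dialect plus its ground-truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pyramid(slide.pyramid, outdir)
    rows = []
    for lesion in slide.spec.lesions:
        rows.append({"row": lesion.center[0], "col": lesion.center[1],
                     "diameter_um": lesion.diameter_um,
                     "cell_count": -1 if lesion.cell_count is None else lesion.cell_count,
                     "class": label_from_lesions([lesion])})
    pd.DataFrame(rows, columns=["row", "col", "diameter_um", "cell_count", "class"]) \
        .to_csv(outdir / "lesions.csv", index=False)
    nuc = pd.DataFrame({
        "row": slide.nuclei_points[:, 0], "col": slide.nuclei_points[:, 1],
        "r0": slide.nuclei_bboxes[:, 0], "c0": slide.nuclei_bboxes[:, 1],
        "r1": slide.nuclei_bboxes[:, 2], "c1": slide.nuclei_bboxes[:, 3],
        "tumor": slide.nuclei_tumor.astype(int),
    })
    nuc.to_csv(outdir / "nuclei.csv", index=False)
    (outdir / "label.txt").write_text(slide.true_label + "\n")


def read_slide(path):
    """Read back a written slide as ``(pyramid, nuclei_df, label)``."""
    path = Path(path)
    pyramid = read_pyramid(path)
    nuclei = pd.read_csv(path / "nuclei.csv")
    label = (path / "label.txt").read_text().strip()
    return pyramid, nuclei, label
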