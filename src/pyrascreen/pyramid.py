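"""Image-pyramid data model, tissue masking, tiling and patch preprocessing.

A whole-slide image is stored as an ordered stack of RGB levels: level 0 is
the finest; each coarser level halves both spatial dimensions and doubles the
physical pixel size.  Coordinates are 0-based ``(row, col)``, intervals
half-open.

On disk a pyramid is a directory of ``level_<l>.png`` files plus a
``pyramid.yaml`` with ``n_levels`` and ``pixel_size_um``; optional per-level
ground-truth masks are ``mask_<l>.png`` (0/255).  Pyramidal TIFF is accepted
read-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from matplotlib.path import Path as MplPath
from skimage.color import rgb2hsv
from skimage.exposure import match_histograms
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk
from skimage.transform import resize, rotate


@dataclass
class Pyramid:
    """Ordered stack of RGB levels, finest first.

    Parameters
    ----------
    levels : list of (H, W, 3) uint8 arrays
        ``levels[l+1]`` has ``ceil`` half the dims of ``levels[l]``.
    pixel_size_um : float
        Physical pixel size at level 0 in micrometres; level ``l`` has pixel
        size ``pixel_size_um * 2**l``.
    masks : list of (H, W) bool arrays, optional
        Per-level binary ground truth, same dims as the image levels.
    """

    levels: list
    pixel_size_um: float
    masks: list | None = None

    def __post_init__(self):
        for l in range(len(self.levels) - 1):
            h, w = self.levels[l].shape[:2]
            h2, w2 = self.levels[l + 1].shape[:2]
            if (h2, w2) != (-(-h // 2), -(-w // 2)):
                raise ValueError(
                    f"level {l + 1} dims {(h2, w2)} are not ceil-half of level {l} {(h, w)}"
                )
        if self.masks is not None and len(self.masks) != len(self.levels):
            raise ValueError("masks must match levels one-to-one")

    @property
    def n_levels(self):
        return len(self.levels)

    def level_pixel_size_um(self, level):
        return self.pixel_size_um * (2 ** level)

    def level_dims(self, level):
        return self.levels[level].shape[:2]


@dataclass
class Patch:
    """A rectangular crop of one pyramid level."""

    image: np.ndarray
    level: int
    origin: tuple
    size: tuple
    lci: object = None
    tissue_fraction: float | None = field(default=None, compare=False)


def build_pyramid(base_image, n_levels, pixel_size_um=0.25, base_mask=None):
    """Build an ``n_levels`` pyramid from a level-0 RGB image.

    Each coarser level is a 2x2 mean-pooled (area-averaged) downsampling of
    its predecessor; odd dims are edge-padded to even before pooling, so
    ``dims(l+1) == ceil(dims(l) / 2)``.  If ``base_mask`` is given, per-level
    masks are produced with the any-positive rule.
    """
    base_image = np.asarray(base_image)
    if base_image.ndim != 3 or base_image.shape[2] != 3:
        raise ValueError("base_image must be (H, W, 3) RGB")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if 2 ** (n_levels - 1) > min(base_image.shape[:2]):
        raise ValueError(
            f"n_levels={n_levels} exceeds log2 of the smallest base dimension"
        )
    levels = [base_image]
    for _ in range(n_levels - 1):
        levels.append(downsample2(levels[-1]))
    masks = None
    if base_mask is not None:
        masks = [np.asarray(base_mask, dtype=bool)]
        for _ in range(n_levels - 1):
            masks.append(downsample2_mask(masks[-1]))
    return Pyramid(levels=levels, pixel_size_um=pixel_size_um, masks=masks)


def downsample2(image):
    """2x2 mean pooling of an RGB image; odd dims edge-padded first."""
    img = np.asarray(image)
    h, w = img.shape[:2]
    ph, pw = h % 2, w % 2
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw), (0, 0)), mode="edge")
        h, w = img.shape[:2]
    pooled = img.reshape(h // 2, 2, w // 2, 2, -1).astype(np.float64).mean(axis=(1, 3))
    if np.issubdtype(image.dtype, np.integer):
        return np.round(pooled).astype(image.dtype)
    return pooled.astype(image.dtype)


def downsample2_mask(mask):
    """2x downsampling of a binary mask with the any-positive rule."""
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    ph, pw = h % 2, w % 2
    if ph or pw:
        m = np.pad(m, ((0, ph), (0, pw)), mode="constant")
        h, w = m.shape
    return m.reshape(h // 2, 2, w // 2, 2).any(axis=(1, 3))


def otsu_tissue_mask(level_image):
    """Tissue/background segmentation of one RGB level.

    Otsu's between-class-variance-maximizing threshold is applied on the HSV
    saturation channel (H&E tissue is chromatic, the glass background is
    achromatic white); a morphological closing with a radius-2 disk fills
    pinholes from nuclei and texture.
    """
    img = np.asarray(level_image)
    if img.size == 0:
        raise ValueError("empty image")
    sat = rgb2hsv(img)[:, :, 1]
    if np.allclose(sat.max(), sat.min()):
        warnings.warn("constant image: returning all-background tissue mask")
        return np.zeros(sat.shape, dtype=bool)
    thresh = threshold_otsu(sat)
    mask = sat > thresh
    return closing(mask, disk(2)).astype(bool)


def contour_to_mask(contours, shape):
    """Rasterize closed polygons into a binary mask with the even-odd rule.

    Each contour is a sequence of ``(row, col)`` vertices forming a closed
    ring (the last vertex connects back to the first).  A pixel is set when
    its center lies inside an odd number of contours; centers on a contour
    boundary count as inside.  Degenerate contours (< 3 distinct vertices)
    raise, since they cannot enclose a region.
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    if not contours:
        return mask
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    centers = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    for poly in contours:
        pts = np.asarray(poly, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(np.unique(pts, axis=0)) < 3:
            raise ValueError("contour must be a closed ring of >= 3 distinct (row, col) vertices")
        # explicit closing vertex: MplPath(closed=True) treats the final
        # vertex as the close-poly marker and would drop it otherwise
        ring = np.vstack([pts, pts[:1]])
        path = MplPath(ring, closed=True)
        # signed-radius dilation in both directions makes boundary centers
        # count as inside regardless of ring orientation
        inside = path.contains_points(centers, radius=1e-6)
        inside |= path.contains_points(centers, radius=-1e-6)
        mask ^= inside.reshape(h, w)
    return mask


def tile_level(pyramid, level, patch_size, stride, tissue_only=False,
               tissue_threshold=0.10):
    """Tile one level into a row-major grid of patches.

    Grid starts are ``0, stride, ..., floor((dim - patch_size)/stride)*stride``
    per axis; if that leaves an uncovered strip a final edge-aligned start is
    appended and the patch zero-padded to ``patch_size``.  With
    ``tissue_only`` patches with less than ``tissue_threshold`` tissue (by
    :func:`otsu_tissue_mask` on the level) are dropped.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    img = pyramid.levels[level]
    h, w = img.shape[:2]
    if patch_size > min(h, w):
        raise ValueError(f"patch_size {patch_size} exceeds level dims {(h, w)}")
    tissue = otsu_tissue_mask(img) if tissue_only else None

    def starts(dim):
        last = (dim - patch_size) // stride * stride
        s = list(range(0, last + 1, stride))
        if last + patch_size < dim:
            s.append(last + stride)
        return s

    patches = []
    for r in starts(h):
        for c in starts(w):
            crop = img[r:r + patch_size, c:c + patch_size]
            frac = None
            if tissue_only:
                tcrop = tissue[r:r + patch_size, c:c + patch_size]
                frac = tcrop.mean() * tcrop.size / (patch_size * patch_size)
                if frac < tissue_threshold:
                    continue
            if crop.shape[:2] != (patch_size, patch_size):
                padded = np.zeros((patch_size, patch_size, 3), dtype=img.dtype)
                padded[:crop.shape[0], :crop.shape[1]] = crop
                crop = padded
            patches.append(Patch(image=crop, level=level, origin=(r, c),
                                 size=(patch_size, patch_size), tissue_fraction=frac))
    return patches


def extract_patch(pyramid, level, origin, size):
    """Extract a patch at (level, origin); out-of-bounds area is zero-padded."""
    img = pyramid.levels[level]
    h, w = img.shape[:2]
    r, c = origin
    ph, pw = size
    out = np.zeros((ph, pw, 3), dtype=img.dtype)
    r0, c0 = max(r, 0), max(c, 0)
    r1, c1 = min(r + ph, h), min(c + pw, w)
    if r1 > r0 and c1 > c0:
        out[r0 - r:r1 - r, c0 - c:c1 - c] = img[r0:r1, c0:c1]
    return Patch(image=out, level=level, origin=(r, c), size=(ph, pw))


def map_coords(coords, from_level, to_level):
    """Map (row, col) between levels: multiply by 2**(from-to), floor when coarsening."""
    r, c = coords
    d = from_level - to_level
    if d >= 0:
        f = 2 ** d
        return (r * f, c * f)
    f = 2 ** (-d)
    return (r // f, c // f)


def equalize_color(patch, reference):
    """Per-channel histogram matching of ``patch`` to ``reference``.

    The standard color-equalization step that evens out stain and
    illumination differences between slides; dtype and range of the input
    are preserved.
    """
    p_img = patch.image if isinstance(patch, Patch) else np.asarray(patch)
    r_img = reference.image if isinstance(reference, Patch) else np.asarray(reference)
    matched = match_histograms(p_img, r_img, channel_axis=-1)
    if np.issubdtype(p_img.dtype, np.integer):
        matched = np.clip(np.round(matched), 0, np.iinfo(p_img.dtype).max).astype(p_img.dtype)
    else:
        matched = matched.astype(p_img.dtype)
    if isinstance(patch, Patch):
        return Patch(image=matched, level=patch.level, origin=patch.origin,
                     size=patch.size, lci=patch.lci)
    return matched


_AUGMENT_OPS = ("crop", "color_jitter", "scale", "rotate")


def augment_patch(patch, ops, seed, crop_fraction=0.8, jitter=0.1,
                  scale_range=(0.9, 1.1), right_angles=True):
    """Classical augmentation: random cropping, colour jittering, scaling, rotation.

    Deterministic under a fixed ``seed``; the output is resized back to the
    input patch size.  ``rotate`` draws from {0, 90, 180, 270} degrees by
    default (exact, interpolation-free); set ``right_angles=False`` for a
    continuous angle.
    """
    if not ops:
        raise ValueError("ops must be nonempty")
    for op in ops:
        if op not in _AUGMENT_OPS:
            raise ValueError(f"unknown augmentation op {op!r}; choose from {_AUGMENT_OPS}")
    rng = np.random.default_rng(seed)
    p_img = patch.image if isinstance(patch, Patch) else np.asarray(patch)
    dtype = p_img.dtype
    h, w = p_img.shape[:2]
    img = p_img.astype(np.float64)
    for op in _AUGMENT_OPS:  # fixed order so seeds are comparable across calls
        if op not in ops:
            continue
        if op == "crop":
            ch, cw = int(round(h * crop_fraction)), int(round(w * crop_fraction))
            r = int(rng.integers(0, h - ch + 1))
            c = int(rng.integers(0, w - cw + 1))
            img = resize(img[r:r + ch, c:c + cw], (h, w), preserve_range=True,
                         anti_aliasing=False)
        elif op == "color_jitter":
            gains = rng.uniform(1 - jitter, 1 + jitter, size=3)
            offset = rng.uniform(-jitter, jitter) * 255.0
            img = img * gains + offset
        elif op == "scale":
            s = rng.uniform(*scale_range)
            sh, sw = max(1, int(round(h * s))), max(1, int(round(w * s)))
            zoomed = resize(img, (sh, sw), preserve_range=True, anti_aliasing=False)
            if s >= 1.0:
                r = (sh - h) // 2
                c = (sw - w) // 2
                img = zoomed[r:r + h, c:c + w]
            else:
                img = resize(zoomed, (h, w), preserve_range=True, anti_aliasing=False)
        elif op == "rotate":
            if right_angles:
                k = int(rng.integers(0, 4))
                img = np.rot90(img, k=k, axes=(0, 1)).copy()
            else:
                angle = float(rng.uniform(0, 360))
                img = rotate(img, angle, preserve_range=True, mode="edge")
    if np.issubdtype(dtype, np.integer):
        img = np.clip(np.round(img), 0, np.iinfo(dtype).max).astype(dtype)
    else:
        img = img.astype(dtype)
    if isinstance(patch, Patch):
        return Patch(image=img, level=patch.level, origin=patch.origin,
                     size=patch.size, lci=patch.lci)
    return img


# ---------------------------------------------------------------------------
# On-disk dialect


def write_pyramid(pyramid, outdir):
    """Write the PNG-level directory dialect (plus masks when present)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for l, img in enumerate(pyramid.levels):
        iio.imwrite(outdir / f"level_{l}.png", img)
    if pyramid.masks is not None:
        for l, m in enumerate(pyramid.masks):
            iio.imwrite(outdir / f"mask_{l}.png", (m.astype(np.uint8) * 255))
    meta = {"n_levels": int(pyramid.n_levels),
            "pixel_size_um": float(pyramid.pixel_size_um)}
    (outdir / "pyramid.yaml").write_text(yaml.safe_dump(meta))


def read_pyramid(path):
    """Read a pyramid from the PNG-level directory dialect or a pyramidal TIFF."""
    path = Path(path)
    if path.is_file():
        return read_pyramid_tiff(path)
    meta = yaml.safe_load((path / "pyramid.yaml").read_text())
    levels = [np.asarray(iio.imread(path / f"level_{l}.png"))
              for l in range(meta["n_levels"])]
    masks = None
    if (path / "mask_0.png").exists():
        masks = [np.asarray(iio.imread(path / f"mask_{l}.png")) > 127
                 for l in range(meta["n_levels"])]
    return Pyramid(levels=levels, pixel_size_um=meta["pixel_size_um"], masks=masks)


def read_pyramid_tiff(path, pixel_size_um=0.25):
    """Read a multiresolution (SubIFD-pyramidal) TIFF, read-only."""
    import tifffile

    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        levels = [np.asarray(lvl.asarray()) for lvl in series.levels]
    return Pyramid(levels=levels, pixel_size_um=pixel_size_um)


def read_contours_csv(path):
    """Read contours from CSV ``polygon_id,row,col`` into a list of vertex arrays."""
    df = pd.read_csv(path)
    return [g[["row", "col"]].to_numpy(dtype=float)
            for _, g in df.groupby("polygon_id", sort=True)]


def camelyon_xml_to_csv(xml_path, csv_path):
    """Converter stub for Camelyon annotation XML (out of scope).

    The mapping, for reference: each ``<Annotation>`` element holds a
    ``<Coordinates>`` list of ``<Coordinate Order= X= Y=>`` vertices; ``X`` is
    the column and ``Y`` the row in level-0 pixels, one polygon per
    annotation.  Writing that as ``polygon_id,row,col`` rows yields the CSV
    dialect :func:`read_contours_csv` consumes.
    """
    raise NotImplementedError(
        "Camelyon XML parsing is out of scope; convert annotations to the "
        "polygon_id,row,col CSV dialect as described in this docstring"
    )
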