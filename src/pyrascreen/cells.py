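"""Cell-level detection: Gaussian point-label densities, NMS, counting, clustering.

Point annotations (one dot per nucleus) are turned into training targets by
stamping a truncated bivariate Gaussian kernel at each point; the spatial
integral of the resulting density map equals the number of points, so a
regressor trained on these maps counts by integration.  Detected positions
are recovered from a predicted density by non-maximum suppression and grouped
into candidate lesion regions by single-linkage clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import maximum_filter, minimum_filter
from scipy.spatial.distance import pdist


@dataclass
class GaussianKernelSpec:
    """Bivariate Gaussian kernel N(mu, sigma) used to rasterize a point label.

    ``sigma`` may be a scalar standard deviation (isotropic, the default
    sigma = 3 px) or a full 2x2 covariance matrix, which must be symmetric
    positive definite.
    """

    sigma: object = 3.0
    truncate: float = 3.0

    def covariance(self):
        s = self.sigma
        if np.isscalar(s):
            cov = np.eye(2) * float(s) ** 2
        else:
            cov = np.asarray(s, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError("covariance must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("covariance must be positive definite")
        return cov

    def peak_value(self):
        """Theoretical (untruncated) peak density (2*pi)^(-1) |Sigma|^(-1/2)."""
        cov = self.covariance()
        return 1.0 / (2.0 * np.pi * np.sqrt(np.linalg.det(cov)))


@dataclass
class CellRegion:
    """A cluster of detected cells forming one candidate lesion region."""

    points: np.ndarray
    diameter_um: float
    cell_count: int = field(init=False)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.cell_count = len(self.points)
        if self.cell_count < 1:
            raise ValueError("a region has at least one member point")


def points_to_density(points, shape, spec=None, peak_normalized=False):
    """Rasterize point labels into a density map by Gaussian stamping.

    Each point contributes ``P(x) = (2 pi)^(-D/2) |Sigma|^(-1/2)
    exp(-1/2 (x-mu)^T Sigma^-1 (x-mu))`` truncated at ``truncate`` standard
    deviations and rescaled post-truncation to unit mass, so the map integral
    equals the point count for interior points.  With ``peak_normalized`` the
    map is instead scaled so kernels peak at 1 (a 0-1 "mask" rendering; its
    integral is no longer a count and counting must go through peak
    enumeration).
    """
    spec = spec or GaussianKernelSpec()
    h, w = shape
    density = np.zeros((h, w), dtype=np.float64)
    if len(points) == 0:
        return density
    cov = spec.covariance()
    cov_inv = np.linalg.inv(cov)
    # truncation radius: `truncate` std devs along the widest principal axis
    radius = int(np.ceil(spec.truncate * np.sqrt(np.max(np.linalg.eigvalsh(cov)))))
    offs = np.arange(-radius, radius + 1)
    orr, occ = np.meshgrid(offs, offs, indexing="ij")
    for (pr, pc) in points:
        if not (0 <= pr < h and 0 <= pc < w):
            raise ValueError(f"point ({pr}, {pc}) outside map of shape {shape}")
        ir, ic = int(round(pr)), int(round(pc))
        dr = (ir + orr) - pr
        dc = (ic + occ) - pc
        quad = (dr * dr * cov_inv[0, 0] + 2 * dr * dc * cov_inv[0, 1]
                + dc * dc * cov_inv[1, 1])
        kernel = np.exp(-0.5 * quad)
        kernel /= kernel.sum()  # unit mass after truncation
        r0, r1 = ir - radius, ir + radius + 1
        c0, c1 = ic - radius, ic + radius + 1
        kr0, kc0 = max(0, -r0), max(0, -c0)
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1, cc1 = min(r1, h), min(c1, w)
        density[rr0:rr1, cc0:cc1] += kernel[kr0:kr0 + rr1 - rr0, kc0:kc0 + cc1 - cc0]
    if peak_normalized and density.max() > 0:
        density = density / density.max()
    return density


def _disk_footprint(radius):
    r = int(np.ceil(radius))
    yy, xx = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    fp = (yy * yy + xx * xx) <= radius * radius
    return fp


def nms_peaks(density, radius, min_height, smooth_sigma=0.0):
    """Non-maximum suppression: dominant local maxima of a density map.

    A pixel is a peak when its value is at least ``min_height``, no pixel
    within ``radius`` exceeds it, and at least one pixel within ``radius``
    is strictly smaller (so constant plateaus produce no peaks).  When two
    candidate pixels within ``radius`` tie exactly, the lexicographically
    smallest ``(row, col)`` wins and suppresses the others.

    ``smooth_sigma`` > 0 applies a Gaussian pre-filter before peak picking;
    useful on regressed density maps, whose upsampling ripple otherwise
    spawns spurious shallow maxima (exact rasterized densities need none).
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    d = np.asarray(density, dtype=np.float64)
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter
        d = gaussian_filter(d, smooth_sigma)
    fp = _disk_footprint(radius)
    fp_nc = fp.copy()
    fp_nc[fp.shape[0] // 2, fp.shape[1] // 2] = False
    neigh_max = maximum_filter(d, footprint=fp_nc, mode="constant", cval=-np.inf)
    neigh_min = minimum_filter(d, footprint=fp_nc, mode="constant", cval=np.inf)
    cand = (d >= neigh_max) & (d > neigh_min) & (d >= min_height)
    rows, cols = np.nonzero(cand)
    peaks = []
    r2 = radius * radius
    for r, c in sorted(zip(rows.tolist(), cols.tolist())):
        if all((r - pr) ** 2 + (c - pc) ** 2 > r2 for pr, pc in peaks):
            peaks.append((r, c))
    return peaks


def count_cells(points):
    """Detection count = cell count."""
    return len(points)


def cluster_points(points, cutoff_um, pixel_size_um=1.0):
    """Single-linkage clustering of detected points into candidate regions.

    Two points share a region iff a chain of pairwise distances each at most
    ``cutoff_um`` connects them (connected components of the distance graph).
    Point coordinates are in pixels; distances are measured in micrometres
    via ``pixel_size_um``.  Region diameter is the maximum pairwise member
    distance in micrometres.
    """
    if cutoff_um <= 0:
        raise ValueError("cutoff must be positive")
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        return []
    um = pts * pixel_size_um
    if len(pts) == 1:
        return [CellRegion(points=pts, diameter_um=0.0)]
    labels = fcluster(linkage(um, method="single"), t=cutoff_um, criterion="distance")
    regions = []
    for lab in np.unique(labels):
        member = pts[labels == lab]
        if len(member) == 1:
            diam = 0.0
        else:
            diam = float(pdist(member * pixel_size_um).max())
        regions.append(CellRegion(points=member, diameter_um=diam))
    return regions
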