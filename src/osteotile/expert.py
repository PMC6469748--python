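"""Expert-guided features: the eight per-tile statistics a pathologist reads.

The stage mirrors how experts scan H&E tissue: (1) discard strongly red
objects — bone matrix, red blood cells — by thresholding the a* (green-red)
channel of CIELAB; (2) split the remaining pixels into stain-dense foreground
("blue") and background ("red") by Otsu's criterion; (3) group foreground
pixels into nuclei clusters by flood fill and measure their shape; (4) summarise
cluster density in 32x32 windows.

Output per tile, in fixed order: total_clusters, average_clusters (per 32x32
window), red_count, red_percentage, blue_count, blue_percentage, mean_area,
mean_circularity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

EXPERT_FEATURE_NAMES = (
    "total_clusters",
    "average_clusters",
    "red_count",
    "red_percentage",
    "blue_count",
    "blue_percentage",
    "mean_area",
    "mean_circularity",
)

#: 8-connectivity structure for flood-fill clustering.
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ExpertParams:
    """Tunables of the expert-feature stage.

    ``delta`` is the a*-channel exclusion threshold (empirical default 64);
    ``strict`` selects the comparator (True: exclude a* > delta, as in the
    algorithmic definition; False: exclude a* >= delta as in the prose).
    ``window`` is the density-window edge length in pixels.
    """

    delta: float = 64.0
    strict: bool = True
    window: int = 32


@dataclass
class MaskedTile:
    """RGB image plus the per-pixel inclusion mask left by the a* filter."""

    image: np.ndarray
    included: np.ndarray  # bool, True = retained


@dataclass
class ClusterStats:
    """Per-cluster shape measurements of the flood-filled foreground.

    ``perimeter`` is a geometric length estimate (weighted chain code, as in
    ``skimage.measure.regionprops``) so that circularity ``4*pi*A/P**2`` is
    ~1 for disks; ``boundary_pixels`` is the raw count of foreground pixels
    with at least one background 4-neighbor, kept for reference.
    ``labels`` is the integer-labeled cluster image.
    """

    count: int
    area: np.ndarray
    perimeter: np.ndarray
    circularity: np.ndarray
    center: np.ndarray  # (count, 2) (row, col)
    boundary_pixels: np.ndarray = field(default_factory=lambda: np.empty(0))
    labels: np.ndarray | None = None


def astar_filter(image: np.ndarray, params: ExpertParams = ExpertParams()
                 ) -> MaskedTile:
    """Exclude strongly-red pixels by the a* channel of CIELAB (D65).

    Pixels with a* beyond ``params.delta`` (strictly greater by default) are
    marked excluded; all others are untouched.  Raising delta can only grow
    the retained set.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("astar_filter expects an HxWx3 RGB image")
    lab = skcolor.rgb2lab(image)
    a = lab[..., 1]
    excluded = a > params.delta if params.strict else a >= params.delta
    return MaskedTile(image=image, included=~excluded)


def otsu_foreground(masked: MaskedTile) -> tuple[np.ndarray, int, int]:
    """Split included pixels into stain-dense foreground and background.

    The Otsu threshold maximizes between-class intensity variance over the
    included pixels; darker pixels (stain-dense) are foreground — rendered
    blue in the reference visualization, background red.  Returns
    ``(binary foreground map, blue_count, red_count)`` with
    blue + red = included pixel count.  A constant (degenerate) image yields
    an all-background result with a warning.
    """
    gray = skcolor.rgb2gray(masked.image)
    vals = gray[masked.included]
    binary = np.zeros(gray.shape, dtype=bool)
    if vals.size == 0:
        return binary, 0, 0
    if np.all(vals == vals.flat[0]):
        warnings.warn("constant image: Otsu threshold undefined; "
                      "treating all pixels as background")
        return binary, 0, int(vals.size)
    t = threshold_otsu(vals)
    binary = (gray < t) & masked.included
    blue = int(binary.sum())
    red = int(masked.included.sum()) - blue
    return binary, blue, red


def flood_fill_clusters(binary: np.ndarray) -> ClusterStats:
    """Connected components of the foreground under 8-connectivity.

    Equivalent to repeated flood fill from unvisited foreground pixels.
    Shape statistics per cluster: area (pixel count), perimeter (geometric
    estimate), circularity 4*pi*A/P^2, centroid.
    """
    labels, n = ndi.label(binary, structure=_STRUCT8)
    if n == 0:
        z = np.empty(0)
        return ClusterStats(0, z, z.copy(), z.copy(), np.empty((0, 2)),
                            z.copy(), labels)
    props = regionprops(labels)
    area = np.array([p.area for p in props], dtype=float)
    perim = np.array([p.perimeter for p in props], dtype=float)
    center = np.array([p.centroid for p in props], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        circ = np.where(perim > 0, 4 * np.pi * area / perim ** 2, 0.0)
    # raw boundary-pixel count (>=1 background 4-neighbor), for reference
    eroded = ndi.binary_erosion(binary, structure=ndi.generate_binary_structure(2, 1))
    bpix = np.bincount(labels[binary & ~eroded], minlength=n + 1)[1:].astype(float)
    return ClusterStats(int(n), area, perim, circ, center, bpix, labels)


def window_density(clusters: ClusterStats, image_shape: tuple[int, int],
                   params: ExpertParams = ExpertParams()) -> float:
    """Average cluster-centroid count over the non-overlapping window grid.

    The image is partitioned into ``window`` x ``window`` cells (edge cells may
    be partial); the per-cell centroid counts are averaged.
    """
    w = params.window
    if w > min(image_shape):
        raise ValueError("window exceeds image edge")
    nrow = -(-image_shape[0] // w)
    ncol = -(-image_shape[1] // w)
    if clusters.count == 0:
        return 0.0
    ri = np.minimum((clusters.center[:, 0] // w).astype(int), nrow - 1)
    ci = np.minimum((clusters.center[:, 1] // w).astype(int), ncol - 1)
    counts = np.zeros((nrow, ncol))
    np.add.at(counts, (ri, ci), 1)
    return float(counts.mean())


def expert_vector(tile_or_image, params: ExpertParams = ExpertParams()
                  ) -> dict[str, float]:
    """The eight expert-guided features of a tile, in documented order.

    Accepts a TileRecord or a raw HxWx3 uint8 array.  Empty-set statistics
    (mean area / circularity with zero clusters) are 0 so feature matrices
    stay finite; percentages are of counted (= included) pixels and sum
    to 100 whenever any pixel is included.
    """
    image = getattr(tile_or_image, "image", tile_or_image)
    masked = astar_filter(image, params)
    binary, blue, red = otsu_foreground(masked)
    clusters = flood_fill_clusters(binary)
    counted = blue + red
    blue_pct = 100.0 * blue / counted if counted else 0.0
    red_pct = 100.0 * red / counted if counted else 0.0
    return {
        "total_clusters": float(clusters.count),
        "average_clusters": window_density(clusters, image.shape[:2], params),
        "red_count": float(red),
        "red_percentage": red_pct,
        "blue_count": float(blue),
        "blue_percentage": blue_pct,
        "mean_area": float(clusters.area.mean()) if clusters.count else 0.0,
        "mean_circularity": float(clusters.circularity.mean()) if clusters.count else 0.0,
    }
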