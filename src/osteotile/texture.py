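"""Native texture-feature bank: 53 named statistics per tile.

The bank emulates a CellProfiler-style measurement pipeline without depending
on it: H&E color deconvolution (Beer-Lambert optical density projected onto
the Ruifrok-Johnston stain basis), the 13 classical Haralick co-occurrence
statistics in three image contexts, a Gabor striped-texture score, Otsu
binarization with primary/secondary object detection, and neighbor ("clump")
counting.

Feature catalog (the module contract; exactly 53 entries, fixed order):

====================  ==========================================================
block                 features
====================  ==========================================================
haralick_h1_*   (13)  Haralick on the hematoxylin channel, full resolution
haralick_h2_*   (13)  Haralick on the hematoxylin channel, 2x downsampled
haralick_fg_*   (13)  Haralick restricted to the Otsu stain-dense foreground
gabor            (1)  mean Gabor filter magnitude (striped texture)
object stats     (6)  primary_count, primary_mean_area, primary_mean_diameter,
                      foreground_fraction, weighted_variance, sum_of_entropies
neighbor stats   (7)  neighbor_mean, neighbor_max, neighbor_median,
                      pct_touching, n_clumps, largest_clump, mean_clump_size
====================  ==========================================================

The 13 Haralick names (suffixes): asm, contrast, correlation, variance, idm,
sum_average, sum_variance, sum_entropy, entropy, difference_variance,
difference_entropy, imc1, imc2.  Entropies use base-2 logarithms.

This catalog is disjoint from the expert-guided features: no red/blue pixel
counts, flood-fill cluster counts or cluster shape statistics appear here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.signal import fftconvolve
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from skimage.filters import gabor_kernel, threshold_otsu

# Ruifrok & Johnston optical-density stain vectors for hematoxylin and eosin.
RUIFROK_HE = np.array([
    [0.650, 0.704, 0.286],   # hematoxylin
    [0.072, 0.990, 0.105],   # eosin
])

HARALICK_NAMES = (
    "asm", "contrast", "correlation", "variance", "idm",
    "sum_average", "sum_variance", "sum_entropy", "entropy",
    "difference_variance", "difference_entropy", "imc1", "imc2",
)

TEXTURE_FEATURE_NAMES = (
    tuple(f"haralick_h1_{n}" for n in HARALICK_NAMES)
    + tuple(f"haralick_h2_{n}" for n in HARALICK_NAMES)
    + tuple(f"haralick_fg_{n}" for n in HARALICK_NAMES)
    + ("gabor",)
    + ("primary_count", "primary_mean_area", "primary_mean_diameter",
       "foreground_fraction", "weighted_variance", "sum_of_entropies")
    + ("neighbor_mean", "neighbor_max", "neighbor_median", "pct_touching",
       "n_clumps", "largest_clump", "mean_clump_size")
)
assert len(TEXTURE_FEATURE_NAMES) == 53


@dataclass
class StainPair:
    """Hematoxylin / eosin optical-density images (same dims as the input)."""

    hematoxylin: np.ndarray
    eosin: np.ndarray


@dataclass(frozen=True)
class GlcmSpec:
    """Gray-level co-occurrence setup: 8 levels, the four distance-1 offsets
    (0, 45, 90, 135 degrees), symmetric and normalized by default."""

    levels: int = 8
    offsets: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")


@dataclass(frozen=True)
class TextureConfig:
    glcm: GlcmSpec = field(default_factory=GlcmSpec)
    gabor_frequency: float = 0.08
    gabor_orientations: int = 4
    d_min: float = 30.0
    d_max: float = 120.0
    neighbor_distance: float = 5.0
    stain_vectors: np.ndarray = field(default_factory=lambda: RUIFROK_HE)


@dataclass
class ObjectSet:
    """Integer-labeled objects plus a per-object measurement table.

    ``labels`` holds 0 for background and 1..n for objects (contiguous);
    ``table`` has columns label, area, centroid_r, centroid_c, eq_diameter,
    where equivalent diameter = 2*sqrt(area/pi).
    """

    labels: np.ndarray
    table: pd.DataFrame

    @property
    def count(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# Stain deconvolution

def stains_to_rgb(concentrations: np.ndarray,
                  stain_vectors: np.ndarray = RUIFROK_HE) -> np.ndarray:
    """Forward Beer-Lambert model: per-pixel stain concentrations -> 8-bit RGB.

    Used to build synthetic mixtures with known ground truth.
    ``concentrations`` has shape (..., n_stains).
    """
    M = np.asarray(stain_vectors, dtype=float)
    M = M / np.linalg.norm(M, axis=1, keepdims=True)
    od = concentrations @ M
    rgb = 255.0 * np.power(10.0, -od)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def unmix_he(image: np.ndarray,
             stain_vectors: np.ndarray = RUIFROK_HE) -> StainPair:
    """Separate an RGB tile into hematoxylin and eosin optical densities.

    OD = -log10(I/255) per channel is projected (least squares) onto the
    two-stain basis; negative concentrations are clipped to 0.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("unmix_he expects an HxWx3 RGB image")
    M = np.asarray(stain_vectors, dtype=float)
    M = M / np.linalg.norm(M, axis=1, keepdims=True)
    if np.linalg.matrix_rank(M) < M.shape[0]:
        raise ValueError("stain basis is singular")
    od = -np.log10(np.maximum(image.astype(float), 1.0) / 255.0)
    conc = od @ np.linalg.pinv(M)
    conc = np.clip(conc, 0.0, None)
    return StainPair(hematoxylin=conc[..., 0], eosin=conc[..., 1])


# ---------------------------------------------------------------------------
# GLCM / Haralick

def quantize(gray: np.ndarray, levels: int = 8) -> np.ndarray:
    """Equal-width quantization of a grayscale image to ``levels`` bins."""
    g = np.asarray(gray, dtype=float)
    lo, hi = g.min(), g.max()
    if hi == lo:
        return np.zeros(g.shape, dtype=np.intp)
    q = ((g - lo) / (hi - lo) * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


def glcm(quantized: np.ndarray, offset: tuple[int, int], levels: int,
         symmetric: bool = True, normalized: bool = True,
         mask: np.ndarray | None = None) -> np.ndarray:
    """Co-occurrence matrix for one (dr, dc) displacement.

    With a mask, only pixel pairs whose both members are inside the mask are
    counted (the foreground-restricted context).
    """
    dr, dc = offset
    h, w = quantized.shape
    rs = slice(max(0, -dr), h - max(0, dr))
    cs = slice(max(0, -dc), w - max(0, dc))
    rd = slice(max(0, -dr) + dr, h - max(0, dr) + dr)
    cd = slice(max(0, -dc) + dc, w - max(0, dc) + dc)
    i = quantized[rs, cs].ravel()
    j = quantized[rd, cd].ravel()
    if mask is not None:
        keep = (mask[rs, cs] & mask[rd, cd]).ravel()
        i, j = i[keep], j[keep]
    counts = np.bincount(i * levels + j, minlength=levels * levels)
    P = counts.reshape(levels, levels).astype(float)
    if symmetric:
        P = P + P.T
    if normalized:
        s = P.sum()
        if s > 0:
            P = P / s
    return P


def haralick_from_glcm(P: np.ndarray) -> dict[str, float]:
    """The 13 classical Haralick statistics of a normalized GLCM (base-2 logs).

    For a degenerate (single-entry) matrix the correlation-type statistics
    (correlation, imc1, imc2) are undefined and reported as 0 with a warning.
    """
    L = P.shape[0]
    idx = np.arange(L, dtype=float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mx = (idx * px).sum()
    my = (idx * py).sum()
    sx = np.sqrt(((idx - mx) ** 2 * px).sum())
    sy = np.sqrt(((idx - my) ** 2 * py).sum())
    ii, jj = np.meshgrid(idx, idx, indexing="ij")

    def ent(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    # p_{x+y}(k), k = 0..2L-2 and p_{x-y}(k), k = 0..L-1
    ks = (ii + jj).astype(int)
    kd = np.abs(ii - jj).astype(int)
    pxy_sum = np.bincount(ks.ravel(), weights=P.ravel(), minlength=2 * L - 1)
    pxy_diff = np.bincount(kd.ravel(), weights=P.ravel(), minlength=L)
    k_sum = np.arange(2 * L - 1, dtype=float)
    k_diff = np.arange(L, dtype=float)

    out: dict[str, float] = {}
    out["asm"] = float((P ** 2).sum())
    out["contrast"] = float((((ii - jj) ** 2) * P).sum())
    degenerate = sx == 0 or sy == 0
    if degenerate:
        warnings.warn("constant image: correlation-type Haralick features "
                      "undefined, reported as 0")
        out["correlation"] = 0.0
    else:
        out["correlation"] = float(((ii * jj * P).sum() - mx * my) / (sx * sy))
    out["variance"] = float((((ii - mx) ** 2) * P).sum())
    out["idm"] = float((P / (1.0 + (ii - jj) ** 2)).sum())
    f6 = float((k_sum * pxy_sum).sum())
    out["sum_average"] = f6
    out["sum_variance"] = float((((k_sum - f6) ** 2) * pxy_sum).sum())
    out["sum_entropy"] = ent(pxy_sum)
    out["entropy"] = ent(P.ravel())
    mu_d = float((k_diff * pxy_diff).sum())
    out["difference_variance"] = float((((k_diff - mu_d) ** 2) * pxy_diff).sum())
    out["difference_entropy"] = ent(pxy_diff)
    hxy = out["entropy"]
    hx, hy = ent(px), ent(py)
    pq = np.outer(px, py)
    nz = (P > 0) & (pq > 0)
    hxy1 = float(-(P[nz] * np.log2(pq[nz])).sum())
    nzq = pq > 0
    hxy2 = float(-(pq[nzq] * np.log2(pq[nzq])).sum())
    if degenerate or max(hx, hy) == 0:
        out["imc1"] = 0.0
        out["imc2"] = 0.0
    else:
        out["imc1"] = (hxy - hxy1) / max(hx, hy)
        out["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    return out


def haralick13(quantized: np.ndarray, spec: GlcmSpec = GlcmSpec(),
               mask: np.ndarray | None = None) -> dict[str, float]:
    """13 Haralick statistics averaged over the configured offsets."""
    per_offset = []
    for off in spec.offsets:
        P = glcm(quantized, off, spec.levels, spec.symmetric, spec.normalized,
                 mask=mask)
        per_offset.append(haralick_from_glcm(P))
    return {n: float(np.mean([d[n] for d in per_offset])) for n in HARALICK_NAMES}


# ---------------------------------------------------------------------------
# Gabor

def gabor_score(gray: np.ndarray, frequency: float = 0.08,
                orientations: int = 4) -> float:
    """Mean Gabor response magnitude, averaged over evenly spaced orientations.

    The image mean is subtracted first so a constant image scores exactly 0;
    a sinusoidal grating at the filter frequency scores highest (matched
    filter).
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    g = np.asarray(gray, dtype=float)
    g = g - g.mean()
    score = 0.0
    for k in range(orientations):
        kern = gabor_kernel(frequency, theta=np.pi * k / orientations)
        re = fftconvolve(g, np.real(kern), mode="same")
        im = fftconvolve(g, np.imag(kern), mode="same")
        score += float(np.hypot(re, im).mean())
    return score / orientations


# ---------------------------------------------------------------------------
# Objects and neighbors

_STRUCT8 = np.ones((3, 3), dtype=bool)


def _object_table(labels: np.ndarray, n: int) -> pd.DataFrame:
    area = np.bincount(labels.ravel(), minlength=n + 1)[1:].astype(float)
    if n:
        centers = ndi.center_of_mass(np.ones_like(labels, dtype=float), labels,
                                     index=np.arange(1, n + 1))
        centers = np.asarray(centers, dtype=float)
    else:
        centers = np.empty((0, 2))
    return pd.DataFrame({
        "label": np.arange(1, n + 1),
        "area": area,
        "centroid_r": centers[:, 0] if n else [],
        "centroid_c": centers[:, 1] if n else [],
        "eq_diameter": 2.0 * np.sqrt(area / np.pi),
    })


def primary_objects(binary: np.ndarray, d_min: float = 30.0,
                    d_max: float = 120.0) -> ObjectSet:
    """Connected stain-dense components with equivalent diameter in
    [d_min, d_max]; smaller and larger components are discarded.

    Equivalent diameter = 2*sqrt(area/pi).  Labels are relabeled contiguously.
    """
    labels, n = ndi.label(binary, structure=_STRUCT8)
    tab = _object_table(labels, n)
    keep = tab[(tab.eq_diameter >= d_min) & (tab.eq_diameter <= d_max)]
    mapping = np.zeros(n + 1, dtype=np.int64)
    mapping[keep.label.to_numpy()] = np.arange(1, len(keep) + 1)
    new_labels = mapping[labels]
    tab2 = keep.reset_index(drop=True).copy()
    tab2["label"] = np.arange(1, len(keep) + 1)
    return ObjectSet(labels=new_labels, table=tab2)


def secondary_objects(primary: ObjectSet, intensity: np.ndarray | None = None,
                      mask: np.ndarray | None = None) -> ObjectSet:
    """Grow one secondary region (cell/cytoplasm/stroma territory) per primary.

    Support = an Otsu mask of the intensity image (stain-positive side)
    unioned with the seeds; each support pixel is assigned to the nearest
    primary object (Euclidean), so secondary regions partition the support
    and there is exactly one secondary region per primary object.
    """
    if mask is None:
        if intensity is None:
            raise ValueError("provide an intensity image or an explicit mask")
        vals = np.asarray(intensity, dtype=float)
        if np.all(vals == vals.flat[0]):
            mask = np.ones(vals.shape, dtype=bool)
        else:
            mask = vals > threshold_otsu(vals)
    mask = mask | (primary.labels > 0)
    if primary.count == 0:
        return ObjectSet(labels=np.zeros_like(primary.labels),
                         table=_object_table(np.zeros_like(primary.labels), 0))
    _, (ir, ic) = ndi.distance_transform_edt(primary.labels == 0,
                                             return_indices=True)
    sec = primary.labels[ir, ic]
    sec = np.where(mask, sec, 0)
    return ObjectSet(labels=sec, table=_object_table(sec, primary.count))


def neighbor_counts(objects: ObjectSet, distance: float = 5.0
                    ) -> tuple[np.ndarray, dict[str, float]]:
    """Per-object count of other objects within ``distance`` pixels
    (minimum pixel-to-pixel Euclidean distance), plus summary statistics.

    Returns ``(counts, summary)`` where summary holds the mean and max count
    and the clump statistics of the resulting neighbor graph (clump =
    connected component of the "is neighbor of" relation).
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    n = objects.count
    counts = np.zeros(n, dtype=float)
    pairs: set[tuple[int, int]] = set()
    if n:
        pad = int(np.ceil(distance)) + 1
        slices = ndi.find_objects(objects.labels)
        h, w = objects.labels.shape
        for lab, sl in enumerate(slices, start=1):
            if sl is None:
                continue
            r0 = max(sl[0].start - pad, 0)
            r1 = min(sl[0].stop + pad, h)
            c0 = max(sl[1].start - pad, 0)
            c1 = min(sl[1].stop + pad, w)
            crop = objects.labels[r0:r1, c0:c1]
            d = ndi.distance_transform_edt(crop != lab)
            near = np.unique(crop[(d <= distance) & (crop != lab) & (crop > 0)])
            for other in near:
                pairs.add((min(lab, int(other)), max(lab, int(other))))
        for a, b in pairs:
            counts[a - 1] += 1
            counts[b - 1] += 1
    if n and pairs:
        rows = np.array([p[0] - 1 for p in pairs])
        cols = np.array([p[1] - 1 for p in pairs])
        adj = coo_matrix((np.ones(len(pairs)), (rows, cols)), shape=(n, n))
        n_comp, comp = connected_components(adj, directed=False)
        sizes = np.bincount(comp)
    elif n:
        n_comp, sizes = n, np.ones(n)
    else:
        n_comp, sizes = 0, np.array([0.0])
    summary = {
        "neighbor_mean": float(counts.mean()) if n else 0.0,
        "neighbor_max": float(counts.max()) if n else 0.0,
        "neighbor_median": float(np.median(counts)) if n else 0.0,
        "pct_touching": float(100.0 * (counts > 0).mean()) if n else 0.0,
        "n_clumps": float(n_comp),
        "largest_clump": float(sizes.max()) if n else 0.0,
        "mean_clump_size": float(sizes.mean()) if n else 0.0,
    }
    return counts, summary


# ---------------------------------------------------------------------------
# Full vector

def _downsample2(gray: np.ndarray) -> np.ndarray:
    h, w = gray.shape
    g = gray[: h - h % 2, : w - w % 2]
    return g.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def _otsu_stats(h: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    """Otsu split of the hematoxylin OD image; returns (foreground mask,
    foreground fraction, weighted within-class variance, sum of fore/back
    histogram entropies)."""
    vals = h.ravel()
    if np.all(vals == vals[0]):
        return np.zeros(h.shape, dtype=bool), 0.0, 0.0, 0.0
    t = threshold_otsu(h)
    fg = h > t
    w1 = fg.mean()
    w0 = 1.0 - w1
    v1 = float(h[fg].var()) if fg.any() else 0.0
    v0 = float(h[~fg].var()) if (~fg).any() else 0.0
    wvar = w0 * v0 + w1 * v1

    def hist_entropy(x):
        if x.size == 0:
            return 0.0
        c, _ = np.histogram(x, bins=64)
        p = c[c > 0] / c.sum()
        return float(-(p * np.log2(p)).sum())

    soe = hist_entropy(h[fg]) + hist_entropy(h[~fg])
    return fg, float(w1), float(wvar), soe


def texture_vector(tile_or_image, config: TextureConfig = TextureConfig()
                   ) -> dict[str, float]:
    """The 53 named texture features of a tile (see module docstring).

    All texture measurements are taken on the hematoxylin optical-density
    channel; object and neighbor statistics come from the Otsu-binarized
    stain-dense foreground of that channel.
    """
    image = getattr(tile_or_image, "image", tile_or_image)
    stains = unmix_he(image, config.stain_vectors)
    h = stains.hematoxylin
    h2 = _downsample2(h)
    fg, fg_frac, wvar, soe = _otsu_stats(h)

    out: dict[str, float] = {}
    q1 = quantize(h, config.glcm.levels)
    for k, v in haralick13(q1, config.glcm).items():
        out[f"haralick_h1_{k}"] = v
    q2 = quantize(h2, config.glcm.levels)
    for k, v in haralick13(q2, config.glcm).items():
        out[f"haralick_h2_{k}"] = v
    for k, v in haralick13(q1, config.glcm, mask=fg).items():
        out[f"haralick_fg_{k}"] = v
    out["gabor"] = gabor_score(h2, config.gabor_frequency,
                               config.gabor_orientations)

    prim = primary_objects(fg, config.d_min, config.d_max)
    out["primary_count"] = float(prim.count)
    out["primary_mean_area"] = float(prim.table.area.mean()) if prim.count else 0.0
    out["primary_mean_diameter"] = (float(prim.table.eq_diameter.mean())
                                    if prim.count else 0.0)
    out["foreground_fraction"] = fg_frac
    out["weighted_variance"] = wvar
    out["sum_of_entropies"] = soe

    _, summary = neighbor_counts(prim, config.neighbor_distance)
    out.update(summary)

    assert tuple(out) == TEXTURE_FEATURE_NAMES
    return out
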