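"""Synthetic H&E-like tiles, patches and annotation tables.

Real osteosarcoma whole-slide images are gigapixel files that cannot ship with
a software package, so this module generates a stand-in corpus with the
statistical structure the pipeline assumes: three visually separable tissue
archetypes rendered as 1024x1024 8-bit RGB tiles,

* **NT** (non-tumor): sparse pale tissue, few nuclei on a light background;
* **VT** (viable tumor): dense clusters of dark hematoxylin-stained nuclei;
* **NEC** (necrotic tumor): fragmented, desaturated low-contrast texture with
  small debris specks.

Every generator is a pure function of ``(spec, seed)``: the same inputs yield
byte-identical images.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage as ndi

#: The three admissible tissue classes, in canonical order.
CLASS_LABELS = ("NT", "NEC", "VT")

TILE_SIZE = 1024


def _check_label(label: str) -> str:
    if label not in CLASS_LABELS:
        raise ValueError(f"label must be one of {CLASS_LABELS}, got {label!r}")
    return label


@dataclass(frozen=True)
class ArchetypeSpec:
    """Appearance model for one tissue class.

    Parameters
    ----------
    label : {"NT", "NEC", "VT"}
    nuclei_density : float
        Expected number of nuclei per 1024x1024 tile (Poisson mean).
    nucleus_radius_range : (float, float)
        Min/max semi-major axis of the elliptical nuclei, pixels.
    nucleus_color, background_color : (int, int, int)
        8-bit RGB triples; the nucleus color emulates hematoxylin staining.
    fragmentation : float in [0, 1]
        Strength of the low-frequency texture break-up + desaturation applied
        to necrotic tissue (0 disables).
    noise_sd : float
        Per-channel Gaussian pixel noise, 8-bit units.
    n_clusters : int or None
        If set, nucleus centers are scattered around this many cluster
        parents (normal scatter ``cluster_sigma``) instead of uniformly —
        emulates the clumped growth pattern of viable tumor.
    """

    label: str
    nuclei_density: float
    nucleus_radius_range: tuple[float, float] = (4.0, 9.0)
    nucleus_color: tuple[int, int, int] = (64, 32, 112)
    background_color: tuple[int, int, int] = (232, 216, 230)
    fragmentation: float = 0.0
    noise_sd: float = 3.0
    n_clusters: int | None = None
    cluster_sigma: float = 30.0

    def validate(self) -> None:
        _check_label(self.label)
        if self.nuclei_density < 0:
            raise ValueError("nuclei_density must be >= 0")
        rmin, rmax = self.nucleus_radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("nucleus_radius_range must be positive and ordered")
        for c in (*self.nucleus_color, *self.background_color):
            if not 0 <= c <= 255:
                raise ValueError("colors must lie in [0, 255]")
        if not 0.0 <= self.fragmentation <= 1.0:
            raise ValueError("fragmentation must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_archetypes() -> dict[str, ArchetypeSpec]:
    """The stated world: well-separated NT / NEC / VT appearance models.

    VT-to-NT nuclei density ratio is 8 (400 vs 50), comfortably past the
    4x separability requirement; VT nuclei are clustered so that merged
    stain-dense components reach the primary-object diameter band.
    """
    return {
        "NT": ArchetypeSpec(
            label="NT",
            nuclei_density=50,
            nucleus_radius_range=(4.0, 8.0),
            nucleus_color=(128, 96, 160),
            background_color=(240, 232, 240),
            noise_sd=3.0,
        ),
        "NEC": ArchetypeSpec(
            label="NEC",
            nuclei_density=150,
            nucleus_radius_range=(3.0, 7.0),
            nucleus_color=(140, 110, 130),
            background_color=(226, 205, 198),
            fragmentation=0.6,
            noise_sd=5.0,
        ),
        "VT": ArchetypeSpec(
            label="VT",
            nuclei_density=400,
            nucleus_radius_range=(5.0, 10.0),
            nucleus_color=(56, 24, 104),
            background_color=(214, 164, 196),
            noise_sd=3.0,
            n_clusters=25,
            cluster_sigma=30.0,
        ),
    }


@dataclass
class TileRecord:
    """One annotated 1024x1024 RGB tile.

    ``tin`` is the Tile Identification Number keying the annotation CSV;
    ``origin`` is the (row, col) pixel offset in a parent synthetic slide
    (0-based); ``nuclei_truth`` lists the ground-truth ``((row, col), radius)``
    of every rendered nucleus for generator-level checks.
    """

    tin: str
    image: np.ndarray
    label: str
    origin: tuple[int, int] = (0, 0)
    nuclei_truth: list[tuple[tuple[float, float], float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.image.shape != (TILE_SIZE, TILE_SIZE, 3):
            raise ValueError(
                f"tile image must be {TILE_SIZE}x{TILE_SIZE}x3, got {self.image.shape}"
            )
        _check_label(self.label)


@dataclass
class PatchRecord:
    """A 128x128 sub-image of a tile; the CNN input unit.

    ``offset`` is the (row, col) of the patch's top-left corner in the parent
    tile, half-open extent ``[row, row+128) x [col, col+128)``.  ``euler`` is
    filled by the CNN preprocessing stage; ``keep`` by the significance filter.
    """

    parent_tin: str
    image: np.ndarray
    offset: tuple[int, int]
    label: str
    euler: int | None = None
    keep: bool = True

    def __post_init__(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("patch image must be HxWx3")
        _check_label(self.label)


def _ellipse_mask(shape, center, a, b, theta):
    """Boolean mask of a rotated ellipse (semi-axes a >= b) inside `shape`."""
    r0 = max(int(np.floor(center[0] - a - 1)), 0)
    r1 = min(int(np.ceil(center[0] + a + 2)), shape[0])
    c0 = max(int(np.floor(center[1] - a - 1)), 0)
    c1 = min(int(np.ceil(center[1] + a + 2)), shape[1])
    if r0 >= r1 or c0 >= c1:
        return None, None
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0, (slice(r0, r1), slice(c0, c1))


def _smooth_field(rng: np.random.Generator, size: int, cells: int = 8) -> np.ndarray:
    """Low-frequency random field in [0, 1] via zoomed coarse noise."""
    coarse = rng.random((cells, cells))
    f = ndi.zoom(coarse, size / cells, order=3, mode="nearest")[:size, :size]
    f = f - f.min()
    peak = f.max()
    return f / peak if peak > 0 else f


def synth_tile(spec: ArchetypeSpec, seed: int, size: int = TILE_SIZE,
               tin: str = "T000000", origin: tuple[int, int] = (0, 0)) -> TileRecord:
    """Render one synthetic tile for `spec`, deterministically in (spec, seed)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    img = np.empty((size, size, 3), dtype=np.float64)
    img[:] = np.asarray(spec.background_color, dtype=np.float64)

    # faint eosin-like background mottling so tiles are not flat fields
    mottle = _smooth_field(rng, size, cells=16) - 0.5
    img += mottle[..., None] * 10.0

    n = rng.poisson(spec.nuclei_density * (size / TILE_SIZE) ** 2)
    if spec.n_clusters:
        parents = rng.uniform(0, size, size=(spec.n_clusters, 2))
        which = rng.integers(0, spec.n_clusters, size=n)
        centers = parents[which] + rng.normal(0, spec.cluster_sigma, size=(n, 2))
        centers = np.clip(centers, 0, size - 1)
    else:
        centers = rng.uniform(0, size, size=(n, 2))

    rmin, rmax = spec.nucleus_radius_range
    radii = rng.uniform(rmin, rmax, size=n)
    ratios = rng.uniform(0.6, 1.0, size=n)
    thetas = rng.uniform(0, np.pi, size=n)
    color = np.asarray(spec.nucleus_color, dtype=np.float64)
    truth: list[tuple[tuple[float, float], float]] = []
    for i in range(n):
        mask, sl = _ellipse_mask((size, size), centers[i], radii[i],
                                 radii[i] * ratios[i], thetas[i])
        if mask is None:
            continue
        region = img[sl]
        # slight per-nucleus shade jitter
        shade = color + rng.normal(0, 6, size=3)
        region[mask] = np.clip(shade, 0, 255)
        truth.append(((float(centers[i, 0]), float(centers[i, 1])), float(radii[i])))

    if spec.fragmentation > 0:
        # multiply the stain contrast by a low-frequency break-up mask and
        # desaturate toward gray — necrosis loses crisp nuclear detail
        frag = _smooth_field(rng, size, cells=6)
        bg = np.asarray(spec.background_color, dtype=np.float64)
        atten = 1.0 - spec.fragmentation * frag[..., None]
        img = bg + (img - bg) * atten
        gray = img.mean(axis=2, keepdims=True)
        img = img + spec.fragmentation * 0.5 * (gray - img)
        # small dark debris specks
        n_debris = rng.poisson(200 * spec.fragmentation * (size / TILE_SIZE) ** 2)
        dr = rng.uniform(0, size, size=(n_debris, 2))
        for i in range(n_debris):
            mask, sl = _ellipse_mask((size, size), dr[i],
                                     rng.uniform(1, 3), rng.uniform(1, 2),
                                     rng.uniform(0, np.pi))
            if mask is not None:
                img[sl][mask] *= 0.6

    if spec.noise_sd > 0:
        img += rng.normal(0, spec.noise_sd, size=img.shape)

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return TileRecord(tin=tin, image=image, label=spec.label, origin=origin,
                      nuclei_truth=truth)


def annotation_rows(n_per_class: tuple[int, int, int]) -> pd.DataFrame:
    """Annotation table for a corpus of (nNT, nNEC, nVT) tiles.

    TINs are ``T%06d``, assigned sequentially in class order NT, NEC, VT for
    a stable lexicographic ordering.
    """
    if any(n < 0 for n in n_per_class):
        raise ValueError("n_per_class entries must be nonnegative")
    rows = []
    counter = 0
    for label, n in zip(CLASS_LABELS, n_per_class):
        for _ in range(n):
            rows.append({"tin": f"T{counter:06d}", "label": label})
            counter += 1
    return pd.DataFrame(rows, columns=["tin", "label"])


def synth_dataset(n_per_class: tuple[int, int, int],
                  specs: dict[str, ArchetypeSpec] | None = None,
                  seed: int = 0) -> tuple[list[TileRecord], pd.DataFrame]:
    """Generate a labeled corpus: ``n_per_class`` = (nNT, nNEC, nVT).

    Returns the tiles and the annotation table (columns ``tin``, ``label``),
    in 1-1 correspondence.
    """
    rows = annotation_rows(n_per_class)
    specs = specs or default_archetypes()
    ss = np.random.SeedSequence(seed)
    tiles: list[TileRecord] = []
    for label, n in zip(CLASS_LABELS, n_per_class):
        child_seeds = ss.spawn(1)[0].generate_state(max(n, 1)) >> 1  # < 2**31
        for i in range(n):
            tiles.append(synth_tile(specs[label], int(child_seeds[i])))
    for tile, row in zip(tiles, rows.itertuples()):
        tile.tin = row.tin
    return tiles, rows


def extract_patches(tile: TileRecord, size: int = 128, stride: int | None = None
                    ) -> list[PatchRecord]:
    """Cut `tile` into fully contained ``size`` x ``size`` windows on a regular
    grid with the given ``stride`` (default: non-overlapping, stride = size).

    Each patch inherits the tile's class label.  ``stride > size`` would leave
    unsampled gaps and is rejected.
    """
    stride = size if stride is None else stride
    h, w = tile.image.shape[:2]
    if not 0 < size <= min(h, w):
        raise ValueError(f"size must be in (0, {min(h, w)}]")
    if not 0 < stride <= size:
        raise ValueError("stride must be in (0, size]; larger strides leave gaps")
    patches = []
    for r in range(0, h - size + 1, stride):
        for c in range(0, w - size + 1, stride):
            patches.append(PatchRecord(
                parent_tin=tile.tin,
                image=tile.image[r:r + size, c:c + size].copy(),
                offset=(r, c),
                label=tile.label,
            ))
    return patches


def patch_grid_count(edge: int, size: int, stride: int) -> int:
    """Closed-form patch count per axis-pair: ((edge - size)//stride + 1)**2."""
    return ((edge - size) // stride + 1) ** 2


def synth_slide(label_grid: list[list[str]],
                specs: dict[str, ArchetypeSpec] | None = None,
                seed: int = 0) -> tuple[np.ndarray, list[TileRecord]]:
    """Assemble a slide-scale image from a grid of archetype tiles.

    ``label_grid`` is a nested list of class labels (row-major).  Returns the
    stitched RGB image and the constituent TileRecords (with grid origins),
    which carry the construction truth for round-trip map tests.
    """
    specs = specs or default_archetypes()
    nrow, ncol = len(label_grid), len(label_grid[0])
    slide = np.empty((nrow * TILE_SIZE, ncol * TILE_SIZE, 3), dtype=np.uint8)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(nrow * ncol) >> 1
    tiles = []
    k = 0
    for i, row in enumerate(label_grid):
        for j, label in enumerate(row):
            t = synth_tile(specs[label], int(seeds[k]), tin=f"S{k:06d}",
                           origin=(i * TILE_SIZE, j * TILE_SIZE))
            slide[i * TILE_SIZE:(i + 1) * TILE_SIZE,
                  j * TILE_SIZE:(j + 1) * TILE_SIZE] = t.image
            tiles.append(t)
            k += 1
    return slide, tiles


# ---------------------------------------------------------------------------
# I/O

def write_annotations(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, index=False, columns=["tin", "label"])


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tin": str, "label": str})
    bad = set(df["label"]) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"unknown class labels in annotation CSV: {sorted(bad)}")
    return df[["tin", "label"]]


def write_tile_png(tile: TileRecord, path: str | Path) -> None:
    Image.fromarray(tile.image).save(str(path), format="PNG")


def read_tile_png(path: str | Path, tin: str | None = None,
                  label: str = "NT") -> TileRecord:
    arr = np.asarray(Image.open(str(path)).convert("RGB"))
    return TileRecord(tin=tin or Path(path).stem, image=arr, label=label)


def tile_png_bytes(tile: TileRecord) -> bytes:
    buf = io.BytesIO()
    Image.fromarray(tile.image).save(buf, format="PNG")
    return buf.getvalue()
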