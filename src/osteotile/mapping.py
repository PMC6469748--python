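"""Whole-slide assessment: tile grid, per-tile classification, tumor map,
percent necrosis.

A slide-scale RGB image is cut into a non-overlapping grid of 1024x1024
tiles (partial edge tiles are dropped — the featurizers assume full tiles),
each tile is classified by a trained model, and the label grid is rendered
as an eye-fit color map: viable tumor red, necrotic tumor green, non-tumor
blue.  Near-blank tiles (tissue fraction below threshold) are flagged absent
and left uncolored.  Percent necrosis — the clinical endpoint — is the
necrotic fraction of tumor tiles:

    necrosis_pct = 100 * |NEC| / (|NEC| + |VT|)

NT and absent cells are excluded from the denominator, matching the
pathology convention that necrosis is fractionated over tumor, not tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import CLASS_LABELS, TILE_SIZE, TileRecord

#: Legend colors (pre-blend): VT red, NEC green, NT blue; absent black.
LEGEND = {"VT": (255, 0, 0), "NEC": (0, 255, 0), "NT": (0, 0, 255)}


@dataclass
class LabelGrid:
    """2-D grid of per-tile class labels; None marks a non-tissue cell."""

    labels: list[list[str | None]]
    tile_size: int
    slide_shape: tuple[int, int]

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.labels), len(self.labels[0])

    def counts(self) -> dict[str, int]:
        flat = [v for row in self.labels for v in row]
        out = {c: flat.count(c) for c in CLASS_LABELS}
        out["absent"] = flat.count(None)
        return out


@dataclass
class TumorMap:
    """Rendered tumor-prediction map (and optional overlay) plus the
    necrosis percentage (None when the grid holds no tumor cells)."""

    image: np.ndarray
    overlay: np.ndarray | None
    necrosis_pct: float | None


def grid_tiles(slide: np.ndarray, tile: int = TILE_SIZE
               ) -> tuple[list[TileRecord], tuple[int, int]]:
    """Cut a slide into a row-major non-overlapping tile grid.

    Partial edge tiles are dropped.  Returns the tiles (TINs ``G<row>_<col>``,
    origins set) and the grid shape.
    """
    h, w = slide.shape[:2]
    if h < tile or w < tile:
        raise ValueError("slide is smaller than one tile")
    nrow, ncol = h // tile, w // tile
    tiles = []
    for i in range(nrow):
        for j in range(ncol):
            img = slide[i * tile:(i + 1) * tile, j * tile:(j + 1) * tile]
            tiles.append(TileRecord(tin=f"G{i}_{j}", image=np.ascontiguousarray(img),
                                    label="NT", origin=(i * tile, j * tile)))
    return tiles, (nrow, ncol)


def tissue_fraction(image: np.ndarray, white_level: int = 235) -> float:
    """Fraction of pixels darker than the near-white background level."""
    gray = image.mean(axis=2) if image.ndim == 3 else image
    return float((gray < white_level).mean())


def classify_grid(tiles: list[TileRecord], grid_shape: tuple[int, int],
                  predict_tile, tile_size: int = TILE_SIZE,
                  min_tissue: float = 0.02) -> LabelGrid:
    """Label every grid cell with ``predict_tile(image) -> label``.

    Cells whose tissue fraction falls below ``min_tissue`` are flagged absent
    without invoking the model.
    """
    nrow, ncol = grid_shape
    labels: list[list[str | None]] = [[None] * ncol for _ in range(nrow)]
    for t in tiles:
        i, j = t.origin[0] // tile_size, t.origin[1] // tile_size
        if tissue_fraction(t.image) < min_tissue:
            labels[i][j] = None
        else:
            lab = predict_tile(t.image)
            if lab not in CLASS_LABELS:
                raise ValueError(f"model returned unknown label {lab!r}")
            labels[i][j] = lab
    return LabelGrid(labels=labels, tile_size=tile_size,
                     slide_shape=(nrow * tile_size, ncol * tile_size))


def necrosis_pct(grid: LabelGrid) -> float | None:
    """100 * NEC / (NEC + VT) over the grid; None if no tumor cells."""
    c = grid.counts()
    tumor = c["NEC"] + c["VT"]
    if tumor == 0:
        return None
    return 100.0 * c["NEC"] / tumor


def render_map(grid: LabelGrid, slide: np.ndarray | None = None,
               alpha: float = 0.5, max_edge: int = 2048) -> TumorMap:
    """Render the label grid as solid color blocks at eye-fit scale.

    Colors are the exact legend values pre-blend; the optional overlay
    alpha-blends the map onto the nearest-neighbor-downscaled slide (so
    legend colors survive the downscale exactly in the pure map).
    """
    nrow, ncol = grid.shape
    ts = grid.tile_size
    scale = max(1, int(np.ceil(max(nrow, ncol) * ts / max_edge)))
    block = max(ts // scale, 1)
    img = np.zeros((nrow * block, ncol * block, 3), dtype=np.uint8)
    for i in range(nrow):
        for j in range(ncol):
            lab = grid.labels[i][j]
            color = LEGEND.get(lab, (0, 0, 0))
            img[i * block:(i + 1) * block, j * block:(j + 1) * block] = color
    overlay = None
    if slide is not None:
        down = slide[::scale, ::scale][: nrow * block, : ncol * block]
        if down.shape[:2] != img.shape[:2]:
            pad = np.zeros_like(img)
            pad[: down.shape[0], : down.shape[1]] = down[..., :3]
            down = pad
        overlay = np.clip(np.rint((1 - alpha) * down.astype(float)
                                  + alpha * img.astype(float)), 0, 255).astype(np.uint8)
    return TumorMap(image=img, overlay=overlay, necrosis_pct=necrosis_pct(grid))


def feature_tile_classifier(model, expert_params=None, texture_config=None):
    """Bridge a trained classical model to ``predict_tile``: extracts the
    61 combined features of a tile image and predicts its label."""
    from .expert import ExpertParams, expert_vector
    from .ml import COMBINED_FEATURE_NAMES, predict
    from .texture import TextureConfig, texture_vector
    expert_params = expert_params or ExpertParams()
    texture_config = texture_config or TextureConfig()

    def predict_tile(image: np.ndarray) -> str:
        feats = expert_vector(image, expert_params)
        feats.update(texture_vector(image, texture_config))
        x = np.array([[feats[n] for n in COMBINED_FEATURE_NAMES]])
        return str(predict(model, x)[0])

    return predict_tile
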