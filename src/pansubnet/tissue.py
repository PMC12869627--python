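"""Dual-scale spatial structure of a slide: patch grid and cell-to-patch mapping.

Slides are scanned at x40 ("base frame"); patches are defined at x20, so one
256 px patch covers 256 * patch_mag_factor base pixels.  All coordinates are
kept in the base frame: 0-based pixels, origin top-left, half-open tile
intervals [c*T, (c+1)*T) so boundary centroids belong to exactly one tile.
Partial edge tiles are dropped, and cells whose centroids fall in the dropped
remainder are discarded (counted, logged) rather than re-assigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

CELL_TYPES = ("neoplastic", "inflammatory", "connective", "dead", "epithelial")


@dataclass(frozen=True)
class SlideGeometry:
    """Slide extent in the base (level-0, x40) frame."""

    width_px: int
    height_px: int
    mpp: float | None = None
    patch_mag_factor: int = 2

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        if self.patch_mag_factor < 1:
            raise ValueError("patch_mag_factor must be >= 1")


@dataclass
class CellRecord:
    cell_id: str
    centroid_x: float
    centroid_y: float
    embedding: np.ndarray
    cell_type: str = "neoplastic"

    def __post_init__(self) -> None:
        self.embedding = np.asarray(self.embedding, dtype=float)
        if not np.all(np.isfinite(self.embedding)):
            raise ValueError(f"cell {self.cell_id!r} has a non-finite embedding")
        if not (np.isfinite(self.centroid_x) and np.isfinite(self.centroid_y)):
            raise ValueError(f"cell {self.cell_id!r} has a non-finite centroid")


@dataclass
class PatchRecord:
    grid_col: int
    grid_row: int
    origin_x: int
    origin_y: int
    embedding: np.ndarray | None = None
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.embedding is not None:
            self.embedding = np.asarray(self.embedding, dtype=float)
            if not np.all(np.isfinite(self.embedding)):
                raise ValueError(
                    f"patch ({self.grid_col},{self.grid_row}) has a non-finite embedding"
                )


@dataclass
class SlideBag:
    """One slide's bag of patch instances plus the cells assigned to them."""

    slide_id: str
    geometry: SlideGeometry
    patches: list[PatchRecord]
    cells: list[CellRecord]
    label: str | None = None
    n_discarded_cells: int = 0

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in ("basal_like", "classical"):
            raise ValueError(f"unknown slide label {self.label!r}")
        grids = [(p.grid_col, p.grid_row) for p in self.patches]
        if len(set(grids)) != len(grids):
            raise ValueError("duplicate patch grid indices")
        assigned = [cid for p in self.patches for cid in p.cell_ids]
        if len(set(assigned)) != len(assigned):
            raise ValueError("a cell is referenced by more than one patch")
        known = {c.cell_id for c in self.cells}
        unknown = set(assigned) - known
        if unknown:
            raise ValueError(f"patches reference unknown cells: {sorted(unknown)[:5]}")

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(n_cols, n_rows) of the tile grid."""
        if not self.patches:
            return (0, 0)
        return (
            max(p.grid_col for p in self.patches) + 1,
            max(p.grid_row for p in self.patches) + 1,
        )

    def cells_of(self, patch: PatchRecord) -> list[CellRecord]:
        by_id = {c.cell_id: c for c in self.cells}
        return [by_id[cid] for cid in patch.cell_ids]


def tile_extent_base_px(geometry: SlideGeometry, tile_size_patch_px: int = 256) -> int:
    """Tile side length in base-frame pixels."""
    return tile_size_patch_px * geometry.patch_mag_factor


def tile_grid(geometry: SlideGeometry, tile_size_patch_px: int = 256) -> list[PatchRecord]:
    """Non-overlapping tile skeletons covering the slide; partial edge tiles dropped."""
    if tile_size_patch_px <= 0:
        raise ValueError("tile size must be positive")
    T = tile_extent_base_px(geometry, tile_size_patch_px)
    n_cols, n_rows = geometry.width_px // T, geometry.height_px // T
    if n_cols == 0 or n_rows == 0:
        logger.warning("slide (%d x %d) smaller than one %d px tile; empty grid",
                       geometry.width_px, geometry.height_px, T)
        return []
    return [
        PatchRecord(grid_col=c, grid_row=r, origin_x=c * T, origin_y=r * T)
        for r in range(n_rows)
        for c in range(n_cols)
    ]


def map_cells_to_patches(
    cells: Sequence[CellRecord],
    patches: Sequence[PatchRecord],
    geometry: SlideGeometry,
    tile_size_patch_px: int = 256,
    slide_id: str = "slide",
    label: str | None = None,
) -> SlideBag:
    """Assign each cell to the tile containing its centroid and assemble the bag.

    Cells in the dropped edge remainder are discarded with a logged count; a
    centroid outside the slide bounds is an error.
    """
    T = tile_extent_base_px(geometry, tile_size_patch_px)
    by_grid = {(p.grid_col, p.grid_row): p for p in patches}
    for p in by_grid.values():
        p.cell_ids = []
    kept: list[CellRecord] = []
    discarded = 0
    for cell in cells:
        x, y = cell.centroid_x, cell.centroid_y
        if not (0 <= x < geometry.width_px and 0 <= y < geometry.height_px):
            raise ValueError(
                f"cell {cell.cell_id!r} centroid ({x}, {y}) outside slide bounds"
            )
        key = (int(x // T), int(y // T))
        patch = by_grid.get(key)
        if patch is None:
            discarded += 1
            continue
        patch.cell_ids.append(cell.cell_id)
        kept.append(cell)
    if discarded:
        logger.info("discarded %d cells in dropped edge remainders", discarded)
    return SlideBag(
        slide_id=slide_id,
        geometry=geometry,
        patches=list(patches),
        cells=kept,
        label=label,
        n_discarded_cells=discarded,
    )
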