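"""Attention-mask rendering.

Per-patch MIL attention weights are min-max scaled to 8-bit grayscale
(0 = black = lowest attention, 255 = white = highest) on the tile grid, one
square block per patch, and optionally alpha-blended over a slide thumbnail.
"""

from __future__ import annotations

import numpy as np
from PIL import Image


def attention_to_grid(attention: np.ndarray, grid_coords: np.ndarray,
                      grid_shape: tuple[int, int]) -> np.ndarray:
    """Scatter per-patch weights onto an (n_rows, n_cols) array (NaN = no patch)."""
    attention = np.asarray(attention, dtype=float)
    grid_coords = np.asarray(grid_coords, dtype=int).reshape(-1, 2)
    if attention.shape[0] != grid_coords.shape[0]:
        raise ValueError("one attention weight per patch required")
    n_cols, n_rows = grid_shape
    if grid_coords.size and (grid_coords[:, 0].max() >= n_cols
                             or grid_coords[:, 1].max() >= n_rows):
        raise ValueError("grid coordinates exceed the stated grid shape")
    grid = np.full((n_rows, n_cols), np.nan)
    grid[grid_coords[:, 1], grid_coords[:, 0]] = attention
    return grid


def render_attention_mask(
    attention: np.ndarray,
    grid_coords: np.ndarray,
    grid_shape: tuple[int, int],
    block_px: int = 16,
) -> Image.Image:
    """Min-max scale weights to [0, 255] and paint one block per patch.

    Constant (or single-patch) weights map to 0 by convention; grid positions
    without a patch render as 0.
    """
    if np.any(np.asarray(attention) < 0):
        raise ValueError("attention weights must be non-negative")
    grid = attention_to_grid(attention, grid_coords, grid_shape)
    vals = grid[~np.isnan(grid)]
    lo, hi = (vals.min(), vals.max()) if vals.size else (0.0, 0.0)
    scaled = np.zeros_like(grid)
    if hi > lo:
        scaled = (grid - lo) / (hi - lo) * 255.0
    scaled = np.nan_to_num(scaled, nan=0.0)
    mask = np.kron(scaled, np.ones((block_px, block_px)))
    return Image.fromarray(np.clip(np.round(mask), 0, 255).astype(np.uint8), mode="L")


def overlay_attention(mask: Image.Image, thumbnail: Image.Image,
                      alpha: float = 0.5) -> Image.Image:
    """Blend the grayscale mask over a thumbnail at the given alpha."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    base = thumbnail.convert("RGB").resize(mask.size)
    return Image.blend(base, mask.convert("RGB"), alpha)
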