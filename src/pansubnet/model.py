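"""The dual-scale subtype network.

Per patch, variable-length cell embeddings are aggregated by self-attention
with a learnable CLS token; the pairwise physical distance between cell
centroids, scaled by ``distance_scale`` (gamma), is subtracted from the raw
attention logits so nearby cells attend to each other more strongly.  The CLS
output is fused with the patch embedding by an outer product, flattened, and
projected to ``fused_dim`` (default 768).  The bag of fused patch vectors is
pooled with gated attention MIL (optionally with a fixed sinusoidal encoding
of the patch grid coordinates, the "2D" variant) and a linear head yields the
slide logit; sigmoid(logit) is the probability of the basal-like subtype.

Implemented on a small reverse-mode autodiff tape (`pansubnet._autodiff`);
gradients are verified against finite differences in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, sigmoid, stack_outer
from .tissue import SlideBag

POSITIVE_CLASS = "basal_like"  # y = 1
NEGATIVE_CLASS = "classical"


@dataclass
class PanSubNetConfig:
    """Architecture and training hyperparameters.

    ``distance_scale`` (gamma) divides pixel (or micron, when the slide
    carries an mpp) distances before they are subtracted from attention
    logits; the default is the patch extent in the base frame so biases are
    O(1).  ``mil_variant`` is ``"gated"`` (pure gated attention) or
    ``"gated2d"`` (adds the sinusoidal grid encoding).
    """

    D_p: int = 64
    D_c: int = 32
    attn_dim: int = 32
    n_heads: int = 1
    fused_dim: int = 768
    mil_hidden: int = 64
    mil_variant: str = "gated2d"
    distance_scale: float | None = None  # None -> patch extent in base px (or microns)
    tile_size_patch_px: int = 256
    lr: float = 5e-5
    weight_decay: float = 1e-5
    max_epochs: int = 100
    patience: int = 10
    n_folds: int = 5
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("D_p", "D_c", "attn_dim", "n_heads", "fused_dim", "mil_hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.attn_dim % self.n_heads:
            raise ValueError("attn_dim must be divisible by n_heads")
        if self.lr <= 0 or self.weight_decay <= 0:
            raise ValueError("lr and weight_decay must be positive")
        if self.mil_variant not in ("gated", "gated2d"):
            raise ValueError(f"unknown mil_variant {self.mil_variant!r}")


@dataclass
class PredictionResult:
    slide_id: str
    p: float
    predicted_label: str
    margin: float
    confidence_flag: str
    patch_attention: np.ndarray

    @classmethod
    def from_probability(cls, slide_id: str, p: float, attention: np.ndarray,
                         lo: float = 0.10, hi: float = 0.90) -> "PredictionResult":
        # tie at p = 0.5 goes to classical, deterministically
        label = POSITIVE_CLASS if p > 0.5 else NEGATIVE_CLASS
        flag = "high" if (p <= lo or p >= hi) else "low"
        return cls(slide_id, float(p), label, abs(p - 0.5), flag, attention)


def init_params(config: PanSubNetConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    """Fixed-seed uniform initialization, scaled by 1/sqrt(fan_in) per array."""

    def uniform(*shape: int) -> Tensor:
        fan_in = shape[-1] if len(shape) > 1 else shape[0]
        a = 1.0 / math.sqrt(fan_in)
        return Tensor(rng.uniform(-a, a, size=shape), requires_grad=True)

    c = config
    params = {
        "cls_token": uniform(1, c.D_c),
        "W_q": uniform(c.attn_dim, c.D_c),
        "W_k": uniform(c.attn_dim, c.D_c),
        "W_v": uniform(c.attn_dim, c.D_c),
        "W_o": uniform(c.D_c, c.attn_dim),
        "W_fuse": uniform(c.fused_dim, c.D_p * c.D_c),
        "b_fuse": Tensor(np.zeros(c.fused_dim), requires_grad=True),
        "mil_V": uniform(c.mil_hidden, c.fused_dim),
        "mil_U": uniform(c.mil_hidden, c.fused_dim),
        "mil_w": uniform(1, c.mil_hidden),
        "clf_w": uniform(1, c.fused_dim),
        "clf_b": Tensor(np.zeros(1), requires_grad=True),
    }
    return params


def init_baseline_params(config: PanSubNetConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    """Patch-only gated-attention MIL baseline: attention layer + linear head."""

    def uniform(*shape: int) -> Tensor:
        a = 1.0 / math.sqrt(shape[-1])
        return Tensor(rng.uniform(-a, a, size=shape), requires_grad=True)

    c = config
    return {
        "mil_V": uniform(c.mil_hidden, c.D_p),
        "mil_U": uniform(c.mil_hidden, c.D_p),
        "mil_w": uniform(1, c.mil_hidden),
        "clf_w": uniform(1, c.D_p),
        "clf_b": Tensor(np.zeros(1), requires_grad=True),
    }


def _pairwise_distances(centroids: np.ndarray) -> np.ndarray:
    diff = centroids[:, None, :] - centroids[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def distance_bias(centroids: np.ndarray, gamma: float) -> np.ndarray:
    """(n+1, n+1) additive attention bias: -d/gamma between cells, 0 for CLS pairs."""
    n = centroids.shape[0]
    bias = np.zeros((n + 1, n + 1))
    if n:
        bias[1:, 1:] = -_pairwise_distances(np.asarray(centroids, dtype=float)) / gamma
    return bias


def resolve_gamma(config: PanSubNetConfig, mpp: float | None = None,
                  patch_mag_factor: int = 2) -> float:
    if config.distance_scale is not None:
        return config.distance_scale
    extent = config.tile_size_patch_px * patch_mag_factor
    return extent * mpp if mpp else float(extent)


def cell_aggregate(
    cell_embeddings: np.ndarray,
    centroids: np.ndarray,
    params: dict[str, Tensor],
    config: PanSubNetConfig,
    gamma: float | None = None,
) -> Tensor:
    """Spatially biased CLS self-attention over one patch's cells -> (D_c,) vector.

    With zero cells the CLS token simply passes through the value/output path.
    """
    cell_embeddings = np.asarray(cell_embeddings, dtype=float).reshape(-1, config.D_c)
    if not np.all(np.isfinite(cell_embeddings)):
        bad = np.where(~np.isfinite(cell_embeddings).all(axis=1))[0][0]
        raise ValueError(f"non-finite embedding for cell index {bad}")
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if not np.all(np.isfinite(centroids)):
        bad = np.where(~np.isfinite(centroids).all(axis=1))[0][0]
        raise ValueError(f"non-finite centroid for cell index {bad}")
    if gamma is None:
        gamma = resolve_gamma(config)

    tokens = concat([params["cls_token"], Tensor(cell_embeddings)], axis=0)
    d_head = config.attn_dim // config.n_heads
    q = tokens @ params["W_q"].T  # (n+1, attn_dim)
    k = tokens @ params["W_k"].T
    v = tokens @ params["W_v"].T
    bias = Tensor(distance_bias(centroids, gamma))
    heads = []
    for h in range(config.n_heads):
        sl = slice(h * d_head, (h + 1) * d_head)
        scores = (q[:, sl] @ k[:, sl].T) / math.sqrt(d_head) + bias
        attn = scores.softmax(axis=-1)
        heads.append(attn @ v[:, sl])
    out = heads[0] if config.n_heads == 1 else concat(heads, axis=1)
    out = out @ params["W_o"].T
    return out[0]  # CLS position


def fuse_patch_cell(patch_embedding, cls_vector, params: dict[str, Tensor]) -> Tensor:
    """Outer-product fusion of one patch: vec(p x c) projected to fused_dim."""
    p = patch_embedding if isinstance(patch_embedding, Tensor) else Tensor(
        np.asarray(patch_embedding, dtype=float))
    c = cls_vector if isinstance(cls_vector, Tensor) else Tensor(
        np.asarray(cls_vector, dtype=float))
    dp, dc = p.shape[0], c.shape[0]
    if params["W_fuse"].shape[1] != dp * dc:
        raise ValueError(
            f"fusion projection expects {params['W_fuse'].shape[1]} inputs, got {dp}*{dc}"
        )
    fused = fuse_batch(p.reshape(1, dp), c.reshape(1, dc), params)
    return fused[0]


def fuse_batch(patch_embeddings: Tensor, cls_vectors: Tensor,
               params: dict[str, Tensor]) -> Tensor:
    """Row-wise outer-product fusion: (k, D_p), (k, D_c) -> (k, fused_dim)."""
    outer = stack_outer(patch_embeddings, cls_vectors)
    return outer @ params["W_fuse"].T + params["b_fuse"]


def grid_positional_encoding(grid_coords: np.ndarray, dim: int) -> np.ndarray:
    """Fixed sinusoidal encoding of (grid_col, grid_row) pairs -> (k, dim)."""
    coords = np.asarray(grid_coords, dtype=float).reshape(-1, 2)
    half = dim // 2
    pe = np.zeros((coords.shape[0], dim))
    for axis in range(2):
        n = half if axis == 0 else dim - half
        i = np.arange(n)
        freq = 1.0 / (10000.0 ** (2 * (i // 2) / n))
        phase = coords[:, axis : axis + 1] * freq[None, :]
        block = np.where(i % 2 == 0, np.sin(phase), np.cos(phase))
        pe[:, axis * half : axis * half + n] = block
    return pe


def attmil_pool(
    fused: Tensor,
    params: dict[str, Tensor],
    grid_coords: np.ndarray | None = None,
    variant: str = "gated",
) -> tuple[Tensor, Tensor]:
    """Gated attention MIL over a (k, d) bag -> (scalar logit, (k,) weights)."""
    if fused.shape[0] == 0:
        raise ValueError("cannot pool an empty bag")
    h = fused
    if variant == "gated2d":
        if grid_coords is None:
            raise ValueError("gated2d pooling needs grid coordinates")
        h = h + Tensor(grid_positional_encoding(grid_coords, fused.shape[1]))
    gate = (h @ params["mil_V"].T).tanh() * (h @ params["mil_U"].T).sigmoid()
    scores = (gate @ params["mil_w"].T).reshape(-1)
    attn = scores.softmax(axis=-1)
    pooled = attn.reshape(1, -1) @ h
    logit = (pooled @ params["clf_w"].T + params["clf_b"]).reshape(())
    return logit, attn


def _bag_arrays(bag: SlideBag, config: PanSubNetConfig):
    """Extract per-patch numpy inputs from a bag once (cached on the bag)."""
    cache = getattr(bag, "_fwd_cache", None)
    if cache is not None:
        return cache
    by_id = {c.cell_id: c for c in bag.cells}
    scale = bag.geometry.mpp or 1.0
    patch_embs = np.stack([np.asarray(p.embedding, dtype=float) for p in bag.patches])
    grids = np.array([(p.grid_col, p.grid_row) for p in bag.patches], dtype=float)
    cell_data = []
    for p in bag.patches:
        cells = [by_id[cid] for cid in p.cell_ids]
        emb = (np.stack([c.embedding for c in cells])
               if cells else np.zeros((0, config.D_c)))
        cent = (np.array([(c.centroid_x, c.centroid_y) for c in cells], dtype=float) * scale
                if cells else np.zeros((0, 2)))
        cell_data.append((emb, cent))
    cache = (patch_embs, grids, cell_data)
    bag._fwd_cache = cache  # type: ignore[attr-defined]
    return cache


def forward_bag(bag: SlideBag, params: dict[str, Tensor],
                config: PanSubNetConfig) -> tuple[Tensor, Tensor]:
    """Full network on one bag -> (slide logit, patch attention)."""
    if not bag.patches:
        raise ValueError(f"slide {bag.slide_id!r} has an empty bag")
    patch_embs, grids, cell_data = _bag_arrays(bag, config)
    gamma = resolve_gamma(config, bag.geometry.mpp, bag.geometry.patch_mag_factor)
    cls_rows = [
        cell_aggregate(emb, cent, params, config, gamma=gamma).reshape(1, -1)
        for emb, cent in cell_data
    ]
    cls_mat = cls_rows[0] if len(cls_rows) == 1 else concat(cls_rows, axis=0)
    fused = fuse_batch(Tensor(patch_embs), cls_mat, params)
    return attmil_pool(fused, params, grid_coords=grids, variant=config.mil_variant)


def forward_baseline(bag: SlideBag, params: dict[str, Tensor],
                     config: PanSubNetConfig) -> tuple[Tensor, Tensor]:
    """Patch-only AttMIL baseline on one bag."""
    if not bag.patches:
        raise ValueError(f"slide {bag.slide_id!r} has an empty bag")
    patch_embs, grids, _ = _bag_arrays(bag, config)
    return attmil_pool(Tensor(patch_embs), params, grid_coords=grids, variant="gated")


def forward_slide(bag: SlideBag, params: dict[str, Tensor], config: PanSubNetConfig,
                  baseline: bool = False) -> PredictionResult:
    """Predict one slide and package the probability, margin and attention."""
    fwd = forward_baseline if baseline else forward_bag
    logit, attn = fwd(bag, params, config)
    p = float(sigmoid(np.asarray([logit.data]))[0])
    return PredictionResult.from_probability(bag.slide_id, p, attn.data.copy())


def bce_loss(logit: Tensor, y: float) -> Tensor:
    """Binary cross-entropy from the logit (numerically stable)."""
    return logit.softplus() - logit * y
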