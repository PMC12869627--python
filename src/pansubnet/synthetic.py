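"""Synthetic cohorts with planted structure.

Three generators, all pure functions of (config, seed):

* an expression cohort with subtype-dependent signature means, a continuum of
  intermediate samples, and bimodal GATA6 — a stand-in for bulk RNA-seq;
* slide bags of patch/cell embeddings with tunable class effect sizes — a
  stand-in for foundation-model patch encoders and cell segmenters;
* two-group exponential survival tables.

Expression is generated in log space (log-normal background, per-gene
baselines) and renormalized to TPM.  A sample's position on the
basal-classical continuum is t in [-1, +1]: classical-signature genes shift
by +t * effect SD in log space and basal-signature genes by -t * effect SD,
so t = +1 is a pure classical profile and t = -1 pure basal-like.
Intermediates draw t uniformly from the middle of the continuum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, TPM_TOTAL
from .labels import MoffittSignature, load_moffitt_signature
from .tissue import (
    CELL_TYPES,
    CellRecord,
    SlideBag,
    SlideGeometry,
    map_cells_to_patches,
    tile_grid,
)
from .evaluation import SurvivalRecord


@dataclass
class ExpressionSimConfig:
    n_classical: int = 100
    n_basal: int = 100
    n_intermediate: int = 50
    signature_effect: float = 2.0  # log-space mean shift, in within-class SD units
    gata6_low_mode: float = 10.0  # TPM
    gata6_high_mode: float = 100.0  # TPM
    noise_sd: float = 1.0  # log-space within-class SD
    n_background_genes: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_classical, self.n_basal, self.n_intermediate) < 0:
            raise ValueError("sample counts must be non-negative")
        if self.n_classical + self.n_basal + self.n_intermediate == 0:
            raise ValueError("cohort must contain at least one sample")
        if self.signature_effect < 0:
            raise ValueError("signature_effect must be non-negative")
        if self.gata6_low_mode <= 0 or self.gata6_high_mode <= 0:
            raise ValueError("GATA6 modes must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def simulate_expression_cohort(
    config: ExpressionSimConfig,
    signature: MoffittSignature | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Expression cohort plus the planted-truth table.

    Returns a TPM matrix over (background genes + 50 signature genes + GATA6)
    and a table with columns sample_id, planted_label, t (continuum position).
    """
    signature = signature or load_moffitt_signature()
    rng = np.random.default_rng(config.seed)
    classical_genes = sorted(signature.classical)
    basal_genes = sorted(signature.basal)
    background = [f"BG{i:05d}" for i in range(config.n_background_genes)]
    gene_ids = background + classical_genes + basal_genes + ["GATA6"]
    n_genes = len(gene_ids)

    # continuum positions: classical at +1, basal at -1, intermediates inside
    t = np.concatenate([
        np.ones(config.n_classical),
        -np.ones(config.n_basal),
        rng.uniform(-0.5, 0.5, size=config.n_intermediate),
    ])
    labels = (
        ["classical"] * config.n_classical
        + ["basal_like"] * config.n_basal
        + ["intermediate"] * config.n_intermediate
    )
    n_samples = t.size
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]

    # per-gene baseline log-abundance; scale so the expected column total is 1e6
    base_log = rng.normal(0.0, 1.0, size=n_genes)
    scale = TPM_TOTAL / (n_genes * np.exp((1.0 + config.noise_sd**2) / 2))
    shift = np.zeros((n_genes, n_samples))
    is_classical_gene = np.isin(gene_ids, classical_genes)
    is_basal_gene = np.isin(gene_ids, basal_genes)
    shift[is_classical_gene] = t[None, :] * config.signature_effect * config.noise_sd
    shift[is_basal_gene] = -t[None, :] * config.signature_effect * config.noise_sd
    log_noise = rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))
    abundance = scale * np.exp(base_log[:, None] + shift + log_noise)

    # bimodal GATA6: mode interpolated geometrically along the continuum
    frac = (t + 1) / 2  # 0 = basal, 1 = classical
    gata6_mode = np.exp(
        np.log(config.gata6_low_mode)
        + frac * (np.log(config.gata6_high_mode) - np.log(config.gata6_low_mode))
    )
    s = 0.3
    abundance[-1, :] = gata6_mode * np.exp(rng.normal(0.0, s, size=n_samples) - s**2 / 2)

    tpm = abundance / abundance.sum(axis=0, keepdims=True) * TPM_TOTAL
    matrix = ExpressionMatrix(gene_ids, sample_ids, tpm, unit="TPM")
    truth = pd.DataFrame({"sample_id": sample_ids, "planted_label": labels, "t": t})
    return matrix, truth


@dataclass
class BagSimConfig:
    n_slides: int = 120
    patches_per_slide: tuple[int, int] = (6, 12)
    cells_per_patch: tuple[int, int] = (5, 15)
    D_p: int = 64
    D_c: int = 32
    patch_effect: float = 1.0  # separation between class-conditional patch means
    cell_effect: float = 1.0  # class tilt of the cell-type mixing weights
    n_cell_types: int = 5
    basal_fraction: float = 0.5
    tile_size_patch_px: int = 256
    patch_mag_factor: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slides <= 0:
            raise ValueError("n_slides must be positive")
        for rng_name in ("patches_per_slide", "cells_per_patch"):
            lo, hi = getattr(self, rng_name)
            if not (0 < lo <= hi):
                raise ValueError(f"{rng_name} range must satisfy 0 < lo <= hi")
        if self.D_p <= 0 or self.D_c <= 0 or self.n_cell_types <= 0:
            raise ValueError("dimensions must be positive")
        if not 0 < self.basal_fraction < 1:
            raise ValueError("basal_fraction must be in (0, 1)")


def simulate_slide_bags(config: BagSimConfig) -> list[SlideBag]:
    """Labeled slide bags with class-conditional patch and cell embeddings.

    Patch embeddings sit at a common baseline mean plus/minus half the patch
    effect along a fixed direction (basal +, classical -), with unit Gaussian
    noise.  Cell embeddings are a mixture over ``n_cell_types`` Gaussian
    clusters whose mixing weights tilt with the class in proportion to
    ``cell_effect``; cell centroids are uniform within their patch.  The
    non-zero patch baseline mirrors real encoder features (which are far from
    zero-mean) and lets cell-borne signal survive the outer-product fusion.
    """
    rng = np.random.default_rng(config.seed)
    patch_base = rng.normal(0.0, 1.0, size=config.D_p)
    patch_dir = rng.normal(0.0, 1.0, size=config.D_p)
    patch_dir /= np.linalg.norm(patch_dir)
    cluster_means = rng.normal(0.0, 2.0, size=(config.n_cell_types, config.D_c))
    # per-type tilt pattern: symmetric ramp so classes prefer opposite type mixes
    ramp = np.linspace(-1.0, 1.0, config.n_cell_types)
    base_w = np.full(config.n_cell_types, 1.0 / config.n_cell_types)

    n_basal = int(round(config.n_slides * config.basal_fraction))
    labels = ["basal_like"] * n_basal + ["classical"] * (config.n_slides - n_basal)
    labels = [labels[i] for i in rng.permutation(config.n_slides)]
    T = config.tile_size_patch_px * config.patch_mag_factor
    bags = []
    for s, label in enumerate(labels):
        sign = 1.0 if label == "basal_like" else -1.0
        n_patches = int(rng.integers(config.patches_per_slide[0],
                                     config.patches_per_slide[1] + 1))
        n_cols = int(np.ceil(np.sqrt(n_patches)))
        n_rows = int(np.ceil(n_patches / n_cols))
        geometry = SlideGeometry(width_px=n_cols * T, height_px=n_rows * T,
                                 patch_mag_factor=config.patch_mag_factor)
        skeleton = tile_grid(geometry, config.tile_size_patch_px)[:n_patches]
        w = base_w * np.exp(sign * config.cell_effect * ramp)
        w /= w.sum()
        cells: list[CellRecord] = []
        for p in skeleton:
            p.embedding = (
                patch_base
                + sign * (config.patch_effect / 2) * patch_dir
                + rng.normal(0.0, 1.0, size=config.D_p)
            )
            n_cells = int(rng.integers(config.cells_per_patch[0],
                                       config.cells_per_patch[1] + 1))
            types = rng.choice(config.n_cell_types, size=n_cells, p=w)
            for j, ty in enumerate(types):
                emb = cluster_means[ty] + rng.normal(0.0, 1.0, size=config.D_c)
                cells.append(CellRecord(
                    cell_id=f"s{s}_p{p.grid_col}_{p.grid_row}_c{j}",
                    centroid_x=p.origin_x + rng.uniform(0, T),
                    centroid_y=p.origin_y + rng.uniform(0, T),
                    embedding=emb,
                    cell_type=CELL_TYPES[ty % len(CELL_TYPES)],
                ))
        bag = map_cells_to_patches(cells, skeleton, geometry,
                                   config.tile_size_patch_px,
                                   slide_id=f"slide_{s:04d}", label=label)
        bags.append(bag)
    return bags


@dataclass
class SurvivalSimConfig:
    n_per_group: int = 100
    hazard_classical: float = 1 / 24.0  # events per month
    hazard_basal: float = 1 / 12.0
    censor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")
        if self.hazard_classical <= 0 or self.hazard_basal <= 0:
            raise ValueError("hazards must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")


def simulate_survival(config: SurvivalSimConfig) -> list[SurvivalRecord]:
    """Two-group exponential survival times in months with uniform censoring.

    Each subject is independently censored with probability ``censor_rate``;
    a censored subject's recorded time is uniform on (0, event time).
    """
    rng = np.random.default_rng(config.seed)
    records = []
    for group, hazard in (("classical", config.hazard_classical),
                          ("basal_like", config.hazard_basal)):
        times = rng.exponential(1.0 / hazard, size=config.n_per_group)
        censored = rng.random(config.n_per_group) < config.censor_rate
        obs = np.where(censored, rng.uniform(0, times), times)
        for i, (t, c) in enumerate(zip(obs, censored)):
            records.append(SurvivalRecord(
                sample_id=f"{group}_{i:04d}",
                time_months=float(max(t, 1e-9)),
                event=0 if c else 1,
                group=group,
            ))
    return records
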