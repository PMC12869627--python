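"""Molecular-subtype labeling: Moffitt signature scoring with GATA6 refinement.

Pipeline: per-sample ssGSEA enrichment of the classical and basal-like gene
sets, subtype score = ES(classical) - ES(basal), cohort z-scoring of the
score, |z| > threshold thresholding into high-confidence calls, and optional
GATA6 tertile refinement of the intermediate band.

The subtype score is positive for classical-leaning samples.  A sample is a
high-confidence classical call when z > +threshold, high-confidence
basal-like when z < -threshold, and intermediate (low confidence) inside the
closed band [-threshold, +threshold].  GATA6, a marker of pancreatic
epithelial differentiation, is high in classical and low/absent in basal-like
tumors; refinement relabels intermediates by GATA6 tertile (low -> basal-like,
high -> classical, middle -> ambiguous).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

import numpy as np

from .expression import ExpressionMatrix, zscore
from .ssgsea import moffitt_subtype_score, ssgsea_enrichment

logger = logging.getLogger(__name__)

LABELS = ("classical", "basal_like", "intermediate", "ambiguous")


@dataclass(frozen=True)
class MoffittSignature:
    """The two disjoint marker-gene sets of the 50-gene PDAC subtype signature."""

    classical: frozenset[str]
    basal: frozenset[str]

    def __post_init__(self) -> None:
        if self.classical & self.basal:
            raise ValueError("classical and basal gene sets must be disjoint")
        if not self.classical or not self.basal:
            raise ValueError("both gene sets must be non-empty")

    @property
    def n_genes(self) -> int:
        return len(self.classical) + len(self.basal)


def load_moffitt_signature() -> MoffittSignature:
    """The bundled 25+25 classical/basal-like marker signature."""
    from .io import read_gmt

    path = resources.files("pansubnet.data") / "moffitt.gmt"
    sets = read_gmt(str(path))
    return MoffittSignature(
        classical=frozenset(sets["MOFFITT_CLASSICAL"]),
        basal=frozenset(sets["MOFFITT_BASAL"]),
    )


@dataclass
class SubtypeScoreRecord:
    sample_id: str
    es_classical: float
    es_basal: float
    score: float
    z: float = float("nan")


@dataclass
class SubtypeLabelRecord:
    sample_id: str
    label: str
    confidence: str
    gata6_tpm: float | None = None
    gata6_tertile: str = "unknown"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.confidence not in ("high", "low"):
            raise ValueError(f"unknown confidence {self.confidence!r}")


@dataclass
class LabelConfig:
    """Tunable knobs of the labeling engine.

    z_threshold
        Half-width of the intermediate band on the z-scored subtype score.
    ssgsea_alpha
        Rank-weight exponent of the running-sum enrichment.
    gata6_mode
        ``"cohort_tertiles"`` (cut points from the cohort's GATA6 values) or
        ``"fixed_cutoffs"`` (low/high TPM cut points, default 20 / 60).
    refinement_scope
        ``"intermediate_only"`` refines only the intermediate band;
        ``"all"`` re-labels every sample by GATA6.
    refined_high_confidence
        Whether GATA6-refined calls are promoted to high confidence
        (default: they stay low confidence).
    zscore_reference
        ``"this_cohort"`` z-scores on the cohort being labeled;
        ``"provided_reference"`` uses frozen (mean, sd) from ``reference_stats``.
    """

    z_threshold: float = 1.0
    ssgsea_alpha: float = 0.25
    gata6_mode: str = "cohort_tertiles"
    gata6_low_tpm: float = 20.0
    gata6_high_tpm: float = 60.0
    refinement_scope: str = "intermediate_only"
    refined_high_confidence: bool = False
    zscore_reference: str = "this_cohort"
    reference_stats: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.ssgsea_alpha < 0:
            raise ValueError("ssgsea_alpha must be non-negative")
        if self.gata6_mode not in ("cohort_tertiles", "fixed_cutoffs"):
            raise ValueError(f"unknown gata6_mode {self.gata6_mode!r}")
        if not self.gata6_low_tpm < self.gata6_high_tpm:
            raise ValueError("fixed GATA6 cutoffs require low < high")
        if self.refinement_scope not in ("intermediate_only", "all"):
            raise ValueError(f"unknown refinement_scope {self.refinement_scope!r}")
        if self.zscore_reference not in ("this_cohort", "provided_reference"):
            raise ValueError(f"unknown zscore_reference {self.zscore_reference!r}")
        if self.zscore_reference == "provided_reference" and self.reference_stats is None:
            raise ValueError("provided_reference mode needs reference_stats=(mean, sd)")


def score_samples(
    matrix: ExpressionMatrix, signature: MoffittSignature, config: LabelConfig | None = None
) -> list[SubtypeScoreRecord]:
    """Per-sample enrichment of both signature sets and the subtype score."""
    config = config or LabelConfig()
    present = set(matrix.gene_ids)
    for name, genes in (("classical", signature.classical), ("basal", signature.basal)):
        missing = sorted(genes - present)
        if len(missing) > len(genes) / 2:
            raise ValueError(
                f"more than half of the {name} signature is missing from the matrix: {missing}"
            )
        if missing:
            warnings.warn(f"missing {name} signature genes: {missing}", stacklevel=2)
    records = []
    for j, sample in enumerate(matrix.sample_ids):
        expr = matrix.values[:, j]
        es_c = ssgsea_enrichment(expr, matrix.gene_ids, signature.classical, config.ssgsea_alpha)
        es_b = ssgsea_enrichment(expr, matrix.gene_ids, signature.basal, config.ssgsea_alpha)
        records.append(
            SubtypeScoreRecord(sample, es_c, es_b, moffitt_subtype_score(es_c, es_b))
        )
    return records


def zscore_scores(
    records: Sequence[SubtypeScoreRecord], config: LabelConfig | None = None
) -> list[SubtypeScoreRecord]:
    """Fill the z field by standardizing scores across the cohort (or a frozen reference)."""
    config = config or LabelConfig()
    scores = np.array([r.score for r in records], dtype=float)
    if config.zscore_reference == "provided_reference":
        mu, sd = config.reference_stats  # type: ignore[misc]
        if sd <= 0:
            raise ValueError("reference sd must be positive")
        z = (scores - mu) / sd
    else:
        z = zscore(scores)
    return [replace(r, z=float(zi)) for r, zi in zip(records, z)]


def assign_confidence_labels(
    records: Sequence[SubtypeScoreRecord], config: LabelConfig | None = None
) -> list[SubtypeLabelRecord]:
    """Threshold cohort z-scores into subtype calls.

    z > +t -> classical (high confidence); z < -t -> basal-like (high);
    the closed band [-t, +t] -> intermediate (low).
    """
    config = config or LabelConfig()
    t = config.z_threshold
    out = []
    for r in records:
        if not np.isfinite(r.z):
            raise ValueError(f"non-finite z-score for sample {r.sample_id!r}")
        if r.z > t:
            out.append(SubtypeLabelRecord(r.sample_id, "classical", "high"))
        elif r.z < -t:
            out.append(SubtypeLabelRecord(r.sample_id, "basal_like", "high"))
        else:
            out.append(SubtypeLabelRecord(r.sample_id, "intermediate", "low"))
    return out


def gata6_tertile_cutoffs(gata6_tpm: Sequence[float], config: LabelConfig) -> tuple[float, float]:
    if config.gata6_mode == "fixed_cutoffs":
        return config.gata6_low_tpm, config.gata6_high_tpm
    x = np.asarray(gata6_tpm, dtype=float)
    lo, hi = np.quantile(x, [1 / 3, 2 / 3])
    return float(lo), float(hi)


def gata6_tertile_refine(
    labels: Sequence[SubtypeLabelRecord],
    gata6_tpm: Sequence[float],
    config: LabelConfig | None = None,
) -> list[SubtypeLabelRecord]:
    """Relabel in-scope samples by GATA6 tertile.

    Lowest tertile (GATA6 <= low cut) -> basal_like, highest (>= high cut) ->
    classical, between the cuts -> ambiguous.  Out-of-scope records pass
    through with their tertile annotated.
    """
    config = config or LabelConfig()
    gata6 = np.asarray(gata6_tpm, dtype=float)
    if gata6.shape != (len(labels),):
        raise ValueError("need one GATA6 value per label record")
    in_scope = [
        config.refinement_scope == "all" or rec.label == "intermediate" for rec in labels
    ]
    for rec, g, scoped in zip(labels, gata6, in_scope):
        if scoped and not np.isfinite(g):
            raise ValueError(f"missing GATA6 value for sample {rec.sample_id!r}")
    lo, hi = gata6_tertile_cutoffs(gata6[np.isfinite(gata6)], config)
    out = []
    for rec, g, scoped in zip(labels, gata6, in_scope):
        tertile = "unknown"
        if np.isfinite(g):
            tertile = "low" if g <= lo else ("high" if g >= hi else "mid")
        if not scoped:
            out.append(replace(rec, gata6_tpm=float(g) if np.isfinite(g) else None,
                               gata6_tertile=tertile))
            continue
        conf = "high" if config.refined_high_confidence else "low"
        if tertile == "low":
            new = ("basal_like", conf)
        elif tertile == "high":
            new = ("classical", conf)
        else:
            new = ("ambiguous", "low")
        out.append(
            SubtypeLabelRecord(rec.sample_id, new[0], new[1], gata6_tpm=float(g),
                               gata6_tertile=tertile)
        )
    return out


def build_label_table(
    matrix: ExpressionMatrix,
    signature: MoffittSignature | None = None,
    gata6_symbol: str | None = "GATA6",
    config: LabelConfig | None = None,
) -> tuple[list[SubtypeLabelRecord], list[SubtypeScoreRecord]]:
    """Run the full labeling pipeline on a TPM matrix.

    Returns one label record and one score record per sample.  GATA6
    refinement is skipped when ``gata6_symbol`` is None or absent from the
    matrix (with a warning).
    """
    config = config or LabelConfig()
    signature = signature or load_moffitt_signature()
    if matrix.unit != "TPM":
        raise ValueError("build_label_table expects a TPM matrix; run counts_to_tpm first")
    scores = zscore_scores(score_samples(matrix, signature, config), config)
    labels = assign_confidence_labels(scores, config)
    if gata6_symbol is not None:
        if gata6_symbol in matrix.gene_ids:
            labels = gata6_tertile_refine(labels, matrix.gene_values(gata6_symbol), config)
        else:
            warnings.warn(f"GATA6 symbol {gata6_symbol!r} not in matrix; refinement skipped",
                          stacklevel=2)
    return labels, scores
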