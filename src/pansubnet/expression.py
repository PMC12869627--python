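"""Expression containers and bulk RNA-seq preprocessing.

The labeling engine works on a genes x samples abundance matrix, either raw
gene-level counts or TPM (transcripts per million).  TPM is a within-sample,
length-normalized unit: for gene g in a sample,

    TPM_g = (count_g / length_g) / sum_h (count_h / length_h) * 1e6

so every column of a TPM matrix sums to one million.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

TPM_TOTAL = 1e6


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table.

    Parameters
    ----------
    gene_ids
        Unique gene symbols, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    values
        Non-negative float matrix of shape ``(len(gene_ids), len(sample_ids))``.
    unit
        ``"counts"`` or ``"TPM"``.  For TPM matrices over the full gene universe
        each column must sum to 1e6 (the check is waived after gene subsetting,
        flagged by ``subset=True``).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: str = "TPM"
    subset: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.unit not in ("counts", "TPM"):
            raise ValueError(f"unit must be 'counts' or 'TPM', got {self.unit!r}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.unit == "TPM" and not self.subset and self.values.size:
            colsums = self.values.sum(axis=0)
            bad = np.where(np.abs(colsums - TPM_TOTAL) > 1e-6 * TPM_TOTAL)[0]
            if bad.size:
                raise ValueError(
                    f"TPM columns must sum to 1e6; first offending sample: "
                    f"{self.sample_ids[bad[0]]} (sum {colsums[bad[0]]:.6g})"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, symbol: str) -> int:
        try:
            return self.gene_ids.index(symbol)
        except ValueError:
            raise KeyError(f"gene {symbol!r} not in matrix") from None

    def gene_values(self, symbol: str) -> np.ndarray:
        """Per-sample values for one gene."""
        return self.values[self.gene_index(symbol)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unit: str = "TPM", subset: bool = False) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
            unit=unit,
            subset=subset,
        )


def counts_to_tpm(counts: ExpressionMatrix, gene_lengths: Sequence[float]) -> ExpressionMatrix:
    """Convert gene-level counts to TPM using per-gene effective lengths (bp).

    Raises if any length is non-positive or a sample has zero total rate.
    """
    if counts.unit != "counts":
        raise ValueError("input matrix must be in counts")
    lengths = np.asarray(gene_lengths, dtype=float)
    if lengths.shape != (counts.n_genes,):
        raise ValueError(
            f"need one length per gene ({counts.n_genes}), got shape {lengths.shape}"
        )
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be strictly positive")
    rates = counts.values / lengths[:, None]
    totals = rates.sum(axis=0)
    zero = np.where(totals <= 0)[0]
    if zero.size:
        raise ValueError(f"sample {counts.sample_ids[zero[0]]!r} has zero total rate")
    tpm = rates / totals[None, :] * TPM_TOTAL
    return ExpressionMatrix(counts.gene_ids, counts.sample_ids, tpm, unit="TPM")


def zscore(values: np.ndarray, axis: int | None = None) -> np.ndarray:
    """Standardize to mean 0 / SD 1 (population SD, divisor N).

    ``axis=None`` standardizes a 1-D vector; ``axis=1`` standardizes each row
    across columns (per-gene across samples).  Zero-variance slices map to all
    zeros so downstream sums stay finite.
    """
    x = np.asarray(values, dtype=float)
    if axis is None:
        if x.ndim != 1:
            raise ValueError("axis=None expects a 1-D vector")
        if x.size < 2:
            raise ValueError("need at least 2 entries to z-score")
        mu, sd = x.mean(), x.std()
        return np.zeros_like(x) if sd == 0 else (x - mu) / sd
    if x.shape[axis] < 2:
        raise ValueError("need at least 2 entries along the standardization axis")
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    out = np.zeros_like(x)
    np.divide(x - mu, sd, out=out, where=sd > 0)
    return out
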