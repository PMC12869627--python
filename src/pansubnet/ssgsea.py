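"""Single-sample gene-set enrichment (ssGSEA) scoring.

The score is a rank-based running sum (Barbie-style).  Within one sample,
genes are ranked by expression (1 = lowest) and walked in decreasing order.
At each position i the in-set mass is the rank-weight fraction accumulated so
far,

    P_in(i)  = sum_{j<=i, j in S} r_j^alpha / sum_{j in S} r_j^alpha
    P_out(i) = #{j<=i, j not in S} / (G - |S|)

and ES = sum_i (P_in(i) - P_out(i)).  ``alpha`` = 0 weights set genes
uniformly; the conventional default is 0.25.  No range normalization is
applied.  Ties in expression receive average ranks, so the score is invariant
to gene storage order and to any strictly increasing transform of expression.
"""

from __future__ import annotations

from typing import Collection, Sequence

import numpy as np
from scipy.stats import rankdata


def rank_genes(sample_expression: Sequence[float]) -> np.ndarray:
    """Ascending ranks in 1..G, average ranks on ties."""
    x = np.asarray(sample_expression, dtype=float)
    if x.size == 0:
        raise ValueError("cannot rank an empty expression vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("expression values must be finite")
    return rankdata(x, method="average")


def ssgsea_enrichment(
    sample_expression: Sequence[float],
    gene_ids: Sequence[str],
    gene_set: Collection[str],
    alpha: float = 0.25,
) -> float:
    """Enrichment score of ``gene_set`` within one sample.

    ``gene_ids`` labels the entries of ``sample_expression``; set members
    absent from the universe are ignored.  Raises if no set gene is present,
    or if the set covers the whole universe (the out-of-set denominator would
    vanish).
    """
    x = np.asarray(sample_expression, dtype=float)
    gene_ids = list(gene_ids)
    if len(gene_ids) != x.size:
        raise ValueError("gene_ids and expression vector lengths differ")
    in_set = np.array([g in gene_set for g in gene_ids], dtype=bool)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError(f"no genes of set {sorted(gene_set)[:3]}... present in the matrix")
    if n_in == x.size:
        raise ValueError("gene set covers the whole universe; out-of-set mass undefined")

    ranks = rank_genes(x)
    # walk genes from highest to lowest expression; break rank ties stably
    order = np.argsort(-ranks, kind="stable")
    in_ordered = in_set[order]
    weights = np.where(in_ordered, ranks[order] ** alpha, 0.0)
    p_in = np.cumsum(weights) / weights.sum()
    p_out = np.cumsum(~in_ordered) / (x.size - n_in)
    return float(np.sum(p_in - p_out))


def moffitt_subtype_score(es_classical: float, es_basal: float) -> float:
    """Classical-minus-basal enrichment difference; positive = classical-leaning."""
    if not (np.isfinite(es_classical) and np.isfinite(es_basal)):
        raise ValueError("enrichment scores must be finite")
    return float(es_classical - es_basal)
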