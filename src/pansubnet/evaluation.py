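"""Evaluation: classification metrics, decision-margin analysis, survival, DDR.

All model metrics flow through :func:`classification_metrics` so every report
in the package uses one definition.  The positive class is basal-like:
sensitivity is recall for basal-like slides and specificity is recall for
classical slides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix, zscore
from .model import POSITIVE_CLASS, PredictionResult

DDR_GENES = ("BRCA1", "BRCA2", "PALB2", "RAD51", "ATM", "CHEK1")


@dataclass
class ConfusionTable:
    """Per-class totals and errors for a two-class subtype problem."""

    n_basal: int
    err_basal: int
    n_classical: int
    err_classical: int

    def __post_init__(self) -> None:
        if min(self.n_basal, self.err_basal, self.n_classical, self.err_classical) < 0:
            raise ValueError("counts must be non-negative")
        if self.err_basal > self.n_basal or self.err_classical > self.n_classical:
            raise ValueError("errors cannot exceed class totals")

    @property
    def n_total(self) -> int:
        return self.n_basal + self.n_classical

    @property
    def n_errors(self) -> int:
        return self.err_basal + self.err_classical

    @property
    def accuracy(self) -> float:
        return (self.n_total - self.n_errors) / self.n_total

    @property
    def error_rate_basal(self) -> float:
        return self.err_basal / self.n_basal

    @property
    def error_rate_classical(self) -> float:
        return self.err_classical / self.n_classical

    @property
    def sensitivity(self) -> float:
        """Recall for basal-like."""
        return 1.0 - self.error_rate_basal

    @property
    def specificity(self) -> float:
        """Recall for classical."""
        return 1.0 - self.error_rate_classical


@dataclass
class MetricsReport:
    auc: float
    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float

    def scaled(self, factor: float = 100.0) -> dict[str, float]:
        return {k: getattr(self, k) * factor for k in
                ("auc", "accuracy", "balanced_accuracy", "sensitivity", "specificity")}


def classification_metrics(
    y_true: Sequence[str], p: Sequence[float], threshold: float = 0.5
) -> tuple[MetricsReport, ConfusionTable]:
    """Threshold probabilities of the basal-like class and score the calls.

    AUC is the Mann-Whitney pair statistic (ties count one half), computed
    via the ROC integral.  Raises when only one class is present (AUC
    undefined); :func:`confusion_metrics` still works on raw counts.
    """
    y = np.array([1 if t == POSITIVE_CLASS else 0 for t in y_true])
    p = np.asarray(p, dtype=float)
    if y.size != p.size or y.size == 0:
        raise ValueError("y_true and p must be equal-length and non-empty")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined with a single class present")
    pred = (p > threshold).astype(int)
    table = ConfusionTable(
        n_basal=int((y == 1).sum()),
        err_basal=int(((y == 1) & (pred == 0)).sum()),
        n_classical=int((y == 0).sum()),
        err_classical=int(((y == 0) & (pred == 1)).sum()),
    )
    report = MetricsReport(
        auc=float(roc_auc_score(y, p)),
        accuracy=table.accuracy,
        balanced_accuracy=(table.sensitivity + table.specificity) / 2,
        sensitivity=table.sensitivity,
        specificity=table.specificity,
    )
    return report, table


def confusion_metrics(table: ConfusionTable) -> dict[str, float]:
    """Summary arithmetic for printed confusion counts (no probabilities needed)."""
    return {
        "accuracy": table.accuracy,
        "n_errors": table.n_errors,
        "error_rate_basal": table.error_rate_basal,
        "error_rate_classical": table.error_rate_classical,
        "sensitivity": table.sensitivity,
        "specificity": table.specificity,
        "balanced_accuracy": (table.sensitivity + table.specificity) / 2,
    }


def margin_confidence_analysis(
    results: Sequence[PredictionResult],
    correct: Sequence[bool],
    lo: float = 0.10,
    hi: float = 0.90,
    margin_def: str = "half",
) -> dict:
    """Compare decision margins of correct vs incorrect predictions.

    The margin is |p - 0.5| (``margin_def="half"``, range [0, 0.5]) or
    |2p - 1| (``margin_def="full"``).  Reports group medians, a two-sided
    Mann-Whitney U p-value (exact enumeration for n <= 20 per group, normal
    approximation with tie correction above), and the share of errors made
    with high predicted confidence (p <= lo or p >= hi).
    """
    if margin_def not in ("half", "full"):
        raise ValueError(f"unknown margin_def {margin_def!r}")
    if len(results) != len(correct):
        raise ValueError("results and correctness flags must align")
    scale = 1.0 if margin_def == "half" else 2.0
    margins = np.array([abs(r.p - 0.5) * scale for r in results])
    correct = np.asarray(correct, dtype=bool)
    m_corr, m_err = margins[correct], margins[~correct]
    errors = [r for r, ok in zip(results, correct) if not ok]
    n_conf_err = sum(1 for r in errors if r.p <= lo or r.p >= hi)
    out = {
        "median_margin_correct": float(np.median(m_corr)) if m_corr.size else float("nan"),
        "median_margin_incorrect": float(np.median(m_err)) if m_err.size else float("nan"),
        "n_errors": len(errors),
        "n_high_confidence_errors": n_conf_err,
        "high_confidence_error_share": (n_conf_err / len(errors)) if errors else float("nan"),
        "mannwhitney_p": None,
        "note": None,
    }
    if m_corr.size and m_err.size:
        method = "exact" if max(m_corr.size, m_err.size) <= 20 else "asymptotic"
        res = stats.mannwhitneyu(m_corr, m_err, alternative="two-sided", method=method)
        out["mannwhitney_p"] = float(res.pvalue)
    else:
        out["note"] = "one group empty; Mann-Whitney test skipped"
    return out


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalRecord:
    sample_id: str
    time_months: float
    event: int
    group: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.time_months) or self.time_months <= 0:
            raise ValueError(f"sample {self.sample_id!r}: time must be positive and finite")
        if self.event not in (0, 1):
            raise ValueError(f"sample {self.sample_id!r}: event must be 0 or 1")


@dataclass
class GroupKM:
    group: str
    times: np.ndarray
    survival: np.ndarray
    median_os: float | None
    median_ci: tuple[float | None, float | None]
    n: int
    n_events: int


@dataclass
class KMEstimate:
    groups: dict[str, GroupKM]
    logrank_chi2: float
    logrank_p: float


def logrank_pvalue(records: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank (chi-square, p) without fitting the KM curves."""
    from lifelines.statistics import logrank_test

    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    a = [r for r in records if r.group == groups[0]]
    b = [r for r in records if r.group == groups[1]]
    lr = logrank_test(
        [r.time_months for r in a], [r.time_months for r in b],
        event_observed_A=[r.event for r in a], event_observed_B=[r.event for r in b],
    )
    return float(lr.test_statistic), float(lr.p_value)


def km_logrank(records: Sequence[SurvivalRecord], include_censored: bool = False) -> KMEstimate:
    """Kaplan-Meier curves per group plus the two-group log-rank test.

    ``include_censored=False`` (default) keeps only subjects with observed
    death events, mirroring an events-only analysis in which alive subjects
    are excluded; ``True`` performs standard right-censoring.  Medians carry
    Brookmeyer-Crowley style 95% confidence intervals.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.utils import median_survival_times

    recs = list(records)
    if not include_censored:
        recs = [r for r in recs if r.event == 1]
    groups = sorted({r.group for r in recs})
    if len(groups) != 2:
        raise ValueError(f"need exactly two non-empty groups, got {groups}")
    fits: dict[str, GroupKM] = {}
    frames = {}
    for g in groups:
        sub = [r for r in recs if r.group == g]
        t = np.array([r.time_months for r in sub])
        e = np.array([r.event for r in sub])
        kmf = KaplanMeierFitter()
        kmf.fit(t, e, label=g)
        med = kmf.median_survival_time_
        ci = median_survival_times(kmf.confidence_interval_)
        lo_med, hi_med = ci.iloc[0, 0], ci.iloc[0, 1]
        fits[g] = GroupKM(
            group=g,
            times=kmf.survival_function_.index.to_numpy(),
            survival=kmf.survival_function_[g].to_numpy(),
            median_os=None if np.isinf(med) else float(med),
            median_ci=(
                None if np.isinf(lo_med) else float(lo_med),
                None if np.isinf(hi_med) else float(hi_med),
            ),
            n=len(sub),
            n_events=int(e.sum()),
        )
        frames[g] = (t, e)
    chi2, p = logrank_pvalue(recs)
    return KMEstimate(groups=fits, logrank_chi2=chi2, logrank_p=p)


def km_survival_at(estimate: GroupKM, time: float) -> float:
    """Step-function evaluation S(t) of a fitted group curve."""
    idx = np.searchsorted(estimate.times, time, side="right") - 1
    return float(estimate.survival[idx]) if idx >= 0 else 1.0


# ---------------------------------------------------------------------------
# DDR composite score and over-representation
# ---------------------------------------------------------------------------

def ddr_composite_score(
    matrix: ExpressionMatrix, ddr_genes: Sequence[str] = DDR_GENES
) -> pd.Series:
    """Sum of per-gene expression z-scores over the DDR panel, per sample.

    Each available DDR gene is z-scored across samples (population SD,
    zero-variance genes contribute 0) and the z-scores are summed; cohort
    scores therefore sum to zero.  Missing panel genes are warned about; an
    entirely absent panel is an error.
    """
    import warnings

    present = [g for g in ddr_genes if g in matrix.gene_ids]
    missing = [g for g in ddr_genes if g not in matrix.gene_ids]
    if not present:
        raise ValueError(f"none of the DDR genes {list(ddr_genes)} are in the matrix")
    if missing:
        warnings.warn(f"DDR genes missing from matrix: {missing}", stacklevel=2)
    rows = np.stack([matrix.gene_values(g) for g in present])
    z = zscore(rows, axis=1)
    return pd.Series(z.sum(axis=0), index=matrix.sample_ids, name="ddr_score")


@dataclass
class EnrichmentResult:
    term: str
    overlap: int
    term_size: int
    p: float
    p_adjusted: float


def overrepresentation_test(
    selected: set[str],
    term_sets: dict[str, set[str]],
    universe: set[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``selected`` in each term set.

    Upper-tail p-value of the observed overlap given the universe, BH-adjusted
    across terms, sorted by adjusted p.
    """
    if not selected:
        raise ValueError("selection is empty")
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    names, pvals, overlaps, sizes = [], [], [], []
    for name, genes in term_sets.items():
        term = genes & universe
        k = len(selected & term)
        # P(X >= k) with X ~ Hypergeom(N=|universe|, K=|term|, n=|selected|)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(term), len(selected)))
        names.append(name)
        pvals.append(min(p, 1.0))
        overlaps.append(k)
        sizes.append(len(term))
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(n, k, s, p, float(pa))
        for n, k, s, p, pa in zip(names, overlaps, sizes, pvals, p_adj)
    ]
    return sorted(results, key=lambda r: (r.p_adjusted, r.p))
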