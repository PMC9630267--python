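"""LME threshold stage: derive constraint/conservation thresholds from the
deciles enriched in confirmed disorder genes, then classify every gene by
the number of criteria met.

The three criteria are L (LOEUF at or below a low threshold), M (missense-Z
at or above a high threshold) and E (exonic conservation at or above a high
threshold).  Each threshold is the outer boundary of the maximal contiguous
run of enriched deciles starting at the metric's informative extreme —
lowest deciles for LOEUF, highest for misZ and exon conservation.
Comparisons at the threshold are inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .stats import DecileEnrichmentResult, decile_boundaries, decile_enrichment

__all__ = ["LMEThresholds", "DecileLMEClassifier",
           "derive_thresholds", "classify_lme", "euler_counts"]

#: metric -> (informative extreme, comparison direction)
DEFAULT_METRICS = {
    "loeuf": "low_extreme",
    "mis_z": "high_extreme",
    "exon_score": "high_extreme",
}
CRITERION_OF_METRIC = {"loeuf": "L", "mis_z": "M", "exon_score": "E"}


@dataclass
class LMEThresholds:
    """Derived thresholds; a criterion whose extreme decile is not enriched
    is absent (None) and disabled."""

    loeuf_max: float | None
    misz_min: float | None
    exon_min: float | None
    provenance: dict[str, list[int]] = field(default_factory=dict)
    per_metric: dict[str, float | None] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"loeuf_max": self.loeuf_max, "misz_min": self.misz_min,
                "exon_min": self.exon_min, "provenance": self.provenance,
                "per_metric": self.per_metric}


def _threshold_from_run(results: list[DecileEnrichmentResult],
                        boundaries: np.ndarray, direction: str):
    """Outer boundary of the maximal contiguous enriched run at the extreme."""
    enriched = [r.decile for r in results if r.enriched]
    if direction == "low_extreme":
        run = 0
        while run + 1 in enriched:
            run += 1
        if run == 0:
            if enriched:
                warnings.warn(
                    "enriched deciles exist but none at the low extreme; "
                    "criterion disabled", stacklevel=3)
            return None, []
        return float(boundaries[run - 1]), list(range(1, run + 1))
    elif direction == "high_extreme":
        run = 0
        while 10 - run in enriched:
            run += 1
        if run == 0:
            if enriched:
                warnings.warn(
                    "enriched deciles exist but none at the high extreme; "
                    "criterion disabled", stacklevel=3)
            return None, []
        return float(boundaries[9 - run]), list(range(10 - run + 1, 11))
    raise ValueError(f"unknown direction {direction!r}")


def derive_thresholds(decile_results: dict[str, list[DecileEnrichmentResult]],
                      boundaries: dict[str, np.ndarray],
                      directions: dict[str, str] | None = None) -> LMEThresholds:
    """Derive LME thresholds from per-metric decile-enrichment results.

    ``boundaries[metric]`` are the nine pooled decile boundaries of the
    metric, so each threshold equals a decile boundary by construction.
    """
    directions = directions or DEFAULT_METRICS
    values, provenance = {}, {}
    for metric, direction in directions.items():
        thr, run = _threshold_from_run(decile_results[metric],
                                       np.asarray(boundaries[metric]), direction)
        values[metric] = thr
        if run:
            provenance[CRITERION_OF_METRIC.get(metric, metric)] = run
    return LMEThresholds(loeuf_max=values.get("loeuf"),
                         misz_min=values.get("mis_z"),
                         exon_min=values.get("exon_score"),
                         provenance=provenance, per_metric=values)


def classify_lme(features: pd.DataFrame, thresholds: LMEThresholds) -> pd.DataFrame:
    """Per-gene L/M/E booleans and criterion count.

    A missing feature value makes that criterion false for the gene (and is
    flagged in the ``incomplete`` column); a disabled criterion is false for
    every gene.  Comparisons are inclusive at the threshold.
    """
    out = pd.DataFrame(index=features.index)
    loeuf, misz, exon = (features.get(c) for c in ("loeuf", "mis_z", "exon_score"))
    out["L"] = ((loeuf <= thresholds.loeuf_max).fillna(False)
                if thresholds.loeuf_max is not None and loeuf is not None
                else False)
    out["M"] = ((misz >= thresholds.misz_min).fillna(False)
                if thresholds.misz_min is not None and misz is not None
                else False)
    out["E"] = ((exon >= thresholds.exon_min).fillna(False)
                if thresholds.exon_min is not None and exon is not None
                else False)
    out["n_criteria"] = out[["L", "M", "E"]].sum(axis=1).astype(int)
    present = pd.concat([s.notna() if s is not None else
                         pd.Series(False, index=features.index)
                         for s in (loeuf, misz, exon)], axis=1)
    out["incomplete"] = ~present.all(axis=1)
    return out


def euler_counts(status: pd.DataFrame) -> dict[str, int]:
    """Euler-style counts: genes meeting exactly each subset of {L, M, E}."""
    counts = {}
    for k in range(4):
        for subset in combinations("LME", k):
            key = "".join(subset) or "none"
            m = np.ones(len(status), dtype=bool)
            for c in "LME":
                m &= status[c].to_numpy() == (c in subset)
            counts[key] = int(m.sum())
    return counts


class DecileLMEClassifier(BaseEstimator, ClassifierMixin):
    """Threshold classifier derived from decile enrichment of confirmed genes.

    ``fit(X, y)`` takes a feature frame containing the metric columns and a
    label vector where the positive class is ``"confirmed"``; it computes
    per-metric decile enrichment (Bonferroni across the 10 deciles of every
    metric tested, i.e. ``n_tests = 10 * n_metrics`` by default) and derives
    the thresholds.  ``predict(X)`` returns True for genes meeting at least
    ``min_criteria`` criteria.

    Parameters
    ----------
    metrics : dict, default LOEUF/misZ/exon-score with their extremes
    min_criteria : int, default 1
        Minimum number of satisfied criteria to call a gene LME-positive.
    alpha : float, default 0.05
        Adjusted-p significance level for the enrichment flag.
    n_tests : int or None
        Bonferroni family size; None means 10 x number of metrics.
    """

    def __init__(self, metrics: dict[str, str] | None = None,
                 min_criteria: int = 1, alpha: float = 0.05,
                 n_tests: int | None = None):
        self.metrics = metrics
        self.min_criteria = min_criteria
        self.alpha = alpha
        self.n_tests = n_tests

    def fit(self, X: pd.DataFrame, y):
        metrics = self.metrics or DEFAULT_METRICS
        y = pd.Series(np.asarray(y), index=X.index)
        labels = np.where(y.astype(str) == "confirmed", "confirmed", "other")
        labels = pd.Series(labels, index=X.index)
        n_tests = self.n_tests if self.n_tests is not None else 10 * len(metrics)
        self.decile_results_ = {}
        self.boundaries_ = {}
        for metric in metrics:
            vals = X[metric]
            self.decile_results_[metric] = decile_enrichment(
                vals, labels, n_tests=n_tests, alpha=self.alpha)
            self.boundaries_[metric] = decile_boundaries(vals.dropna().to_numpy())
        self.thresholds_ = derive_thresholds(
            self.decile_results_, self.boundaries_, metrics)
        self.classes_ = np.array([False, True])
        return self

    def status(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "thresholds_")
        return classify_lme(X, self.thresholds_)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.status(X)["n_criteria"] >= self.min_criteria).to_numpy()

    def summary(self, X: pd.DataFrame, by=None) -> dict:
        """Thresholds, provenance and Euler counts (optionally per class)."""
        status = self.status(X)
        out = {"thresholds": self.thresholds_.as_dict(),
               "min_criteria": self.min_criteria,
               "euler": euler_counts(status)}
        if by is not None:
            by = pd.Series(np.asarray(by), index=X.index)
            out["euler_by_class"] = {
                str(c): euler_counts(status[by == c]) for c in by.unique()}
        return out
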