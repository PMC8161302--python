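"""Comparison of two fitted relative-risk surfaces.

Given the per-area posterior-mean relative risks of two outcomes, this
module quantifies their spatial overlap two ways:

* the Pearson correlation of the **log** relative risks (the natural scale
  for multiplicative risks; an RR and its reciprocal are symmetric around
  zero in the log), and
* a four-way **coincidence classification**: each area is labelled high or
  low for each outcome relative to the average risk (RR > 1), giving
  matched categories (high-high, low-low) and mismatched ones (high-low,
  low-high), summarised as matched/mismatched percentages.

Ties (RR exactly at the threshold) count as "low": "high" means strictly
above average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoincidenceResult",
    "pearson_log_rr",
    "classify_coincidence",
    "compare_surfaces",
]

CATEGORIES = ("high_high", "low_low", "high_low", "low_high")
MATCHED = ("high_high", "low_low")


@dataclass
class CoincidenceResult:
    """Per-area coincidence classification plus overlap summaries.

    ``table`` has one row per area: id, both RRs, both log RRs and the
    category label.  ``matched_pct + mismatched_pct == 100`` exactly, and
    the category counts partition the areas.  ``pearson_r`` is the
    correlation of the log relative risks (None when not computed).
    """

    table: pd.DataFrame
    counts: dict[str, int]
    matched_pct: float
    mismatched_pct: float
    pearson_r: float | None = None
    threshold: float = 1.0
    tie_rule: str = "ties classified low (high means strictly above threshold)"

    @property
    def n_areas(self) -> int:
        return len(self.table)

    def summary_dict(self) -> dict:
        return {
            "n_areas": self.n_areas,
            "pearson_r": self.pearson_r,
            "matched_pct": self.matched_pct,
            "mismatched_pct": self.mismatched_pct,
            "counts": dict(self.counts),
            "threshold": self.threshold,
            "tie_rule": self.tie_rule,
        }


def pearson_log_rr(rr1: np.ndarray, rr2: np.ndarray) -> float:
    """Pearson correlation of log relative risks.

    Requires two positive vectors of equal length >= 3 with non-degenerate
    logs; raises on zero variance, where the coefficient is undefined.
    """
    r1 = np.asarray(rr1, dtype=float)
    r2 = np.asarray(rr2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1 or r1.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 areas")
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise ValueError("relative risks must be strictly positive")
    l1, l2 = np.log(r1), np.log(r2)
    if l1.std() == 0 or l2.std() == 0:
        raise ValueError("correlation undefined: a log-risk vector has zero variance")
    return float(stats.pearsonr(l1, l2).statistic)


def classify_coincidence(
    rr1: np.ndarray,
    rr2: np.ndarray,
    threshold: float = 1.0,
    area_ids=None,
) -> CoincidenceResult:
    """Four-way high/low classification of two risk surfaces.

    Area *i* is "high" for an outcome iff its RR is strictly above the
    threshold (average risk by default).  Matched percentage counts the
    high-high and low-low areas.
    """
    r1 = np.asarray(rr1, dtype=float)
    r2 = np.asarray(rr2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1 or r1.size == 0:
        raise ValueError("need two equal-length non-empty vectors")
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise ValueError("relative risks must be strictly positive")
    ids = (
        [str(a) for a in area_ids]
        if area_ids is not None
        else [str(i + 1) for i in range(r1.size)]
    )
    if len(ids) != r1.size:
        raise ValueError("area_ids length must match the surfaces")
    hi1, hi2 = r1 > threshold, r2 > threshold
    labels = np.where(
        hi1, np.where(hi2, "high_high", "high_low"),
        np.where(hi2, "low_high", "low_low"),
    )
    table = pd.DataFrame(
        {
            "area_id": ids,
            "rr1": r1,
            "rr2": r2,
            "log_rr1": np.log(r1),
            "log_rr2": np.log(r2),
            "category": labels,
        }
    )
    counts = {cat: int(np.sum(labels == cat)) for cat in CATEGORIES}
    matched = sum(counts[c] for c in MATCHED)
    matched_pct = 100.0 * matched / r1.size
    return CoincidenceResult(
        table=table,
        counts=counts,
        matched_pct=matched_pct,
        mismatched_pct=100.0 - matched_pct,
        threshold=threshold,
    )


def compare_surfaces(
    surface1: pd.DataFrame,
    surface2: pd.DataFrame,
    threshold: float = 1.0,
    log_scale_corr: bool = True,
) -> CoincidenceResult:
    """Align two risk-surface tables by area id and compare them.

    Each surface is a DataFrame with ``area_id`` and ``rr_mean`` columns
    (as produced by the regression stage).  Posterior-mean RRs feed both
    the correlation and the classification.  ``log_scale_corr=False``
    computes the correlation on the RR scale instead (sensitivity option).
    """
    s1 = surface1.set_index(surface1["area_id"].astype(str))
    s2 = surface2.set_index(surface2["area_id"].astype(str))
    diff = set(s1.index).symmetric_difference(s2.index)
    if diff:
        raise ValueError(f"surfaces cover different areas: {sorted(diff)}")
    if s1.index.has_duplicates or s2.index.has_duplicates:
        raise ValueError("duplicate area ids in a risk surface")
    order = list(s1.index)
    rr1 = s1["rr_mean"].to_numpy(dtype=float)
    rr2 = s2.loc[order, "rr_mean"].to_numpy(dtype=float)
    result = classify_coincidence(rr1, rr2, threshold=threshold, area_ids=order)
    if log_scale_corr:
        result.pearson_r = pearson_log_rr(rr1, rr2)
    else:
        if rr1.std() == 0 or rr2.std() == 0:
            raise ValueError("correlation undefined: zero variance")
        result.pearson_r = float(stats.pearsonr(rr1, rr2).statistic)
    return result
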