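"""Cross-cohort harmonization and fold-change classification.

Region sets called in a reference cohort (e.g. knockout vs parental) are
first restricted to regions that also show mark enrichment in the query
cohort (either-condition percentile rule), then each region's
reference-cohort ratio is classified as gained / unchanged / other, and
the query cohort's log2 ratios are summarized per reference label to test
whether the query mirrors ("genocopies") the reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from oncomark.errors import InvalidInputError
from oncomark.region_calling import (
    RegionSet,
    nearest_rank_percentile,
    quantile_summary,
)

LABELS = ("gained", "unchanged", "other")


@dataclass
class FoldChangeConfig:
    gain_threshold: float = 1.5
    unchanged_low: float = 0.8
    unchanged_high: float = 1.0
    cross_cohort_percentile: float = 90.0  # 90 for H3K9me3, 75 for H3K36me3

    def __post_init__(self) -> None:
        if not self.gain_threshold > self.unchanged_high:
            raise InvalidInputError("gain_threshold must exceed the unchanged interval")
        if not 0 <= self.unchanged_low <= self.unchanged_high:
            raise InvalidInputError("unchanged interval bounds out of order")
        if not 0 < self.cross_cohort_percentile < 100:
            raise InvalidInputError("cross_cohort_percentile must lie in (0, 100)")


@dataclass
class FoldChangeCall:
    label: str
    ratio: float
    infinite_ratio: bool = False
    zero_flag: bool = False


def harmonize_cohorts(
    region_set: RegionSet,
    query_wt_scores: Sequence[float],
    query_mut_scores: Sequence[float],
    config: FoldChangeConfig,
) -> tuple:
    """Keep regions whose query score clears the percentile in WT or mutant.

    The threshold is the nearest-rank ``cross_cohort_percentile`` computed
    per condition over this region set's scores; a region is retained when
    it strictly exceeds the threshold in at least one query condition.
    Returns (filtered RegionSet, boolean retention mask).
    """
    regs = list(region_set)
    wt = np.asarray(query_wt_scores, dtype=float)
    mut = np.asarray(query_mut_scores, dtype=float)
    if len(regs) != wt.size or wt.size != mut.size:
        raise InvalidInputError("score vectors must align with the region set")
    if not regs:
        warnings.warn("empty region set passed to harmonize_cohorts", stacklevel=2)
        return RegionSet(regions=[]), np.zeros(0, dtype=bool)
    thr_wt = nearest_rank_percentile(wt, config.cross_cohort_percentile)
    thr_mut = nearest_rank_percentile(mut, config.cross_cohort_percentile)
    keep = (wt > thr_wt) | (mut > thr_mut)
    kept = [r for r, k in zip(regs, keep) if k]
    dropped = [(r, "below-query-percentile") for r, k in zip(regs, keep) if not k]
    return RegionSet(regions=kept, excluded=dropped), keep


def classify_fold_change(
    wt: float, ko: float, config: FoldChangeConfig | None = None
) -> FoldChangeCall:
    """gained if ko/wt > gain_threshold; unchanged if ratio in [0.8, 1]; else other.

    wt == 0 with ko > 0 is gained with an infinite-ratio flag; wt == ko == 0
    is other with a zero flag.  The unchanged interval is closed on both
    ends.
    """
    config = config or FoldChangeConfig()
    if wt < 0 or ko < 0:
        raise InvalidInputError("scores must be non-negative")
    if wt == 0:
        if ko > 0:
            return FoldChangeCall("gained", math.inf, infinite_ratio=True)
        return FoldChangeCall("other", math.nan, zero_flag=True)
    ratio = ko / wt
    if ratio > config.gain_threshold:
        return FoldChangeCall("gained", ratio)
    if config.unchanged_low <= ratio <= config.unchanged_high:
        return FoldChangeCall("unchanged", ratio)
    return FoldChangeCall("other", ratio)


def classify_fold_changes(
    wt_scores: Sequence[float],
    ko_scores: Sequence[float],
    config: FoldChangeConfig | None = None,
) -> list:
    """Vector form of :func:`classify_fold_change` over aligned score pairs."""
    wt = np.asarray(wt_scores, dtype=float)
    ko = np.asarray(ko_scores, dtype=float)
    if wt.shape != ko.shape:
        raise InvalidInputError("score vectors must have equal length")
    return [classify_fold_change(w, k, config) for w, k in zip(wt, ko)]


def mirror_comparison(
    reference_calls: Sequence[FoldChangeCall],
    query_wt_scores: Sequence[float],
    query_mut_scores: Sequence[float],
) -> dict:
    """Per-reference-label distributions of query log2(mut/wt) ratios.

    Regions whose query pair contains a zero are skipped within a label
    (no pseudocount).  Labels with no regions are omitted with a warning.
    Each entry carries the raw log2 ratios and their five-number
    quantile summary.
    """
    wt = np.asarray(query_wt_scores, dtype=float)
    mut = np.asarray(query_mut_scores, dtype=float)
    if len(reference_calls) != wt.size or wt.size != mut.size:
        raise InvalidInputError("query scores must align with reference calls")
    out: dict = {}
    for label in ("gained", "unchanged"):
        idx = [i for i, c in enumerate(reference_calls) if c.label == label]
        if not idx:
            warnings.warn(f"no regions labelled {label!r}; omitted", stacklevel=2)
            continue
        w = wt[idx]
        m = mut[idx]
        ok = (w > 0) & (m > 0)
        ratios = np.log2(m[ok] / w[ok])
        entry = {"log2_ratios": ratios, "n": int(ratios.size), "n_skipped_zero": int((~ok).sum())}
        if ratios.size:
            entry["summary"] = quantile_summary(ratios)
        out[label] = entry
    return out
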