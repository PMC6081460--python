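"""Enrichment-region calling, factor stratification and profile matrices.

The calling pipeline: threshold matched tracks at a per-track percentile
over genic bins (either-condition rule), merge nearby selected bins, drop
overlong regions and extreme outliers, then stratify the surviving regions
by occupancy of independent factor tracks and build scaled-region profile
matrices for metaregion plots.

Thresholding uses the nearest-rank percentile convention ("exceeds the Pth
percentile" means strictly greater than the nearest-rank value), which is
reproducible on integer-valued counts; the descriptive
:func:`quantile_summary` uses linear interpolation to match box-plot
conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from oncomark.coverage import CoverageTrack, GenomeGrid
from oncomark.errors import InvalidInputError


# --------------------------------------------------------------------------
# configuration and result containers


@dataclass
class EnrichmentConfig:
    """Thresholds governing selection, merging, filtering and stratification."""

    select_percentile: float = 95.0
    merge_distance: int = 100
    max_region_length: int = 500
    extreme_top_fraction: float = 0.0001
    factor_enriched_percentile: float = 75.0
    factor_depleted_percentile: float = 25.0

    def __post_init__(self) -> None:
        if not 0 < self.select_percentile < 100:
            raise InvalidInputError("select_percentile must lie in (0, 100)")
        if not 0 < self.extreme_top_fraction < 1:
            raise InvalidInputError("extreme_top_fraction must lie in (0, 1)")
        if not (
            0
            < self.factor_depleted_percentile
            < self.factor_enriched_percentile
            < 100
        ):
            raise InvalidInputError(
                "need 0 < depleted percentile < enriched percentile < 100"
            )
        if self.merge_distance < 0 or self.max_region_length <= 0:
            raise InvalidInputError("merge_distance >= 0 and max_region_length > 0 required")


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    score: float
    n_bins: int
    source_condition: str = "either"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """Merged enrichment regions plus an exclusion log with reasons."""

    regions: list
    excluded: list = field(default_factory=list)  # (Region, reason) pairs

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def scores(self) -> np.ndarray:
        return np.array([r.score for r in self.regions], dtype=float)


@dataclass
class BinSet:
    """Selected bins in grid order: parallel coordinate/value/source arrays."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    value: np.ndarray
    source: np.ndarray

    def __len__(self) -> int:
        return len(self.start)


@dataclass
class FactorClassification:
    """Per-region enriched/depleted/neither labels for one factor track."""

    factor_id: str
    labels: np.ndarray
    scores: np.ndarray
    enriched_threshold: float
    depleted_threshold: float

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class ProfileMatrix:
    """Region x column value matrix: flank, rescaled body, flank."""

    matrix: np.ndarray
    regions: list
    n_flank_cols: int
    n_body_cols: int

    def column_means(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


# --------------------------------------------------------------------------
# percentile helpers


def nearest_rank_percentile(values: Sequence[float], percentile: float) -> float:
    """Value at rank ceil(p/100 * n) of the ascending-sorted values (1-based)."""
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise InvalidInputError("cannot take a percentile of an empty collection")
    rank = max(1, math.ceil(percentile / 100.0 * arr.size))
    return float(arr[min(rank, arr.size) - 1])


def quantile_summary(values: Sequence[float]) -> tuple:
    """(10th, 25th, 50th, 75th, 90th) percentiles under linear interpolation."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("quantile_summary requires at least one value")
    return tuple(float(v) for v in np.percentile(arr, [10, 25, 50, 75, 90]))


# --------------------------------------------------------------------------
# genic bin selection


def genic_bin_mask(grid: GenomeGrid, genes: Iterable) -> np.ndarray:
    """Boolean mask over grid bins overlapping (>= 1 bp) any gene body."""
    mask = np.zeros(grid.n_bins, dtype=bool)
    w = grid.bin_width
    for gene in genes:
        chrom, start, end = gene[0], int(gene[1]), int(gene[2])
        if chrom not in grid.chrom_sizes:
            continue
        size = grid.chrom_sizes[chrom]
        start = max(0, start)
        end = min(size, end)
        if start >= end:
            continue
        sl = grid.chrom_slice(chrom)
        first = start // w
        last = (end - 1) // w
        mask[sl.start + first : sl.start + last + 1] = True
    return mask


def select_enriched_genic_bins(
    track_wt: CoverageTrack,
    track_mut: CoverageTrack,
    genes: Iterable,
    config: EnrichmentConfig,
) -> BinSet:
    """Genic bins above the per-track select percentile in WT or mutant.

    Thresholds are nearest-rank percentiles computed over the genic bins of
    each track separately; a bin is selected when it strictly exceeds its
    track's threshold in either condition.  Each selected bin carries the
    larger of its two condition values and a source label (``WT``,
    ``mutant`` or ``either`` when both conditions exceed).
    """
    if track_wt.grid != track_mut.grid:
        raise InvalidInputError("tracks must share the same genome grid")
    grid = track_wt.grid
    genes = list(genes)
    if not genes:
        raise InvalidInputError("gene models must be non-empty")
    mask = genic_bin_mask(grid, genes)
    if not mask.any():
        import warnings

        warnings.warn("no genic bins on the grid; empty selection", stacklevel=2)
        empty = np.array([], dtype=object)
        zeros = np.array([], dtype=float)
        iz = np.array([], dtype=np.int64)
        return BinSet(empty, iz, iz.copy(), zeros, empty.copy())

    thr_wt = nearest_rank_percentile(track_wt.values[mask], config.select_percentile)
    thr_mut = nearest_rank_percentile(track_mut.values[mask], config.select_percentile)
    above_wt = mask & (track_wt.values > thr_wt)
    above_mut = mask & (track_mut.values > thr_mut)
    selected = above_wt | above_mut

    idx = np.flatnonzero(selected)
    chroms, starts, ends = grid.bin_table()
    source = np.where(
        above_wt[idx] & above_mut[idx],
        "either",
        np.where(above_wt[idx], "WT", "mutant"),
    ).astype(object)
    value = np.maximum(track_wt.values[idx], track_mut.values[idx])
    return BinSet(chroms[idx], starts[idx], ends[idx], value, source)


# --------------------------------------------------------------------------
# merging and filtering


def _combine_source(sources: Sequence[str]) -> str:
    uniq = set(sources)
    return uniq.pop() if len(uniq) == 1 else "either"


def merge_and_filter(bins: BinSet, config: EnrichmentConfig) -> RegionSet:
    """Merge selected bins within ``merge_distance`` and filter the result.

    Bins whose inter-bin gap is <= merge_distance join one region whose
    score is the mean of its member-bin values.  Regions longer than
    ``max_region_length`` bp are excluded (reason ``length``), then the top
    ``round(n * extreme_top_fraction)`` surviving regions by score are
    excluded (reason ``extreme``; half-up rounding, so small sets are not
    forced to lose their top region).
    """
    n = len(bins)
    if n == 0:
        return RegionSet(regions=[])

    order = np.lexsort((bins.start, bins.chrom.astype(str)))
    merged: list = []
    cur = None  # [chrom, start, end, values, sources]
    for i in order:
        c, s, e = bins.chrom[i], int(bins.start[i]), int(bins.end[i])
        if cur is not None and c == cur[0] and s - cur[2] <= config.merge_distance:
            cur[2] = max(cur[2], e)
            cur[3].append(float(bins.value[i]))
            cur[4].append(str(bins.source[i]))
        else:
            if cur is not None:
                merged.append(cur)
            cur = [c, s, e, [float(bins.value[i])], [str(bins.source[i])]]
    if cur is not None:
        merged.append(cur)

    regions = [
        Region(
            chrom=str(c),
            start=s,
            end=e,
            score=float(np.mean(vals)),
            n_bins=len(vals),
            source_condition=_combine_source(srcs),
        )
        for c, s, e, vals, srcs in merged
    ]

    excluded: list = []
    kept = []
    for r in regions:
        if r.length > config.max_region_length:
            excluded.append((r, "length"))
        else:
            kept.append(r)

    if kept:
        k = math.floor(len(kept) * config.extreme_top_fraction + 0.5)
        if k > 0:
            scores = np.array([r.score for r in kept])
            top = set(np.argsort(scores, kind="stable")[-k:].tolist())
            excluded.extend((kept[i], "extreme") for i in sorted(top))
            kept = [r for i, r in enumerate(kept) if i not in top]

    return RegionSet(regions=kept, excluded=excluded)


def region_set_to_binset(region_set: RegionSet) -> BinSet:
    """View retained regions as a BinSet (for idempotence checks)."""
    regs = region_set.regions
    return BinSet(
        chrom=np.array([r.chrom for r in regs], dtype=object),
        start=np.array([r.start for r in regs], dtype=np.int64),
        end=np.array([r.end for r in regs], dtype=np.int64),
        value=np.array([r.score for r in regs], dtype=float),
        source=np.array([r.source_condition for r in regs], dtype=object),
    )


# --------------------------------------------------------------------------
# factor stratification and overlaps


def region_track_score(region: Region, track: CoverageTrack) -> float:
    """Length-weighted mean of track bin values over the region span."""
    grid = track.grid
    if region.chrom not in grid.chrom_sizes:
        return 0.0
    w = grid.bin_width
    size = grid.chrom_sizes[region.chrom]
    start = max(0, region.start)
    end = min(size, region.end)
    if start >= end:
        return 0.0
    sl = grid.chrom_slice(region.chrom)
    first = start // w
    last = (end - 1) // w
    total = 0.0
    length = 0
    for b in range(first, last + 1):
        b_start = b * w
        b_end = min(b_start + w, size)
        ov = min(end, b_end) - max(start, b_start)
        total += track.values[sl.start + b] * ov
        length += ov
    return total / length if length else 0.0


def classify_by_factor(
    regions: RegionSet | Sequence[Region],
    factor_track: CoverageTrack,
    config: EnrichmentConfig,
    factor_id: str = "factor",
) -> FactorClassification:
    """Label each region enriched/depleted/neither by factor occupancy.

    Percentile thresholds are nearest-rank over the region scores of this
    region set; ``enriched`` means strictly above the enriched threshold,
    ``depleted`` strictly below the depleted threshold.
    """
    regs = list(regions)
    if len(regs) < 4:
        raise InvalidInputError(
            f"classification needs at least 4 regions, got {len(regs)}"
        )
    scores = np.array([region_track_score(r, factor_track) for r in regs])
    thr_enr = nearest_rank_percentile(scores, config.factor_enriched_percentile)
    thr_dep = nearest_rank_percentile(scores, config.factor_depleted_percentile)
    labels = np.full(len(regs), "neither", dtype=object)
    labels[scores > thr_enr] = "enriched"
    labels[scores < thr_dep] = "depleted"
    return FactorClassification(
        factor_id=factor_id,
        labels=labels,
        scores=scores,
        enriched_threshold=thr_enr,
        depleted_threshold=thr_dep,
    )


def overlap_classes(classifications: Sequence[FactorClassification]) -> dict:
    """Exclusive overlap counts over every non-empty factor combination.

    A region counts toward combination S when it is enriched for every
    factor in S, enriched for no factor outside S, and depleted for no
    factor in S (depletion acts as an exclusion criterion: a depleted
    region can never contribute to that factor's sets).
    """
    if not classifications:
        return {}
    n = len(classifications[0])
    if any(len(c) != n for c in classifications):
        raise InvalidInputError("classifications cover different region sets")
    names = [c.factor_id for c in classifications]
    if len(set(names)) != len(names):
        raise InvalidInputError("factor ids must be unique")
    counts: dict = {}
    m = len(classifications)
    for mask in range(1, 2**m):
        inside = [i for i in range(m) if mask >> i & 1]
        outside = [i for i in range(m) if not mask >> i & 1]
        key = tuple(names[i] for i in inside)
        c = 0
        for r in range(n):
            if all(classifications[i].labels[r] == "enriched" for i in inside) and not any(
                classifications[i].labels[r] == "enriched" for i in outside
            ) and not any(
                classifications[i].labels[r] == "depleted" for i in inside
            ):
                c += 1
        counts[key] = c
    return counts


# --------------------------------------------------------------------------
# scaled-region profile matrices


def _overlaps_blacklist(region: Region, blacklist: Iterable) -> bool:
    for item in blacklist:
        chrom, start, end = item[0], int(item[1]), int(item[2])
        if region.chrom == chrom and region.start < end and start < region.end:
            return True
    return False


def _bin_value_at(track: CoverageTrack, chrom: str, pos: float) -> float:
    # out-of-chromosome flank positions contribute zero signal
    grid = track.grid
    size = grid.chrom_sizes[chrom]
    p = int(pos)
    if not 0 <= p < size:
        return 0.0
    return float(track.values[grid.bin_index(chrom, p)])


def scaled_region_matrix(
    regions: RegionSet | Sequence[Region],
    track: CoverageTrack,
    body_length: int = 500,
    flank: int = 1000,
    blacklist: Iterable = (),
) -> ProfileMatrix:
    """Flank + rescaled-body + flank value matrix over a coverage track.

    Each region body is rescaled to ``ceil(body_length / bin_width)``
    columns by linear interpolation over the centers of its member-bin
    segments; a region shorter than one bin contributes its single bin
    value to every body column.  Flank columns sample the track at native
    bin resolution (``ceil(flank / bin_width)`` columns per side, zeros
    beyond chromosome ends).  Regions overlapping a blacklist interval are
    removed before computation.
    """
    grid = track.grid
    w = grid.bin_width
    blacklist = list(blacklist)
    kept = [r for r in regions if not _overlaps_blacklist(r, blacklist)]
    if not kept:
        raise InvalidInputError("no regions remain after blacklist exclusion")
    n_body = max(1, math.ceil(body_length / w))
    n_flank = max(0, math.ceil(flank / w))

    rows = []
    for r in kept:
        size = grid.chrom_sizes[r.chrom]
        start = max(0, r.start)
        end = min(size, r.end)
        sl = grid.chrom_slice(r.chrom)
        first = start // w
        last = (end - 1) // w
        centers = []
        vals = []
        for b in range(first, last + 1):
            b_start = max(start, b * w)
            b_end = min(end, min(b * w + w, size))
            centers.append(((b_start + b_end) / 2 - start) / (end - start))
            vals.append(track.values[sl.start + b])
        body_x = (np.arange(n_body) + 0.5) / n_body
        body = np.interp(body_x, centers, vals)
        up = [
            _bin_value_at(track, r.chrom, r.start - flank + (k + 0.5) * w)
            for k in range(n_flank)
        ]
        down = [
            _bin_value_at(track, r.chrom, r.end + (k + 0.5) * w)
            for k in range(n_flank)
        ]
        rows.append(np.concatenate([up, body, down]))

    return ProfileMatrix(
        matrix=np.vstack(rows),
        regions=kept,
        n_flank_cols=n_flank,
        n_body_cols=n_body,
    )
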