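"""Fixed-width genome binning, read counting and track normalization.

A :class:`GenomeGrid` tiles every chromosome with half-open ``bin_width``
windows (last window truncated at the chromosome end).  Reads are counted
into the bin containing their 5' start position, optionally after removing
PCR duplicates, producing a :class:`CoverageTrack` that can be scaled to
reads-per-million and distribution-matched against a second track so two
conditions become directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from oncomark.errors import InvalidInputError, InvalidStateError

NORMALIZATION_STATES = ("raw", "per_million", "matched")


@dataclass(frozen=True)
class ReadInterval:
    """A single aligned read as a 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InvalidInputError(
                f"read interval must satisfy start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise InvalidInputError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """5' start coordinate: ``start`` on +/unknown strand, ``end - 1`` on -."""
        return self.end - 1 if self.strand == "-" else self.start


@dataclass(frozen=True)
class GenomeGrid:
    """Deterministic tiling of a genome into fixed-width half-open bins.

    Bins are ordered by chromosome (insertion order of ``chrom_sizes``) and
    then by start coordinate; they never cross chromosome boundaries and the
    last bin of each chromosome is truncated at the chromosome end.
    """

    chrom_sizes: Mapping[str, int]
    bin_width: int
    _chroms: tuple = field(init=False, repr=False, compare=False)
    _bins_per_chrom: tuple = field(init=False, repr=False, compare=False)
    _offsets: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise InvalidInputError(f"bin_width must be > 0, got {self.bin_width}")
        if not self.chrom_sizes:
            raise InvalidInputError("chrom_sizes must not be empty")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise InvalidInputError(f"chromosome {chrom!r} has non-positive length {size}")
        chroms = tuple(self.chrom_sizes)
        nbins = tuple(-(-self.chrom_sizes[c] // self.bin_width) for c in chroms)
        offsets = {}
        cum = 0
        for c, n in zip(chroms, nbins):
            offsets[c] = cum
            cum += n
        object.__setattr__(self, "_chroms", chroms)
        object.__setattr__(self, "_bins_per_chrom", nbins)
        object.__setattr__(self, "_offsets", offsets)

    @property
    def chroms(self) -> tuple:
        return self._chroms

    @property
    def n_bins(self) -> int:
        return sum(self._bins_per_chrom)

    def bins_in_chrom(self, chrom: str) -> int:
        return self._bins_per_chrom[self._chroms.index(chrom)]

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing position ``pos`` on ``chrom``."""
        if chrom not in self._offsets:
            raise KeyError(chrom)
        size = self.chrom_sizes[chrom]
        if not 0 <= pos < size:
            raise InvalidInputError(f"position {pos} outside chromosome {chrom!r} [0, {size})")
        return self._offsets[chrom] + pos // self.bin_width

    def bin_bounds(self, index: int) -> tuple:
        """(chrom, start, end) of the bin with global index ``index``."""
        if not 0 <= index < self.n_bins:
            raise IndexError(index)
        for chrom, n in zip(self._chroms, self._bins_per_chrom):
            if index < n:
                start = index * self.bin_width
                end = min(start + self.bin_width, self.chrom_sizes[chrom])
                return chrom, start, end
            index -= n
        raise AssertionError("unreachable")

    def bin_table(self) -> tuple:
        """Vectorized (chroms, starts, ends) arrays for all bins in grid order."""
        chroms = np.empty(self.n_bins, dtype=object)
        starts = np.empty(self.n_bins, dtype=np.int64)
        ends = np.empty(self.n_bins, dtype=np.int64)
        i = 0
        for chrom, n in zip(self._chroms, self._bins_per_chrom):
            s = np.arange(n, dtype=np.int64) * self.bin_width
            chroms[i : i + n] = chrom
            starts[i : i + n] = s
            ends[i : i + n] = np.minimum(s + self.bin_width, self.chrom_sizes[chrom])
            i += n
        return chroms, starts, ends

    def chrom_slice(self, chrom: str) -> slice:
        """Slice of the global bin vector covering one chromosome."""
        off = self._offsets[chrom]
        return slice(off, off + self.bins_in_chrom(chrom))


@dataclass
class CoverageTrack:
    """Per-bin quantitation of one sample over a :class:`GenomeGrid`."""

    grid: GenomeGrid
    sample_id: str
    values: np.ndarray
    total_reads: int
    normalization_state: str = "raw"
    n_skipped: int = 0
    n_duplicates_removed: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bins,):
            raise InvalidInputError(
                f"values length {self.values.shape} does not match grid with {self.grid.n_bins} bins"
            )
        if np.any(self.values < 0):
            raise InvalidInputError("track values must be non-negative")
        if self.total_reads < 0:
            raise InvalidInputError("total_reads must be >= 0")
        if self.normalization_state not in NORMALIZATION_STATES:
            raise InvalidInputError(
                f"normalization_state must be one of {NORMALIZATION_STATES}"
            )


def bin_genome(chrom_sizes: Mapping[str, int], bin_width: int) -> GenomeGrid:
    """Tile a genome into half-open bins of ``bin_width`` bp.

    The number of bins per chromosome is ``ceil(length / bin_width)``; the
    last bin of each chromosome is truncated at the chromosome end.
    """
    return GenomeGrid(dict(chrom_sizes), bin_width)


def count_reads(
    reads: Iterable[ReadInterval],
    grid: GenomeGrid,
    drop_duplicates: bool = True,
    sample_id: str = "sample",
) -> CoverageTrack:
    """Count reads into grid bins by 5' start position.

    Each retained read increments exactly one bin.  With
    ``drop_duplicates=True``, reads identical in (chrom, start, end, strand)
    are collapsed to a single representative before counting.  Reads on
    chromosomes absent from the grid are skipped (tallied, not fatal), so
    counting is conservative::

        sum(values) + n_skipped + n_duplicates_removed == len(reads)
    """
    values = np.zeros(grid.n_bins, dtype=float)
    seen: set = set()
    n_skipped = 0
    n_dups = 0
    n_retained = 0
    for read in reads:
        if drop_duplicates:
            key = (read.chrom, read.start, read.end, read.strand)
            if key in seen:
                n_dups += 1
                continue
            seen.add(key)
        if read.chrom not in grid.chrom_sizes:
            n_skipped += 1
            continue
        pos = read.five_prime
        if not 0 <= pos < grid.chrom_sizes[read.chrom]:
            n_skipped += 1
            continue
        values[grid.bin_index(read.chrom, pos)] += 1
        n_retained += 1
    return CoverageTrack(
        grid=grid,
        sample_id=sample_id,
        values=values,
        total_reads=n_retained,
        normalization_state="raw",
        n_skipped=n_skipped,
        n_duplicates_removed=n_dups,
    )


def normalize_per_million(track: CoverageTrack) -> CoverageTrack:
    """Scale every bin value by 1e6 / total_reads."""
    if track.normalization_state != "raw":
        raise InvalidStateError(
            f"per-million scaling requires a raw track, got {track.normalization_state!r}"
        )
    if track.total_reads <= 0:
        raise InvalidStateError("cannot per-million normalize a track with total_reads == 0")
    return replace(
        track,
        values=track.values * (1e6 / track.total_reads),
        normalization_state="per_million",
    )


def _map_to_reference(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    # Quantile mapping: value at rank r -> reference[r]; tied values receive
    # the mean reference value over their tied rank positions.
    n = values.size
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    new_group[1:] = sorted_vals[1:] != sorted_vals[:-1]
    group = np.cumsum(new_group) - 1
    sums = np.bincount(group, weights=reference)
    counts = np.bincount(group)
    mapped_sorted = (sums / counts)[group]
    out = np.empty(n, dtype=float)
    out[order] = mapped_sorted
    return out


def match_distributions(
    track_a: CoverageTrack, track_b: CoverageTrack
) -> tuple:
    """Map two per-million tracks onto their common reference distribution.

    The reference is the element-wise mean of the two sorted value vectors.
    Each track's value at rank r becomes reference[r]; ties receive the mean
    reference value over their tied positions, so within-track rank order is
    preserved.  For tie-free inputs the resulting value multisets of the two
    tracks are identical to numerical tolerance.
    """
    if track_a.grid != track_b.grid:
        raise InvalidInputError("tracks must share the same genome grid")
    for t in (track_a, track_b):
        if t.normalization_state != "per_million":
            raise InvalidStateError(
                f"match_distributions requires per_million tracks, got {t.normalization_state!r}"
            )
    reference = (np.sort(track_a.values) + np.sort(track_b.values)) / 2.0
    a_new = _map_to_reference(track_a.values, reference)
    b_new = _map_to_reference(track_b.values, reference)
    return (
        replace(track_a, values=a_new, normalization_state="matched"),
        replace(track_b, values=b_new, normalization_state="matched"),
    )
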