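"""Gene-expression quantitation and allele-informative read classification.

RPKM is computed over isoform-merged (union) exons with strand-specific
read assignment by 5' start position; genes with zero counts in every
sample are excluded.  Gene-set comparisons report per-gene log2 ratios
sorted ascending next to a seeded random-gene control.  Allele
classification assigns transcript reads spanning a diagnostic codon to one
of three near-identical coding sequences.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from oncomark.coverage import ReadInterval
from oncomark.errors import InvalidInputError

STRANDEDNESS = ("reverse", "forward", "unstranded")


def merge_intervals(intervals: Iterable) -> list:
    """Union of half-open intervals as a sorted non-overlapping list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list = []
    for s, e in ivs:
        if s >= e:
            raise InvalidInputError(f"empty exon interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class GeneModel:
    """One gene with isoform-merged exons."""

    gene_id: str
    chrom: str
    strand: str
    exons: list

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvalidInputError(f"gene strand must be '+' or '-', got {self.strand!r}")
        self.exons = merge_intervals(self.exons)
        if not self.exons:
            raise InvalidInputError(f"gene {self.gene_id} has no exons")

    @property
    def union_exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class ExpressionTable:
    """Raw counts and RPKM per gene (rows) per sample (columns)."""

    counts: pd.DataFrame
    rpkm: pd.DataFrame
    gene_lengths: pd.Series
    total_assigned: pd.Series
    n_ambiguous: pd.Series
    n_unassigned: pd.Series

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


class _ExonIndex:
    """Per-chromosome containment lookup over (possibly overlapping) exons."""

    def __init__(self, genes: Sequence[GeneModel]):
        self._by_chrom: dict = {}
        for gi, g in enumerate(genes):
            for s, e in g.exons:
                self._by_chrom.setdefault(g.chrom, []).append((s, e, gi))
        self._starts: dict = {}
        self._maxend: dict = {}
        for chrom, items in self._by_chrom.items():
            items.sort()
            starts = [s for s, _, _ in items]
            maxend = []
            cur = 0
            for _, e, _ in items:
                cur = max(cur, e)
                maxend.append(cur)
            self._starts[chrom] = starts
            self._maxend[chrom] = maxend

    def genes_at(self, chrom: str, pos: int) -> set:
        items = self._by_chrom.get(chrom)
        if not items:
            return set()
        starts = self._starts[chrom]
        maxend = self._maxend[chrom]
        hi = bisect_right(starts, pos)
        hits = set()
        i = hi - 1
        while i >= 0 and maxend[i] > pos:
            s, e, gi = items[i]
            if s <= pos < e:
                hits.add(gi)
            i -= 1
        return hits


def compute_rpkm(
    counts: pd.DataFrame, lengths: pd.Series, total_assigned: pd.Series
) -> pd.DataFrame:
    """raw_count * 1e9 / (union_exon_length * total_assigned_reads), per sample."""
    with np.errstate(divide="ignore", invalid="ignore"):
        rpkm = counts * 1e9
        return (
            rpkm.div(lengths, axis=0)
            .div(total_assigned.replace(0, np.nan), axis=1)
            .fillna(0.0)
        )


def _strand_compatible(read_strand: str, gene_strand: str, strandedness: str) -> bool:
    if strandedness == "unstranded":
        return True
    if read_strand == ".":
        return False
    if strandedness == "reverse":
        return read_strand != gene_strand
    return read_strand == gene_strand


def quantify_rpkm(
    read_alignments: Mapping[str, Iterable[ReadInterval]],
    gene_models: Sequence[GeneModel],
    strandedness: str = "reverse",
) -> ExpressionTable:
    """Count reads per gene per sample and derive RPKM.

    A read is assigned to a gene when its 5' start lies inside a union exon
    and its strand is compatible under ``strandedness`` (default reverse:
    read strand opposite to the gene strand).  Reads assignable to more
    than one gene are left unassigned and tallied.  RPKM =
    raw_count * 1e9 / (union_exon_length * total_assigned_reads) with the
    total taken per sample over assigned reads only.  Genes with zero
    counts in every sample are dropped from the table.
    """
    if strandedness not in STRANDEDNESS:
        raise InvalidInputError(f"strandedness must be one of {STRANDEDNESS}")
    genes = list(gene_models)
    if not genes:
        raise InvalidInputError("gene models must be non-empty")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise InvalidInputError("gene ids must be unique")
    index = _ExonIndex(genes)

    samples = list(read_alignments)
    counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    n_ambig = np.zeros(len(samples), dtype=np.int64)
    n_unassigned = np.zeros(len(samples), dtype=np.int64)
    for si, sample in enumerate(samples):
        for read in read_alignments[sample]:
            hits = {
                gi
                for gi in index.genes_at(read.chrom, read.five_prime)
                if _strand_compatible(read.strand, genes[gi].strand, strandedness)
            }
            if len(hits) == 1:
                counts[hits.pop(), si] += 1
            elif len(hits) > 1:
                n_ambig[si] += 1
            else:
                n_unassigned[si] += 1

    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="gene_id"), columns=samples)
    lengths = pd.Series([g.union_exon_length for g in genes], index=counts_df.index)
    total = counts_df.sum(axis=0)
    rpkm = compute_rpkm(counts_df, lengths, total)
    nonzero = counts_df.sum(axis=1) > 0
    return ExpressionTable(
        counts=counts_df[nonzero],
        rpkm=rpkm[nonzero],
        gene_lengths=lengths[nonzero],
        total_assigned=total,
        n_ambiguous=pd.Series(n_ambig, index=samples),
        n_unassigned=pd.Series(n_unassigned, index=samples),
    )


@dataclass
class GeneSetComparison:
    set_ratios: pd.Series       # log2(mut/wt), ascending
    control_ratios: pd.Series   # same, for the random control genes
    missing_ids: list
    zero_excluded: list         # set genes dropped because one RPKM was 0


def gene_set_log_ratio(
    table: ExpressionTable,
    gene_set: Iterable[str],
    sample_pair: tuple,
    random_control_size: int | None = None,
    seed: int = 0,
) -> GeneSetComparison:
    """log2(mut/wt) RPKM per set gene, ascending, with a random-gene control.

    Genes with zero RPKM in either sample of the pair are excluded from the
    ratios (no pseudocount) and reported separately.  The control is a
    uniform without-replacement draw of non-set genes of the requested size
    (default: the resolvable set size), deterministic for a given seed.
    """
    wt_sample, mut_sample = sample_pair
    for s in (wt_sample, mut_sample):
        if s not in table.samples:
            raise InvalidInputError(f"sample {s!r} not in expression table")
    gene_set = list(dict.fromkeys(gene_set))
    present = [g for g in gene_set if g in table.genes]
    missing = [g for g in gene_set if g not in table.genes]
    if not present:
        raise InvalidInputError(f"no gene-set ids resolvable in table; missing: {missing}")

    def ratios_for(genes: list) -> tuple:
        wt = table.rpkm.loc[genes, wt_sample]
        mut = table.rpkm.loc[genes, mut_sample]
        ok = (wt > 0) & (mut > 0)
        dropped = [g for g, k in zip(genes, ok) if not k]
        r = np.log2(mut[ok] / wt[ok])
        return r.sort_values(ascending=True), dropped

    set_ratios, zero_excluded = ratios_for(present)

    pool = [g for g in table.genes if g not in set(gene_set)]
    k = random_control_size if random_control_size is not None else len(present)
    if k > len(pool):
        raise InvalidInputError(
            f"random_control_size {k} exceeds the {len(pool)} genes outside the set"
        )
    rng = np.random.default_rng(seed)
    control_genes = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
    control_ratios, _ = ratios_for(control_genes)
    return GeneSetComparison(
        set_ratios=set_ratios,
        control_ratios=control_ratios,
        missing_ids=missing,
        zero_excluded=zero_excluded,
    )


# --------------------------------------------------------------------------
# allele-informative read classification

#: conventional class names: transgene, wild-type gene A, wild-type gene B
ALLELE_NAMES_DEFAULT = ("G34R", "geneA_WT", "geneB_WT")


@dataclass
class AlleleLibrary:
    """Three positionally aligned coding sequences differing near one codon.

    ``codon_offset`` is the 0-based position of the diagnostic codon's
    first base (identical across the three equal-length sequences).
    Diagnostic positions are the columns where the three sequences do not
    all agree, restricted to ``window`` bp either side of the codon.
    """

    names: tuple
    sequences: tuple
    codon_offset: int
    window: int = 25
    diagnostic_positions: tuple = field(init=False)

    def __post_init__(self) -> None:
        if len(self.names) != 3 or len(self.sequences) != 3:
            raise InvalidInputError("allele library requires exactly three sequences")
        self.sequences = tuple(s.upper() for s in self.sequences)
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise InvalidInputError("allele sequences must be equal length (aligned CDS)")
        L = lengths.pop()
        if not 0 <= self.codon_offset <= L - 3:
            raise InvalidInputError("diagnostic codon not contained in the sequences")
        lo = max(0, self.codon_offset - self.window)
        hi = min(L, self.codon_offset + 3 + self.window)
        diag = tuple(
            p
            for p in range(lo, hi)
            if len({s[p] for s in self.sequences}) > 1
        )
        if not diag:
            raise InvalidInputError("sequences are identical within the codon window")
        for i in range(3):
            for j in range(i + 1, 3):
                if all(self.sequences[i][p] == self.sequences[j][p] for p in diag):
                    raise InvalidInputError(
                        f"alleles {self.names[i]!r} and {self.names[j]!r} are "
                        "indistinguishable within the codon window"
                    )
        self.diagnostic_positions = diag

    @property
    def length(self) -> int:
        return len(self.sequences[0])


@dataclass
class AlleleCallSummary:
    counts: dict                 # class name or 'uninformative' -> count
    n_duplicates_removed: int
    n_ambiguous: int = 0

    @property
    def n_informative(self) -> int:
        return sum(v for k, v in self.counts.items() if k != "uninformative")


def _best_placement(read: str, ref: str) -> tuple:
    # best ungapped offset of read within ref (fewest mismatches);
    # exact substring search is the fast path
    exact = ref.find(read)
    if exact >= 0:
        return exact, 0
    L = len(read)
    best_off, best_mm = 0, L + 1
    for off in range(0, len(ref) - L + 1):
        mm = sum(1 for a, b in zip(read, ref[off : off + L]) if a != b)
        if mm < best_mm:
            best_off, best_mm = off, mm
    return best_off, best_mm


def classify_read(read: str, library: AlleleLibrary, max_mismatches: int = 2) -> str:
    """Class label for one read: an allele name or ``uninformative``.

    The read is placed ungapped at its best offset against the library; if
    the placement does not cover the diagnostic codon and every diagnostic
    position the read is uninformative.  Otherwise it is assigned to the
    unique allele matching it at all diagnostic positions with at most
    ``max_mismatches`` mismatches elsewhere; zero or several matching
    alleles make it uninformative.
    """
    read = read.upper()
    if len(read) > library.length:
        return "uninformative"
    placements = [_best_placement(read, s) for s in library.sequences]
    off = min(placements, key=lambda t: t[1])[0]
    span = range(off, off + len(read))
    diag = library.diagnostic_positions
    codon = range(library.codon_offset, library.codon_offset + 3)
    if not all(p in span for p in diag) or not all(p in span for p in codon):
        return "uninformative"
    candidates = []
    for name, seq in zip(library.names, library.sequences):
        if any(read[p - off] != seq[p] for p in diag):
            continue
        mm = sum(1 for p in span if p not in diag and read[p - off] != seq[p])
        if mm <= max_mismatches:
            candidates.append(name)
    if len(candidates) == 1:
        return candidates[0]
    return "ambiguous" if len(candidates) > 1 else "uninformative"


def classify_codon_reads(
    reads: Iterable[str],
    library: AlleleLibrary,
    max_mismatches: int = 2,
) -> AlleleCallSummary:
    """Assign codon-spanning reads to one of three alleles.

    Exact-sequence duplicates are collapsed before counting, then each
    unique read is labelled by :func:`classify_read`; ambiguous reads are
    tallied separately and counted as uninformative.
    """
    reads = [r.upper() for r in reads]
    unique = list(dict.fromkeys(reads))
    n_dups = len(reads) - len(unique)
    counts = {name: 0 for name in library.names}
    counts["uninformative"] = 0
    n_ambiguous = 0
    for read in unique:
        label = classify_read(read, library, max_mismatches)
        if label == "ambiguous":
            n_ambiguous += 1
            counts["uninformative"] += 1
        else:
            counts[label] += 1
    return AlleleCallSummary(counts=counts, n_duplicates_removed=n_dups, n_ambiguous=n_ambiguous)
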