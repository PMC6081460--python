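"""Readers and writers for the plain-text formats the pipeline speaks.

BED6 or SAM for reads, two-column TSV for chromosome sizes, BED12 for gene
models, bedGraph/TSV for tracks and matrices, FASTA for allele libraries,
and two-column CSV for spectra.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from oncomark.coverage import CoverageTrack, GenomeGrid, ReadInterval
from oncomark.errors import InvalidInputError
from oncomark.methylspec import Spectrum
from oncomark.region_calling import Region, RegionSet
from oncomark.transcriptome import GeneModel


def read_chrom_sizes(path) -> dict:
    """Two-column TSV: chromosome name, length."""
    sizes: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise InvalidInputError(f"malformed chrom-sizes line: {line!r}")
        sizes[fields[0]] = int(fields[1])
    if not sizes:
        raise InvalidInputError(f"no chromosomes found in {path}")
    return sizes


def read_bed_reads(path) -> list:
    """BED3/BED6 intervals as reads; strand taken from column 6 when present."""
    reads = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "."
        reads.append(ReadInterval(f[0], int(f[1]), int(f[2]), strand))
    return reads


def read_sam_reads(path) -> list:
    """Primary mapped alignments from a SAM/BAM file."""
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            reads.append(
                ReadInterval(
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    "-" if aln.is_reverse else "+",
                    is_duplicate=aln.is_duplicate,
                )
            )
    return reads


def write_reads_bed(reads: Iterable[ReadInterval], path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread{i}\t0\t{r.strand}\n")


def write_bedgraph(track: CoverageTrack, path, header: str | None = None) -> None:
    chroms, starts, ends = track.grid.bin_table()
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for c, s, e, v in zip(chroms, starts, ends, track.values):
            fh.write(f"{c}\t{s}\t{e}\t{v:.6g}\n")


def write_bin_matrix(grid: GenomeGrid, tracks: Sequence[CoverageTrack], path) -> None:
    """TSV with chrom/start/end plus one value column per track."""
    for t in tracks:
        if t.grid != grid:
            raise InvalidInputError("all tracks must share the output grid")
    chroms, starts, ends = grid.bin_table()
    with open(path, "w") as fh:
        names = "\t".join(t.sample_id for t in tracks)
        fh.write(f"chrom\tstart\tend\t{names}\n")
        for i in range(grid.n_bins):
            vals = "\t".join(f"{t.values[i]:.6g}" for t in tracks)
            fh.write(f"{chroms[i]}\t{starts[i]}\t{ends[i]}\t{vals}\n")


def read_bed_intervals(path) -> list:
    """Generic (chrom, start, end) triples from a BED file."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_regions(region_set: RegionSet, bed_path, tsv_path=None) -> None:
    """BED (score capped per convention) plus full-precision sidecar TSV."""
    with open(bed_path, "w") as fh:
        for i, r in enumerate(region_set):
            bed_score = min(1000, int(round(r.score * 1000)))
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.source_condition}\t{bed_score}\t.\n"
            )
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("region_id\tchrom\tstart\tend\tscore\tn_bins\tsource_condition\n")
            for i, r in enumerate(region_set):
                fh.write(
                    f"region{i}\t{r.chrom}\t{r.start}\t{r.end}\t{r.score:.9g}"
                    f"\t{r.n_bins}\t{r.source_condition}\n"
                )


def read_regions_tsv(path) -> RegionSet:
    regions = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            regions.append(
                Region(
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    score=float(row["score"]),
                    n_bins=int(row["n_bins"]),
                    source_condition=row["source_condition"],
                )
            )
    return RegionSet(regions=regions)


def read_bed12_genes(path) -> list:
    """BED12 gene models; exon blocks become the gene's exon intervals."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise InvalidInputError("BED12 requires 12 columns for gene models")
        chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        genes.append(GeneModel(name, chrom, strand, exons))
    return genes


def write_bed12_genes(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start, end = g.start, g.end
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}"
                f"\t{start}\t{end}\t0\t{len(g.exons)}\t{sizes},\t{offsets},\n"
            )


def read_fasta(path) -> dict:
    """name -> sequence, upper-cased."""
    seqs: dict = {}
    name = None
    chunks: list = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks).upper()
            name = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        seqs[name] = "".join(chunks).upper()
    if not seqs:
        raise InvalidInputError(f"no sequences found in {path}")
    return seqs


def write_fasta(seqs: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_spectrum_csv(path, window=(1200.0, 3500.0)) -> Spectrum:
    """Two-column (mz, intensity) CSV, with or without a header row."""
    mz = []
    intensity = []
    with open(path) as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip():
                continue
            try:
                m = float(row[0])
            except ValueError:
                continue  # header
            mz.append(m)
            intensity.append(float(row[1]))
    return Spectrum(mz=np.array(mz), intensity=np.array(intensity), window=window)


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("mz,intensity\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{m:.6f},{i:.6f}\n")
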