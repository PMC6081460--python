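"""Seeded generators for every input the analysis pipeline consumes.

Each generator plants a known truth (enriched blocks, expression effects,
allele origins, methylation abundances), records it in a
:class:`TruthRecord`, and derives all randomness from one
``numpy.random.default_rng(seed)`` so identical (config, seed) pairs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from oncomark.coverage import ReadInterval
from oncomark.errors import InvalidInputError
from oncomark.transcriptome import ALLELE_NAMES_DEFAULT, GeneModel

DNA = np.array(list("ACGT"))


@dataclass
class TruthRecord:
    """Planted ground truth serialized alongside every generated dataset."""

    kind: str
    payload: dict

    def to_json(self, **kwargs) -> str:
        return json.dumps({"kind": self.kind, **self.payload}, sort_keys=True, **kwargs)


# ==========================================================================
# ChIP-seq simulation


@dataclass
class ChipSimConfig:
    chrom_sizes: dict = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000}
    )
    bin_width: int = 200
    n_genes: int = 200
    gene_length_range: tuple = (4_000, 8_000)
    n_planted_blocks: int = 200
    # blocks are planted on bin boundaries; with the default 200 bp bins and
    # the literal >500 bp merged-region exclusion, blocks spanning >= 3 bins
    # can never survive calling, so the default range keeps them to <= 2 bins
    block_length_range: tuple = (100, 400)
    mark_gain_factor: float = 2.0
    gain_only_factor_bound: bool = False   # restrict the mutant gain to factor-bound blocks
    block_enrichment: float = 8.0          # mean fold over background inside a block (WT)
    n_factor_sites: int = 120
    factor_overlap_fraction: float = 0.6   # fraction of factor sites placed on blocks
    factor_enrichment: float = 8.0
    background_mean: float = 5.0           # expected reads per bin per condition
    nb_dispersion: float = 0.2
    read_length: int = 50
    n_blacklist: int = 4

    def __post_init__(self) -> None:
        if not 0 <= self.factor_overlap_fraction <= 1:
            raise InvalidInputError("factor_overlap_fraction must lie in [0, 1]")
        if self.nb_dispersion < 0 or self.background_mean <= 0:
            raise InvalidInputError("need nb_dispersion >= 0 and background_mean > 0")
        if self.mark_gain_factor <= 0 or self.block_enrichment < 1:
            raise InvalidInputError("gain factor must be > 0 and enrichment >= 1")


def _nb_counts(rng: np.random.Generator, means: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-mixed Poisson (negative binomial) draws; Poisson when dispersion=0."""
    means = np.asarray(means, dtype=float)
    if dispersion == 0:
        return rng.poisson(means)
    lam = rng.gamma(shape=1.0 / dispersion, scale=means * dispersion)
    return rng.poisson(lam)


def _reads_from_bin_counts(
    rng: np.random.Generator,
    counts: np.ndarray,
    chrom: str,
    chrom_size: int,
    bin_width: int,
    read_length: int,
) -> list:
    reads = []
    for b, c in enumerate(counts):
        if c == 0:
            continue
        b_start = b * bin_width
        b_end = min(b_start + bin_width, chrom_size)
        starts = rng.integers(b_start, b_end, size=int(c))
        strands = rng.choice(["+", "-"], size=int(c))
        for s, st in zip(starts, strands):
            # 5' end stays inside the bin for either strand: '+' reads run
            # rightward from s, '-' reads run leftward (5' = end - 1 = s)
            if st == "+":
                lo, hi = int(s), min(int(s) + read_length, chrom_size)
            else:
                lo, hi = max(0, int(s) - read_length + 1), int(s) + 1
            reads.append(ReadInterval(chrom, lo, hi, st))
    return reads


def _place_genes(rng: np.random.Generator, config: ChipSimConfig) -> list:
    """Non-overlapping gene bodies spread evenly across the genome."""
    genes = []
    chroms = list(config.chrom_sizes)
    per_chrom = np.full(len(chroms), config.n_genes // len(chroms))
    per_chrom[: config.n_genes % len(chroms)] += 1
    gi = 0
    for chrom, n in zip(chroms, per_chrom):
        size = config.chrom_sizes[chrom]
        slot = int(size // max(1, n))
        for k in range(n):
            lo, hi = config.gene_length_range
            length = int(rng.integers(lo, hi + 1))
            length = min(length, slot - 200)
            start = k * slot + int(rng.integers(0, max(1, slot - length - 100)))
            genes.append((chrom, start, start + length, f"gene{gi}"))
            gi += 1
    return genes


@dataclass
class ChipSimResult:
    reads_wt: list
    reads_mut: list
    reads_factor: list
    genes: list          # (chrom, start, end, gene_id)
    blacklist: list      # (chrom, start, end)
    truth: TruthRecord


def simulate_chipseq(
    config: ChipSimConfig, seed: int, structure_seed: int | None = None
) -> ChipSimResult:
    """Two-condition mark tracks with planted enriched blocks + a factor track.

    Background bin counts are negative-binomial around ``background_mean``;
    bins overlapped by a planted block have their mean raised by
    ``block_enrichment`` (times ``mark_gain_factor`` in the mutant; with
    ``gain_only_factor_bound`` the gain applies only to blocks that carry a
    factor site).  A configured fraction of factor sites coincides with
    planted blocks, the rest sit in unplanted genic space.  Reads are
    emitted so that 5'-start counting reproduces the drawn bin intensities.

    ``structure_seed`` (default: ``seed``) controls gene/block/factor
    placement separately from read noise, so two cohorts can share planted
    structure while drawing independent reads.
    """
    rng_structure = np.random.default_rng(seed if structure_seed is None else structure_seed)
    rng = np.random.default_rng(seed)
    w = config.bin_width
    genes = _place_genes(rng_structure, config)

    lo_len, hi_len = config.block_length_range
    if hi_len > min(e - s for _, s, e, _ in genes):
        raise InvalidInputError("planted blocks do not fit inside the simulated genes")

    # planted blocks inside randomly chosen genes (at most one per gene so
    # unplanted genic space stays well defined)
    n_blocks = min(config.n_planted_blocks, len(genes))
    block_genes = rng_structure.choice(len(genes), size=n_blocks, replace=False)
    blocks = []
    for gidx in block_genes:
        chrom, gstart, gend, _ = genes[gidx]
        length = int(rng_structure.integers(lo_len, hi_len + 1))
        # bin-aligned start so the block's footprint spans as few bins as possible
        first_bin = -(-gstart // w)
        last_bin = (gend - length) // w
        start = int(rng_structure.integers(first_bin, max(first_bin + 1, last_bin + 1))) * w
        blocks.append((chrom, start, start + length))

    n_on_block = int(round(config.n_factor_sites * config.factor_overlap_fraction))
    n_on_block = min(n_on_block, len(blocks))
    on_block_idx = rng_structure.choice(len(blocks), size=n_on_block, replace=False)
    factor_sites = [blocks[i] for i in on_block_idx]
    bound_blocks = set(int(i) for i in on_block_idx)
    # remaining factor sites in genes that carry no block
    free_genes = [i for i in range(len(genes)) if i not in set(int(g) for g in block_genes)]
    n_free = min(config.n_factor_sites - n_on_block, len(free_genes))
    for gidx in rng_structure.choice(len(free_genes), size=n_free, replace=False):
        chrom, gstart, gend, _ = genes[free_genes[gidx]]
        length = int(rng_structure.integers(lo_len, hi_len + 1))
        start = int(rng_structure.integers(gstart, gend - length))
        factor_sites.append((chrom, start, start + length))

    def bin_means(intervals_with_mult: list) -> dict:
        """Per-chromosome bin mean vectors from (interval, extra-multiplier)."""
        means = {
            c: np.full(-(-s // w), config.background_mean, dtype=float)
            for c, s in config.chrom_sizes.items()
        }
        for (chrom, start, end), mult in intervals_with_mult:
            vec = means[chrom]
            first, last = start // w, (end - 1) // w
            for b in range(first, last + 1):
                b_start, b_end = b * w, min(b * w + w, config.chrom_sizes[chrom])
                frac = (min(end, b_end) - max(start, b_start)) / (b_end - b_start)
                vec[b] += config.background_mean * (mult - 1.0) * frac
        return means

    wt_means = bin_means([(blk, config.block_enrichment) for blk in blocks])
    mut_means = bin_means(
        [
            (
                blk,
                config.block_enrichment * config.mark_gain_factor
                if (not config.gain_only_factor_bound or i in bound_blocks)
                else config.block_enrichment,
            )
            for i, blk in enumerate(blocks)
        ]
    )
    factor_means = bin_means([(s, config.factor_enrichment) for s in factor_sites])

    def emit(means: dict) -> list:
        reads = []
        for chrom, vec in means.items():
            counts = _nb_counts(rng, vec, config.nb_dispersion)
            reads.extend(
                _reads_from_bin_counts(
                    rng, counts, chrom, config.chrom_sizes[chrom], w, config.read_length
                )
            )
        return reads

    reads_wt = emit(wt_means)
    reads_mut = emit(mut_means)
    reads_factor = emit(factor_means)

    # blacklist intervals in intergenic space (between gene slots)
    blacklist = []
    chroms = list(config.chrom_sizes)
    for k in range(config.n_blacklist):
        chrom = chroms[k % len(chroms)]
        size = config.chrom_sizes[chrom]
        start = int(rng.integers(0, size - 1000))
        blacklist.append((chrom, start, start + 1000))

    truth = TruthRecord(
        kind="chipseq",
        payload={
            "blocks": [
                {
                    "chrom": c,
                    "start": s,
                    "end": e,
                    "gain_in_mutant": (
                        config.mark_gain_factor
                        if (not config.gain_only_factor_bound or i in bound_blocks)
                        else 1.0
                    ),
                    "factor_bound": i in bound_blocks,
                }
                for i, (c, s, e) in enumerate(blocks)
            ],
            "factor_sites": [
                {"chrom": c, "start": s, "end": e} for c, s, e in factor_sites
            ],
            "config": dataclasses.asdict(config),
            "seed": seed,
        },
    )
    return ChipSimResult(
        reads_wt=reads_wt,
        reads_mut=reads_mut,
        reads_factor=reads_factor,
        genes=genes,
        blacklist=blacklist,
        truth=truth,
    )


# ==========================================================================
# RNA-seq + allele simulation


@dataclass
class RnaSimConfig:
    n_genes: int = 400
    chrom: str = "chrT"
    chrom_size: int = 6_000_000
    gene_length_range: tuple = (1_000, 8_000)
    expression_log_mean: float = 2.0       # log-normal parameters for per-gene level
    # modest spread and a small set share keep the per-million total nearly
    # constant between conditions, so unperturbed log-ratios centre near zero
    expression_log_sigma: float = 0.6
    n_set_genes: int = 20
    set_effect: float = 0.5                # mutant expression multiplier for set genes
    depth: float = 0.015                   # expected reads per expression unit per bp
    read_length: int = 50
    cds_length: int = 201                  # allele CDS length (multiple of 3)
    codon_offset: int = 99                 # 0-based first base of codon 34
    allele_proportions: tuple = (0.25, 0.35, 0.40)   # (G34R, geneA_WT, geneB_WT)
    n_allele_reads: int = 300
    per_base_error: float = 0.0
    n_planted_duplicates: int = 5

    def __post_init__(self) -> None:
        if abs(sum(self.allele_proportions) - 1.0) > 1e-9:
            raise InvalidInputError("allele proportions must sum to 1")
        if not 0 <= self.per_base_error < 1:
            raise InvalidInputError("per_base_error must lie in [0, 1)")
        if self.cds_length % 3 or not 0 <= self.codon_offset <= self.cds_length - 3:
            raise InvalidInputError("invalid CDS geometry")
        if self.n_set_genes >= self.n_genes:
            raise InvalidInputError("gene set must leave genes for the random control")


ALLELE_NAMES = ALLELE_NAMES_DEFAULT


def build_allele_sequences(config: RnaSimConfig, rng: np.random.Generator) -> tuple:
    """Three equal-length CDS: wild-type gene A, its G34R transgene, gene B.

    The transgene carries a G->A substitution at the first base of the
    diagnostic codon (Gly GGG -> Arg AGG); gene B carries two synonymous
    marker substitutions within 10 bp of the codon.
    """
    base = rng.choice(DNA, size=config.cds_length)
    off = config.codon_offset
    base[off : off + 3] = list("GGG")  # glycine codon in both wild types
    gene_a = base.copy()
    transgene = base.copy()
    transgene[off] = "A"  # AGG = arginine
    gene_b = base.copy()
    for delta in (-6, 8):
        p = off + delta
        current = gene_b[p]
        gene_b[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[current]
    return "".join(transgene), "".join(gene_a), "".join(gene_b)


@dataclass
class RnaSimResult:
    gene_models: list                 # GeneModel objects
    reads: dict                       # sample -> list[ReadInterval]
    allele_reads: dict                # sample -> list[str]
    allele_sequences: tuple           # (G34R, geneA_WT, geneB_WT)
    truth: TruthRecord


def simulate_rnaseq_alleles(config: RnaSimConfig, seed: int) -> RnaSimResult:
    """Stranded expression reads for WT/mutant plus codon-spanning allele reads.

    Per-gene read counts are Poisson(depth x expression); set genes have
    their mutant expression multiplied by ``set_effect``.  Allele reads are
    error-injected substrings of the three CDS at the configured mixture,
    deduplicated and then re-duplicated exactly ``n_planted_duplicates``
    times so the collapse count is known.
    """
    rng = np.random.default_rng(seed)

    # gene models: single- and two-exon genes laid end to end
    genes = []
    slot = config.chrom_size // config.n_genes
    lo, hi = config.gene_length_range
    for k in range(config.n_genes):
        length = int(rng.integers(lo, min(hi, slot - 200) + 1))
        start = k * slot + 100
        strand = "+" if rng.random() < 0.5 else "-"
        if length > 2_000 and rng.random() < 0.5:
            third = length // 3
            exons = [(start, start + third), (start + 2 * third, start + length)]
        else:
            exons = [(start, start + length)]
        genes.append(GeneModel(f"gene{k}", config.chrom, strand, exons))

    set_genes = sorted(
        f"gene{i}" for i in rng.choice(config.n_genes, size=config.n_set_genes, replace=False)
    )
    set_lookup = set(set_genes)
    expression = np.exp(
        rng.normal(config.expression_log_mean, config.expression_log_sigma, config.n_genes)
    )

    reads: dict = {"WT": [], "G34R": []}
    true_counts: dict = {"WT": {}, "G34R": {}}
    for sample in ("WT", "G34R"):
        for g, level in zip(genes, expression):
            eff = level
            if sample == "G34R" and g.gene_id in set_lookup:
                eff = level * config.set_effect
            n = int(rng.poisson(config.depth * eff * g.union_exon_length))
            true_counts[sample][g.gene_id] = n
            if n == 0:
                continue
            # draw 5' starts uniformly over union-exon positions
            offsets = rng.integers(0, g.union_exon_length, size=n)
            read_strand = {"+": "-", "-": "+"}[g.strand]  # reverse-stranded protocol
            for o in offsets:
                pos = None
                rem = int(o)
                for s, e in g.exons:
                    if rem < e - s:
                        pos = s + rem
                        break
                    rem -= e - s
                if read_strand == "+":
                    iv = (pos, min(pos + config.read_length, config.chrom_size))
                else:
                    iv = (max(0, pos - config.read_length + 1), pos + 1)
                reads[sample].append(ReadInterval(config.chrom, iv[0], iv[1], read_strand))

    seqs = build_allele_sequences(config, rng)
    from oncomark.transcriptome import AlleleLibrary

    _library = AlleleLibrary(
        names=ALLELE_NAMES, sequences=seqs, codon_offset=config.codon_offset
    )
    L = config.cds_length
    rl = config.read_length
    allele_reads: dict = {}
    allele_truth: dict = {}
    for sample in ("WT", "G34R"):
        props = np.asarray(config.allele_proportions, dtype=float)
        if sample == "WT":
            # the parental line carries no transgene
            props = np.array([0.0, props[1], props[2]])
            props = props / props.sum()
        picks = rng.choice(3, size=config.n_allele_reads, p=props)
        diag = _library.diagnostic_positions
        codon = range(config.codon_offset, config.codon_offset + 3)
        raw = []
        origins = []
        starts = []
        for a in picks:
            start = int(rng.integers(0, L - rl + 1))
            seq = list(seqs[a][start : start + rl])
            if config.per_base_error > 0:
                errs = np.flatnonzero(rng.random(rl) < config.per_base_error)
                for p in errs:
                    choices = [b for b in "ACGT" if b != seq[p]]
                    seq[p] = choices[int(rng.integers(0, 3))]
            raw.append("".join(seq))
            origins.append(ALLELE_NAMES[a])
            starts.append(start)
        uniq = list(dict.fromkeys(raw))
        uniq_meta: dict = {}
        for r, o, s in zip(raw, origins, starts):
            uniq_meta.setdefault(r, (o, s))
        n_dup = min(config.n_planted_duplicates, len(uniq))
        dup_idx = rng.choice(len(uniq), size=n_dup, replace=False)
        final = uniq + [uniq[i] for i in dup_idx]
        allele_reads[sample] = final
        allele_truth[sample] = {
            "origins": [uniq_meta[r][0] for r in uniq],
            "starts": [uniq_meta[r][1] for r in uniq],
            # a read can be informative only if its placement covers the
            # diagnostic codon and every diagnostic position
            "covers_diagnostics": [
                all(
                    uniq_meta[r][1] <= p < uniq_meta[r][1] + rl
                    for p in (*diag, *codon)
                )
                for r in uniq
            ],
            "n_planted_duplicates": int(n_dup),
            "proportions": props.tolist(),
            "n_picks": {
                name: int((picks == i).sum()) for i, name in enumerate(ALLELE_NAMES)
            },
        }

    truth = TruthRecord(
        kind="rnaseq",
        payload={
            "expression": {g.gene_id: float(x) for g, x in zip(genes, expression)},
            "set_genes": set_genes,
            "set_effect": config.set_effect,
            "true_counts": true_counts,
            "alleles": allele_truth,
            "config": dataclasses.asdict(config),
            "seed": seed,
        },
    )
    return RnaSimResult(
        gene_models=genes,
        reads=reads,
        allele_reads=allele_reads,
        allele_sequences=seqs,
        truth=truth,
    )


# ==========================================================================
# spectrum simulation


@dataclass
class SpectrumSimConfig:
    base_mz: float = 2000.0
    n_states: int = 4
    abundances: tuple = (0.1, 0.2, 0.3, 0.4)
    peak_width_da: float = 0.25
    noise_sigma: float = 0.005        # relative to the tallest peak
    mz_range: tuple = (1200.0, 3500.0)
    mz_step: float = 0.05
    peak_scale: float = 1000.0

    def __post_init__(self) -> None:
        if len(self.abundances) != self.n_states:
            raise InvalidInputError("abundances must match n_states")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise InvalidInputError("abundances must sum to 1")
        if self.peak_width_da <= 0 or self.mz_step <= 0:
            raise InvalidInputError("peak width and mz step must be positive")


def simulate_spectrum(config: SpectrumSimConfig, seed: int):
    """Gaussian peaks at the methyl-ladder masses plus baseline noise."""
    from oncomark.methylspec import Spectrum, methyl_mass_series

    rng = np.random.default_rng(seed)
    series = methyl_mass_series(config.base_mz, config.n_states)
    lo, hi = config.mz_range
    mz = np.arange(lo, hi + config.mz_step / 2, config.mz_step)
    intensity = np.zeros_like(mz)
    for state_mz, ab in zip(series.states, config.abundances):
        intensity += (
            config.peak_scale
            * ab
            * np.exp(-0.5 * ((mz - state_mz) / config.peak_width_da) ** 2)
        )
    if config.noise_sigma > 0:
        scale = config.noise_sigma * config.peak_scale * max(config.abundances)
        intensity = np.clip(intensity + rng.normal(0, scale, mz.size), 0, None)
    spectrum = Spectrum(mz=mz, intensity=intensity, window=config.mz_range)
    truth = TruthRecord(
        kind="spectrum",
        payload={
            "abundances": list(config.abundances),
            "series": list(series.states),
            "config": dataclasses.asdict(config),
            "seed": seed,
        },
    )
    return spectrum, truth
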