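"""End-to-end orchestration: simulate -> quantitate -> call -> compare.

A single YAML/dict config drives three independent branches (chipseq,
rnaseq, spectrum).  A failing branch does not abort the others; the run
report records per-stage record counts and per-branch status, and the run
id is a hash of the canonical config so reruns are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from oncomark import __version__
from oncomark.coverage import bin_genome, count_reads, match_distributions, normalize_per_million
from oncomark.differential import (
    FoldChangeConfig,
    classify_fold_changes,
    harmonize_cohorts,
    mirror_comparison,
)
from oncomark.errors import InvalidInputError
from oncomark.methylspec import assign_methyl_states, methyl_mass_series
from oncomark.region_calling import (
    EnrichmentConfig,
    classify_by_factor,
    merge_and_filter,
    region_track_score,
    scaled_region_matrix,
    select_enriched_genic_bins,
)
from oncomark.synthetic_data import (
    ChipSimConfig,
    RnaSimConfig,
    SpectrumSimConfig,
    simulate_chipseq,
    simulate_rnaseq_alleles,
    simulate_spectrum,
)
from oncomark.transcriptome import (
    ALLELE_NAMES_DEFAULT,
    AlleleLibrary,
    classify_codon_reads,
    gene_set_log_ratio,
    quantify_rpkm,
)
from oncomark import io as omio

log = logging.getLogger("oncomark")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "branches": ["chipseq", "rnaseq", "spectrum"],
    "chipseq": {
        "sim": {},             # ChipSimConfig overrides
        "enrichment": {},      # EnrichmentConfig overrides
        "fold_change": {},     # FoldChangeConfig overrides
        "body_length": 500,
        "flank": 1000,
    },
    "rnaseq": {
        "sim": {},             # RnaSimConfig overrides
        "strandedness": "reverse",
        "control_seed": 0,
    },
    "spectrum": {
        "sim": {},             # SpectrumSimConfig overrides
        "tolerance_ppm": 200.0,
    },
}


def _merge_config(user: dict | None) -> dict:
    def merge(base, over, path=""):
        out = dict(base)
        for key, val in (over or {}).items():
            if key not in base:
                raise InvalidInputError(f"unknown config key {path + key!r}")
            if isinstance(base[key], dict) and key not in ("sim", "enrichment", "fold_change"):
                out[key] = merge(base[key], val, path + key + ".")
            else:
                out[key] = val
        return out

    return merge(DEFAULT_CONFIG, user or {})


def _dataclass_from(cls, overrides: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - valid
    if unknown:
        raise InvalidInputError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {}
    for k, v in overrides.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    return cls(**coerced)


@dataclass
class PipelineRun:
    run_id: str
    version: str
    config: dict
    stage_counts: dict = field(default_factory=dict)
    branch_status: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    input_checksums: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)

    @property
    def failed(self) -> bool:
        return any(s != "ok" for s in self.branch_status.values())


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _run_chipseq(cfg: dict, seed: int, outdir: Path, run: PipelineRun) -> None:
    sim_cfg = _dataclass_from(ChipSimConfig, cfg["sim"])
    enr_cfg = _dataclass_from(EnrichmentConfig, cfg["enrichment"])
    fc_cfg = _dataclass_from(FoldChangeConfig, cfg["fold_change"])
    sim = simulate_chipseq(sim_cfg, seed)

    grid = bin_genome(sim_cfg.chrom_sizes, sim_cfg.bin_width)
    wt = count_reads(sim.reads_wt, grid, sample_id="WT")
    mut = count_reads(sim.reads_mut, grid, sample_id="mutant")
    factor = count_reads(sim.reads_factor, grid, sample_id="factor")
    wt_m, mut_m = match_distributions(normalize_per_million(wt), normalize_per_million(mut))
    factor_pm = normalize_per_million(factor)

    genes = [(c, s, e) for c, s, e, _ in sim.genes]
    bins = select_enriched_genic_bins(wt_m, mut_m, genes, enr_cfg)
    regions = merge_and_filter(bins, enr_cfg)
    run.stage_counts["chipseq"] = {
        "reads_wt": wt.total_reads,
        "reads_mut": mut.total_reads,
        "bins_selected": len(bins),
        "regions_merged": len(regions) + len(regions.excluded),
        "regions_excluded_length": sum(1 for _, r in regions.excluded if r == "length"),
        "regions_excluded_extreme": sum(1 for _, r in regions.excluded if r == "extreme"),
        "regions_called": len(regions),
    }

    omio.write_bedgraph(wt_m, outdir / "wt.matched.bedgraph", header=f"run_id={run.run_id}")
    omio.write_bedgraph(mut_m, outdir / "mutant.matched.bedgraph", header=f"run_id={run.run_id}")
    omio.write_regions(regions, outdir / "regions.bed", outdir / "regions.tsv")
    (outdir / "chipseq.truth.json").write_text(sim.truth.to_json(indent=2))

    if len(regions) >= 4:
        classification = classify_by_factor(regions, factor_pm, enr_cfg, factor_id="factor")
        with open(outdir / "factor_classes.tsv", "w") as fh:
            fh.write(f"# run_id={run.run_id}\nregion_id\tchrom\tstart\tend\tfactor_score\tlabel\n")
            for i, (reg, lab, sc) in enumerate(
                zip(regions, classification.labels, classification.scores)
            ):
                fh.write(f"region{i}\t{reg.chrom}\t{reg.start}\t{reg.end}\t{sc:.6g}\t{lab}\n")
        run.stage_counts["chipseq"]["regions_factor_enriched"] = int(
            (classification.labels == "enriched").sum()
        )

        profile = scaled_region_matrix(
            regions, mut_m, body_length=cfg["body_length"], flank=cfg["flank"],
            blacklist=sim.blacklist,
        )
        np.savetxt(
            outdir / "profile_matrix.tsv", profile.matrix, delimiter="\t",
            header=f"run_id={run.run_id} flank_cols={profile.n_flank_cols} body_cols={profile.n_body_cols}",
        )

        # fold-change comparison of the matched tracks over called regions
        wt_scores = [region_track_score(r, wt_m) for r in regions]
        mut_scores = [region_track_score(r, mut_m) for r in regions]
        harmonized, keep = harmonize_cohorts(regions, wt_scores, mut_scores, fc_cfg)
        calls = classify_fold_changes(
            [s for s, k in zip(wt_scores, keep) if k],
            [s for s, k in zip(mut_scores, keep) if k],
            fc_cfg,
        )
        mirror = mirror_comparison(
            calls,
            [s for s, k in zip(wt_scores, keep) if k],
            [s for s, k in zip(mut_scores, keep) if k],
        )
        with open(outdir / "fold_change.tsv", "w") as fh:
            fh.write(f"# run_id={run.run_id}\nregion_id\tchrom\tstart\tend\twt\tmut\tratio\tlabel\n")
            kept_regions = list(harmonized)
            kept_wt = [s for s, k in zip(wt_scores, keep) if k]
            kept_mut = [s for s, k in zip(mut_scores, keep) if k]
            for i, (reg, w_, m_, call) in enumerate(zip(kept_regions, kept_wt, kept_mut, calls)):
                fh.write(
                    f"region{i}\t{reg.chrom}\t{reg.start}\t{reg.end}"
                    f"\t{w_:.6g}\t{m_:.6g}\t{call.ratio:.6g}\t{call.label}\n"
                )
        run.stage_counts["chipseq"]["regions_harmonized"] = len(harmonized)
        run.stage_counts["chipseq"]["mirror_labels"] = {
            k: v["n"] for k, v in mirror.items()
        }
    run.outputs.extend(
        str(outdir / f)
        for f in (
            "wt.matched.bedgraph", "mutant.matched.bedgraph", "regions.bed",
            "regions.tsv", "chipseq.truth.json",
        )
    )


def _run_rnaseq(cfg: dict, seed: int, outdir: Path, run: PipelineRun) -> None:
    sim_cfg = _dataclass_from(RnaSimConfig, cfg["sim"])
    sim = simulate_rnaseq_alleles(sim_cfg, seed)

    table = quantify_rpkm(sim.reads, sim.gene_models, strandedness=cfg["strandedness"])
    table.rpkm.to_csv(outdir / "rpkm.tsv", sep="\t")
    omio.write_bed12_genes(sim.gene_models, outdir / "genes.bed12")
    omio.write_fasta(
        dict(zip(ALLELE_NAMES_DEFAULT, sim.allele_sequences)), outdir / "alleles.fasta"
    )
    (outdir / "rnaseq.truth.json").write_text(sim.truth.to_json(indent=2))

    set_genes = sim.truth.payload["set_genes"]
    comparison = gene_set_log_ratio(
        table, set_genes, ("WT", "G34R"), seed=cfg["control_seed"]
    )
    comparison.set_ratios.to_csv(outdir / "geneset_log2.tsv", sep="\t", header=["log2_ratio"])
    comparison.control_ratios.to_csv(
        outdir / "geneset_control_log2.tsv", sep="\t", header=["log2_ratio"]
    )

    library = AlleleLibrary(
        names=ALLELE_NAMES_DEFAULT,
        sequences=sim.allele_sequences,
        codon_offset=sim_cfg.codon_offset,
    )
    allele_counts = {}
    for sample, reads in sim.allele_reads.items():
        summary = classify_codon_reads(reads, library)
        allele_counts[sample] = {
            **summary.counts,
            "n_duplicates_removed": summary.n_duplicates_removed,
        }
    (outdir / "allele_calls.json").write_text(json.dumps(allele_counts, indent=2, sort_keys=True))

    run.stage_counts["rnaseq"] = {
        "genes_quantified": int(len(table.genes)),
        "set_genes_compared": int(comparison.set_ratios.size),
        "allele_reads_classified": {
            s: sum(v for k, v in c.items() if k != "n_duplicates_removed")
            for s, c in allele_counts.items()
        },
    }
    run.outputs.extend(
        str(outdir / f)
        for f in (
            "rpkm.tsv", "genes.bed12", "alleles.fasta", "geneset_log2.tsv",
            "geneset_control_log2.tsv", "allele_calls.json", "rnaseq.truth.json",
        )
    )


def _run_spectrum(cfg: dict, seed: int, outdir: Path, run: PipelineRun) -> None:
    sim_cfg = _dataclass_from(SpectrumSimConfig, cfg["sim"])
    spectrum, truth = simulate_spectrum(sim_cfg, seed)
    omio.write_spectrum_csv(spectrum, outdir / "spectrum.csv")
    (outdir / "spectrum.truth.json").write_text(truth.to_json(indent=2))

    series = methyl_mass_series(sim_cfg.base_mz, sim_cfg.n_states)
    profile = assign_methyl_states(spectrum, series, tolerance_ppm=cfg["tolerance_ppm"])
    with open(outdir / "methyl_profile.tsv", "w") as fh:
        fh.write(f"# run_id={run.run_id}\nstate\texpected_mz\tabundance\tmatched_mz\tmass_error_ppm\n")
        for k in range(sim_cfg.n_states):
            fh.write(
                f"me{k}\t{series.states[k]:.4f}\t{profile.abundances[k]:.6f}"
                f"\t{profile.matched_mz[k]:.4f}\t{profile.mass_error_ppm[k]:.2f}\n"
            )
    run.stage_counts["spectrum"] = {
        "states_matched": int(np.sum(~np.isnan(profile.matched_mz))),
    }
    run.outputs.extend(
        str(outdir / f)
        for f in ("spectrum.csv", "spectrum.truth.json", "methyl_profile.tsv")
    )


_BRANCHES = {"chipseq": _run_chipseq, "rnaseq": _run_rnaseq, "spectrum": _run_spectrum}


def run_pipeline(config: dict | None, outdir) -> PipelineRun:
    """Execute all requested branches; a failure in one does not stop others."""
    config = _merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_id = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    run = PipelineRun(run_id=run_id, version=__version__, config=config)
    seed = int(config["seed"])
    for branch in config["branches"]:
        if branch not in _BRANCHES:
            raise InvalidInputError(f"unknown pipeline branch {branch!r}")
    # validate every sub-config before any stage runs so a bad key fails fast
    _dataclass_from(ChipSimConfig, config["chipseq"]["sim"])
    _dataclass_from(EnrichmentConfig, config["chipseq"]["enrichment"])
    _dataclass_from(FoldChangeConfig, config["chipseq"]["fold_change"])
    _dataclass_from(RnaSimConfig, config["rnaseq"]["sim"])
    _dataclass_from(SpectrumSimConfig, config["spectrum"]["sim"])
    for branch in config["branches"]:
        branch_dir = outdir / branch
        branch_dir.mkdir(exist_ok=True)
        try:
            _BRANCHES[branch](config[branch], seed, branch_dir, run)
            run.branch_status[branch] = "ok"
        except Exception as exc:  # noqa: BLE001 - independent branches must continue
            log.error("branch %s failed: %s", branch, exc)
            log.debug("%s", traceback.format_exc())
            run.branch_status[branch] = f"failed: {exc}"
    for out in run.outputs:
        p = Path(out)
        if p.exists():
            run.input_checksums[p.name] = _sha256(p)
    (outdir / "run_report.json").write_text(run.to_json())
    return run
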