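"""End-to-end orchestration: simulate -> filter -> map -> count -> qc -> de -> cluster.

Every stage reads and writes plain-text files under the run directory, so a
run is resumable: with ``resume=True`` a stage whose outputs already exist
is skipped. The resolved configuration is written next to the outputs, and
a JSON manifest accumulates per-stage read accounting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import clustering, counting, diffexpr, mapping, qc, regions, simulate
from .colorspace import filter_low_information, read_csfasta_batch, write_csfasta
from .reference import concatenate_reference, read_fasta

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs; the defaults are the method's published constants."""

    outdir: str = "fivedge_run"
    # inputs; empty genome path means the simulate stage generates them
    genome_fasta: str = ""
    gff3: str = ""
    sample_sheet: str = ""
    # simulation
    n_scaffolds: int = 2
    n_genes: int = 60
    depth: int = 100_000
    n_timepoints: int = 6
    n_replicates: int = 3
    n_patterns: int = 3
    fraction_null: float = 0.5
    color_error_rate: float = simulate.DEFAULT_COLOR_ERROR_RATE
    seed: int = 0
    # mapping and filtering
    tag_length: int = 25
    max_mismatches: int = 2
    low_info_threshold: int = 3
    # counting
    five_ext: int = regions.FIVE_EXT_BP
    three_ext: int = regions.THREE_EXT_BP
    gap_threshold: int = regions.GAP_THRESHOLD_BP
    strand_convention: str = "antisense"
    # statistics
    fdr: float = diffexpr.DEFAULT_FDR
    pseudo: float = diffexpr.DEFAULT_PSEUDO
    anova_method: str = diffexpr.DEFAULT_METHOD
    min_tpm: float = 1.0
    som_rows: int = 3
    som_cols: int = 3
    som_iterations: int = clustering.DEFAULT_ITERATIONS

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, resume: bool = False) -> Path:
    """Run all stages; returns the run directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"stages": {}}
    stages = [
        ("simulate", _stage_simulate),
        ("filter", _stage_filter),
        ("map", _stage_map),
        ("count", _stage_count),
        ("qc", _stage_qc),
        ("de", _stage_de),
        ("cluster", _stage_cluster),
    ]
    for name, fn in stages:
        marker = out / f".done_{name}"
        if resume and marker.exists():
            logger.info("stage %s: outputs present, skipping", name)
            continue
        try:
            info = fn(config, out)
        except Exception as exc:
            raise StageError(name, exc) from exc
        manifest["stages"][name] = info or {}
        marker.write_text("done\n")
        logger.info("stage %s: done", name)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def _samples(config: RunConfig, out: Path) -> pd.DataFrame:
    sheet = out / "sample_sheet.tsv"
    if config.sample_sheet:
        sheet = Path(config.sample_sheet)
    return pd.read_csv(sheet, sep="\t")


def _stage_simulate(config: RunConfig, out: Path) -> dict:
    if config.genome_fasta:  # externally supplied inputs; nothing to do
        return {"skipped": "external inputs provided"}
    genome, models = simulate.make_toy_genome(
        config.n_scaffolds, config.n_genes, seed=config.seed
    )
    genome.write_fasta(out / "genome.fa")
    regions.write_gff3(models, out / "genes.gff3")
    truth = simulate.assign_expression_profiles(
        models,
        n_timepoints=config.n_timepoints,
        n_patterns=config.n_patterns,
        fraction_null=config.fraction_null,
        seed=config.seed + 1,
    )
    truth.write_tsv(out / "truth_tpm.tsv")
    sheet = simulate.write_sample_sheet(
        truth.timepoints, config.n_replicates, out / "sample_sheet.tsv"
    )
    params = simulate.LibraryParams(
        depth=config.depth,
        tag_length=config.tag_length,
        color_error_rate=config.color_error_rate,
    )
    n_reads = {}
    for i, row in sheet.iterrows():
        batch, truth_hits = simulate.simulate_tags(
            genome, models, truth, params,
            sample_id=row["sample"], timepoint=row["timepoint"],
            seed=config.seed + 100 + i,
        )
        write_csfasta(batch, out / f"reads_{row['sample']}.csfasta")
        truth_hits.to_csv(out / f"truth_hits_{row['sample']}.tsv", sep="\t", index=False)
        n_reads[row["sample"]] = len(batch)
    return {"reads_per_sample": n_reads}


def _stage_filter(config: RunConfig, out: Path) -> dict:
    info = {}
    for _, row in _samples(config, out).iterrows():
        sample = row["sample"]
        batch = read_csfasta_batch(out / f"reads_{sample}.csfasta")
        kept, _, report = filter_low_information(batch, config.low_info_threshold)
        write_csfasta(kept, out / f"filtered_{sample}.csfasta")
        info[sample] = {
            "total": report.total,
            "removed": report.removed,
            "removed_fraction": round(report.removed_fraction, 5),
        }
    return info


def _stage_map(config: RunConfig, out: Path) -> dict:
    fasta = Path(config.genome_fasta) if config.genome_fasta else out / "genome.fa"
    reference = concatenate_reference(read_fasta(fasta))
    index = mapping.ColorIndex(reference, config.tag_length, config.max_mismatches)
    info = {}
    for _, row in _samples(config, out).iterrows():
        sample = row["sample"]
        batch = read_csfasta_batch(out / f"filtered_{sample}.csfasta")
        hits = mapping.map_reads(batch, index)
        mapping.write_hits_tsv(hits, batch, reference, out / f"hits_{sample}.tsv")
        n_best_unique = _count_unique(hits)
        info[sample] = {
            "reads": len(batch),
            "mapped": hits.mapped_read_count,
            "unique": n_best_unique,
        }
    return info


def _count_unique(hits: mapping.MapHits) -> int:
    if len(hits) == 0:
        return 0
    ri = hits.read_index
    new_seg = np.diff(ri, prepend=ri[0] - 1) != 0
    starts = np.flatnonzero(new_seg)
    seg_min = np.minimum.reduceat(hits.mismatches, starts)
    seg_id = np.cumsum(new_seg) - 1
    n_best = np.add.reduceat(
        (hits.mismatches == seg_min[seg_id]).astype(np.int64), starts
    )
    return int((n_best == 1).sum())


def _load_hits(path: Path, reference) -> mapping.MapHits:
    df = pd.read_csv(path, sep="\t", comment="#")
    codes, uniques = pd.factorize(df["read_id"], sort=False)
    gpos = np.array(
        [reference.to_global(s, p) for s, p in zip(df["scaffold"], df["position"])],
        dtype=np.int64,
    )
    order = np.argsort(codes, kind="stable")
    return mapping.MapHits(
        codes[order].astype(np.int64),
        gpos[order],
        (df["strand"].to_numpy() == "-")[order].astype(np.uint8),
        df["mismatches"].to_numpy()[order].astype(np.uint8),
        n_reads=len(uniques),
        tag_length=25,
    )


def _stage_count(config: RunConfig, out: Path) -> dict:
    fasta = Path(config.genome_fasta) if config.genome_fasta else out / "genome.fa"
    gff = Path(config.gff3) if config.gff3 else out / "genes.gff3"
    reference = concatenate_reference(read_fasta(fasta))
    models = regions.parse_gff3(gff)
    ext = regions.extend_gene_models(
        models, reference.lengths,
        five_ext=config.five_ext, three_ext=config.three_ext,
        gap_threshold=config.gap_threshold,
    )
    regions.write_regions_bed(ext, out / "extended_regions.bed")
    regions.write_extension_audit(ext, out / "extension_audit.tsv")
    table = counting.CountTable.empty([m.gene_id for m in models])
    for _, row in _samples(config, out).iterrows():
        sample = row["sample"]
        hits = _load_hits(out / f"hits_{sample}.tsv", reference)
        hits.tag_length = config.tag_length
        tags = counting.accumulate_tags(
            hits, reference.lengths, mode="fractional", reference=reference,
            tag_length=config.tag_length,
        )
        table.add_sample(sample, tags, ext, config.strand_convention)
    table.write_tsv(out / "count_table.tsv")
    return {"n_genes": len(models), "n_samples": len(table.total_mapped)}


def _stage_qc(config: RunConfig, out: Path) -> dict:
    counts, tpm = counting.CountTable.read_tsv(out / "count_table.tsv")
    sheet = _samples(config, out)
    gff = Path(config.gff3) if config.gff3 else out / "genes.gff3"
    models = regions.parse_gff3(gff)
    rows = []
    by_tp = sheet.groupby("timepoint")["sample"].apply(list)
    for tp, samples in by_tp.items():
        for a, b in zip(samples, samples[1:]):
            try:
                r2 = qc.replicate_correlation(tpm, a, b, min_tpm=config.min_tpm)
            except ValueError:
                r2 = float("nan")
            rows.append({"timepoint": tp, "sample_a": a, "sample_b": b, "r2": r2})
    pd.DataFrame(rows).to_csv(out / "replicate_r2.tsv", sep="\t", index=False)
    first = sheet["sample"].iloc[0]
    qc.length_vs_tpm(models, tpm[first], bin_size_genes=max(len(models) // 3, 1)).to_csv(
        out / "length_vs_tpm.tsv", sep="\t"
    )
    return {"n_replicate_pairs": len(rows)}


def _stage_de(config: RunConfig, out: Path) -> dict:
    _, tpm = counting.CountTable.read_tsv(out / "count_table.tsv")
    sheet = _samples(config, out)
    times = dict(zip(sheet["sample"], sheet["timepoint"]))
    result = diffexpr.de_pipeline(
        tpm, times, fdr=config.fdr, pseudo=config.pseudo, method=config.anova_method
    )
    with open(out / "de_results.tsv", "w") as fh:
        fh.write(f"# {result.method} ANOVA across time points, BH FDR {config.fdr}\n")
        result.table.to_csv(fh, sep="\t")
    result.normalized.to_csv(out / "normalized_tpm.tsv", sep="\t")
    return {
        "n_tested": len(result.table),
        "n_significant": int(result.table["significant"].sum()),
        "n_excluded_zero_median": len(result.excluded),
    }


def _stage_cluster(config: RunConfig, out: Path) -> dict:
    de_table = pd.read_csv(out / "de_results.tsv", sep="\t", comment="#", index_col=0)
    normalized = pd.read_csv(out / "normalized_tpm.tsv", sep="\t", index_col=0)
    sheet = _samples(config, out)
    times = dict(zip(sheet["sample"], sheet["timepoint"]))
    sig = de_table.index[de_table["significant"].astype(bool)]
    logged = diffexpr.log_transform(normalized, config.pseudo)
    profiles = diffexpr.mean_profiles_by_timepoint(logged, times)
    n_nodes = config.som_rows * config.som_cols
    info: dict = {"n_significant": len(sig)}
    if len(sig) >= n_nodes:
        som = clustering.som_cluster(
            profiles.loc[sig],
            shape=(config.som_rows, config.som_cols),
            n_iterations=config.som_iterations,
            seed=config.seed,
        )
        som.write_tsv(out / "som_assignments.tsv", out / "som_codebook.tsv")
        clustering.cluster_report(som, profiles.loc[sig]).to_csv(
            out / "som_report.tsv", sep="\t"
        )
        info["som"] = "som_assignments.tsv"
    else:
        logger.warning("only %d significant genes; SOM skipped", len(sig))
    if len(sig) >= 2:
        clustering.build_tree(profiles.loc[sig], axis="genes").write_newick(
            out / "gene_tree.nwk"
        )
    clustering.build_tree(profiles, axis="conditions").write_newick(
        out / "condition_tree.nwk"
    )
    return info
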