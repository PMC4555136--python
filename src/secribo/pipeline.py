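"""End-to-end orchestration: simulate/load -> process -> QC -> quantify -> DE.

A run is described by a :class:`RunConfig` (constructible from YAML).  Two
input modes exist:

``simulate``
    generate footprint (and optionally RNA) libraries from the bundled
    selenoprotein panel or a user :class:`~secribo.simulate.SimulationConfig`;
``files``
    process existing FASTQ or transcript-space SAM/BAM against a reference
    FASTA + annotation TSV.

Every stage logs input/output read counts into a conservation ledger, and
the run writes a manifest with the configuration echo so results are
reproducible byte-for-byte for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import default_panel_config
from .diffexpr import CountTable, de_analysis, replicate_correlation, top_table
from .profiling import (
    PeriodicityError,
    apply_offset,
    infer_asite_offset,
    metagene_profile,
    phasing_table,
)
from .quant import fold_change_table, quantify_sample, readthrough_table
from .readproc import (
    FOOTPRINT_RANGE,
    ReferenceIndex,
    align_unique,
    alignments_to_frame,
    filter_rrna,
    trim_reads,
)
from .simulate import (
    SampleReads,
    SimulationConfig,
    simulate_sample_footprints,
    simulate_sample_rnaseq,
    synthetic_rrna,
    write_fastq,
)
from .transcriptome import TranscriptModel, load_transcripts, windows_table

log = logging.getLogger("secribo")


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    outdir: str = "secribo_run"
    seed: int = 1
    mode: str = "simulate"            # "simulate" | "files"
    library_size: int = 1_000_000
    run_rnaseq: bool = True
    offset: int | str = "infer"       # nt, or "infer" from the metagene
    which_sec: int | None = None      # Sec codon for 5'/3' splitting
    min_window_count: int = 100       # coverage floor for fold-change tables
    de_min_cpm: float = 1.0
    de_min_samples: int = 3
    de_fold_threshold: float = 1.5
    de_fdr_threshold: float = 0.05
    keep_fastq: bool = False
    numerator: str = "0.1Se"
    denominator: str = "0Se"
    # files mode
    fasta: str | None = None
    annotation: str | None = None
    rrna_fasta: str | None = None
    samples: list[dict] = field(default_factory=list)
    # simulate-mode overrides (rrna_fraction, phasing_fidelity, ...)
    sim_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        from dataclasses import asdict
        return asdict(self)


@dataclass
class PipelineResult:
    config: RunConfig
    transcripts: list[TranscriptModel]
    sample_conditions: dict[str, str]
    stats: pd.DataFrame
    offset_used: int
    metagene_start: pd.Series
    phasing: pd.DataFrame
    quants: pd.DataFrame                 # all samples, all windows
    folds: dict[str, pd.DataFrame]       # per (kind, window) fold tables
    readthrough: pd.DataFrame
    counts: dict[str, CountTable]
    de: dict[str, pd.DataFrame]
    replicate_r2: dict[str, pd.DataFrame]
    truth: pd.DataFrame | None
    manifest: dict


def _read_fastq(path: str | Path) -> list[str]:
    import pysam
    with pysam.FastxFile(str(path)) as fh:
        return [rec.sequence for rec in fh]


def _load_rrna(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO
    return [(rec.id, str(rec.seq).upper().replace("U", "T"))
            for rec in SeqIO.parse(str(path), "fasta")]


def _gather_samples(config: RunConfig,
                    sim: SimulationConfig | None) -> list[SampleReads]:
    """Produce in-memory read sets for every sample of the design."""
    if config.mode == "simulate":
        assert sim is not None
        samples = []
        for ci in range(len(sim.conditions)):
            for rep in range(1, sim.replicates + 1):
                samples.append(simulate_sample_footprints(sim, ci, rep))
                if config.run_rnaseq:
                    samples.append(simulate_sample_rnaseq(sim, ci, rep))
        return samples
    out = []
    for entry in config.samples:
        sid = entry["sample_id"]
        reads = _read_fastq(entry["fastq"]) if "fastq" in entry else []
        out.append(SampleReads(sid, entry.get("kind", "fp"),
                               entry["condition"],
                               int(entry.get("replicate", 1)),
                               reads, pd.DataFrame()))
    return out


def run_pipeline(config: RunConfig,
                 sim_config: SimulationConfig | None = None
                 ) -> PipelineResult:
    """Execute the full chain and write all result tables under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        return _run(config, sim_config, outdir)
    except Exception as exc:  # annotate failures with the failing stage
        stage = getattr(exc, "_secribo_stage", stage)
        manifest = {"status": "failed", "stage": str(stage),
                    "error": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise


def _run(config: RunConfig, sim_config: SimulationConfig | None,
         outdir: Path) -> PipelineResult:
    # --- reference -------------------------------------------------------
    truth = None
    if config.mode == "simulate":
        if sim_config is None:
            sim_config = default_panel_config(
                seed=config.seed, library_size=config.library_size,
                **config.sim_overrides)
        sim_config.validate()
        transcripts = sim_config.transcripts
        rrna = synthetic_rrna()
        adapter = sim_config.adapter
    else:
        if not (config.fasta and config.annotation):
            raise ValueError("files mode needs 'fasta' and 'annotation'")
        transcripts, rejected = load_transcripts(config.fasta,
                                                 config.annotation)
        for rid, reason in rejected:
            log.warning("rejected transcript %s: %s", rid, reason)
        if config.rrna_fasta is None:
            raise ValueError("files mode needs 'rrna_fasta' for depletion")
        rrna = _load_rrna(config.rrna_fasta)
        from .simulate import DEFAULT_ADAPTER
        adapter = DEFAULT_ADAPTER

    windows_table(transcripts).to_csv(outdir / "windows.tsv", sep="\t",
                                      index=False)

    # --- per-sample processing ------------------------------------------
    samples = _gather_samples(config, sim_config)
    sample_conditions = {s.sample_id: s.condition for s in samples}
    sample_kinds = {s.sample_id: s.kind for s in samples}
    index = ReferenceIndex.from_transcripts(transcripts)

    if config.mode == "simulate":
        truth = pd.concat([s.truth for s in samples], ignore_index=True)
        truth.to_csv(outdir / "sim_truth.tsv", sep="\t", index=False)
        if config.keep_fastq:
            for s in samples:
                write_fastq(s.reads, outdir / f"{s.sample_id}.fastq.gz",
                            s.sample_id)

    alignments: dict[str, list] = {}
    stat_rows = []
    for s in samples:
        log.info("processing %s (%d reads)", s.sample_id, len(s.reads))
        n_raw = len(s.reads)
        kept, n_trim_discard = trim_reads(s.reads, adapter)
        retained, n_rrna = filter_rrna(kept, rrna)
        lrange = FOOTPRINT_RANGE if s.kind == "fp" else None
        aligned, astats = align_unique(retained, transcripts, s.sample_id,
                                       length_range=lrange, index=index)
        alignments[s.sample_id] = aligned
        conserved = (n_raw == n_trim_discard + n_rrna + astats.n_input
                     - 0) and astats.conserved()
        stat_rows.append({
            "sample": s.sample_id, "kind": s.kind,
            "condition": s.condition, "replicate": s.replicate,
            "n_raw": n_raw, "n_trim_discarded": n_trim_discard,
            "n_rrna_removed": n_rrna, "n_after_filter": astats.n_input,
            "n_aligned": astats.n_aligned, "n_multi": astats.n_multi,
            "n_unaligned": astats.n_unaligned,
            "conserved": bool(conserved),
        })
    stats = pd.DataFrame(stat_rows)
    stats.to_csv(outdir / "processing_stats.tsv", sep="\t", index=False)
    for sid, al in alignments.items():
        alignments_to_frame(al).to_csv(outdir / f"alignments_{sid}.tsv.gz",
                                       sep="\t", index=False)

    # --- QC: metagene, offset, phasing ----------------------------------
    fp_ids = [sid for sid, k in sample_kinds.items() if k == "fp"]
    fp_all = [a for sid in fp_ids for a in alignments[sid]]
    metagene = metagene_profile(fp_all, transcripts, anchor="start")
    metagene.rename_axis("relative_pos").reset_index().to_csv(
        outdir / "metagene_start.tsv", sep="\t", index=False)
    if config.offset == "infer":
        try:
            offset_used = infer_asite_offset(metagene)
        except PeriodicityError:
            raise
    else:
        offset_used = int(config.offset)
    phasing = phasing_table(fp_all, transcripts)
    phasing.to_csv(outdir / "phasing.tsv", sep="\t", index=False)

    # --- quantification --------------------------------------------------
    quant_frames = []
    for s in samples:
        al = alignments[s.sample_id]
        if not al:
            log.warning("sample %s has no aligned reads", s.sample_id)
            continue
        profiles, _dropped = apply_offset(al, transcripts, offset_used)
        q = quantify_sample(profiles, transcripts, total=len(al),
                            sample_id=s.sample_id,
                            which_sec=config.which_sec)
        quant_frames.append(q)
    quants = pd.concat(quant_frames, ignore_index=True)
    quants.to_csv(outdir / "region_quant.tsv", sep="\t", index=False)

    folds: dict[str, pd.DataFrame] = {}
    for kind in sorted(set(sample_kinds.values())):
        sub = quants[quants["sample"].map(sample_kinds) == kind]
        if sub.empty or len(set(sample_conditions.values())) < 2:
            continue
        fc = fold_change_table(sub, sample_conditions,
                               numerator=config.numerator,
                               denominator=config.denominator)
        fc = _apply_coverage_rule(fc, sub, sample_conditions,
                                  config.denominator,
                                  config.min_window_count)
        folds[kind] = fc
        fc.to_csv(outdir / f"fold_changes_{kind}.tsv", sep="\t", index=False)

    fp_quants = quants[quants["sample"].map(sample_kinds) == "fp"]
    readthrough = readthrough_table(fp_quants)
    readthrough.to_csv(outdir / "readthrough.tsv", sep="\t", index=False)

    # --- differential expression -----------------------------------------
    counts: dict[str, CountTable] = {}
    de: dict[str, pd.DataFrame] = {}
    rep_r2: dict[str, pd.DataFrame] = {}
    tx_gene = {t.id: t.gene for t in transcripts}
    for kind in sorted(set(sample_kinds.values())):
        ids = [sid for sid, k in sample_kinds.items() if k == kind]
        if len(ids) < config.de_min_samples:
            continue
        mat = {}
        for sid in ids:
            counter: dict[str, int] = {}
            for a in alignments[sid]:
                g = tx_gene[a.transcript_id]
                counter[g] = counter.get(g, 0) + 1
            mat[sid] = counter
        frame = pd.DataFrame(mat).fillna(0).astype(int)
        table = CountTable(frame, {sid: sample_conditions[sid]
                                   for sid in ids})
        counts[kind] = table
        frame.to_csv(outdir / f"counts_{kind}.tsv", sep="\t")
        if len(set(sample_conditions[sid] for sid in ids)) == 2:
            res = de_analysis(table, numerator=config.numerator,
                              denominator=config.denominator,
                              min_cpm=config.de_min_cpm,
                              min_samples=config.de_min_samples,
                              fold_threshold=config.de_fold_threshold,
                              fdr_threshold=config.de_fdr_threshold)
            de[kind] = res
            res.to_csv(outdir / f"de_{kind}.tsv", sep="\t")
            rep_r2[kind] = replicate_correlation(table)
            rep_r2[kind].to_csv(outdir / f"replicate_r2_{kind}.tsv",
                                sep="\t", index=False)

    # --- manifest ---------------------------------------------------------
    cfg_dict = config.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "status": "ok",
        "secribo_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "offset_used": int(offset_used),
        "n_samples": len(samples),
        "conservation_ok": bool(stats["conserved"].all()),
        "stage_counts": stats.to_dict(orient="records"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        config=config, transcripts=transcripts,
        sample_conditions=sample_conditions, stats=stats,
        offset_used=offset_used, metagene_start=metagene, phasing=phasing,
        quants=quants, folds=folds, readthrough=readthrough, counts=counts,
        de=de, replicate_r2=rep_r2, truth=truth, manifest=manifest,
    )


def _apply_coverage_rule(fc: pd.DataFrame, quants: pd.DataFrame,
                         sample_conditions: Mapping[str, str],
                         denominator: str, min_count: int) -> pd.DataFrame:
    """Flag windows whose baseline-condition mean count is below the floor.

    RPKM ratios from a handful of counts are dominated by shot noise; the
    floor plays the role the genome-wide CPM filter plays for DE calls.
    Flagged rows stay in the table with flag ``low_coverage``.
    """
    q = quants.copy()
    q["condition"] = q["sample"].map(sample_conditions)
    base = q[q["condition"] == denominator].groupby(
        ["gene", "label"])["count"].mean()
    fc = fc.copy()
    flags = []
    for row in fc.itertuples(index=False):
        key = (row.gene, row.label)
        if row.flag == "ok" and key in base and base[key] < min_count:
            flags.append("low_coverage")
        else:
            flags.append(row.flag)
    fc["flag"] = flags
    return fc


def make_figure_tables(result: PipelineResult) -> dict[str, pd.DataFrame]:
    """Result tables in the layouts of the published figure panels.

    ``mrna_fold``: per-gene RNA-Seq CDS-core RPKM fold (mean, SD);
    ``fp_3prime_fold``: per-gene footprint 3'-of-Sec RPKM fold;
    ``top_de_<kind>``: ranked top up/down differentially expressed genes.
    Genes flagged not-analyzable or low-coverage are excluded from the fold
    panels (they remain in the full fold tables and the manifest).
    """
    out: dict[str, pd.DataFrame] = {}
    if "rna" in result.folds:
        rna = result.folds["rna"]
        sel = rna[(rna["label"] == "cds_core") & (rna["flag"] == "ok")]
        out["mrna_fold"] = sel[["gene", "fold", "fold_sd"]].reset_index(
            drop=True)
    if "fp" in result.folds:
        fp = result.folds["fp"]
        sel = fp[(fp["label"] == "three_prime_of_sec") & (fp["flag"] == "ok")]
        out["fp_3prime_fold"] = sel[["gene", "fold", "fold_sd"]].reset_index(
            drop=True)
    for kind, res in result.de.items():
        out[f"top_de_{kind}"] = top_table(res)
    return out


def write_figure_tables(result: PipelineResult,
                        outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in make_figure_tables(result).items():
        p = outdir / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=(name.startswith("top_de")))
        paths[name] = p
    return paths
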