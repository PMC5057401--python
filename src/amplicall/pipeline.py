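"""End-to-end orchestration: simulate/ingest -> demux -> align -> [correct]
-> assess -> call -> annotate -> filter -> report.

Raw and corrected analyses run as parallel branches over the same
alignments, each producing SAM, error-assessment, coverage, VCF, annotated
and report/rejected tables under ``<output_dir>/<branch>/``. A manifest
records the resolved configuration hash, seed, package version and
per-stage counts so runs can be audited (reads in = assigned + unassigned,
per-sample aligned counts, calls per branch).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .align import AlignedRead, DEFAULT_BAND, Scoring, align_reads, read_sam, write_sam
from .annotate import (
    AnnotatedVariant,
    FilterConfig,
    annotate_variants,
    apply_filters,
)
from .call import CallerConfig, VariantCall, call_variants, write_vcf
from .correct import CorrectionParams, correct_reads
from .errors import ValidationError
from .pileup import build_pileup
from .qc import (
    assess_errors,
    coverage_profile,
    coverage_to_tsv,
    error_report_to_tsv,
    length_histogram,
    length_summary,
)
from .refmodel import (
    AmpliconRef,
    read_annotation_table,
    read_gene_model,
    read_reference,
)
from .simulate import (
    DemuxRead,
    ErrorProfile,
    SampleSpec,
    SimConfig,
    SpikeVariant,
    demultiplex,
    read_fastq,
    simulate_run,
    write_fastq,
    write_truth_table,
)

logger = logging.getLogger(__name__)

BRANCHES = ("raw", "corrected")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("seed", 0)
    cfg.setdefault("branches", list(BRANCHES))
    if not cfg["branches"]:
        raise ValidationError("branches must be non-empty")
    base = Path(path).parent
    for key in ("gene_model", "annotation_table", "input_fastq"):
        if cfg.get(key):
            cfg[key] = str((base / cfg[key]).resolve()) if not Path(cfg[key]).is_absolute() else cfg[key]
    refc = cfg.get("reference", {})
    if refc.get("fasta") and not Path(refc["fasta"]).is_absolute():
        refc["fasta"] = str((base / refc["fasta"]).resolve())
    return cfg


def _sim_config(cfg: dict) -> SimConfig:
    sc = cfg["simulate"]
    err = ErrorProfile(**sc.get("error", {}))
    samples = []
    for s in sc["samples"]:
        variants = [
            SpikeVariant(
                amplicon_offset=int(v["offset"]),
                ref_allele=v.get("ref", ""),
                alt_allele=v.get("alt", ""),
                vaf=float(v["vaf"]),
            )
            for v in s.get("variants", [])
        ]
        samples.append(SampleSpec(s["id"], s.get("barcode", ""), variants))
    return SimConfig(
        samples=samples,
        n_reads=int(sc.get("n_reads", 200)),
        error=err,
        full_length_fraction=float(sc.get("full_length_fraction", 0.6)),
        fragment_min_len=int(sc.get("fragment_min_len", 150)),
        seed=int(cfg.get("seed", 0)),
    )


def load_reference(cfg: dict) -> AmpliconRef:
    refc = cfg["reference"]
    return read_reference(
        refc["fasta"], anchor=int(refc["anchor"]),
        chrom=refc.get("chrom", "chrom"), name=refc.get("name"),
    )


def scoring_from_config(cfg: dict) -> Scoring:
    a = cfg.get("align", {})
    return Scoring(
        match=a.get("match", 2), mismatch=a.get("mismatch", -3),
        gap_open=a.get("gap_open", -5), gap_extend=a.get("gap_extend", -2),
    )


def caller_from_config(cfg: dict, branch: str) -> CallerConfig:
    c = dict(cfg.get("caller", {}))
    raw_e = c.pop("baseline_error_raw", 0.15)
    corr_e = c.pop("baseline_error_corrected", 0.05)
    c.pop("baseline_error", None)
    return CallerConfig(baseline_error=raw_e if branch == "raw" else corr_e, **c)


def filters_from_config(cfg: dict) -> FilterConfig:
    f = dict(cfg.get("filters", {}))
    if "exclude_effects" in f:
        f["exclude_effects"] = frozenset(f["exclude_effects"])
    return FilterConfig(**f)


def correction_from_config(cfg: dict) -> CorrectionParams:
    return CorrectionParams(**cfg.get("correction", {}))


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _get_reads(cfg: dict, ref: AmpliconRef, outdir: Path, manifest: dict):
    """Simulate or load FASTQ; returns (reads as (id, seq), barcodes map)."""
    if cfg.get("simulate"):
        sim = _sim_config(cfg)
        sim_reads = simulate_run(ref, sim)
        write_fastq(sim_reads, outdir / "reads.fastq")
        write_truth_table(sim_reads, outdir / "truth.tsv")
        reads = [(r.read_id, r.sequence) for r in sim_reads]
        barcodes = {s.sample_id: s.barcode for s in sim.samples if s.barcode}
        manifest["counts"]["simulated_reads"] = len(reads)
        return reads, barcodes
    if not cfg.get("input_fastq"):
        raise ValidationError("config needs either a 'simulate' section or 'input_fastq'")
    reads = read_fastq(cfg["input_fastq"])
    barcodes = cfg.get("barcodes") or {}
    return reads, barcodes


def run_pipeline(config, output_dir=None) -> dict:
    """Run the full workflow; returns the manifest dict (also written).

    ``config`` is a path to a YAML file or an already-loaded dict.
    """
    if not isinstance(config, dict):
        cfg = load_config(config)
    else:
        cfg = dict(config)
        cfg.setdefault("seed", 0)
        cfg.setdefault("branches", list(BRANCHES))
    logging.basicConfig(level=getattr(logging, str(cfg.get("log_level", "INFO")).upper(), logging.INFO))
    outdir = Path(output_dir or cfg.get("output_dir", "amplicall_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.get("seed", 0),
        "version": __version__,
        "counts": {},
        "branches": {},
    }

    ref = load_reference(cfg)
    model = read_gene_model(cfg["gene_model"])
    table = read_annotation_table(cfg["annotation_table"]) if cfg.get("annotation_table") else None

    reads, barcodes = _get_reads(cfg, ref, outdir, manifest)
    manifest["counts"]["reads_in"] = len(reads)

    # ---------------------------------------------------------------- demux
    if barcodes:
        assigned, unassigned = demultiplex(reads, barcodes, int(cfg.get("demux_max_edit", 3)))
    else:
        assigned = {"sample": [DemuxRead(rid, seq, 0) for rid, seq in reads]}
        unassigned = []
    manifest["counts"]["assigned"] = sum(len(v) for v in assigned.values())
    manifest["counts"]["unassigned"] = len(unassigned)
    manifest["counts"]["per_sample_assigned"] = {k: len(v) for k, v in sorted(assigned.items())}

    summary = length_summary([r.sequence for rs in assigned.values() for r in rs])
    pd.DataFrame([asdict(summary)]).to_csv(outdir / "length_summary.tsv", sep="\t", index=False)
    length_histogram([r.sequence for rs in assigned.values() for r in rs]).to_csv(
        outdir / "length_histogram.tsv", sep="\t", index=False)

    # ---------------------------------------------------------------- align
    scoring = scoring_from_config(cfg)
    band = int(cfg.get("align", {}).get("band", DEFAULT_BAND))
    min_identity = float(cfg.get("align", {}).get("min_identity", 0.6))
    per_sample_alignments: dict[str, list[AlignedRead]] = {}
    align_stats: dict[str, dict] = {}
    for sid in sorted(assigned):
        alns, stats = align_reads(
            [(r.read_id, r.sequence) for r in assigned[sid]], ref,
            scoring=scoring, band=band, sample_id=sid, min_identity=min_identity,
        )
        per_sample_alignments[sid] = alns
        align_stats[sid] = stats
    manifest["counts"]["per_sample_aligned"] = {k: s["aligned"] for k, s in sorted(align_stats.items())}
    manifest["counts"]["mapped_total"] = sum(s["aligned"] for s in align_stats.values())

    filters = filters_from_config(cfg)
    correction = correction_from_config(cfg)

    branch_reports: dict[str, list[dict]] = {}
    for branch in cfg["branches"]:
        if branch not in BRANCHES:
            raise ValidationError(f"unknown branch {branch!r}")
        bdir = outdir / branch
        bdir.mkdir(exist_ok=True)
        if branch == "raw":
            branch_alns = per_sample_alignments
        else:
            branch_alns = {}
            for sid, alns in per_sample_alignments.items():
                pile = build_pileup(alns, ref)
                branch_alns[sid] = correct_reads(alns, pile, correction)

        all_alns = [a for alns in branch_alns.values() for a in alns]
        write_sam(all_alns, ref, bdir / "alignments.sam")
        report = assess_errors(all_alns, ref)
        error_report_to_tsv(report, bdir / "errors.tsv")
        coverage_to_tsv(coverage_profile(all_alns, ref), ref, bdir / "coverage.tsv")

        caller = caller_from_config(cfg, branch)
        calls: list[VariantCall] = []
        per_sample_annotated: dict[str, list[AnnotatedVariant]] = {}
        for sid, alns in sorted(branch_alns.items()):
            pile = build_pileup(alns, ref)
            sample_calls = call_variants(pile, caller, ref, sample_id=sid)
            calls.extend(sample_calls)
            per_sample_annotated[sid] = annotate_variants(sample_calls, model, ref, table)
        write_vcf(calls, ref, bdir / "calls.vcf")
        annotated_to_tsv(per_sample_annotated, bdir / "annotated.tsv")
        rep_rows, rej_rows = apply_filters(per_sample_annotated, filters)
        pd.DataFrame(rep_rows).to_csv(bdir / "report.tsv", sep="\t", index=False)
        pd.DataFrame(rej_rows).to_csv(bdir / "rejected.tsv", sep="\t", index=False)
        branch_reports[branch] = rep_rows
        manifest["branches"][branch] = {
            "total_per100": round(report.total_per100, 3),
            "mean_indel_event_len": round(report.mean_indel_event_len, 3),
            "n_calls": len(calls),
            "n_report_rows": len(rep_rows),
            "n_rejected_rows": len(rej_rows),
        }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return manifest


def annotated_to_tsv(per_sample: dict[str, list[AnnotatedVariant]], path) -> None:
    rows = []
    for sid in sorted(per_sample):
        for v in per_sample[sid]:
            rows.append({
                "sample": sid,
                "genomic_description": v.hgvs_g,
                "genomic_description_standard": v.hgvs_g_standard,
                "protein_description": v.hgvs_p,
                "exon_intron": v.exon_intron,
                "effect": v.effect,
                "functional_domain": v.functional_domain,
                "iarc_match": int(v.iarc_match),
                "class": v.call.var_class,
                "genomic_pos": v.call.genomic_pos,
                "ref": v.call.ref_allele,
                "alt": v.call.alt_allele,
                "depth": v.call.depth,
                "alt_reads": v.call.alt_reads,
                "vaf": v.call.vaf,
                "p_value": v.call.p_value,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def annotated_from_tsv(path) -> dict[str, list[AnnotatedVariant]]:
    """Rebuild per-sample annotated variants from the TSV interchange file."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str}).fillna("")
    out: dict[str, list[AnnotatedVariant]] = {}
    for _, row in df.iterrows():
        call = VariantCall(
            sample_id=str(row["sample"]),
            genomic_pos=int(row["genomic_pos"]),
            ref_allele=str(row["ref"]),
            alt_allele=str(row["alt"]),
            var_class=str(row["class"]),
            depth=int(row["depth"]),
            alt_reads=int(row["alt_reads"]),
            vaf=float(row["vaf"]),
            p_value=float(row["p_value"]),
        )
        out.setdefault(str(row["sample"]), []).append(AnnotatedVariant(
            call=call,
            hgvs_g=str(row["genomic_description"]),
            hgvs_g_standard=str(row["genomic_description_standard"]),
            hgvs_p=str(row["protein_description"]),
            exon_intron=str(row["exon_intron"]),
            effect=str(row["effect"]),
            functional_domain=str(row["functional_domain"]),
            iarc_match=bool(row["iarc_match"]),
        ))
    return out
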