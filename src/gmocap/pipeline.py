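"""End-to-end orchestration: database -> (simulate | ingest) -> classify ->
detect -> assemble -> annotate, with every intermediate persisted.

``PipelineConfig`` captures one run: the element database (a synthetic panel
seed or FASTA + metadata paths), probe design parameters, the sample (a named
simulation scenario or an existing FASTQ pair), per-stage parameters and the
declared sample species for endogenous masking.  Negative controls for the
background model are designated in the config (simulated 0 %-GM runs by
default), never auto-detected.

Re-running an identical config with the same seed reproduces every output
byte-for-byte (timestamps are excluded from reports).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotate import (
    annotate_contigs, call_junctions, junctions_to_json,
    layout_to_json, reconstruct_layout, write_gff3,
)
from .assemble import assemble_contigs, extract_positive_reads, write_contigs_fasta
from .classify import AlignParams, classify_reads, index_database, write_assignments
from .detect import call_detection, count_table, fit_background, mask_endogenous
from .element_db import build_database, design_probes, write_probe_bed
from .panel import synthetic_panel_database
from .scenarios import make_gts_like, make_mixed_pat_bar
from .simulate import simulate_sample

log = logging.getLogger("gmocap")


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    # database
    panel_seed: int = 0
    db_fasta: str | None = None
    db_metadata: str | None = None
    # probes
    probe_length_bp: int = 120
    step_bp: int = 110
    # sample: simulation scenario ...
    scenario: str | None = "gts_like"     # gts_like | mixed_pat_bar | None
    gm_fraction: float = 0.01
    n_fragments: int = 500_000
    host_len: int = 60_000
    error_rate: float = 0.002
    off_target_rate: float = 1e-4
    # ... or an existing FASTQ pair
    fastq1: str | None = None
    fastq2: str | None = None
    # negative controls for the background model
    n_negative_controls: int = 2
    negative_n_fragments: int = 200_000
    # classify
    classify_k: int = 15
    min_identity: float = 0.90
    min_len: int = 40
    # detect
    rpkm_floor: float = 25.0
    sample_species: list = field(default_factory=lambda: ["soybean"])
    # assemble
    assemble_k: int = 31
    min_edge_cov: int = 2
    min_contig_len: int = 100

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", newline="\n") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    version: str
    total_reads: int
    reads_aligned: int
    pct_aligned: float
    detected_elements: list
    endogenous_flagged: list
    n_contigs: int
    n_layouts: int
    n_junctions: int
    paths: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", newline="\n") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_all(config: PipelineConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    # --- build-db ---
    @_stage("build-db")
    def _build_db():
        if config.db_fasta and config.db_metadata:
            return build_database(config.db_fasta, config.db_metadata)
        return synthetic_panel_database(config.panel_seed)

    db = _build_db()
    db.to_fasta(out / "db.fasta")
    db.to_metadata(out / "db.tsv")
    log.info("build-db: %d elements, %d bp", len(db), db.total_length_bp)

    # --- design-probes ---
    @_stage("design-probes")
    def _probes():
        ps = design_probes(db, config.probe_length_bp, config.step_bp)
        write_probe_bed(ps, out / "probes.bed")
        return ps

    probes = _probes()
    log.info("design-probes: %d probes", len(probes))

    # --- simulate | ingest ---
    hosts = []
    scenario = None

    @_stage("simulate")
    def _sample():
        nonlocal hosts, scenario
        if config.fastq1:
            return Path(config.fastq1), Path(config.fastq2) if config.fastq2 else None
        if config.scenario == "gts_like":
            scenario = make_gts_like(
                db, probes, config.gm_fraction, config.n_fragments,
                seed=config.seed, host_len=config.host_len,
                error_rate=config.error_rate,
                off_target_rate=config.off_target_rate,
            )
        elif config.scenario == "mixed_pat_bar":
            scenario = make_mixed_pat_bar(
                db, probes, config.n_fragments, seed=config.seed,
                host_len=config.host_len, error_rate=config.error_rate,
                off_target_rate=config.off_target_rate,
            )
        else:
            raise ValueError(f"unknown scenario {config.scenario!r} and no FASTQ given")
        hosts = scenario.hosts
        res = simulate_sample(scenario.spec, probes, out, prefix="sample")
        log.info("simulate: %d captured pairs", res["n_pairs"])
        return res["fastq1"], res["fastq2"]

    fastq1, fastq2 = _sample()

    # --- classify ---
    index = index_database(db, k=config.classify_k)
    aparams = AlignParams(min_identity=config.min_identity, min_len=config.min_len)

    @_stage("classify")
    def _classify():
        df, summary = classify_reads(fastq1, fastq2, index, db, aparams)
        write_assignments(df, out / "assignments.tsv")
        return df, summary

    assignments, summary = _classify()
    log.info("classify: %d/%d reads aligned (%.3f%%)", summary["reads_aligned"],
             summary["total_reads"], summary["pct_aligned"])

    # --- detect (with designated negative controls) ---
    @_stage("detect")
    def _detect():
        sample_counts = count_table(assignments, db, summary["total_reads"])
        sample_counts.to_csv(out / "counts.tsv", sep="\t", index=False,
                             lineterminator="\n")
        bg = None
        if config.n_negative_controls > 0 and config.scenario is not None:
            neg_tables = []
            for i in range(config.n_negative_controls):
                neg = make_gts_like(
                    db, probes, 0.0, config.negative_n_fragments,
                    seed=config.seed + 7000 + i, host_len=config.host_len,
                    error_rate=config.error_rate,
                    off_target_rate=config.off_target_rate,
                )
                res = simulate_sample(neg.spec, probes, out, prefix=f"negctrl{i}")
                ndf, nsum = classify_reads(res["fastq1"], res["fastq2"], index,
                                           db, aparams)
                neg_tables.append(count_table(ndf, db, max(nsum["total_reads"], 1)))
            if neg_tables:
                bg = fit_background(neg_tables)
        else:
            log.warning("detect: no negative controls designated; floor-only thresholds")
        calls = call_detection(sample_counts, bg, floor=config.rpkm_floor)
        calls = mask_endogenous(calls, config.sample_species)
        calls.to_csv(out / "detection.tsv", sep="\t", index=False,
                     lineterminator="\n")
        return calls

    calls = _detect()
    detected = sorted(calls.loc[calls["detected"], "element_id"])
    flagged = sorted(calls.loc[calls["detected"] & calls["endogenous_flag"],
                               "element_id"])
    log.info("detect: %d elements detected %s", len(detected), detected)

    # --- assemble ---
    @_stage("assemble")
    def _assemble():
        if not detected:
            return []
        pos = extract_positive_reads(assignments, str(fastq1), detected,
                                     fastq2=str(fastq2) if fastq2 else None)
        if not pos:
            return []
        return assemble_contigs(
            [seq for _rid, seq in pos],
            k=config.assemble_k, min_edge_cov=config.min_edge_cov,
            min_contig_len=config.min_contig_len,
        )

    contigs = _assemble()
    write_contigs_fasta(contigs, out / "contigs.fasta")
    log.info("assemble: %d contigs", len(contigs))

    # --- annotate ---
    @_stage("annotate")
    def _annotate():
        anns = annotate_contigs(contigs, db, host_refs=hosts or None)
        write_gff3(anns, out / "annotations.gff3")
        junctions = [j for ann in anns for j in call_junctions(ann)]
        junctions_to_json(junctions, out / "junctions.json")
        layout = reconstruct_layout(anns, db)
        layout_to_json(layout, out / "layout.json")
        return anns, junctions, layout

    anns, junctions, layout = _annotate()
    log.info("annotate: %d layouts, %d junctions", len(layout["layouts"]),
             len(junctions))

    report = RunReport(
        config_hash=config.config_hash(),
        version=__version__,
        total_reads=summary["total_reads"],
        reads_aligned=summary["reads_aligned"],
        pct_aligned=round(summary["pct_aligned"], 6),
        detected_elements=detected,
        endogenous_flagged=flagged,
        n_contigs=len(contigs),
        n_layouts=len(layout["layouts"]),
        n_junctions=len(junctions),
        paths={
            "db_fasta": str(out / "db.fasta"),
            "probes_bed": str(out / "probes.bed"),
            "assignments": str(out / "assignments.tsv"),
            "detection": str(out / "detection.tsv"),
            "contigs": str(out / "contigs.fasta"),
            "annotations": str(out / "annotations.gff3"),
            "junctions": str(out / "junctions.json"),
            "layout": str(out / "layout.json"),
        },
    )
    report.to_json(out / "report.json")
    return report
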