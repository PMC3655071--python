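"""End-to-end orchestration: simulate -> filter -> subsample -> assemble ->
metrics -> ortholog scoring -> saturation table.

Each stage writes its artifacts before the next starts, every stage is
driven by the single run seed, and a manifest records parameters and
output checksums so a rerun can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io_formats
from .assembly_metrics import summarize
from .kog_completeness import (DEFAULT_EVALUE, read_cluster_fasta,
                               saturation_table, score_assembly)
from .read_processing import (FilterParams, filter_pairs, n_reads,
                              nested_subsets, randomize_order)
from .synthetic_data import (TRUSEQ_ADAPTER, clusters_to_fasta_records,
                             gen_reads, simulate_study)
from .toy_assembler import Assembly, AssemblyParams, assemble
from .io_formats import unit_reads

log = logging.getLogger("depthsat")


@dataclass
class SimulateParams:
    n_genes: int = 60
    n_kog: int = 50
    n_pairs: int = 22000
    read_len: int = 100
    insert_mean: int = 180
    insert_sd: int = 20
    orders_of_magnitude: float = 1.0
    error_rate: float = 0.001
    adapter_rate: float = 0.004
    polyt_rate: float = 0.002
    lowq_rate: float = 0.11
    adapter_seq: str = TRUSEQ_ADAPTER


@dataclass
class RunConfig:
    """Everything needed to reproduce one saturation run."""

    seed: int = 1
    depths: list[int] = field(default_factory=lambda: [4000, 14000, 36000])
    simulate: SimulateParams = field(default_factory=SimulateParams)
    filter: FilterParams = field(
        default_factory=lambda: FilterParams(adapter_seqs=[TRUSEQ_ADAPTER]))
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    evalue_cutoff: float = DEFAULT_EVALUE
    out_dir: str = "depthsat_run"
    # optional external inputs replacing the simulator
    reads1: Optional[str] = None
    reads2: Optional[str] = None
    kogs_fasta: Optional[str] = None
    canonical_fasta: Optional[str] = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        for key, sub in (("simulate", SimulateParams),
                         ("filter", FilterParams),
                         ("assembly", AssemblyParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run(config: RunConfig) -> "pd.DataFrame":
    """Execute the full pipeline; returns the saturation table.

    Artifacts written under ``config.out_dir``: simulated FASTQ + truth
    (when simulating), the filter report, per-depth contig FASTA and locus
    TSV, ``saturation.tsv``, and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    # --- stage 1: obtain reads + reference clusters -----------------------
    if config.reads1:
        stage = "load"
        pairs = list(io_formats.read_fastq_paired(config.reads1, config.reads2))
        if not config.kogs_fasta:
            raise ValueError("stage kogscan: external reads require --kogs")
        clusters = read_cluster_fasta(io_formats.read_fasta(config.kogs_fasta))
    else:
        stage = "simulate"
        sim = config.simulate
        study = simulate_study(
            n_genes=sim.n_genes, n_kog=sim.n_kog,
            orders_of_magnitude=sim.orders_of_magnitude, seed=config.seed)
        pairs, truth = gen_reads(
            study.transcripts, study.weights, sim.n_pairs,
            read_len=sim.read_len, insert_mean=sim.insert_mean,
            insert_sd=sim.insert_sd, error_rate=sim.error_rate,
            adapter_seq=sim.adapter_seq, adapter_rate=sim.adapter_rate,
            polyt_rate=sim.polyt_rate, lowq_rate=sim.lowq_rate,
            seed=config.seed + 1)
        clusters = study.clusters
        save("sim_1.fastq", lambda p: io_formats.write_fastq(
            (u.r1 for u in pairs), p, mate_suffix=True))
        save("sim_2.fastq", lambda p: io_formats.write_fastq(
            (u.r2 for u in pairs), p, mate_suffix=True))
        save("sim_truth.json", lambda p: p.write_text(truth.to_json()))
        save("sim_transcripts.fasta", lambda p: io_formats.write_fasta(
            ((t.id, t.sequence) for t in study.transcripts), p))
        save("sim_kogs.fasta", lambda p: io_formats.write_fasta(
            clusters_to_fasta_records(clusters), p))
    log.info("stage %s: %d read pairs, %d reference clusters",
             stage, len(pairs), len(clusters))

    canonical = None
    if config.canonical_fasta:
        canonical = dict(io_formats.read_fasta(config.canonical_fasta))

    # --- stage 2: randomize, filter, subsample ----------------------------
    randomized = randomize_order(pairs, config.seed + 2)
    units, report = filter_pairs(randomized, config.filter)
    log.info("stage filter: %s", report.as_dict())
    save("filter_report.tsv", lambda p: io_formats.write_tsv(
        [report.as_dict()], p))
    available = n_reads(units)
    if config.depths and config.depths[-1] > available:
        raise ValueError(
            f"stage subsample: depth {config.depths[-1]} exceeds the "
            f"{available} filtered reads")
    subsets = nested_subsets(units, config.depths)

    # --- stage 3: per-depth assembly, metrics, completeness ---------------
    ladder = []
    for depth, subset in zip(config.depths, subsets):
        reads = [r for u in subset for r in unit_reads(u)]
        assembly = assemble(reads, config.assembly)
        save(f"contigs_{depth}.fasta", lambda p, a=assembly: io_formats.write_fasta(
            ((c.id, c.sequence) for c in a.contigs), p))
        save(f"loci_{depth}.tsv", lambda p, a=assembly: io_formats.write_tsv(
            ({"locus_id": lid, "contig_id": cid}
             for lid, cids in sorted(a.loci.items()) for cid in cids), p))
        ladder.append((depth, assembly))
        log.info("stage assemble: depth %d -> %d contigs", depth,
                 len(assembly.contigs))

    table = saturation_table(ladder, clusters, config.evalue_cutoff,
                             canonical_proteins=canonical)
    save("saturation.tsv", lambda p: table.to_csv(p, sep="\t", index=False,
                                                  float_format="%.4f"))

    manifest = {
        "config": yaml.safe_load(config.to_yaml()),
        "checksums": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return table
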