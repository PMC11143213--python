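"""End-to-end orchestration: binning, depth partitioning, ensemble merge.

External assemblers and mergers are never bundled; they are invoked
through command-template adapters (placeholders ``{reads}``, ``{out}``,
``{threads}``, ``{inputs}``).  A built-in mock assembler (each read
becomes a "contig") and mock merger (concatenate then drop records with
duplicate sequences) keep the whole pipeline hermetically testable.

Every run writes a manifest listing, per stage, the parameters, input
and output paths with SHA-256 checksums, record counts and wall times;
read conservation is asserted at each stage boundary.
"""

from __future__ import annotations

import hashlib
import json
import shlex
import subprocess
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml
from Bio import SeqIO

from lrbin import clustering, depth as depth_mod, features as features_mod
from lrbin.connectivity import alignments_from_sam
from lrbin.embedding import EmbedderConfig, embed, train_embedder
from lrbin.linked_reads import (
    BarcodedReadPair,
    group_by_barcode,
    read_fastq_pairs,
    write_fastq_pairs,
)


@dataclass
class PipelineConfig:
    """Configuration of a full run; loadable from a YAML file."""

    reads1: str
    reads2: str | None = None
    dialect: str | None = None
    workdir: str = "lrbin_out"
    min_total_bases: int = 2000
    shannon_diversity: float | None = None
    k: int | None = None
    thresholds: tuple[float, ...] = (10.0, 30.0)
    threads: int = 1
    seed: int = 0
    feature: dict = field(default_factory=dict)
    embedder: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)
    adapters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dialect is None:
            raise ValueError("barcode dialect must be set explicitly (stlfr/tellseq/tenx/virtual)")
        if (self.shannon_diversity is None) == (self.k is None):
            raise ValueError("set exactly one of shannon_diversity / k")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "thresholds" in data:
            data["thresholds"] = tuple(data["thresholds"])
        return cls(**data)


@dataclass
class RunManifest:
    """Per-stage record of inputs, outputs, checksums, counts and timings."""

    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, *, seconds: float, outputs: dict | None = None,
            counts: dict | None = None, params: dict | None = None,
            error: str | None = None) -> None:
        entry: dict = {"stage": name, "seconds": round(seconds, 4)}
        if params:
            entry["params"] = params
        if counts:
            entry["counts"] = counts
        if outputs:
            entry["outputs"] = {
                str(p): _sha256(p) for p in outputs.values()
            } if isinstance(outputs, dict) else outputs
        if error:
            entry["error"] = error
        self.stages.append(entry)

    def save(self, path) -> None:
        with open(path, "w") as out:
            json.dump({"stages": self.stages}, out, indent=2)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_binning_pipeline(config: PipelineConfig) -> RunManifest:
    """io -> features -> embedding -> clustering -> per-bin FASTQ emission.

    Bin b goes to ``bin_<b>.fq`` (interleaved); leftover-pool reads
    (no barcode, undersized or flagged groups) go once to ``shared.fq``,
    consumed only by the ensemble stage.  Conservation (sum of bins +
    shared = input) is asserted.
    """
    work = Path(config.workdir)
    work.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    stage = "io"
    try:
        t0 = time.perf_counter()
        pairs = list(read_fastq_pairs(config.reads1, config.reads2, config.dialect))
        groups, pool = group_by_barcode(pairs, config.min_total_bases)
        manifest.add(stage, seconds=time.perf_counter() - t0,
                     counts={"pairs": len(pairs), "groups": len(groups), "pool": len(pool)},
                     params={"dialect": config.dialect,
                             "min_total_bases": config.min_total_bases})

        stage = "features"
        t0 = time.perf_counter()
        fconfig = features_mod.FeatureConfig(**config.feature)
        table = features_mod.build_global_kmer_table(groups, fconfig)
        records = features_mod.extract_features(groups, table, fconfig)
        manifest.add(stage, seconds=time.perf_counter() - t0,
                     counts={"records": len(records),
                             "flagged": sum(r.flagged for r in records),
                             "distinct_kmers": len(table)})

        stage = "embedding"
        t0 = time.perf_counter()
        econfig = EmbedderConfig(seed=config.seed, **config.embedder)
        model, log = train_embedder(records, econfig)
        result = embed(model, records)
        model.save(work / "embedder.npz")
        manifest.add(stage, seconds=time.perf_counter() - t0,
                     counts={"embedded": len(result.barcodes),
                             "excluded": len(result.excluded),
                             "epochs": len(log)},
                     outputs={"embedder": work / "embedder.npz"})

        stage = "clustering"
        t0 = time.perf_counter()
        cconfig = clustering.ClusteringConfig(
            shannon_diversity=config.shannon_diversity, k_override=config.k,
            seed=config.seed, **config.clustering)
        k = cconfig.resolve_k()
        assignment = clustering.cluster_latent(result.mu, k, cconfig, barcodes=result.barcodes)
        with open(work / "bins.tsv", "w") as out:
            out.write("barcode\tbin\n")
            for bc, b in assignment.mapping().items():
                out.write(f"{bc}\t{b}\n")
        manifest.add(stage, seconds=time.perf_counter() - t0,
                     counts={"k": k, "bin_sizes": assignment.bin_sizes.tolist()},
                     outputs={"bins": work / "bins.tsv"})

        stage = "emit-bins"
        t0 = time.perf_counter()
        mapping = assignment.mapping()
        flagged = set(result.excluded)
        bin_files = {}
        emitted = 0
        by_bin: dict[int, list[BarcodedReadPair]] = {b: [] for b in range(k)}
        shared = list(pool)
        for group in groups:
            if group.barcode in flagged or group.barcode not in mapping:
                shared.extend(group.pairs)
                continue
            by_bin[mapping[group.barcode]].extend(group.pairs)
        for b in range(k):
            path = work / f"bin_{b}.fq"
            emitted += write_fastq_pairs(by_bin[b], path, dialect=config.dialect)
            bin_files[f"bin_{b}"] = path
        shared_path = work / "shared.fq"
        emitted += write_fastq_pairs(shared, shared_path, dialect=config.dialect)
        bin_files["shared"] = shared_path
        if emitted != len(pairs):
            raise AssertionError(
                f"read conservation violated: {emitted} emitted vs {len(pairs)} input"
            )
        manifest.add(stage, seconds=time.perf_counter() - t0,
                     counts={"emitted_pairs": emitted, "shared_pairs": len(shared)},
                     outputs=bin_files)
    except Exception as exc:  # record failure, keep partial outputs
        manifest.add(stage, seconds=0.0, error=f"{type(exc).__name__}: {exc}")
        manifest.save(work / "manifest.json")
        raise StageError(stage, exc) from exc
    manifest.save(work / "manifest.json")
    return manifest


def run_partition_pipeline(
    config: PipelineConfig,
    contigs_fasta,
    alignments_sam,
) -> RunManifest:
    """Depth table plus one retained-read FASTQ per threshold."""
    work = Path(config.workdir)
    work.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    stage = "depth"
    try:
        t0 = time.perf_counter()
        lengths = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(contigs_fasta), "fasta")}
        alignments = alignments_from_sam(alignments_sam)
        depths = depth_mod.contig_depths(alignments, lengths)
        depth_mod.depths_to_tsv(depths, work / "depths.tsv")
        manifest.add(stage, seconds=time.perf_counter() - t0,
                     counts={"contigs": len(lengths), "alignments": len(alignments)},
                     outputs={"depths": work / "depths.tsv"})

        stage = "partition"
        t0 = time.perf_counter()
        pairs = list(read_fastq_pairs(config.reads1, config.reads2, config.dialect))
        by_id = {}
        for p in pairs:
            by_id[p.read_id] = p
        results = depth_mod.partition_reads(
            by_id, alignments, depths, depth_mod.PartitionConfig(tuple(config.thresholds))
        )
        outputs = {}
        counts = {}
        for res in results:
            path = work / f"low_abundance_t{res.threshold:g}.fq"
            write_fastq_pairs(
                (by_id[i] for i in sorted(res.retained)), path, dialect=config.dialect
            )
            outputs[f"t{res.threshold:g}"] = path
            counts[f"retained_t{res.threshold:g}"] = len(res.retained)
        manifest.add(stage, seconds=time.perf_counter() - t0, counts=counts, outputs=outputs)
    except Exception as exc:
        manifest.add(stage, seconds=0.0, error=f"{type(exc).__name__}: {exc}")
        manifest.save(work / "partition_manifest.json")
        raise StageError(stage, exc) from exc
    manifest.save(work / "partition_manifest.json")
    return manifest


# -- adapters ---------------------------------------------------------------


def mock_assemble(reads_fastq, out_fasta) -> int:
    """Built-in mock assembler: each input read becomes one "contig"."""
    n = 0
    from lrbin.linked_reads import read_fastq_pairs as _read

    with open(out_fasta, "w") as out:
        for pair in _read(reads_fastq, dialect="stlfr"):
            out.write(f">{pair.read_id}_1\n{pair.seq1}\n>{pair.read_id}_2\n{pair.seq2}\n")
            n += 2
    return n


def mock_merge(contig_fastas: Sequence, out_fasta) -> int:
    """Built-in mock merger: concatenate, drop records with duplicate sequences."""
    seen: set[str] = set()
    n = 0
    with open(out_fasta, "w") as out:
        for path in contig_fastas:
            for rec in SeqIO.parse(str(path), "fasta"):
                seq = str(rec.seq)
                if seq in seen:
                    continue
                seen.add(seq)
                out.write(f">{rec.id}\n{seq}\n")
                n += 1
    return n


def run_adapter(template: str | None, name: str, manifest: RunManifest, **subs) -> None:
    """Run one external command template, recording the exact command line."""
    if not template:
        raise ValueError(f"adapter {name!r} not configured")
    cmd = template.format(**subs)
    t0 = time.perf_counter()
    proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
    entry = {"command": cmd, "returncode": proc.returncode}
    if proc.returncode != 0:
        entry["stderr"] = proc.stderr[-4000:]
    manifest.add(f"adapter:{name}", seconds=time.perf_counter() - t0, params=entry)
    if proc.returncode != 0:
        raise StageError(f"adapter:{name}", RuntimeError(proc.stderr[-500:]))


def run_ensemble(
    adapters: dict,
    contig_sets: dict,
    out_fasta,
    manifest: RunManifest | None = None,
    threads: int = 1,
) -> RunManifest:
    """Merge the contig sets (bin / low / local / original) into one FASTA.

    ``adapters['merger']`` must be configured: either the literal string
    ``"mock"`` (built-in concatenate-and-deduplicate merger, deterministic,
    for hermetic tests) or an external command template run with
    ``{inputs}``/``{out}``/``{threads}``.
    """
    manifest = manifest or RunManifest()
    inputs = [str(contig_sets[name]) for name in sorted(contig_sets)]
    t0 = time.perf_counter()
    merger = adapters.get("merger")
    if not merger:
        raise ValueError("adapter 'merger' not configured")
    if merger == "mock":
        n = mock_merge(inputs, out_fasta)
        manifest.add("ensemble", seconds=time.perf_counter() - t0,
                     counts={"merged_records": n}, outputs={"merged": out_fasta})
    else:
        run_adapter(merger, "merger", manifest,
                    inputs=" ".join(inputs), out=str(out_fasta), threads=threads)
    return manifest
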