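"""Per-contig read depth and multi-threshold read partitioning.

Read binning can scatter the reads of a low-abundance genome across
bins, starving its assembly.  To recover them, reads are re-collected
at increasing depth thresholds: for each threshold t, a read pair is
retained iff neither mate maps (primary alignment) to a contig whose
mean depth exceeds t.  Retained sets are nested -- a larger t marks
fewer contigs as high-depth, so retained(10) is a subset of
retained(30) -- and each set is reassembled independently.

Mean depth is total aligned bases divided by contig length (no edge
trimming or variance correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from lrbin.connectivity import AlignmentRecord


@dataclass(frozen=True)
class DepthRecord:
    """Mean read depth of one contig."""

    contig: str
    length: int
    mean_depth: float


@dataclass(frozen=True)
class PartitionConfig:
    """Ordered depth thresholds; {10, 30} works across community complexities."""

    thresholds: tuple[float, ...] = (10.0, 30.0)

    def __post_init__(self) -> None:
        if not self.thresholds or any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be positive")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")


@dataclass
class PartitionResult:
    """Read-pair ids retained for reassembly at one threshold."""

    threshold: float
    retained: set[str]


def contig_depths(
    alignments: Iterable[AlignmentRecord],
    contig_lengths: Mapping[str, int],
) -> list[DepthRecord]:
    """Mean depth per contig from primary alignments.

    Each alignment contributes its aligned bases (or reference span when
    the CIGAR-derived count is unavailable); contigs without alignments
    get depth 0.  An alignment to a contig absent from
    ``contig_lengths`` is an error.
    """
    totals = {contig: 0 for contig in contig_lengths}
    for aln in alignments:
        if not aln.is_primary:
            continue
        if aln.reference not in totals:
            raise ValueError(f"alignment to unknown contig {aln.reference!r}")
        bases = aln.aligned_bases if aln.aligned_bases is not None else aln.end - aln.start
        totals[aln.reference] += bases
    return [
        DepthRecord(contig=c, length=contig_lengths[c], mean_depth=totals[c] / contig_lengths[c])
        for c in contig_lengths
    ]


def collect_low_abundance_reads(
    pair_ids: Iterable[str],
    alignments: Iterable[AlignmentRecord],
    depths: Sequence[DepthRecord],
    threshold: float,
) -> PartitionResult:
    """Pairs with no primary alignment to any contig of depth > threshold.

    A pair is excluded when either mate maps to a high-depth contig;
    fully unmapped pairs are always retained.
    """
    high = {d.contig for d in depths if d.mean_depth > threshold}
    excluded = {
        aln.read_id
        for aln in alignments
        if aln.is_primary and aln.reference in high
    }
    retained = {pid for pid in pair_ids if pid not in excluded}
    return PartitionResult(threshold=threshold, retained=retained)


def partition_reads(
    pair_ids: Iterable[str],
    alignments: Iterable[AlignmentRecord],
    depths: Sequence[DepthRecord],
    config: PartitionConfig = PartitionConfig(),
) -> list[PartitionResult]:
    """One retained set per threshold, in config order."""
    pair_ids = list(pair_ids)
    alignments = list(alignments)
    return [
        collect_low_abundance_reads(pair_ids, alignments, depths, t)
        for t in config.thresholds
    ]


def depths_to_tsv(depths: Sequence[DepthRecord], path) -> None:
    """Depth table, columns (contig, length, depth)."""
    with open(path, "w") as out:
        out.write("contig\tlength\tdepth\n")
        for d in depths:
            out.write(f"{d.contig}\t{d.length}\t{d.mean_depth:.6g}\n")
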