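"""Synthetic metagenome and linked-read generator with ground truth.

The generator emulates the fragment-level barcode model of linked-read
sequencing: each barcode receives one or more long DNA fragments (the
count is 1 + Poisson(mean - 1), so the configured mean number of
fragments per barcode, N_F/B, is met exactly while every barcode keeps at
least one fragment), fragments land on genomes proportionally to
abundance x length, and short read pairs are drawn uniformly within each
fragment.  Every emitted read pair is recorded in a truth table (source
genome, fragment, coordinates), so binning, fragment reconstruction and
depth partitioning can all be scored without external data.

Genomes are first-order Markov sequences whose stationary base
composition is pinned to the requested GC content while per-genome
transition biases (drawn from a seeded Dirichlet) give each genome a
distinct tetranucleotide signature -- without such composition contrast,
clustering tests would be vacuous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from lrbin import _kmers
from lrbin.connectivity import AlignmentRecord
from lrbin.linked_reads import BarcodedReadPair

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class CommunityConfig:
    """Composition of the synthetic community.

    ``abundances`` are relative sequencing abundances and must sum to 1;
    ``gc_contents`` are per-genome GC fractions.  Defaults are a
    three-genome community with 100x/30x/10x relative abundance and
    well-separated GC, mirroring a strongly uneven mock community.
    """

    n_genomes: int = 3
    genome_length: int | Sequence[int] = 100_000
    abundances: Sequence[float] = (100 / 140, 30 / 140, 10 / 140)
    gc_contents: Sequence[float] = (0.25, 0.50, 0.70)
    tnf_bias: float = 2.0

    def __post_init__(self) -> None:
        if self.n_genomes <= 0:
            raise ValueError("n_genomes must be positive")
        if len(self.abundances) != self.n_genomes or len(self.gc_contents) != self.n_genomes:
            raise ValueError("abundances/gc_contents must have n_genomes entries")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("genome lengths must be positive")

    @property
    def lengths(self) -> list[int]:
        if isinstance(self.genome_length, int):
            return [self.genome_length] * self.n_genomes
        return list(self.genome_length)


@dataclass(frozen=True)
class LinkedReadConfig:
    """Fragment-per-barcode model of the linked-read library.

    ``mean_fragments_per_barcode`` is the target N_F/B (1.54 is typical
    of stLFR, 4.26 of TELL-Seq, 16.61 of 10x Genomics).  Fragment lengths
    are normal (clipped below at 1.5 kb); read pairs have a fixed insert
    size and a substitution-only error model.
    """

    n_barcodes: int = 3000
    mean_fragments_per_barcode: float = 1.54
    fragment_length_mean: float = 20_000.0
    fragment_length_sd: float = 5_000.0
    read_length: int = 100
    pairs_per_fragment_mean: float = 24.0
    insert_size: int = 300
    substitution_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_fragments_per_barcode < 1:
            raise ValueError("mean_fragments_per_barcode must be >= 1")
        if not (0 <= self.substitution_error_rate < 1):
            raise ValueError("substitution_error_rate must be in [0, 1)")
        for name in ("n_barcodes", "fragment_length_mean", "fragment_length_sd",
                     "read_length", "pairs_per_fragment_mean", "insert_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TruthTable:
    """Ground truth for every emitted read pair.

    ``pairs`` has one row per read pair: read_id, barcode, genome,
    fragment_id, fragment start/end (0-based half-open on the genome) and
    the pair's leftmost coordinate.  ``fragments`` summarizes one row per
    fragment.
    """

    pairs: pd.DataFrame

    @property
    def fragments(self) -> pd.DataFrame:
        frags = (
            self.pairs.groupby("fragment_id")
            .agg(
                barcode=("barcode", "first"),
                genome=("genome", "first"),
                start=("fragment_start", "first"),
                end=("fragment_end", "first"),
                n_pairs=("read_id", "size"),
            )
            .reset_index()
        )
        return frags

    def barcode_fragments(self) -> pd.Series:
        """Number of distinct fragments per barcode."""
        return self.pairs.groupby("barcode")["fragment_id"].nunique()

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t"))


def _stationary(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    v = np.real(vecs[:, np.argmax(np.real(vals))])
    v = np.abs(v)
    return v / v.sum()


def _transition_matrix(gc: float, bias: np.ndarray, iters: int = 200) -> np.ndarray:
    """Row-stochastic 4x4 transition matrix with the given Dirichlet bias,
    column-rescaled until the stationary distribution matches the target
    base composition (A/T and G/C split evenly)."""
    target = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    T = bias / bias.sum(axis=1, keepdims=True)
    for _ in range(iters):
        pi = _stationary(T)
        scale = target / np.maximum(pi, 1e-12)
        T = T * scale[None, :]
        T = T / T.sum(axis=1, keepdims=True)
        if np.max(np.abs(_stationary(T) - target)) < 1e-6:
            break
    return T


def _markov_sequence(T: np.ndarray, length: int, rng: np.random.Generator) -> str:
    cum = np.cumsum(T, axis=1)
    us = rng.random(length)
    codes = np.empty(length, dtype=np.int8)
    state = int(np.searchsorted(np.cumsum(_stationary(T)), us[0]))
    state = min(state, 3)
    codes[0] = state
    row = cum[state]
    for i in range(1, length):
        u = us[i]
        state = 0
        while row[state] < u:
            state += 1
        codes[i] = state
        row = cum[state]
    return _kmers.decode(codes)


def simulate_genomes(config: CommunityConfig, seed: int = 0) -> dict[str, str]:
    """Generate the community's genome sequences, keyed ``g0``, ``g1``, ...

    Deterministic under the seed; realized GC tracks the target within
    about two points for genomes of 100 kb or more.
    """
    rng = np.random.default_rng(seed)
    genomes: dict[str, str] = {}
    for g, (length, gc) in enumerate(zip(config.lengths, config.gc_contents)):
        bias = rng.dirichlet(np.full(4, config.tnf_bias), size=4)
        T = _transition_matrix(gc, bias)
        genomes[f"g{g}"] = _markov_sequence(T, length, rng)
    return genomes


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _apply_substitutions(seqs: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    if rate <= 0 or not seqs:
        return seqs
    lengths = np.array([len(s) for s in seqs])
    flat = _kmers.encode("".join(seqs))
    mask = (rng.random(flat.size) < rate) & (flat >= 0)
    # substitute with one of the three other bases, uniformly
    flat[mask] = (flat[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    out_str = _kmers.decode(np.where(flat >= 0, flat, 0))
    # restore Ns
    if np.any(flat < 0):
        chars = np.frombuffer(out_str.encode(), dtype=np.uint8).copy()
        chars[flat < 0] = ord("N")
        out_str = chars.tobytes().decode()
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    return [out_str[bounds[i] : bounds[i + 1]] for i in range(len(seqs))]


def _shifted_poisson(mean: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """1 + Poisson(mean - 1): guaranteed >= 1 with the configured mean."""
    return 1 + rng.poisson(max(mean - 1.0, 0.0), size=size)


def simulate_linked_reads(
    genomes: dict[str, str],
    community: CommunityConfig,
    lrc: LinkedReadConfig,
) -> tuple[list[BarcodedReadPair], TruthTable]:
    """Emit barcoded read pairs plus a complete truth table.

    Fragment counts per barcode follow 1 + Poisson(mean - 1); each
    fragment picks its genome with probability proportional to
    abundance x length and its interval uniformly; pairs are placed
    uniformly within the fragment with a fixed insert size.
    """
    if not genomes:
        raise ValueError("genomes must be non-empty")
    rng = np.random.default_rng(lrc.seed)
    names = list(genomes)
    lengths = np.array([len(genomes[n]) for n in names], dtype=np.int64)
    weights = np.asarray(community.abundances, dtype=np.float64) * lengths
    weights = weights / weights.sum()

    n_frags_per_bc = _shifted_poisson(lrc.mean_fragments_per_barcode, lrc.n_barcodes, rng)
    n_frags = int(n_frags_per_bc.sum())
    frag_barcode = np.repeat(np.arange(lrc.n_barcodes), n_frags_per_bc)
    frag_genome = rng.choice(len(names), size=n_frags, p=weights)
    min_frag = float(max(1500, lrc.insert_size * 2))
    frag_len = np.maximum(
        rng.normal(lrc.fragment_length_mean, lrc.fragment_length_sd, size=n_frags), min_frag
    ).astype(np.int64)
    frag_len = np.minimum(frag_len, lengths[frag_genome])
    frag_start = (rng.random(n_frags) * (lengths[frag_genome] - frag_len + 1)).astype(np.int64)
    frag_end = frag_start + frag_len

    pairs_per_frag = _shifted_poisson(lrc.pairs_per_fragment_mean, n_frags, rng)
    n_pairs = int(pairs_per_frag.sum())
    pair_frag = np.repeat(np.arange(n_frags), pairs_per_frag)
    span = np.maximum(frag_len[pair_frag] - lrc.insert_size, 1)
    pair_start = frag_start[pair_frag] + (rng.random(n_pairs) * span).astype(np.int64)

    r = lrc.read_length
    seqs1, seqs2 = [], []
    for g_idx, start in zip(pair_frag, pair_start):
        genome = genomes[names[frag_genome[g_idx]]]
        s = int(start)
        insert = genome[s : s + lrc.insert_size]
        seqs1.append(insert[:r])
        seqs2.append(revcomp(insert[-r:]))
    seqs1 = _apply_substitutions(seqs1, lrc.substitution_error_rate, rng)
    seqs2 = _apply_substitutions(seqs2, lrc.substitution_error_rate, rng)

    pairs: list[BarcodedReadPair] = []
    rows = {
        "read_id": [], "barcode": [], "genome": [], "fragment_id": [],
        "fragment_start": [], "fragment_end": [], "pair_start": [],
    }
    for j in range(n_pairs):
        f = int(pair_frag[j])
        barcode = f"{int(frag_barcode[f]) + 1}_1_1"
        read_id = f"r{j}"
        s1, s2 = seqs1[j], seqs2[j]
        pairs.append(
            BarcodedReadPair(
                read_id=read_id, seq1=s1, seq2=s2,
                qual1="I" * len(s1), qual2="I" * len(s2),
                barcode=barcode, technology="stlfr",
            )
        )
        rows["read_id"].append(read_id)
        rows["barcode"].append(barcode)
        rows["genome"].append(names[frag_genome[f]])
        rows["fragment_id"].append(f)
        rows["fragment_start"].append(int(frag_start[f]))
        rows["fragment_end"].append(int(frag_end[f]))
        rows["pair_start"].append(int(pair_start[j]))
    return pairs, TruthTable(pd.DataFrame(rows))


def alignments_from_truth(truth: TruthTable, insert_size: int = 300) -> list[AlignmentRecord]:
    """Error-free alignment records implied by the truth table.

    Each read pair becomes one record spanning its insert on the source
    genome, sorted by (reference, coordinate) as an aligner would emit
    after coordinate sorting.  Useful to exercise fragment reconstruction
    without running an aligner.
    """
    df = truth.pairs.sort_values(["genome", "pair_start", "read_id"], kind="mergesort")
    return [
        AlignmentRecord(
            read_id=row.read_id, reference=row.genome,
            start=int(row.pair_start), end=int(row.pair_start) + insert_size,
            barcode=row.barcode, aligned_bases=insert_size,
        )
        for row in df.itertuples()
    ]


def simulate_long_reads(
    genomes: dict[str, str],
    n_reads: int,
    length_mean: float = 10_000.0,
    error_rate: float = 0.0,
    seed: int = 0,
    abundances: Sequence[float] | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Sample long reads (for virtual barcoding) plus their true origins.

    Reads pick a genome proportionally to abundance x length (uniform
    abundances by default), an interval uniformly, and receive
    substitution errors at ``error_rate``.
    """
    if not genomes:
        raise ValueError("genomes must be non-empty")
    rng = np.random.default_rng(seed)
    names = list(genomes)
    lengths = np.array([len(genomes[n]) for n in names], dtype=np.int64)
    ab = np.ones(len(names)) if abundances is None else np.asarray(abundances, dtype=np.float64)
    weights = ab * lengths
    weights = weights / weights.sum()
    reads: dict[str, str] = {}
    rows = {"read_id": [], "genome": [], "start": [], "end": []}
    if n_reads:
        origin = rng.choice(len(names), size=n_reads, p=weights)
        lens = np.clip(
            rng.normal(length_mean, length_mean / 5, size=n_reads), length_mean / 10, None
        ).astype(np.int64)
        lens = np.minimum(lens, lengths[origin])
        starts = (rng.random(n_reads) * (lengths[origin] - lens + 1)).astype(np.int64)
        seqs = [genomes[names[g]][s : s + l] for g, s, l in zip(origin, starts, lens)]
        seqs = _apply_substitutions(seqs, error_rate, rng)
        for i in range(n_reads):
            rid = f"L{i}"
            reads[rid] = seqs[i]
            rows["read_id"].append(rid)
            rows["genome"].append(names[origin[i]])
            rows["start"].append(int(starts[i]))
            rows["end"].append(int(starts[i] + lens[i]))
    return reads, pd.DataFrame(rows)


def barcode_truth_labels(truth: TruthTable) -> dict[str, str]:
    """Majority source genome per barcode (ties broken lexicographically)."""
    counts = truth.pairs.groupby(["barcode", "genome"]).size().reset_index(name="n")
    counts = counts.sort_values(["barcode", "n", "genome"], ascending=[True, False, True])
    return dict(counts.drop_duplicates("barcode")[["barcode", "genome"]].values)
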