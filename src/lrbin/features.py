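"""Per-barcode feature extraction: abundance histogram and TNF vector.

Each barcode group is summarized by two L1-normalized vectors:

* ``X_A`` (400 dims) -- the *k*-mer abundance histogram.  Global 15-mer
  occurrence counts are computed once over the whole dataset; every
  15-mer of the group with global frequency f in (0, 4000] falls into bin
  ceil(f/10).  Frequencies above 4000 are discarded as repetitive
  sequence.  The histogram is a proxy for the abundance of the genome the
  co-barcoded reads came from: at low abundance the erroneous-k-mer peak
  and the true-abundance peak of the frequency distribution coincide in
  the low bins, concentrating the histogram mass.
* ``X_T`` (136 dims) -- tetranucleotide frequencies over
  reverse-complement-collapsed 4-mer classes, a composition signature.

Concatenated (536 dims) they are the input of the variational embedder.
``max(X_A)**2`` serves as the abundance-balancing sampling weight: the
histogram of a low-abundance genome is more concentrated, so its maximum
is larger, and squaring accentuates that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from lrbin import _kmers
from lrbin.linked_reads import BarcodeGroup

N_TNF = _kmers.N_TETRAMER_CLASSES  # 136 canonical tetramer classes


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the feature space.

    The histogram covers global frequencies 1..``max_kmer_frequency`` in
    ``n_bins`` bins of ``bin_width``; the three must satisfy
    n_bins * bin_width == max_kmer_frequency.  ``canonical`` collapses
    15-mers with their reverse complements in both the global table and
    the histogram lookup (reads come from both strands); set it False to
    count literal k-mers instead.
    """

    kmer_size: int = 15
    max_kmer_frequency: int = 4000
    bin_width: int = 10
    n_bins: int = 400
    tnf_k: int = 4
    pseudo: float = 1e-9
    canonical: bool = True

    def __post_init__(self) -> None:
        if self.n_bins * self.bin_width != self.max_kmer_frequency:
            raise ValueError("n_bins * bin_width must equal max_kmer_frequency")
        if self.kmer_size % 2 == 0:
            raise ValueError("kmer_size must be odd (canonical form must be unique)")


class GlobalKmerTable:
    """Global canonical 15-mer occurrence counts over the whole dataset."""

    def __init__(self, keys: np.ndarray, counts: np.ndarray, k: int, canonical: bool = True):
        if keys.size and (np.any(counts < 1) or np.any(np.diff(keys) <= 0)):
            raise ValueError("table keys must be strictly sorted with counts >= 1")
        self.keys = keys
        self.counts = counts
        self.k = k
        self.canonical = canonical

    def __len__(self) -> int:
        return int(self.keys.size)

    def lookup(self, values: np.ndarray) -> np.ndarray:
        """Global frequency for each k-mer value; 0 for unseen k-mers."""
        if self.keys.size == 0:
            return np.zeros(values.size, dtype=np.int64)
        idx = np.searchsorted(self.keys, values)
        idx = np.clip(idx, 0, self.keys.size - 1)
        hit = self.keys[idx] == values
        return np.where(hit, self.counts[idx], 0)

    def save(self, path) -> None:
        np.savez(path, keys=self.keys, counts=self.counts,
                 k=np.int64(self.k), canonical=np.bool_(self.canonical))

    @classmethod
    def load(cls, path) -> "GlobalKmerTable":
        data = np.load(path)
        return cls(data["keys"], data["counts"], int(data["k"]), bool(data["canonical"]))


@dataclass
class FeatureRecord:
    """Feature vectors of one barcode group.

    ``flagged`` marks records whose histogram came out all-zero (every
    group k-mer above the repetitive cap, or no valid k-mers); such
    records are excluded from embedder training.
    """

    barcode: str
    x_a: np.ndarray
    x_t: np.ndarray
    sampling_weight: float
    flagged: bool = False

    @property
    def concat(self) -> np.ndarray:
        return np.concatenate([self.x_a, self.x_t])


def _group_sequences(group) -> Iterable[str]:
    if isinstance(group, BarcodeGroup):
        # one N-joined string: windows never span read boundaries (N is
        # invalid), so counts equal per-read processing at a fraction of
        # the per-call overhead
        yield "N".join(s for pair in group.pairs for s in (pair.seq1, pair.seq2))
    elif isinstance(group, str):
        yield group
    else:  # any iterable of sequences
        yield from group


def build_global_kmer_table(
    reads: Iterable,
    config: FeatureConfig = FeatureConfig(),
    merge_every: int = 4_000_000,
) -> GlobalKmerTable:
    """Count canonical 15-mer occurrences over the whole dataset.

    ``reads`` may yield sequences, read pairs, or barcode groups.  Every
    window without N contributes 1 to its canonical key.  Counting is a
    single streaming pass with bounded memory (see
    :class:`lrbin._kmers.KmerCounter`); counts are exact regardless of
    the merge schedule.
    """
    counter = _kmers.KmerCounter(config.kmer_size, config.canonical, merge_every)
    for item in reads:
        if hasattr(item, "seq1"):  # BarcodedReadPair
            counter.add(item.seq1)
            counter.add(item.seq2)
        else:
            for seq in _group_sequences(item):
                counter.add(seq)
    keys, counts = counter.finalize()
    return GlobalKmerTable(keys, counts, config.kmer_size, config.canonical)


def abundance_histogram(
    group,
    table: GlobalKmerTable,
    config: FeatureConfig = FeatureConfig(),
) -> np.ndarray:
    """L1-normalized 400-bin histogram of the group's global 15-mer frequencies.

    Bin i (1-based) is right-closed, covering frequencies in
    (bin_width*(i-1), bin_width*i]; frequency ``max_kmer_frequency``
    lands in the last bin and anything above is discarded.  Returns the
    all-zero vector when no k-mer survives.
    """
    hist = np.zeros(config.n_bins, dtype=np.float64)
    for seq in _group_sequences(group):
        vals = _kmers.kmer_values(seq, config.kmer_size, config.canonical)
        if vals.size == 0:
            continue
        freq = table.lookup(vals)
        freq = freq[(freq > 0) & (freq <= config.max_kmer_frequency)]
        if freq.size == 0:
            continue
        bins = (freq + config.bin_width - 1) // config.bin_width  # ceil, 1-based
        hist += np.bincount(bins - 1, minlength=config.n_bins).astype(np.float64)
    total = hist.sum()
    if total > 0:
        hist /= total
    return hist


def tnf_vector(group, config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """L1-normalized tetranucleotide frequencies over 136 canonical classes."""
    counts = np.zeros(N_TNF, dtype=np.float64)
    for seq in _group_sequences(group):
        vals = _kmers.kmer_values(seq, config.tnf_k, canonical=False)
        if vals.size:
            counts += np.bincount(_kmers.TETRAMER_CLASS[vals], minlength=N_TNF).astype(np.float64)
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts


def sampling_weight(x_a: np.ndarray) -> float:
    """Abundance-balancing weight ``max(X_A)**2`` (0 for an all-zero histogram)."""
    return float(np.max(x_a)) ** 2 if x_a.size else 0.0


def extract_features(
    groups: Sequence[BarcodeGroup],
    table: GlobalKmerTable,
    config: FeatureConfig = FeatureConfig(),
) -> list[FeatureRecord]:
    """Feature records for every barcode group, in input order."""
    records = []
    for group in groups:
        x_a = abundance_histogram(group, table, config)
        x_t = tnf_vector(group, config)
        flagged = not np.any(x_a > 0)
        records.append(
            FeatureRecord(
                barcode=group.barcode if isinstance(group, BarcodeGroup) else str(len(records)),
                x_a=x_a,
                x_t=x_t,
                sampling_weight=sampling_weight(x_a),
                flagged=flagged,
            )
        )
    return records


def save_features(records: Sequence[FeatureRecord], matrix_path, index_path) -> None:
    """Persist records as a dense matrix (.npy) plus a barcode index TSV."""
    mat = np.stack([r.concat for r in records]) if records else np.empty((0, 536))
    np.save(matrix_path, mat)
    with open(index_path, "w") as out:
        out.write("barcode\tsampling_weight\tflagged\n")
        for r in records:
            out.write(f"{r.barcode}\t{r.sampling_weight:.10g}\t{int(r.flagged)}\n")


def load_features(matrix_path, index_path, config: FeatureConfig = FeatureConfig()) -> list[FeatureRecord]:
    mat = np.load(matrix_path)
    records = []
    with open(index_path) as fh:
        header = fh.readline()
        assert header.startswith("barcode")
        for i, line in enumerate(fh):
            barcode, weight, flagged = line.rstrip("\n").split("\t")
            records.append(
                FeatureRecord(
                    barcode=barcode,
                    x_a=mat[i, : config.n_bins].copy(),
                    x_t=mat[i, config.n_bins :].copy(),
                    sampling_weight=float(weight),
                    flagged=bool(int(flagged)),
                )
            )
    return records
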