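"""Feature extraction vs a naive window-enumeration oracle, plus invariants."""

import numpy as np
import pytest

from lrbin import _kmers
from lrbin.features import (
    FeatureConfig,
    GlobalKmerTable,
    abundance_histogram,
    build_global_kmer_table,
    extract_features,
    sampling_weight,
    tnf_vector,
)
from lrbin.linked_reads import BarcodeGroup
from tests.conftest import make_pair, random_pairs

_COMP = str.maketrans("ACGT", "TGCA")


def _rc(s):
    return s.translate(_COMP)[::-1]


def naive_kmer_counts(seqs, k, canonical=True):
    """O(n*k) string-slicing oracle for canonical k-mer counting."""
    counts = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if set(window) - set("ACGT"):
                continue
            if canonical:
                window = min(window, _rc(window))
            counts[window] = counts.get(window, 0) + 1
    return counts


def naive_histogram(group_seqs, all_seqs, config):
    global_counts = naive_kmer_counts(all_seqs, config.kmer_size)
    hist = np.zeros(config.n_bins)
    for seq in group_seqs:
        for i in range(len(seq) - config.kmer_size + 1):
            window = seq[i : i + config.kmer_size]
            if set(window) - set("ACGT"):
                continue
            f = global_counts[min(window, _rc(window))]
            if 0 < f <= config.max_kmer_frequency:
                hist[-(-f // config.bin_width) - 1] += 1
    return hist / hist.sum() if hist.sum() else hist


def naive_tnf(seqs):
    counts = naive_kmer_counts(seqs, 4, canonical=True)
    classes = sorted(
        {min("".join(t), _rc("".join(t))) for t in __import__("itertools").product("ACGT", repeat=4)}
    )
    vec = np.array([counts.get(c, 0) for c in classes], dtype=float)
    return vec / vec.sum() if vec.sum() else vec


def test_tetramer_class_count_is_136():
    assert _kmers.N_TETRAMER_CLASSES == 136


def test_global_table_homopolymer():
    # "A"*20 has 6 windows of the single 15-mer A^15
    table = build_global_kmer_table(["A" * 20])
    assert len(table) == 1
    assert table.counts.tolist() == [6]
    assert table.keys.tolist() == [0]  # A^15 encodes to 0 and is its own canonical


def test_global_table_revcomp_doubles():
    seq = "ACGTTGCAAGGTCCATTGCA"
    t1 = build_global_kmer_table([seq])
    t2 = build_global_kmer_table([seq, _rc(seq)])
    assert t1.keys.tolist() == t2.keys.tolist()
    assert (2 * t1.counts).tolist() == t2.counts.tolist()


def test_n_windows_not_counted():
    table = build_global_kmer_table(["A" * 7 + "N" + "A" * 7])  # every window spans the N
    assert len(table) == 0


def test_kmer_counter_exact_regardless_of_merge_schedule():
    seqs = ["".join(np.random.default_rng(5).choice(list("ACGTN"), size=60)) for _ in range(8)]
    fine = build_global_kmer_table(seqs, merge_every=10)
    coarse = build_global_kmer_table(seqs)
    assert fine.keys.tolist() == coarse.keys.tolist()
    assert fine.counts.tolist() == coarse.counts.tolist()
    oracle = naive_kmer_counts(seqs, 15)
    assert sum(oracle.values()) == int(fine.counts.sum())


def test_histogram_binning_boundaries():
    config = FeatureConfig()
    # synthetic table: three known 15-mers with frequencies 25, 4000, 4001
    kmers = ["A" * 15, "AC" * 7 + "A", "AG" * 7 + "A"]
    values = [_kmers.kmer_values(s, 15)[0] for s in kmers]
    order = np.argsort(values)
    table = GlobalKmerTable(
        np.array(values, dtype=np.int64)[order],
        np.array([25, 4000, 4001], dtype=np.int64)[order],
        k=15,
    )
    h25 = abundance_histogram(kmers[0], table, config)
    assert h25[2] == 1.0 and h25.sum() == 1.0  # (20,30] is bin 3 -> index 2
    h4000 = abundance_histogram(kmers[1], table, config)
    assert h4000[399] == 1.0  # cap retained in last bin
    h4001 = abundance_histogram(kmers[2], table, config)
    assert not h4001.any()  # above cap -> discarded entirely


def test_features_match_naive_oracle():
    rng = np.random.default_rng(42)
    seqs = ["".join(rng.choice(list("ACGTN"), size=80, p=[0.24] * 4 + [0.04])) for _ in range(10)]
    group = seqs[:4]
    config = FeatureConfig()
    table = build_global_kmer_table(seqs, config)
    np.testing.assert_allclose(
        abundance_histogram(group, table, config), naive_histogram(group, seqs, config),
        atol=1e-12,
    )
    np.testing.assert_allclose(tnf_vector(group, config), naive_tnf(group), atol=1e-12)


def test_feature_dimensions_and_normalization(small_community):
    groups = small_community["groups"][:20]
    table = build_global_kmer_table(groups)
    records = extract_features(groups, table)
    for r in records:
        assert r.x_a.shape == (400,) and r.x_t.shape == (136,) and r.concat.shape == (536,)
        if not r.flagged:
            assert abs(r.x_a.sum() - 1) < 1e-9
        assert abs(r.x_t.sum() - 1) < 1e-9


def test_invariance_to_read_order_and_revcomp():
    pairs = random_pairs(6, "1_1_1", seed=9)
    table = build_global_kmer_table(pairs)
    config = FeatureConfig()
    fwd = BarcodeGroup("1_1_1", pairs)
    rev = BarcodeGroup("1_1_1", pairs[::-1])
    flip = BarcodeGroup(
        "1_1_1",
        [make_pair(p.read_id, _rc(p.seq1), _rc(p.seq2), barcode=p.barcode) for p in pairs],
    )
    for other in (rev, flip):
        np.testing.assert_allclose(
            abundance_histogram(fwd, table, config), abundance_histogram(other, table, config)
        )
        np.testing.assert_allclose(tnf_vector(fwd, config), tnf_vector(other, config))


@pytest.mark.parametrize(
    "x,expected",
    [
        (np.array([0.5, 0.5] + [0.0] * 398), 0.25),
        (np.full(400, 1 / 400), (1 / 400) ** 2),
        (np.eye(400)[0], 1.0),
        (np.zeros(400), 0.0),
    ],
)
def test_sampling_weight(x, expected):
    assert sampling_weight(x) == pytest.approx(expected)


def test_low_abundance_histogram_is_more_concentrated(small_community):
    """The weighting premise: barcodes of the rarest genome show larger max(X_A)."""
    from lrbin.simulate import barcode_truth_labels

    groups = small_community["groups"]
    table = build_global_kmer_table(groups)
    records = extract_features(groups, table)
    labels = barcode_truth_labels(small_community["truth"])
    by_genome = {}
    for r in records:
        by_genome.setdefault(labels[r.barcode], []).append(np.max(r.x_a))
    # g0 is the most abundant genome, g2 the rarest
    assert np.mean(by_genome["g2"]) > np.mean(by_genome["g0"])


def test_config_validation():
    with pytest.raises(ValueError, match="bin_width"):
        FeatureConfig(n_bins=100)
    with pytest.raises(ValueError, match="odd"):
        FeatureConfig(kmer_size=14)


def test_kmer_table_round_trip(tmp_path):
    seqs = ["ACGTACGTACGTACGTACGT", "TTTTTTTTTTTTTTTTTT"]
    table = build_global_kmer_table(seqs)
    path = tmp_path / "table.npz"
    table.save(path)
    loaded = GlobalKmerTable.load(path)
    assert loaded.keys.tolist() == table.keys.tolist()
    assert loaded.counts.tolist() == table.counts.tolist()
    assert (loaded.k, loaded.canonical) == (15, True)
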