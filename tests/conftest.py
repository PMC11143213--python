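"""Shared fixtures: hand-built read pairs and a small simulated community."""

from __future__ import annotations

import numpy as np
import pytest

from lrbin import simulate as sim
from lrbin.linked_reads import BarcodedReadPair, group_by_barcode


def make_pair(read_id: str, seq1: str, seq2: str, barcode=None, technology="stlfr"):
    return BarcodedReadPair(
        read_id=read_id, seq1=seq1, seq2=seq2,
        qual1="I" * len(seq1), qual2="I" * len(seq2),
        barcode=barcode, technology=technology,
    )


def random_pairs(n: int, barcode, length: int = 100, seed: int = 0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        s1 = "".join(rng.choice(list("ACGT"), size=length))
        s2 = "".join(rng.choice(list("ACGT"), size=length))
        out.append(make_pair(f"{barcode}-r{i}", s1, s2, barcode=barcode))
    return out


@pytest.fixture(scope="session")
def small_community():
    """Three 60 kb genomes with 100x/30x/10x abundance and 400 barcodes."""
    cc = sim.CommunityConfig(genome_length=60_000)
    genomes = sim.simulate_genomes(cc, seed=101)
    lrc = sim.LinkedReadConfig(
        n_barcodes=400, mean_fragments_per_barcode=1.54,
        pairs_per_fragment_mean=12.0, seed=102,
    )
    pairs, truth = sim.simulate_linked_reads(genomes, cc, lrc)
    groups, pool = group_by_barcode(pairs)
    return {
        "config": cc, "lrc": lrc, "genomes": genomes,
        "pairs": pairs, "truth": truth, "groups": groups, "pool": pool,
    }
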