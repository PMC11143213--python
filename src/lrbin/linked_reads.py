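"""Barcoded FASTQ I/O and grouping of read pairs by barcode.

Three vendor dialects are supported for carrying the barcode in the FASTQ
title line:

* ``stlfr``   -- barcode appended to the read name after the last ``#``,
  e.g. ``@V300017_L01_1/1#123_456_789``.  The all-zero token ``0_0_0``
  marks an unresolved bead and is treated as no barcode.
* ``tellseq`` / ``tenx`` / ``virtual`` -- a SAM-style ``BX:Z:`` tag in the
  title comment, e.g. ``@r9 BX:Z:ACGTACGT-1``.

The dialect is always an explicit argument: title lines are ambiguous
across vendors, so auto-detection is deliberately not offered.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Literal

from Bio.SeqIO.QualityIO import FastqGeneralIterator

#: Sentinel for "this read pair carries no (resolved) barcode".
ABSENT = None

Dialect = Literal["stlfr", "tellseq", "tenx", "virtual"]

_DIALECTS = ("stlfr", "tellseq", "tenx", "virtual")
_DNA_RE = re.compile(r"^[ACGTN]*$")
_BX_RE = re.compile(r"(?:^|\s)BX:Z:(\S+)")
# stLFR null barcode: every numeric field zero, e.g. 0_0_0
_STLFR_NULL_RE = re.compile(r"^0(?:_0)*$")


class FastqParseError(ValueError):
    """Raised for malformed barcoded-FASTQ input, naming the offending line."""


@dataclass
class BarcodedReadPair:
    """One paired-end read with an optional barcode.

    ``barcode`` is :data:`ABSENT` (``None``) when the pair carries no
    resolved barcode.  Sequences use the {A,C,G,T,N} alphabet and each
    quality string has the same length as its mate sequence.
    """

    read_id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str
    barcode: str | None = ABSENT
    technology: Dialect = "stlfr"

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"seq/qual length mismatch for read {self.read_id!r}")
        if self.barcode is not ABSENT and not self.barcode:
            raise ValueError(f"empty barcode for read {self.read_id!r}; use ABSENT")
        for seq in (self.seq1, self.seq2):
            if not _DNA_RE.match(seq):
                raise ValueError(f"non-ACGTN character in read {self.read_id!r}")

    @property
    def total_bases(self) -> int:
        return len(self.seq1) + len(self.seq2)


@dataclass
class BarcodeGroup:
    """All read pairs sharing one barcode -- the unit of binning."""

    barcode: str
    pairs: list[BarcodedReadPair] = field(default_factory=list)

    @property
    def total_bases(self) -> int:
        return sum(p.total_bases for p in self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def parse_barcode(read_header: str, dialect: Dialect, line_number: int | None = None) -> str | None:
    """Extract the barcode token from a FASTQ title line (without the ``@``).

    Returns :data:`ABSENT` when the token is missing or equals the
    dialect's null token (stLFR ``0_0_0``).  Malformed headers raise
    :class:`FastqParseError` naming ``line_number`` when given.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    where = f" at line {line_number}" if line_number is not None else ""
    if not read_header or read_header[0] == "@":
        raise FastqParseError(f"malformed FASTQ header {read_header!r}{where}")
    if dialect == "stlfr":
        name = read_header.split(None, 1)[0]
        if "#" not in name:
            return ABSENT
        token = name.rsplit("#", 1)[1]
        if not token:
            raise FastqParseError(f"empty stLFR barcode token in {read_header!r}{where}")
        if _STLFR_NULL_RE.match(token):
            return ABSENT
        return token
    m = _BX_RE.search(read_header)
    if m is None:
        return ABSENT
    return m.group(1)


def strip_barcode(read_header: str, dialect: Dialect) -> str:
    """Read id with any barcode decoration removed (pairs share this id)."""
    name = read_header.split(None, 1)[0]
    if dialect == "stlfr" and "#" in name:
        name = name.rsplit("#", 1)[0]
    # strip /1, /2 mate suffixes so both mates share an id
    if name.endswith("/1") or name.endswith("/2"):
        name = name[:-2]
    return name


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(
    path1,
    path2=None,
    dialect: Dialect = "stlfr",
) -> Iterator[BarcodedReadPair]:
    """Stream read pairs from two-file paired or interleaved barcoded FASTQ.

    With ``path2`` given, mate 1 comes from ``path1`` and mate 2 from
    ``path2`` record-by-record; otherwise ``path1`` is interleaved
    (mate 1 followed by mate 2).  Plain or gzip-compressed files accepted.
    """
    if path2 is not None:
        with _open_text(path1) as h1, _open_text(path2) as h2:
            it1 = FastqGeneralIterator(h1)
            it2 = FastqGeneralIterator(h2)
            for lineno, ((t1, s1, q1), (t2, s2, q2)) in enumerate(zip(it1, it2)):
                yield _pair_from_titles(t1, s1, q1, t2, s2, q2, dialect, 4 * lineno + 1)
            # detect ragged inputs
            for leftover in (it1, it2):
                try:
                    next(leftover)
                except StopIteration:
                    continue
                raise FastqParseError("paired FASTQ files have unequal record counts")
    else:
        with _open_text(path1) as h:
            it = FastqGeneralIterator(h)
            for lineno, (t1, s1, q1) in enumerate(it):
                try:
                    t2, s2, q2 = next(it)
                except StopIteration:
                    raise FastqParseError(
                        f"interleaved FASTQ ends with an unpaired record {t1!r}"
                    ) from None
                yield _pair_from_titles(t1, s1, q1, t2, s2, q2, dialect, 8 * lineno + 1)


def _pair_from_titles(t1, s1, q1, t2, s2, q2, dialect: Dialect, line_number: int) -> BarcodedReadPair:
    bc1 = parse_barcode(t1, dialect, line_number)
    bc2 = parse_barcode(t2, dialect, line_number)
    if bc1 != bc2:
        raise FastqParseError(
            f"mates disagree on barcode ({bc1!r} vs {bc2!r}) near line {line_number}"
        )
    read_id = strip_barcode(t1, dialect)
    if read_id != strip_barcode(t2, dialect):
        raise FastqParseError(
            f"mates disagree on read id ({t1!r} vs {t2!r}) near line {line_number}"
        )
    return BarcodedReadPair(
        read_id=read_id, seq1=s1.upper(), seq2=s2.upper(), qual1=q1, qual2=q2,
        barcode=bc1, technology=dialect,
    )


def _title(pair: BarcodedReadPair, mate: int, dialect: Dialect) -> str:
    if dialect == "stlfr":
        bc = pair.barcode if pair.barcode is not ABSENT else "0_0_0"
        return f"{pair.read_id}/{mate}#{bc}"
    if pair.barcode is not ABSENT:
        return f"{pair.read_id}/{mate} BX:Z:{pair.barcode}"
    return f"{pair.read_id}/{mate}"


def write_fastq_pairs(
    pairs: Iterable[BarcodedReadPair],
    path1,
    path2=None,
    dialect: Dialect = "stlfr",
) -> int:
    """Write pairs as barcoded FASTQ; returns the number of pairs written.

    Round-trips with :func:`read_fastq_pairs`: sequences, qualities and
    barcodes are reproduced byte-identically per dialect.
    """
    n = 0
    if path2 is not None:
        with _open_text(path1, "wt") as h1, _open_text(path2, "wt") as h2:
            for pair in pairs:
                h1.write(f"@{_title(pair, 1, dialect)}\n{pair.seq1}\n+\n{pair.qual1}\n")
                h2.write(f"@{_title(pair, 2, dialect)}\n{pair.seq2}\n+\n{pair.qual2}\n")
                n += 1
    else:
        with _open_text(path1, "wt") as h:
            for pair in pairs:
                h.write(f"@{_title(pair, 1, dialect)}\n{pair.seq1}\n+\n{pair.qual1}\n")
                h.write(f"@{_title(pair, 2, dialect)}\n{pair.seq2}\n+\n{pair.qual2}\n")
                n += 1
    return n


def group_by_barcode(
    pairs: Iterable[BarcodedReadPair],
    min_total_bases: int = 2000,
) -> tuple[list[BarcodeGroup], list[BarcodedReadPair]]:
    """Group read pairs by barcode, keeping groups with enough sequence.

    Co-barcoded reads only give stable abundance/composition features when
    the group carries enough sequence, so groups below ``min_total_bases``
    (default 2 kb) are diverted -- together with barcode-less pairs -- to a
    leftover pool.  Groups preserve input read order, and the union of the
    returned groups and the pool equals the input exactly.
    """
    by_barcode: dict[str, BarcodeGroup] = {}
    pool: list[BarcodedReadPair] = []
    for pair in pairs:
        if pair.barcode is ABSENT:
            pool.append(pair)
            continue
        group = by_barcode.get(pair.barcode)
        if group is None:
            group = by_barcode[pair.barcode] = BarcodeGroup(pair.barcode)
        group.pairs.append(pair)
    groups: list[BarcodeGroup] = []
    for group in by_barcode.values():
        if group.total_bases >= min_total_bases:
            groups.append(group)
        else:
            pool.extend(group.pairs)
    return groups, pool
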