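"""MAG quality tiers and the alignment sequence-identity statistic.

Tiers follow the minimum-information-about-MAGs convention:

* ``near_complete`` -- completeness > 90%, contamination < 5%, all
  three rRNAs (5S, 16S, 23S) detected and at least 18 tRNAs;
* ``high``          -- completeness > 90% and contamination < 5%;
* ``medium``        -- completeness >= 50% and contamination < 10%;
* ``low``           -- everything else.

Rules are applied in order, so every MAG gets exactly one tier, and the
inequalities are exactly as stated (strict for 90/5/10, inclusive for
50 and 18).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd


class QualityTier(str, Enum):
    near_complete = "near_complete"
    high = "high"
    medium = "medium"
    low = "low"


@dataclass(frozen=True)
class MagMetrics:
    """External quality metrics of one MAG (completeness/contamination in %)."""

    name: str
    completeness: float
    contamination: float
    has_5s: bool = False
    has_16s: bool = False
    has_23s: bool = False
    trna_count: int = 0
    n50: int | None = None
    mean_depth: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.completeness <= 100 and 0 <= self.contamination <= 100):
            raise ValueError(f"percentages out of [0, 100] for MAG {self.name!r}")
        if self.trna_count < 0:
            raise ValueError(f"negative tRNA count for MAG {self.name!r}")


def classify_mag(m: MagMetrics) -> QualityTier:
    """First matching tier rule wins (see module docstring)."""
    if (
        m.completeness > 90
        and m.contamination < 5
        and m.has_5s and m.has_16s and m.has_23s
        and m.trna_count >= 18
    ):
        return QualityTier.near_complete
    if m.completeness > 90 and m.contamination < 5:
        return QualityTier.high
    if m.completeness >= 50 and m.contamination < 10:
        return QualityTier.medium
    return QualityTier.low


def sequence_identity(total_aligned: float, mismatches: float) -> float:
    """(Total_Aligned_Length - Mismatches) / Total_Aligned_Length."""
    if total_aligned <= 0:
        raise ValueError("total_aligned must be positive")
    if not (0 <= mismatches <= total_aligned):
        raise ValueError("mismatches must lie in [0, total_aligned]")
    return (total_aligned - mismatches) / total_aligned


def count_ncmags(
    metrics: Iterable[MagMetrics],
    min_n50: int | None = None,
    max_depth: float | None = None,
) -> int:
    """Number of near-complete MAGs, optionally filtered by N50 / depth.

    ``min_n50`` keeps MAGs with N50 strictly above the threshold (e.g.
    1 Mb); ``max_depth`` keeps MAGs below the given mean depth.  Asking
    for a filter on a metric a MAG does not carry is an error.
    """
    n = 0
    for m in metrics:
        if classify_mag(m) is not QualityTier.near_complete:
            continue
        if min_n50 is not None:
            if m.n50 is None:
                raise ValueError(f"MAG {m.name!r} lacks n50 but min_n50 was requested")
            if not m.n50 > min_n50:
                continue
        if max_depth is not None:
            if m.mean_depth is None:
                raise ValueError(f"MAG {m.name!r} lacks mean_depth but max_depth was requested")
            if not m.mean_depth < max_depth:
                continue
        n += 1
    return n


_COLUMNS = ["name", "completeness", "contamination", "has_5s", "has_16s",
            "has_23s", "trna_count", "n50", "mean_depth"]


def read_mag_metrics(path) -> list[MagMetrics]:
    """Load MAG metrics from TSV with the documented column header."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise ValueError(f"metrics TSV missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples():
        out.append(
            MagMetrics(
                name=str(row.name),
                completeness=float(row.completeness),
                contamination=float(row.contamination),
                has_5s=bool(row.has_5s),
                has_16s=bool(row.has_16s),
                has_23s=bool(row.has_23s),
                trna_count=int(row.trna_count),
                n50=None if "n50" not in df.columns or pd.isna(row.n50) else int(row.n50),
                mean_depth=None if "mean_depth" not in df.columns or pd.isna(row.mean_depth)
                else float(row.mean_depth),
            )
        )
    return out


def write_mag_tiers(metrics: Sequence[MagMetrics], path) -> None:
    with open(path, "w") as out:
        out.write("name\ttier\n")
        for m in metrics:
            out.write(f"{m.name}\t{classify_mag(m).value}\n")
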