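"""TFBS peak overlap and rare coding-variant filtering.

Two independent annotation tasks share coordinate conventions here:

* overlap of 1-based SNP positions with BED-style peak intervals (0-based,
  half-open) — e.g. checking whether a candidate regulatory SNP falls in a
  CTCF ChIP peak;
* filtering of annotated coding variants down to rare, potentially
  protein-altering calls: population allele frequency strictly below a
  cut-off (default 1%), consequence among the protein-altering classes,
  and not inside a segmental duplication (where short-read calls are
  unreliable).

Pathogenicity scores (CADD, protein-stability ddG) are passthrough
annotations: consumed, never computed.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import FormatError

__all__ = [
    "PeakSet",
    "VariantRecord",
    "KEEP_CONSEQUENCES",
    "overlap_snps_peaks",
    "filter_rare_coding",
    "carrier_summary",
    "read_peaks_bed",
    "read_variant_table",
    "to_zero_based",
]

#: protein-altering consequence classes retained by the rare-variant filter
KEEP_CONSEQUENCES = frozenset(
    {"nonsynonymous_SNV", "stopgain", "frameshift_indel", "nonframeshift_indel"}
)

VALID_CONSEQUENCES = KEEP_CONSEQUENCES | {"synonymous_SNV", "other"}


def to_zero_based(pos_1based: int) -> int:
    """Convert a 1-based position to its 0-based coordinate.

    Centralized so BED (0-based half-open) and VCF/summary-stat (1-based)
    conventions meet in exactly one place: a 1-based SNP position p overlaps
    a BED interval [s, e) iff s <= p-1 < e.
    """
    return pos_1based - 1


@dataclass(frozen=True)
class PeakSet:
    """TFBS peak intervals, 0-based half-open, e.g. from ENCODE ChIP."""

    intervals: tuple  # of (chrom, start, end, label)
    source: str = ""

    def __post_init__(self) -> None:
        ivs = tuple(tuple(iv) for iv in self.intervals)
        for chrom, start, end, _label in ivs:
            if start >= end:
                raise FormatError(f"malformed interval {chrom}:{start}-{end} (start >= end)")
        object.__setattr__(self, "intervals", ivs)


@dataclass(frozen=True)
class VariantRecord:
    """Annotated coding variant with carriers and passthrough annotations.

    ``pop_af`` is the population (e.g. non-Finnish European) alt-allele
    frequency; ``None`` means never observed and is treated as rare.
    """

    snp_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    pop_af: float | None = None
    in_segdup: bool = False
    carriers: tuple = ()  # of (sample_id, genotype string e.g. '0/1')
    annotations: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.consequence not in VALID_CONSEQUENCES:
            raise FormatError(
                f"{self.snp_id}: unknown consequence {self.consequence!r}; "
                f"expected one of {sorted(VALID_CONSEQUENCES)}"
            )
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise FormatError(f"{self.snp_id}: pop_af outside [0, 1]: {self.pop_af}")
        object.__setattr__(self, "carriers", tuple(tuple(c) for c in self.carriers))


def overlap_snps_peaks(
    snps: Iterable[tuple[str, int]],
    peaks: PeakSet,
) -> dict[tuple[str, int], list[str]]:
    """Map each (chrom, 1-based pos) SNP to the labels of overlapping peaks.

    Uses an interval tree per chromosome; results are sorted by label for
    determinism.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for chrom, start, end, label in peaks.intervals:
        trees[chrom].addi(start, end, label)
    out: dict[tuple[str, int], list[str]] = {}
    for chrom, pos in snps:
        hits = trees[chrom][to_zero_based(pos)] if chrom in trees else ()
        out[(chrom, pos)] = sorted(iv.data for iv in hits)
    return out


def filter_rare_coding(
    variants: Sequence[VariantRecord],
    af_max: float = 0.01,
) -> list[VariantRecord]:
    """Keep rare protein-altering variants outside segmental duplications.

    A variant survives iff its population AF is strictly below ``af_max``
    (missing AF counts as rare), its consequence is protein-altering
    (synonymous SNVs and 'other' are dropped), and it is not flagged as
    falling in a segmental duplication.  Monotone in ``af_max``: the output
    at a smaller cut-off is a subset of the output at a larger one.
    """
    if not (0.0 < af_max < 1.0):
        raise ValueError(f"af_max must be in (0, 1), got {af_max}")
    return [
        v
        for v in variants
        if (v.pop_af is None or v.pop_af < af_max)
        and v.consequence in KEEP_CONSEQUENCES
        and not v.in_segdup
    ]


def carrier_summary(
    variants: Sequence[VariantRecord],
    n_samples: int,
) -> dict[str, tuple[int, float]]:
    """Per-variant carrier count and percentage of the cohort.

    A carrier holds at least one alt allele.  Duplicate sample IDs within
    one variant's carrier list are collapsed with a warning.  The percentage
    is rounded to 2 decimals for display (e.g. 3/147 -> 2.04)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    out: dict[str, tuple[int, float]] = {}
    for v in variants:
        seen = {s for s, _gt in v.carriers}
        if len(seen) < len(v.carriers):
            warnings.warn(f"{v.snp_id}: duplicate carrier sample(s) collapsed", stacklevel=2)
        count = len(seen)
        out[v.snp_id] = (count, round(100.0 * count / n_samples, 2))
    return out


def read_peaks_bed(path, source: str = "") -> PeakSet:
    """Read a BED3/BED4 file (0-based half-open); column 4 is the label."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line with fewer than 3 columns: {line!r}")
            label = parts[3] if len(parts) > 3 else f"{parts[0]}:{parts[1]}-{parts[2]}"
            rows.append((parts[0], int(parts[1]), int(parts[2]), label))
    return PeakSet(intervals=tuple(rows), source=source)


# columns of the tab-delimited variant table (mirrors an annotated exome export)
_VARIANT_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt", "consequence",
                    "pop_af", "in_segdup", "carriers"]


def read_variant_table(path) -> list[VariantRecord]:
    """Read a tab-delimited annotated-variant table.

    Required columns: snp_id, chrom, pos, ref, alt, consequence.  Optional:
    pop_af (blank = missing), in_segdup (0/1 or true/false), carriers
    (comma-separated ``sample:genotype`` entries).  Any further columns are
    kept as passthrough annotations.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _VARIANT_COLUMNS[:6]:
        if col not in df.columns:
            raise FormatError(f"variant table missing required column {col!r}")
    extra = [c for c in df.columns if c not in _VARIANT_COLUMNS]
    records = []
    for _, row in df.iterrows():
        af = row.get("pop_af")
        pop_af = None if pd.isna(af) or af == "" else float(af)
        segdup = str(row.get("in_segdup", "0")).strip().lower() in ("1", "true", "yes")
        carriers = []
        raw = row.get("carriers")
        if isinstance(raw, str) and raw:
            for entry in raw.split(","):
                sample, _, gt = entry.partition(":")
                carriers.append((sample, gt or "0/1"))
        records.append(
            VariantRecord(
                snp_id=row["snp_id"],
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                consequence=row["consequence"],
                pop_af=pop_af,
                in_segdup=segdup,
                carriers=tuple(carriers),
                annotations={c: row[c] for c in extra if pd.notna(row[c])},
            )
        )
    return records
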