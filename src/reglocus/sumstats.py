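"""GWAS summary statistics: loading and candidate-SNP selection at a locus.

A record holds one SNP's association summary (position, alleles, effect size
as log-odds per alternative allele, standard error, p-value, allele
frequency).  Candidate selection keeps SNPs inside a genomic region whose
p-value is at or below a suggestive-significance threshold (default
1e-5, the usual sub-genome-wide cut-off).

Coordinates are 1-based inclusive throughout this module, the GWAS
convention; conversion to 0-based half-open happens only at BED interfaces
(see :mod:`reglocus.annotation`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import FormatError

__all__ = [
    "SummaryStatRecord",
    "LocusRegion",
    "DEFAULT_COLUMNS",
    "read_summary_stats",
    "select_candidates",
]

#: default column names in a tab-delimited summary-statistics file.
#: ``beta`` may be replaced by ``or`` (odds ratio); then beta = ln(OR).
DEFAULT_COLUMNS: dict[str, str] = {
    "snp": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "ref": "REF",
    "alt": "ALT",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "af": "AF",
}

_REQUIRED = ("snp", "chrom", "pos", "ref", "alt", "p")


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's GWAS association summary.

    ``alt`` is the effect allele; ``beta`` is the log-odds of disease per alt
    allele, so the odds ratio is ``exp(beta)``.
    """

    snp_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    p: float
    beta: float | None = None
    se: float | None = None
    af_alt: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"{self.snp_id}: position must be >= 1, got {self.pos}")
        if not (0.0 < self.p <= 1.0):
            raise FormatError(f"{self.snp_id}: p-value must be in (0, 1], got {self.p}")
        if self.se is not None and self.se <= 0:
            raise FormatError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.ref == self.alt:
            raise FormatError(f"{self.snp_id}: ref and alt alleles are identical ({self.ref})")
        if self.af_alt is not None and not (0.0 <= self.af_alt <= 1.0):
            raise FormatError(f"{self.snp_id}: allele frequency outside [0, 1]: {self.af_alt}")

    @property
    def odds_ratio(self) -> float | None:
        """Per-alt-allele odds ratio, ``exp(beta)``."""
        return None if self.beta is None else math.exp(self.beta)


@dataclass(frozen=True)
class LocusRegion:
    """A genomic region, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"region start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    @classmethod
    def parse(cls, spec: str) -> "LocusRegion":
        """Parse ``chr3:START-END`` notation."""
        try:
            chrom, span = spec.split(":")
            start, end = span.replace(",", "").split("-")
            return cls(chrom, int(start), int(end))
        except ValueError as exc:
            raise FormatError(f"cannot parse region {spec!r}; expected chrom:start-end") from exc


def read_summary_stats(
    path,
    columns: Mapping[str, str] | None = None,
) -> list[SummaryStatRecord]:
    """Read a tab-delimited summary-statistics file.

    Parameters
    ----------
    path
        File with a header row naming the columns.
    columns
        Mapping from logical names (``snp, chrom, pos, ref, alt, beta, se, p,
        af``) to the header names used in the file; defaults to
        :data:`DEFAULT_COLUMNS`.  Supplying ``"or"`` instead of ``"beta"``
        declares the effect column to be an odds ratio, converted via
        ``beta = ln(OR)``.

    Rows whose p-value is non-numeric or outside (0, 1] are dropped with a
    warning.  A missing required column raises :class:`FormatError` naming it.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
        if "or" in columns and "beta" not in columns:
            colmap.pop("beta", None)

    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and df.columns.size == 0:
        warnings.warn(f"summary-statistics file {path} is empty", stacklevel=2)
        return []

    for key in _REQUIRED:
        if colmap[key] not in df.columns:
            raise FormatError(f"missing required column {colmap[key]!r} (for {key!r})")

    p = pd.to_numeric(df[colmap["p"]], errors="coerce")
    valid = p.notna() & (p > 0) & (p <= 1)
    n_bad = int((~valid).sum())
    if n_bad:
        warnings.warn(f"dropped {n_bad} row(s) with invalid p-value", stacklevel=2)
    df = df.loc[valid].reset_index(drop=True)
    p = p.loc[valid].reset_index(drop=True)

    def _optional(key: str) -> pd.Series | None:
        name = colmap.get(key)
        if name is None or name not in df.columns:
            return None
        return pd.to_numeric(df[name], errors="coerce")

    beta = _optional("beta")
    if beta is None:
        orr = _optional("or")
        if orr is not None:
            beta = orr.map(lambda x: math.log(x) if pd.notna(x) and x > 0 else float("nan"))
    se = _optional("se")
    af = _optional("af")

    records: list[SummaryStatRecord] = []
    for i in range(len(df)):
        def _num(series):
            if series is None:
                return None
            v = series.iloc[i]
            return None if pd.isna(v) else float(v)

        records.append(
            SummaryStatRecord(
                snp_id=str(df[colmap["snp"]].iloc[i]),
                chrom=str(df[colmap["chrom"]].iloc[i]),
                pos=int(df[colmap["pos"]].iloc[i]),
                ref=str(df[colmap["ref"]].iloc[i]),
                alt=str(df[colmap["alt"]].iloc[i]),
                p=float(p.iloc[i]),
                beta=_num(beta),
                se=_num(se),
                af_alt=_num(af),
            )
        )
    return records


def select_candidates(
    records: Sequence[SummaryStatRecord],
    region: LocusRegion,
    p_threshold: float = 1e-5,
) -> list[SummaryStatRecord]:
    """Select candidate SNPs inside ``region`` with ``p <= p_threshold``.

    The threshold boundary is inclusive.  The result is sorted by p-value
    ascending, ties broken by genomic position ascending, so output order is
    deterministic.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError(f"p_threshold must be in (0, 1), got {p_threshold}")
    hits = [r for r in records if region.contains(r.chrom, r.pos) and r.p <= p_threshold]
    hits.sort(key=lambda r: (r.p, r.pos))
    return hits
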