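"""Distance-normalized interaction frequency (DNIF) from Hi-C contact matrices.

Chromatin contact counts decay with genomic distance; to score a specific
SNP-gene contact the raw count is divided by the expected count at the same
bin distance, estimated as the arithmetic mean of the matrix diagonal at
that distance.  A DNIF well above 1 marks an interaction enriched over the
distance background (e.g. a chromatin loop).  Matrices are intra-chromosomal,
binned, and symmetric; the estimator applies no matrix balancing or
smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import FormatError

__all__ = [
    "ContactMatrix",
    "DnifResult",
    "expected_by_distance",
    "dnif",
    "snp_gene_dnif",
    "cross_tissue_rank",
    "read_contact_matrix",
    "write_contact_matrix",
]


@dataclass(frozen=True)
class ContactMatrix:
    """Binned symmetric intra-chromosomal contact matrix.

    ``start_bin_pos`` is the 1-based genomic position of the first base of
    bin 0; bin ``i`` covers positions
    ``[start_bin_pos + i*bin_size, start_bin_pos + (i+1)*bin_size)``.
    """

    chrom: str
    bin_size: int
    start_bin_pos: int
    counts: np.ndarray
    tissue: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise FormatError("counts must be a square matrix")
        if not np.allclose(c, c.T):
            raise FormatError("contact matrix must be symmetric")
        if (c < 0).any():
            raise FormatError("contact counts must be non-negative")
        if self.bin_size <= 0:
            raise FormatError("bin_size must be positive")
        object.__setattr__(self, "counts", c)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def bin_of(self, pos: int, chrom: str | None = None) -> int:
        """Bin index containing 1-based genomic position ``pos``."""
        if chrom is not None and chrom != self.chrom:
            raise IndexError(f"position on {chrom} queried against matrix on {self.chrom}")
        i = (pos - self.start_bin_pos) // self.bin_size
        if not (0 <= i < self.n_bins):
            raise IndexError(
                f"position {pos} outside matrix extent "
                f"[{self.start_bin_pos}, {self.start_bin_pos + self.n_bins * self.bin_size})"
            )
        return int(i)


@dataclass(frozen=True)
class DnifResult:
    bin_i: int
    bin_j: int
    observed: float
    expected: float
    dnif: float
    tissue: str = ""
    degenerate: bool = False  # expected was 0; dnif reported as 0


def expected_by_distance(m: ContactMatrix) -> np.ndarray:
    """Mean contact count per bin distance d = 0 .. n_bins-1."""
    if m.n_bins < 2:
        raise FormatError("need at least 2 bins")
    return np.array([m.counts.diagonal(d).mean() for d in range(m.n_bins)])


def dnif(
    m: ContactMatrix,
    bin_i: int,
    bin_j: int,
    expected: np.ndarray | None = None,
) -> DnifResult:
    """Observed/expected contact score for one bin pair.

    ``expected`` may be precomputed with :func:`expected_by_distance` to
    avoid recomputation over many queries.  A zero expected value yields
    dnif = 0 with ``degenerate=True`` rather than an error.
    """
    n = m.n_bins
    if not (0 <= bin_i < n and 0 <= bin_j < n):
        raise IndexError(f"bin pair ({bin_i}, {bin_j}) outside 0..{n - 1}")
    if expected is None:
        expected = expected_by_distance(m)
    obs = float(m.counts[bin_i, bin_j])
    exp = float(expected[abs(bin_i - bin_j)])
    if exp == 0.0:
        return DnifResult(bin_i, bin_j, obs, exp, 0.0, m.tissue, degenerate=True)
    return DnifResult(bin_i, bin_j, obs, exp, obs / exp, m.tissue)


def snp_gene_dnif(
    m: ContactMatrix,
    snp_pos: int,
    gene_start: int,
    gene_end: int,
    anchor: str = "tss",
) -> DnifResult:
    """DNIF between the SNP's bin and the target gene.

    anchor='tss' scores against the bin containing ``gene_start`` (the
    caller supplies the strand-aware TSS there); anchor='max_over_gene'
    takes the maximal DNIF over all bins overlapping
    [gene_start, gene_end].
    """
    if anchor not in ("tss", "max_over_gene"):
        raise ValueError(f"unknown anchor {anchor!r}")
    bin_i = m.bin_of(snp_pos)
    expected = expected_by_distance(m)
    if anchor == "tss":
        return dnif(m, bin_i, m.bin_of(gene_start), expected)
    if gene_start > gene_end:
        raise FormatError("gene_start must be <= gene_end")
    first = m.bin_of(gene_start)
    last = m.bin_of(gene_end)
    best = None
    for bin_j in range(first, last + 1):
        r = dnif(m, bin_i, bin_j, expected)
        if best is None or r.dnif > best.dnif:
            best = r
    return best


def cross_tissue_rank(
    matrices: Sequence[ContactMatrix],
    snp_pos: int,
    gene_start: int,
    gene_end: int,
    anchor: str = "tss",
) -> list[DnifResult]:
    """Score the SNP-gene contact in every tissue, strongest first.

    Ties are broken by tissue label so the ranking is deterministic and
    independent of input order.
    """
    results = [snp_gene_dnif(m, snp_pos, gene_start, gene_end, anchor) for m in matrices]
    results.sort(key=lambda r: (-r.dnif, r.tissue))
    return results


def write_contact_matrix(m: ContactMatrix, path) -> None:
    """Write the upper triangle as a 3-column triple file with a metadata header."""
    with open(path, "w") as fh:
        fh.write(
            f"#chrom={m.chrom}\tbin_size={m.bin_size}\tstart={m.start_bin_pos}"
            f"\tn_bins={m.n_bins}\ttissue={m.tissue}\n"
        )
        fh.write("bin_i\tbin_j\tcount\n")
        for i in range(m.n_bins):
            for j in range(i, m.n_bins):
                v = m.counts[i, j]
                if v != 0:
                    fh.write(f"{i}\t{j}\t{v:g}\n")


def read_contact_matrix(path) -> ContactMatrix:
    """Read the triple format written by :func:`write_contact_matrix`."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise FormatError("contact matrix file must start with a '#' metadata line")
        meta = dict(kv.split("=", 1) for kv in header.lstrip("#").split("\t"))
        for key in ("chrom", "bin_size", "start", "n_bins"):
            if key not in meta:
                raise FormatError(f"contact matrix header missing {key!r}")
        n = int(meta["n_bins"])
        counts = np.zeros((n, n))
        colnames = fh.readline()  # column header line
        if not colnames.startswith("bin_i"):
            raise FormatError("expected 'bin_i\\tbin_j\\tcount' column header")
        for line in fh:
            if not line.strip():
                continue
            i_s, j_s, v_s = line.split("\t")
            i, j, v = int(i_s), int(j_s), float(v_s)
            counts[i, j] = v
            counts[j, i] = v
    return ContactMatrix(
        chrom=meta["chrom"],
        bin_size=int(meta["bin_size"]),
        start_bin_pos=int(meta["start"]),
        counts=counts,
        tissue=meta.get("tissue", ""),
    )
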