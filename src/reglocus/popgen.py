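"""Hardy-Weinberg testing and pairwise LD from unphased genotypes.

HWE is the 1-df goodness-of-fit chi-square comparing observed genotype
counts with the p^2 : 2pq : q^2 expectation at the observed allele
frequency (no continuity correction).

Pairwise LD is estimated from unphased diploid genotypes by the classic
two-locus EM: the only phase-ambiguous class is the double heterozygote,
whose haplotype composition (AB/ab vs Ab/aB) is resolved iteratively from
the current haplotype-frequency estimates.  From the fitted haplotype
frequencies, D = p_AB - p_A p_B, r^2 = D^2 / (p_A p_a p_B p_b) and
D' = D / D_max.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError

__all__ = ["GenotypeCounts", "LdResult", "hwe_test", "ld_em"]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one biallelic SNP; A is the major/reference allele."""

    n_AA: int
    n_Aa: int
    n_aa: int

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_Aa, self.n_aa) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.total < 1:
            raise ValueError("at least one individual required")

    @property
    def total(self) -> int:
        return self.n_AA + self.n_Aa + self.n_aa

    @property
    def freq_A(self) -> float:
        return (2 * self.n_AA + self.n_Aa) / (2 * self.total)

    @classmethod
    def from_dosages(cls, dosages: Sequence[int]) -> "GenotypeCounts":
        """Counts from alt-allele dosages in {0, 1, 2} (0 = AA)."""
        d = np.asarray(dosages)
        return cls(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))


@dataclass(frozen=True)
class LdResult:
    """Two-locus LD summary from EM haplotype-frequency estimation."""

    D: float
    D_prime: float
    r2: float
    converged: bool
    iterations: int
    #: fitted haplotype frequencies keyed '00','01','10','11'
    #: (first digit = alt allele at SNP A, second at SNP B)
    hap_freqs: dict = field(default_factory=dict, compare=False)


def hwe_test(counts: GenotypeCounts) -> tuple[float, float]:
    """Goodness-of-fit chi-square test for Hardy-Weinberg equilibrium.

    Returns ``(chi2, p)`` with 1 degree of freedom; no continuity
    correction.  Monomorphic input (allele frequency 0 or 1) raises
    :class:`DegenerateInputError` since the test is undefined.
    """
    n = counts.total
    p = counts.freq_A
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        raise DegenerateInputError("monomorphic SNP: HWE test undefined")
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([counts.n_AA, counts.n_Aa, counts.n_aa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


# Per-genotype-pair haplotype composition. Key (g1, g2) = alt dosages at the
# two SNPs; value = fixed haplotype contribution counts for '00','01','10','11'.
# The (1,1) double heterozygote is the only ambiguous class and is handled in
# the E-step.
_UNAMBIGUOUS = {
    (0, 0): (2, 0, 0, 0),
    (0, 1): (1, 1, 0, 0),
    (0, 2): (0, 2, 0, 0),
    (1, 0): (1, 0, 1, 0),
    (2, 0): (0, 0, 2, 0),
    (2, 1): (0, 0, 1, 1),
    (1, 2): (0, 1, 0, 1),
    (2, 2): (0, 0, 0, 2),
}


def _genotype_pair_counts(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    tab = np.zeros((3, 3), dtype=float)
    for a in range(3):
        for b in range(3):
            tab[a, b] = np.sum((g1 == a) & (g2 == b))
    return tab


def _loglik(tab: np.ndarray, f: np.ndarray) -> float:
    f00, f01, f10, f11 = f
    probs = np.array(
        [
            [f00**2, 2 * f00 * f01, f01**2],
            [2 * f00 * f10, 2 * f00 * f11 + 2 * f01 * f10, 2 * f01 * f11],
            [f10**2, 2 * f10 * f11, f11**2],
        ]
    )
    with np.errstate(divide="ignore"):
        lp = np.where(tab > 0, np.log(np.maximum(probs, 1e-300)), 0.0)
    return float((tab * lp).sum())


def ld_em(
    geno_a: Sequence[int],
    geno_b: Sequence[int],
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LdResult:
    """Estimate two-locus LD by EM over unphased genotype pairs.

    Parameters
    ----------
    geno_a, geno_b
        Alt-allele dosages ({0,1,2}) at the two SNPs for the same samples.
    tol
        Convergence tolerance on the max absolute change in haplotype
        frequency per iteration.
    max_iter
        Iteration cap; if reached, the last estimate is returned with
        ``converged=False``.

    Initialization is at linkage equilibrium (products of allele
    frequencies), which is deterministic and cannot start on the boundary.
    The EM log-likelihood is non-decreasing; this is asserted each step.
    """
    g1 = np.asarray(geno_a, dtype=int)
    g2 = np.asarray(geno_b, dtype=int)
    if g1.shape != g2.shape or g1.ndim != 1:
        raise ValueError("genotype vectors must be 1-D and of equal length")
    n = g1.size
    if n < 2:
        raise InsufficientDataError(f"need at least 2 samples, got {n}")
    for name, g in (("A", g1), ("B", g2)):
        if np.ptp(g) == 0:
            raise DegenerateInputError(f"SNP {name} is monomorphic; LD undefined")

    tab = _genotype_pair_counts(g1, g2)
    two_n = 2.0 * n

    pa = g1.sum() / two_n  # alt-allele freq at A
    pb = g2.sum() / two_n
    # haplotype order: 00, 01, 10, 11 (alt indicators at A then B)
    f = np.array([(1 - pa) * (1 - pb), (1 - pa) * pb, pa * (1 - pb), pa * pb])

    base = np.zeros(4)
    for (a, b), contrib in _UNAMBIGUOUS.items():
        base += tab[a, b] * np.asarray(contrib, dtype=float)
    n_dh = tab[1, 1]  # double heterozygotes

    converged = False
    iterations = 0
    ll_prev = _loglik(tab, f)
    for iterations in range(1, max_iter + 1):
        # E-step: split double hets between cis (00/11) and trans (01/10)
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = 0.5 if (cis + trans) == 0 else cis / (cis + trans)
        counts = base.copy()
        counts += n_dh * np.array([w, 1 - w, 1 - w, w])
        f_new = counts / two_n
        ll_new = _loglik(tab, f_new)
        assert ll_new >= ll_prev - 1e-9, "EM log-likelihood decreased"
        delta = float(np.abs(f_new - f).max())
        f = f_new
        ll_prev = ll_new
        if delta < tol:
            converged = True
            break

    p_a = f[2] + f[3]
    p_b = f[1] + f[3]
    D = float(f[3] - p_a * p_b)
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = float(D * D / denom) if denom > 0 else float("nan")
    if D >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = float(D / d_max) if d_max > 0 else float("nan")
    return LdResult(
        D=D,
        D_prime=d_prime,
        r2=min(r2, 1.0) if np.isfinite(r2) else r2,
        converged=converged,
        iterations=iterations,
        hap_freqs={"00": f[0], "01": f[1], "10": f[2], "11": f[3]},
    )
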