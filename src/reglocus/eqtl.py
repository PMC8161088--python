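"""eQTL testing for a target gene and risk-allele expression-direction calls.

The eQTL model is a per-SNP linear regression of (pre-normalized) expression
on alternative-allele dosage; the slope is reported as the normalized effect
size (NES) and the two-sided p-value comes from the t-test on the slope.
Candidates are ranked by eQTL significance, and each significant eQTL is
classified by whether its GWAS risk allele is associated with lower or
higher expression of the target gene.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import AlignmentError, DegenerateInputError, InsufficientDataError
from .sumstats import SummaryStatRecord

__all__ = [
    "EqtlResult",
    "Direction",
    "DirectionCall",
    "test_eqtl",
    "rank_by_eqtl",
    "call_direction",
    "inverse_normal_transform",
]


@dataclass(frozen=True)
class EqtlResult:
    """Per-SNP/gene regression result.

    ``nes`` is the slope of normalized expression per alt-allele dosage;
    ``p`` the two-sided p-value on the slope with n - k degrees of freedom
    (k = number of fitted coefficients, 2 without covariates).
    """

    snp_id: str
    gene: str
    nes: float
    se_nes: float
    p: float
    n: int
    ref: str | None = None
    alt: str | None = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise InsufficientDataError(f"{self.snp_id}: n must be >= 3, got {self.n}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.snp_id}: p outside (0, 1]: {self.p}")
        if self.se_nes <= 0:
            raise ValueError(f"{self.snp_id}: se_nes must be > 0, got {self.se_nes}")


class Direction(enum.Enum):
    RISK_LOWERS_EXPRESSION = "risk_lowers_expression"
    RISK_RAISES_EXPRESSION = "risk_raises_expression"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class DirectionCall:
    snp_id: str
    direction: Direction


def test_eqtl(
    dosage: Sequence[float],
    expression: Sequence[float],
    gene: str,
    snp_id: str,
    covariates: np.ndarray | None = None,
    ref: str | None = None,
    alt: str | None = None,
) -> EqtlResult:
    """OLS of expression on alt-allele dosage; slope = NES.

    Parameters
    ----------
    dosage
        Alt-allele dosages in {0, 1, 2}, length n.
    expression
        Expression values, length n; assumed pre-normalized.
    covariates
        Optional (n, k) matrix of additive covariates included in the fit.

    The p-value is two-sided from the t distribution with n - k degrees of
    freedom.  A p of exactly 0 (below float resolution) is reported as the
    smallest positive double so the (0, 1] invariant holds.
    """
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(expression, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("dosage and expression must be 1-D vectors of equal length")
    n = d.size
    if n < 3:
        raise InsufficientDataError(f"{snp_id}: need at least 3 samples, got {n}")
    if np.ptp(d) == 0:
        raise DegenerateInputError(f"{snp_id}: dosage is constant; slope undefined")

    X = d[:, None]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariate rows must match sample count")
        X = np.hstack([X, C])
    X = sm.add_constant(X, has_constant="add")

    fit = sm.OLS(y, X).fit()
    nes = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(fit.pvalues[1])
    if p <= 0.0:
        p = float(np.nextafter(0.0, 1.0))
    if se <= 0.0 or not np.isfinite(se):
        # perfect fit: slope exact, se numerically zero
        se = float(np.finfo(float).tiny)
        p = float(np.nextafter(0.0, 1.0))
    return EqtlResult(snp_id=snp_id, gene=gene, nes=nes, se_nes=se, p=min(p, 1.0), n=n,
                      ref=ref, alt=alt)


def rank_by_eqtl(
    candidates: Sequence[SummaryStatRecord],
    eqtls: Sequence[EqtlResult],
    top_k: int,
) -> list[tuple[str, float]]:
    """Rank candidate SNPs by eQTL significance (smallest p first).

    Only candidates that possess an eQTL result are ranked; returns up to
    ``top_k`` ``(snp_id, eqtl_p)`` pairs.  Ties are broken by snp_id so the
    order is deterministic.
    """
    by_id = {e.snp_id: e for e in eqtls}
    ranked = sorted(
        ((c.snp_id, by_id[c.snp_id].p) for c in candidates if c.snp_id in by_id),
        key=lambda t: (t[1], t[0]),
    )
    return ranked[: max(top_k, 0)]


def call_direction(
    gwas: SummaryStatRecord,
    eqtl: EqtlResult,
    alpha: float = 0.05,
) -> DirectionCall:
    """Classify the expression direction of the GWAS risk allele.

    The risk allele is the alt allele when ``beta > 0``, else the ref allele.
    The NES is expressed per alt allele; aligned to the risk allele its sign
    flips when the risk allele is ref.  A non-significant eQTL
    (``p > alpha``) or an undefined risk allele (beta missing or 0) yields
    ``INDETERMINATE``.
    """
    if gwas.snp_id != eqtl.snp_id:
        raise AlignmentError(f"records disagree on SNP: {gwas.snp_id} vs {eqtl.snp_id}")
    if eqtl.ref is not None and eqtl.alt is not None:
        if (eqtl.ref, eqtl.alt) != (gwas.ref, gwas.alt):
            raise AlignmentError(
                f"{gwas.snp_id}: allele mismatch between GWAS ({gwas.ref}/{gwas.alt}) "
                f"and eQTL ({eqtl.ref}/{eqtl.alt}) records"
            )
    if eqtl.p > alpha or gwas.beta is None or gwas.beta == 0:
        return DirectionCall(gwas.snp_id, Direction.INDETERMINATE)
    nes_risk = eqtl.nes if gwas.beta > 0 else -eqtl.nes
    if nes_risk < 0:
        return DirectionCall(gwas.snp_id, Direction.RISK_LOWERS_EXPRESSION)
    return DirectionCall(gwas.snp_id, Direction.RISK_RAISES_EXPRESSION)


def inverse_normal_transform(values: Sequence[float]) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom offset 0.5, ties averaged).

    Provided for synthetic expression vectors; real pipelines typically apply
    their own normalization upstream.
    """
    x = np.asarray(values, dtype=float)
    ranks = stats.rankdata(x)
    return stats.norm.ppf((ranks - 0.5) / x.size)
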