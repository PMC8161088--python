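"""Case-control association from genotype counts under standard genetic models.

Given genotype counts in cases and controls, 2x2 tables are built for five
codings: the two codominant contrasts (het vs major-hom, minor-hom vs
major-hom), the allelic contrast on 2N chromosomes, the dominant
(minor-allele carriers vs major homozygotes) and recessive (minor
homozygotes vs all others) models.  Each table yields the odds ratio with a
Woolf (log-normal) 95% confidence interval and a significance test —
Pearson's chi-square without continuity correction by default, Fisher's
exact test as a sparse-cell alternative.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InputError
from .popgen import GenotypeCounts

__all__ = [
    "Model",
    "ContingencyTable",
    "CohortGenotypes",
    "AssocResult",
    "build_tables",
    "odds_ratio_woolf",
    "pearson_chi2",
    "fisher_exact",
    "association_test",
    "cohort_association",
    "assoc_from_frequencies",
]

Z95 = 1.96  # 95% normal quantile; difference from 1.959964 is below display precision


class Model(enum.Enum):
    CODOMINANT_HET = "codominant_het"
    CODOMINANT_HOM = "codominant_hom"
    ALLELIC = "allelic"
    DOMINANT_CARRIER = "dominant_carrier"
    RECESSIVE_HOM = "recessive_hom"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a = exposed cases, b = unexposed cases, c = exposed
    controls, d = unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be non-negative")
        if self.a + self.b < 1 or self.c + self.d < 1:
            raise ValueError("each arm needs at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class CohortGenotypes:
    """Genotype counts for cases and controls at one SNP.

    ``A`` in :class:`~reglocus.popgen.GenotypeCounts` is the major allele; if
    the labelled minor allele exceeds frequency 0.5 in controls, the counts
    are auto-swapped with a warning so "minor" stays the rarer allele.
    """

    case_counts: GenotypeCounts
    control_counts: GenotypeCounts
    minor_allele: str = "a"

    def __post_init__(self) -> None:
        if 1.0 - self.control_counts.freq_A > 0.5:
            warnings.warn(
                "labelled minor allele has control frequency > 0.5; swapping alleles",
                stacklevel=2,
            )
            sw = lambda g: GenotypeCounts(g.n_aa, g.n_Aa, g.n_AA)
            object.__setattr__(self, "case_counts", sw(self.case_counts))
            object.__setattr__(self, "control_counts", sw(self.control_counts))


@dataclass(frozen=True)
class AssocResult:
    model: Model
    table: ContingencyTable
    or_: float
    ci_low: float
    ci_high: float
    p: float
    test: str  # 'pearson_chi2' or 'fisher_exact'
    corrected: bool = False  # Haldane-Anscombe +0.5 applied to the OR/CI


def build_tables(cohort: CohortGenotypes) -> dict[Model, ContingencyTable]:
    """Build the five model-specific 2x2 tables from genotype counts."""
    ca, co = cohort.case_counts, cohort.control_counts
    return {
        Model.CODOMINANT_HET: ContingencyTable(ca.n_Aa, ca.n_AA, co.n_Aa, co.n_AA),
        Model.CODOMINANT_HOM: ContingencyTable(ca.n_aa, ca.n_AA, co.n_aa, co.n_AA),
        Model.ALLELIC: ContingencyTable(
            2 * ca.n_aa + ca.n_Aa,
            2 * ca.n_AA + ca.n_Aa,
            2 * co.n_aa + co.n_Aa,
            2 * co.n_AA + co.n_Aa,
        ),
        Model.DOMINANT_CARRIER: ContingencyTable(
            ca.n_Aa + ca.n_aa, ca.n_AA, co.n_Aa + co.n_aa, co.n_AA
        ),
        Model.RECESSIVE_HOM: ContingencyTable(
            ca.n_aa, ca.n_AA + ca.n_Aa, co.n_aa, co.n_AA + co.n_Aa
        ),
    }


def odds_ratio_woolf(table: ContingencyTable) -> tuple[float, float, float, bool]:
    """Odds ratio with Woolf 95% CI.

    OR = ad/bc; CI = exp(ln OR +- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)).
    Any zero cell triggers the Haldane-Anscombe +0.5 correction on all four
    cells; the returned flag is True when the correction was applied.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    half = Z95 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return orr, orr * math.exp(-half), orr * math.exp(half), corrected


def pearson_chi2(table: ContingencyTable) -> tuple[float, float]:
    """1-df Pearson chi-square without continuity correction."""
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise DegenerateInputError("zero margin: chi-square test undefined")
    chi2 = n * (a * d - b * c) ** 2 / margins
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities <= observed)."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def association_test(
    table: ContingencyTable,
    model: Model = Model.ALLELIC,
    test: str = "pearson_chi2",
) -> AssocResult:
    """Combine OR/Woolf CI with the requested significance test."""
    orr, lo, hi, corrected = odds_ratio_woolf(table)
    if test == "pearson_chi2":
        _, p = pearson_chi2(table)
    elif test == "fisher_exact":
        p = fisher_exact(table)
    else:
        raise ValueError(f"unknown test {test!r}")
    return AssocResult(model, table, orr, lo, hi, max(p, np.nextafter(0.0, 1.0)),
                       test, corrected)


def cohort_association(
    cohort: CohortGenotypes,
    test: str = "pearson_chi2",
) -> dict[Model, AssocResult]:
    """Run all five genetic-model comparisons on one cohort."""
    results = {}
    for model, table in build_tables(cohort).items():
        try:
            results[model] = association_test(table, model=model, test=test)
        except DegenerateInputError:
            # e.g. no minor homozygotes in either arm: fall back to Fisher
            results[model] = association_test(table, model=model, test="fisher_exact")
    return results


def assoc_from_frequencies(
    freq_cases: float,
    n_cases: int,
    freq_controls: float,
    n_controls: int,
    test: str = "pearson_chi2",
) -> AssocResult:
    """Allelic association from printed allele frequencies and sample sizes.

    Counts of the exposed allele are reconstructed as ``round(freq * 2n)``
    (n are individuals, so each arm contributes 2n chromosomes); the allelic
    2x2 table is then analysed as usual.
    """
    for f in (freq_cases, freq_controls):
        if not (0.0 <= f <= 1.0):
            raise InputError(f"frequency outside [0, 1]: {f}")
    alleles_cases, alleles_controls = 2 * n_cases, 2 * n_controls
    a = round(freq_cases * alleles_cases)
    c = round(freq_controls * alleles_controls)
    if a > alleles_cases or c > alleles_controls:
        raise InputError("reconstructed count exceeds allele total")
    table = ContingencyTable(a, alleles_cases - a, c, alleles_controls - c)
    return association_test(table, model=Model.ALLELIC, test=test)


def invert_result(res: AssocResult) -> AssocResult:
    """Swap case/control rows: OR inverts exactly, CI bounds swap and invert."""
    t = res.table
    swapped = ContingencyTable(t.c, t.d, t.a, t.b)
    return replace(
        res,
        table=swapped,
        or_=1.0 / res.or_,
        ci_low=1.0 / res.ci_high,
        ci_high=1.0 / res.ci_low,
    )
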