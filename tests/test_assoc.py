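import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from reglocus.assoc import (
    CohortGenotypes,
    ContingencyTable,
    Model,
    assoc_from_frequencies,
    association_test,
    build_tables,
    fisher_exact,
    invert_result,
    odds_ratio_woolf,
    pearson_chi2,
)
from reglocus.errors import DegenerateInputError, InputError
from reglocus.popgen import GenotypeCounts


def cohort(cases, controls):
    return CohortGenotypes(GenotypeCounts(*cases), GenotypeCounts(*controls))


class TestBuildTables:
    def test_replication_cohort_allelic_cells(self):
        # 202 cases TT/TC/CC=120/72/10, 929 controls 625/266/38:
        # minor-allele counts 92 vs 342 on 404 and 1858 chromosomes
        tables = build_tables(cohort((120, 72, 10), (625, 266, 38)))
        assert tables[Model.ALLELIC] == ContingencyTable(92, 312, 342, 1516)
        assert tables[Model.CODOMINANT_HET] == ContingencyTable(72, 120, 266, 625)
        assert tables[Model.CODOMINANT_HOM] == ContingencyTable(10, 120, 38, 625)
        assert tables[Model.DOMINANT_CARRIER] == ContingencyTable(82, 120, 304, 625)
        assert tables[Model.RECESSIVE_HOM] == ContingencyTable(10, 192, 38, 891)

    def test_all_major_homozygote_cohort_zero_exposed(self):
        tables = build_tables(cohort((50, 0, 0), (60, 0, 0)))
        for t in tables.values():
            assert t.a == 0 and t.c == 0

    def test_margins_match_bruteforce_tallies(self, rng):
        for _ in range(20):
            # keep the labelled minor allele genuinely minor so no auto-swap
            ca = np.array([rng.integers(100, 200), rng.integers(1, 60), rng.integers(1, 30)])
            co = np.array([rng.integers(100, 200), rng.integers(1, 60), rng.integers(1, 30)])
            tables = build_tables(cohort(tuple(ca), tuple(co)))
            n_ca, n_co = ca.sum(), co.sum()
            for model, t in tables.items():
                expected_rows = (2 * n_ca, 2 * n_co) if model is Model.ALLELIC else (n_ca, n_co)
                if model is Model.CODOMINANT_HET:
                    expected_rows = (ca[0] + ca[1], co[0] + co[1])
                if model is Model.CODOMINANT_HOM:
                    expected_rows = (ca[0] + ca[2], co[0] + co[2])
                assert (t.a + t.b, t.c + t.d) == tuple(int(x) for x in expected_rows)

    def test_minor_allele_autoswap_warns(self):
        with pytest.warns(UserWarning, match="swapping"):
            c = cohort((10, 20, 70), (5, 25, 80))
        assert c.control_counts.freq_A >= 0.5


class TestWoolf:
    @pytest.mark.parametrize(
        "table, orr, lo, hi",
        [
            ((92, 312, 342, 1516), 1.307, 1.007, 1.696),  # replication allele contrast
            ((72, 120, 266, 625), 1.410, 1.018, 1.952),
            ((82, 120, 304, 625), 1.405, 1.028, 1.920),
            ((10, 120, 38, 625), 1.371, 0.665, 2.826),
            ((4, 217, 5, 1079), 3.978, 1.060, 14.934),  # rare-variant het contrast
            ((4, 438, 5, 2163), 3.951, 1.057, 14.772),
            ((10, 10, 10, 10), 1.0, None, None),
        ],
    )
    def test_printed_odds_ratios(self, table, orr, lo, hi):
        got_or, got_lo, got_hi, corrected = odds_ratio_woolf(ContingencyTable(*table))
        assert not corrected
        assert round(got_or, 3) == pytest.approx(orr, abs=5e-4)
        if lo is not None:
            assert round(got_lo, 3) == pytest.approx(lo, abs=5e-4)
            assert round(got_hi, 3) == pytest.approx(hi, abs=5e-4)

    def test_zero_cell_haldane_correction(self):
        orr, lo, hi, corrected = odds_ratio_woolf(ContingencyTable(0, 10, 10, 10))
        assert corrected
        assert 0 < lo < orr < hi < math.inf
        # matches the +0.5-on-all-cells formula
        assert orr == pytest.approx((0.5 * 10.5) / (10.5 * 10.5))

    def test_ci_contains_or(self, rng):
        for _ in range(50):
            t = ContingencyTable(*(int(x) for x in rng.integers(1, 500, 4)))
            orr, lo, hi, _ = odds_ratio_woolf(t)
            assert lo <= orr <= hi


class TestPearson:
    @pytest.mark.parametrize(
        "table, p",
        [
            ((92, 312, 342, 1516), 0.0434),
            ((72, 120, 266, 625), 0.0381),
            ((82, 120, 304, 625), 0.0325),
            ((4, 217, 5, 1079), 0.0272),
        ],
    )
    def test_printed_p_values(self, table, p):
        _, got = pearson_chi2(ContingencyTable(*table))
        assert got == pytest.approx(p, abs=5e-4)

    def test_symmetric_table_null(self):
        chi2, p = pearson_chi2(ContingencyTable(10, 10, 10, 10))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_margin_undefined(self):
        with pytest.raises(DegenerateInputError):
            pearson_chi2(ContingencyTable(0, 10, 0, 10))


def fisher_enumeration(a, b, c, d):
    """Oracle: sum hypergeometric probabilities <= P(observed) over all
    tables with the observed margins."""
    r1, n, K = a + b, a + b + c + d, a + c
    dist = hypergeom(n, K, r1)
    p_obs = dist.pmf(a)
    total = 0.0
    for x in range(max(0, r1 + K - n), min(r1, K) + 1):
        px = dist.pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestFisher:
    def test_symmetric_table(self):
        assert fisher_exact(ContingencyTable(10, 10, 10, 10)) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [(0, 10, 10, 0), (3, 7, 9, 2), (1, 15, 4, 2), (5, 0, 1, 9)])
    def test_matches_enumeration_oracle(self, table):
        assert fisher_exact(ContingencyTable(*table)) == pytest.approx(
            fisher_enumeration(*table), rel=1e-9
        )

    def test_extreme_table_smallest_attainable(self):
        # (0,10,10,0) is the most extreme table under its margins
        a, b, c, d = 0, 10, 10, 0
        dist = hypergeom(20, 10, 10)
        assert fisher_exact(ContingencyTable(a, b, c, d)) == pytest.approx(
            2 * dist.pmf(0), rel=1e-9
        )


class TestFromFrequencies:
    def test_delta32_reconstruction(self):
        """10.20% of 294 case chromosomes vs 10.22% of 2190 control
        chromosomes: the null result reproduces (OR ~ 1, p > 0.9)."""
        res = assoc_from_frequencies(0.1020, 147, 0.1022, 1095)
        assert res.table == ContingencyTable(30, 264, 224, 1966)
        assert 0.99 <= res.or_ <= 1.00
        assert res.p > 0.9

    def test_equal_frequencies_unit_or(self):
        res = assoc_from_frequencies(0.25, 100, 0.25, 100)
        assert res.or_ == pytest.approx(1.0)

    def test_round_trip_from_integer_counts(self):
        a, n2 = 37, 400
        res = assoc_from_frequencies(a / n2, n2 // 2, 50 / 600, 300)
        assert (res.table.a, res.table.c) == (37, 50)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(InputError):
            assoc_from_frequencies(1.2, 100, 0.1, 100)


class TestInvariance:
    @given(cells=st.tuples(*[st.integers(1, 300)] * 4))
    @settings(deadline=None, derandomize=True)
    def test_swapping_arms_inverts_or_and_ci(self, cells):
        res = association_test(ContingencyTable(*cells))
        inv = invert_result(res)
        swapped = association_test(inv.table)
        assert swapped.or_ == pytest.approx(1.0 / res.or_, rel=1e-9)
        assert swapped.ci_low == pytest.approx(1.0 / res.ci_high, rel=1e-9)
        assert swapped.ci_high == pytest.approx(1.0 / res.ci_low, rel=1e-9)
        assert swapped.p == pytest.approx(res.p, rel=1e-9)
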