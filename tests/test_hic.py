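import numpy as np
import pytest

from reglocus.errors import FormatError
from reglocus.hic import (
    ContactMatrix,
    cross_tissue_rank,
    dnif,
    expected_by_distance,
    read_contact_matrix,
    snp_gene_dnif,
    write_contact_matrix,
)


def matrix_from_diagonals(values, **kw):
    """Square matrix whose d-th diagonal is constant at values[d]."""
    n = len(values)
    idx = np.arange(n)
    counts = np.asarray(values, dtype=float)[np.abs(idx[:, None] - idx[None, :])]
    defaults = dict(chrom="chr3", bin_size=40_000, start_bin_pos=46_000_000, tissue="lung")
    defaults.update(kw)
    return ContactMatrix(counts=counts, **defaults)


def random_matrix(rng, n=30, **kw):
    upper = np.triu(rng.poisson(20.0, (n, n)).astype(float))
    counts = upper + np.triu(upper, 1).T
    defaults = dict(chrom="chr3", bin_size=40_000, start_bin_pos=46_000_000, tissue="t")
    defaults.update(kw)
    return ContactMatrix(counts=counts, **defaults)


class TestContactMatrix:
    def test_asymmetric_rejected(self):
        with pytest.raises(FormatError):
            ContactMatrix("chr3", 10, 1, np.array([[1.0, 2.0], [3.0, 1.0]]))

    def test_negative_rejected(self):
        with pytest.raises(FormatError):
            ContactMatrix("chr3", 10, 1, np.array([[1.0, -2.0], [-2.0, 1.0]]))

    def test_bin_lookup_and_range(self):
        m = matrix_from_diagonals([5, 3, 2, 1])
        assert m.bin_of(46_000_000) == 0
        assert m.bin_of(46_039_999) == 0
        assert m.bin_of(46_040_000) == 1
        with pytest.raises(IndexError):
            m.bin_of(45_999_999)
        with pytest.raises(IndexError):
            m.bin_of(46_160_000)


class TestExpected:
    def test_constant_diagonals_recovered_exactly(self):
        values = [9.0, 6.0, 4.0, 2.5, 1.0]
        assert expected_by_distance(matrix_from_diagonals(values)) == pytest.approx(values)

    def test_all_zero_matrix(self):
        m = matrix_from_diagonals([0.0, 0.0, 0.0])
        assert expected_by_distance(m) == pytest.approx([0.0, 0.0, 0.0])

    def test_matches_bruteforce_diagonal_means(self, rng):
        m = random_matrix(rng)
        expected = expected_by_distance(m)
        for d in range(m.n_bins):
            vals = [m.counts[i, i + d] for i in range(m.n_bins - d)]
            assert expected[d] == pytest.approx(np.mean(vals))


class TestDnif:
    def test_constant_diagonal_matrix_unity_everywhere(self):
        m = matrix_from_diagonals([7.0, 5.0, 3.0, 2.0])
        for i in range(4):
            for j in range(4):
                assert dnif(m, i, j).dnif == pytest.approx(1.0)

    def test_single_enriched_pixel_matches_direct_ratio(self, rng):
        m = random_matrix(rng, n=50)
        r = dnif(m, 3, 13)
        diag = [m.counts[i, i + 10] for i in range(40)]
        assert r.dnif == pytest.approx(m.counts[3, 13] / np.mean(diag))

    def test_scale_invariance(self, rng):
        m = random_matrix(rng)
        scaled = ContactMatrix(m.chrom, m.bin_size, m.start_bin_pos, 7.3 * m.counts, m.tissue)
        for i, j in [(0, 5), (2, 2), (10, 29)]:
            assert dnif(scaled, i, j).dnif == pytest.approx(dnif(m, i, j).dnif)

    def test_symmetry(self, rng):
        m = random_matrix(rng)
        assert dnif(m, 4, 17).dnif == pytest.approx(dnif(m, 17, 4).dnif)

    def test_zero_expected_flagged_not_raised(self):
        m = matrix_from_diagonals([1.0, 0.0, 2.0])
        r = dnif(m, 0, 1)
        assert r.degenerate and r.dnif == 0.0

    def test_out_of_range_raises(self, rng):
        with pytest.raises(IndexError):
            dnif(random_matrix(rng), 0, 99)

    def test_powerlaw_expected_tracks_decay(self, rng):
        """Poisson noise around C*(d+1)^-1 at 200 bins: the per-distance mean
        estimator recovers the decay curve within 5% over short distances."""
        n, C = 200, 2000.0
        idx = np.arange(n)
        lam = C * (np.abs(idx[:, None] - idx[None, :]) + 1.0) ** -1.0
        upper = np.triu(rng.poisson(lam).astype(float))
        m = ContactMatrix("chr3", 40_000, 1, upper + np.triu(upper, 1).T)
        expected = expected_by_distance(m)
        truth = C / (np.arange(n) + 1.0)
        assert expected[:40] == pytest.approx(truth[:40], rel=0.05)


class TestSnpGene:
    def test_same_bin_distance_zero(self):
        m = matrix_from_diagonals([8.0, 4.0, 2.0, 1.0])
        r = snp_gene_dnif(m, 46_005_000, 46_030_000, 46_030_000)
        assert (r.bin_i, r.bin_j) == (0, 0)
        assert r.dnif == pytest.approx(m.counts[0, 0] / 8.0)

    def test_planted_loop_beats_distance_matched_pairs(self, rng):
        n = 40
        idx = np.arange(n)
        lam = 100.0 * (np.abs(idx[:, None] - idx[None, :]) + 1.0) ** -1.0
        lam[5, 12] *= 5.0
        lam[12, 5] *= 5.0
        upper = np.triu(rng.poisson(lam).astype(float))
        m = ContactMatrix("chr3", 40_000, 46_000_000, upper + np.triu(upper, 1).T)
        d = 7
        loop = dnif(m, 5, 12).dnif
        others = [dnif(m, i, i + d).dnif for i in range(n - d) if i != 5]
        assert loop > max(others)

    def test_max_over_gene_dominates_tss(self, rng):
        m = random_matrix(rng)
        snp = 46_000_000 + 2 * 40_000 + 7
        gs, ge = 46_000_000 + 10 * 40_000, 46_000_000 + 14 * 40_000
        tss = snp_gene_dnif(m, snp, gs, ge, anchor="tss")
        mx = snp_gene_dnif(m, snp, gs, ge, anchor="max_over_gene")
        assert mx.dnif >= tss.dnif

    def test_unknown_anchor_rejected(self, rng):
        with pytest.raises(ValueError):
            snp_gene_dnif(random_matrix(rng), 46_000_001, 46_040_001, 46_080_001, anchor="mid")


class TestCrossTissue:
    def test_single_tissue_singleton(self, rng):
        m = random_matrix(rng, tissue="lung")
        out = cross_tissue_rank([m], 46_000_001, 46_200_001, 46_240_001)
        assert len(out) == 1 and out[0].tissue == "lung"

    def test_planted_loop_tissue_ranks_first_and_order_stable(self, rng):
        n = 30
        idx = np.arange(n)
        lam = 100.0 * (np.abs(idx[:, None] - idx[None, :]) + 1.0) ** -1.0
        mats = []
        for tissue in ("liver", "lung", "spleen"):
            l = lam.copy()
            if tissue == "lung":
                l[3, 10] *= 5.0
                l[10, 3] *= 5.0
            upper = np.triu(rng.poisson(l).astype(float))
            mats.append(
                ContactMatrix("chr3", 40_000, 46_000_000, upper + np.triu(upper, 1).T, tissue)
            )
        snp = 46_000_000 + 3 * 40_000 + 5
        gs = 46_000_000 + 10 * 40_000 + 5
        ranked = cross_tissue_rank(mats, snp, gs, gs)
        assert ranked[0].tissue == "lung"
        permuted = cross_tissue_rank(mats[::-1], snp, gs, gs)
        assert [r.tissue for r in permuted] == [r.tissue for r in ranked]


def test_triple_file_round_trip(tmp_path, rng):
    m = random_matrix(rng, n=12, tissue="lung")
    path = tmp_path / "m.tsv"
    write_contact_matrix(m, path)
    back = read_contact_matrix(path)
    assert back.chrom == m.chrom and back.bin_size == m.bin_size
    assert back.tissue == "lung"
    np.testing.assert_allclose(back.counts, m.counts)
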