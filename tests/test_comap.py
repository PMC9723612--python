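"""Crossover filtering, interval counting, map functions, resampling, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from xocall.core import ALT, MISSING, REF, AlleleCountMatrix, BarcodeList, Haplotype
from xocall.comap import (
    CrossoverMatrix,
    FilterParams,
    bootstrap_dist,
    caf_bins,
    cal_genetic_dist,
    count_cos,
    crossovers_from_segments,
    make_bins,
    map_distance,
    permute_dist,
    phasing_accuracy,
    read_crossover_matrix,
    write_crossover_matrix,
)

from conftest import make_snptable


def _segments(rows, barcode="B0"):
    return pd.DataFrame(
        [
            {
                "barcode": barcode,
                "chrom": "chr1",
                "first_snp_pos": r[0],
                "last_snp_pos": r[1],
                "state": r[2],
                "n_snps": r[3],
                "n_reads": r[3],
                "log_lik_ratio": r[4],
            }
            for r in rows
        ]
    )


LOOSE = FilterParams(min_cell_snps=0, max_raw_co=100, min_seg_snps=0, min_seg_llr=0, min_seg_bp=0)


class TestCrossoversFromSegments:
    def test_weak_middle_segment_absorbed(self):
        seg = _segments(
            [
                (100, 50_000, "H1", 50, 200.0),
                (50_500, 50_600, "H2", 1, 3.0),
                (51_000, 120_000, "H1", 60, 250.0),
            ]
        )
        filters = FilterParams(min_cell_snps=0, max_raw_co=100, min_seg_snps=3, min_seg_llr=0, min_seg_bp=0)
        xos, qc = crossovers_from_segments(seg, filters)
        assert len(xos) == 0
        assert qc.iloc[0].retained_co == 0 and qc.iloc[0].raw_co == 2

    def test_cell_with_excess_crossovers_dropped(self):
        rows = [
            (1000 * i, 1000 * i + 500, "H1" if i % 2 == 0 else "H2", 5, 50.0)
            for i in range(41)  # 40 raw crossovers
        ]
        xos, qc = crossovers_from_segments(
            _segments(rows), FilterParams(min_cell_snps=0, max_raw_co=10, min_seg_snps=0, min_seg_llr=0, min_seg_bp=0)
        )
        assert len(xos) == 0
        assert not qc.iloc[0].kept
        assert qc.iloc[0].reason == "excess_crossovers"

    def test_low_coverage_cell_dropped(self):
        seg = _segments([(100, 900, "H1", 30, 80.0)])
        xos, qc = crossovers_from_segments(seg, FilterParams(min_cell_snps=200))
        assert qc.iloc[0].reason == "low_snp_coverage"

    def test_clean_pair_yields_one_crossover_with_min_confidence(self):
        seg = _segments(
            [(100, 200_000, "H1", 40, 120.0), (205_000, 400_000, "H2", 35, 90.0)]
        )
        xos, qc = crossovers_from_segments(seg, LOOSE)
        assert len(xos) == 1
        row = xos.iloc[0]
        assert (row.left_pos, row.right_pos) == (200_000, 205_000)
        assert row.confidence == 90.0

    def test_unordered_segments_raise(self):
        seg = _segments([(5000, 9000, "H1", 5, 10.0), (100, 4000, "H2", 5, 10.0)])
        with pytest.raises(ValueError, match="ordered"):
            crossovers_from_segments(seg, LOOSE)

    @pytest.mark.parametrize(
        "field,value",
        [("min_seg_snps", 6), ("min_seg_llr", 60.0), ("min_seg_bp", 50_000), ("max_raw_co", 1)],
    )
    def test_tightening_any_filter_never_adds_crossovers(self, field, value):
        rng = np.random.default_rng(0)
        rows, start = [], 100
        for i in range(8):
            span = int(rng.integers(5_000, 120_000))
            rows.append((start, start + span, "H1" if i % 2 == 0 else "H2",
                         int(rng.integers(2, 12)), float(rng.uniform(5, 150))))
            start += span + int(rng.integers(500, 3_000))
        seg = _segments(rows)
        base = FilterParams(min_cell_snps=0, max_raw_co=100, min_seg_snps=3, min_seg_llr=10, min_seg_bp=10_000)
        n0 = len(crossovers_from_segments(seg, base)[0])
        tight = FilterParams(**{**base.__dict__, field: value})
        n1 = len(crossovers_from_segments(seg, tight)[0])
        assert n1 <= n0


class TestCountCos:
    def _xo(self, rows):
        return pd.DataFrame(
            [
                {"barcode": b, "chrom": "chr1", "left_pos": l, "right_pos": r, "confidence": 50.0}
                for b, l, r in rows
            ]
        )

    def test_interval_inside_single_bin(self):
        cells = BarcodeList(["B0"])
        bins = make_bins("chr1", 0, 1000, 500)
        m = count_cos(self._xo([("B0", 100, 200)]), bins, cells)
        assert m.counts[:, 0].tolist() == [1.0, 0.0]

    def test_proportional_split_between_bins(self):
        cells = BarcodeList(["B0"])
        bins = make_bins("chr1", 0, 1000, 500)
        m = count_cos(self._xo([("B0", 300, 800)]), bins, cells)
        assert m.counts[:, 0] == pytest.approx([0.4, 0.6])

    def test_midpoint_mode_assigns_whole_unit(self):
        cells = BarcodeList(["B0"])
        bins = make_bins("chr1", 0, 1000, 500)
        m = count_cos(self._xo([("B0", 300, 800)]), bins, cells, mode="midpoint")
        assert m.counts[:, 0].tolist() == [0.0, 1.0]

    def test_tiling_bins_conserve_total_mass(self):
        rng = np.random.default_rng(1)
        cells = BarcodeList([f"B{i}" for i in range(5)])
        rows = []
        for i in range(30):
            l = int(rng.integers(0, 90_000))
            rows.append((cells[int(rng.integers(0, 5))], l, l + int(rng.integers(1, 9_000))))
        bins = make_bins("chr1", 0, 100_000, 10_000)
        m = count_cos(self._xo(rows), bins, cells)
        assert m.counts.sum() == pytest.approx(30.0)
        assert m.counts.sum(axis=0) == pytest.approx(
            [sum(1 for b, _, _ in rows if b == c) for c in cells]
        )

    def test_mass_outside_bins_warns(self):
        cells = BarcodeList(["B0"])
        bins = make_bins("chr1", 0, 1000, 500)
        with pytest.warns(UserWarning, match="outside"):
            count_cos(self._xo([("B0", 900, 1300)]), bins, cells)

    def test_overlapping_bins_rejected(self):
        bins = pd.DataFrame({"chrom": "chr1", "start": [0, 400], "end": [500, 900]})
        with pytest.raises(ValueError, match="non-overlapping"):
            count_cos(self._xo([("B0", 100, 200)]), bins, BarcodeList(["B0"]))


class TestMapDistance:
    def test_closed_forms(self):
        assert map_distance(0.1, "kosambi") == pytest.approx(25 * math.log(1.5), abs=1e-12)
        assert map_distance(0.1, "haldane") == pytest.approx(-50 * math.log(0.8), abs=1e-12)
        assert map_distance(0.0, "kosambi") == 0.0

    @pytest.mark.parametrize("method", ["kosambi", "haldane"])
    def test_small_r_limit_is_morgan_linear(self, method):
        # Haldane's relative deviation is r + O(r^2): exactly 1.014% at r=0.01
        rel = 0.01 if method == "kosambi" else 0.0102
        for r in (0.001, 0.005, 0.01):
            assert map_distance(r, method) == pytest.approx(100 * r, rel=rel)

    def test_r_at_least_half_rejected_unless_clamped(self):
        with pytest.raises(ValueError):
            map_distance(0.5, "kosambi")
        assert np.isfinite(map_distance(0.6, "kosambi", clamp=True))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            map_distance(0.1, "morgan")


class TestGeneticDist:
    def _matrix(self, counts, labels=None):
        counts = np.asarray(counts, dtype=float)
        bins = make_bins("chr1", 0, counts.shape[0] * 1000, 1000)
        cells = BarcodeList([f"B{i}" for i in range(counts.shape[1])])
        return CrossoverMatrix(bins, cells, counts, labels)

    def test_rate_to_centimorgans(self):
        m = self._matrix(np.concatenate([np.full((1, 100), 0.1), np.zeros((1, 100))]).reshape(2, 100))
        out = cal_genetic_dist(m)
        assert out.cM.iloc[0] == pytest.approx(25 * math.log(1.5))
        assert out.cM.iloc[1] == 0.0
        assert out.cum_cM.iloc[1] == pytest.approx(out.cM.iloc[0])

    def test_identical_groups_give_identical_curves(self):
        col = np.zeros((3, 1))
        col[1] = 0.4
        counts = np.hstack([col] * 6)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        out = cal_genetic_dist(self._matrix(counts), group_by=labels)
        a = out[out.group == "a"].cM.to_numpy()
        b = out[out.group == "b"].cM.to_numpy()
        np.testing.assert_allclose(a, b)


class TestResampling:
    def _null(self, seed, n_cells=20):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(0.3, (15, n_cells)).astype(float)
        bins = make_bins("chr1", 0, 15_000, 1000)
        cells = BarcodeList([f"B{i}" for i in range(n_cells)])
        return CrossoverMatrix(bins, cells, counts)

    def test_identical_constant_groups_have_zero_ci(self):
        counts = np.tile(np.array([[1.0], [0.0], [2.0]]), (1, 6))
        m = CrossoverMatrix(
            make_bins("chr1", 0, 3000, 1000), BarcodeList([f"B{i}" for i in range(6)]), counts
        )
        labels = np.array(["a"] * 3 + ["b"] * 3)
        res = bootstrap_dist(m, labels, B=200, seed=1)
        assert res.observed_diff == 0.0
        assert (res.ci_low, res.ci_high) == (0.0, 0.0)

    def test_bootstrap_deterministic_under_seed(self):
        m = self._null(4)
        labels = np.array(["a"] * 10 + ["b"] * 10)
        r1 = bootstrap_dist(m, labels, B=150, seed=9)
        r2 = bootstrap_dist(m, labels, B=150, seed=9)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_single_cell_group_warns(self):
        m = self._null(5, n_cells=4)
        labels = np.array(["a", "b", "b", "b"])
        with pytest.warns(UserWarning, match="single cell"):
            bootstrap_dist(m, labels, B=100, seed=0)

    def test_zero_observed_diff_gives_p_one(self):
        counts = np.tile(np.array([[1.0], [0.0], [2.0]]), (1, 6))
        m = CrossoverMatrix(
            make_bins("chr1", 0, 3000, 1000), BarcodeList([f"B{i}" for i in range(6)]), counts
        )
        labels = np.array(["a"] * 3 + ["b"] * 3)
        res = permute_dist(m, labels, B=199, seed=2)
        assert res.observed_diff == 0.0
        assert res.p_value == 1.0

    def test_permutation_p_in_unit_interval_and_deterministic(self):
        m = self._null(6)
        labels = np.array(["a"] * 10 + ["b"] * 10)
        r1 = permute_dist(m, labels, B=199, seed=3)
        r2 = permute_dist(m, labels, B=199, seed=3)
        assert 0.0 < r1.p_value <= 1.0
        assert r1.p_value == r2.p_value

    def test_requires_two_groups(self):
        m = self._null(7)
        with pytest.raises(ValueError):
            permute_dist(m, np.repeat("a", 20), B=100, seed=0)

    def test_b_too_small_rejected(self):
        m = self._null(8)
        labels = np.array(["a"] * 10 + ["b"] * 10)
        with pytest.raises(ValueError):
            bootstrap_dist(m, labels, B=50, seed=0)


class TestPhasingAccuracy:
    def _haps(self, n=250, seed=0):
        rng = np.random.default_rng(seed)
        snps = make_snptable(n, seed=seed)
        truth = Haplotype(snps, rng.integers(1, 3, n).astype(np.int8))
        return snps, truth

    def test_identical_haplotypes_score_one(self):
        _, truth = self._haps()
        out = phasing_accuracy(truth, truth, bin_snps=100)
        assert out.accuracy == 1.0
        assert (out.bins.concordance == 1.0).all()

    def test_complement_reoriented_to_one(self):
        _, truth = self._haps(seed=1)
        out = phasing_accuracy(truth.complement(), truth, bin_snps=100)
        assert out.accuracy == 1.0
        assert out.flipped

    def test_single_discordant_snp_in_bin(self):
        snps, truth = self._haps(n=100, seed=2)
        inferred = truth.copy()
        inferred.hap1[7] = ALT if truth.hap1[7] == REF else REF
        out = phasing_accuracy(inferred, truth, bin_snps=100)
        assert out.bins.concordance.iloc[0] == pytest.approx(0.99)

    def test_disjoint_phasing_raises(self):
        snps, truth = self._haps(n=10, seed=3)
        h1 = truth.hap1.copy()
        h1[:5] = MISSING
        h2 = truth.hap1.copy()
        h2[5:] = MISSING
        with pytest.raises(ValueError):
            phasing_accuracy(Haplotype(snps, h1), Haplotype(snps, h2))


class TestCafBins:
    def _counts_and_hap(self, ref, alt, hap1):
        ref = np.atleast_2d(ref)
        snps = make_snptable(ref.shape[1], seed=4)
        bcs = BarcodeList([f"B{i}" for i in range(ref.shape[0])])
        counts = AlleleCountMatrix(snps, bcs, sparse.csr_matrix(ref), sparse.csr_matrix(np.atleast_2d(alt)))
        return counts, Haplotype(snps, np.asarray(hap1, dtype=np.int8))

    def test_unanimous_bin_has_zero_caf(self):
        counts, hap = self._counts_and_hap([[2, 3, 1]], [[0, 0, 0]], [REF] * 3)
        out = caf_bins(counts, hap, bin_snps=3)
        assert out.caf.tolist() == [0.0]

    def test_one_contradictory_read_in_ten(self):
        counts, hap = self._counts_and_hap([[3, 3, 3]], [[0, 0, 1]], [REF] * 3)
        out = caf_bins(counts, hap, bin_snps=3)
        assert out.caf.iloc[0] == pytest.approx(0.1)
        assert out.n_reads.iloc[0] == 10

    def test_caf_never_exceeds_half(self):
        rng = np.random.default_rng(5)
        ref = rng.integers(0, 4, (6, 40))
        alt = rng.integers(0, 4, (6, 40))
        hap1 = rng.integers(1, 3, 40)
        counts, hap = self._counts_and_hap(ref, alt, hap1)
        out = caf_bins(counts, hap, bin_snps=10)
        assert (out.caf <= 0.5).all()

    def test_empty_bins_omitted(self):
        counts, hap = self._counts_and_hap([[2, 0, 0, 0]], [[0, 0, 0, 0]], [REF] * 4)
        out = caf_bins(counts, hap, bin_snps=2)
        assert out.bin_index.tolist() == [0]


def test_crossover_matrix_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    bins = make_bins("chr1", 0, 5000, 1000)
    cells = BarcodeList(["B0", "B1"])
    m = CrossoverMatrix(bins, cells, rng.random((5, 2)))
    write_crossover_matrix(tmp_path / "m.tsv", m)
    back = read_crossover_matrix(tmp_path / "m.tsv")
    assert back.cells == cells
    np.testing.assert_allclose(back.counts, m.counts)
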