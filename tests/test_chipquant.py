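import numpy as np
import pytest

from oracles import consensus_oracle, outlier_filter_oracle, tmm_oracle
from xcikit.chipquant import (
    CountMatrix,
    SampleInfo,
    accumulation_signal,
    consensus_peaks,
    count_fragments_in_windows,
    filter_outlier_windows,
    reads_fraction_by_chrom,
    tmm_factors,
)
from xcikit.genome import GenomicInterval, RegionSet


def _regions(*triples):
    rs = RegionSet(region_class="fixed_window")
    for i, (chrom, s, e) in enumerate(triples):
        rs.add(f"r{i}", GenomicInterval(chrom, s, e))
    return rs


class TestMidpointCounting:
    def test_midpoint_assignment(self):
        regions = _regions(("chr1", 0, 1000))
        cm = count_fragments_in_windows(
            {"s1": [GenomicInterval("chr1", 100, 200)]}, regions
        )
        assert cm.counts[0, 0] == 1

    def test_boundary_spanning_fragment_counted_once(self):
        regions = _regions(("chr1", 0, 1000), ("chr1", 1000, 2000))
        # midpoint 950 lies in the first window
        cm = count_fragments_in_windows(
            {"s1": [GenomicInterval("chr1", 900, 1001)]}, regions
        )
        assert cm.counts[:, 0].tolist() == [1, 0]

    def test_counts_and_library_size(self):
        regions = _regions(("chr1", 0, 1000))
        frags = [GenomicInterval("chr1", i * 10, i * 10 + 100) for i in range(3)]
        cm = count_fragments_in_windows({"s1": frags}, regions)
        assert cm.counts[0, 0] == 3
        assert cm.library_sizes[0] == 3

    def test_uncounted_fragments_still_in_library(self):
        regions = _regions(("chr1", 0, 1000))
        frags = [
            GenomicInterval("chr1", 100, 200),
            GenomicInterval("chr1", 5000, 5100),  # midpoint outside all regions
        ]
        cm = count_fragments_in_windows({"s1": frags}, regions)
        assert cm.counts[0, 0] == 1
        assert cm.library_sizes[0] == 2


class TestConsensusPeaks:
    def test_worked_example(self):
        sets = [
            [GenomicInterval("chr1", 0, 100)],
            [GenomicInterval("chr1", 50, 150)],
            [GenomicInterval("chr1", 120, 200)],
            [GenomicInterval("chr1", 500, 600)],
        ]
        got = consensus_peaks(sets, min_support=2)
        assert [(p.start, p.end) for p in got] == [(50, 100), (120, 150)]

    def test_identical_sets_return_same_intervals(self):
        peaks = [GenomicInterval("chr1", 10, 50), GenomicInterval("chr1", 80, 90)]
        got = consensus_peaks([peaks] * 4, min_support=2)
        assert [(p.start, p.end) for p in got] == [(10, 50), (80, 90)]

    def test_disjoint_sets_empty(self):
        sets = [[GenomicInterval("chr1", i * 100, i * 100 + 50)] for i in range(4)]
        assert consensus_peaks(sets, min_support=2) == []

    def test_fold_change_prefilter(self):
        sets = [
            [GenomicInterval("chr1", 0, 100)],
            [GenomicInterval("chr1", 0, 100)],
        ]
        got = consensus_peaks(sets, min_support=2, fold_changes=[[5.0], [2.0]])
        assert got == []  # second set's peak removed, support drops below 2

    def test_min_support_validation(self):
        with pytest.raises(ValueError):
            consensus_peaks([[], []], min_support=0)

    def test_matches_per_base_oracle_on_random_instances(self, rng):
        for _ in range(30):
            n_sets = int(rng.integers(2, 5))
            sets, raw = [], []
            for _ in range(n_sets):
                peaks = []
                for _ in range(int(rng.integers(0, 6))):
                    s = int(rng.integers(0, 900))
                    e = s + int(rng.integers(1, 120))
                    peaks.append((s, min(e, 1000)))
                raw.append(peaks)
                sets.append([GenomicInterval("chr1", s, e) for s, e in peaks])
            support = int(rng.integers(1, n_sets + 1))
            got = [(p.start, p.end) for p in consensus_peaks(sets, min_support=support)]
            assert got == consensus_oracle(raw, support, 1000)


class TestTMM:
    def test_identical_columns_unit_factors(self):
        counts = np.tile(np.array([[10], [20], [30], [40]]), (1, 2))
        np.testing.assert_allclose(tmm_factors(counts), [1.0, 1.0], atol=1e-12)

    def test_global_column_scaling_absorbed(self):
        a = np.array([[100.0], [50.0], [30.0], [120.0]])
        counts = np.hstack([a, 2 * a])
        np.testing.assert_allclose(tmm_factors(counts), [1.0, 1.0], atol=1e-12)

    def test_spec_worked_instance_matches_oracle(self):
        counts = np.array([[100, 100], [100, 100], [100, 100], [100, 400]])
        np.testing.assert_allclose(
            tmm_factors(counts), tmm_oracle(counts), atol=1e-9
        )

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(30):
            n_s = int(rng.integers(2, 5))
            counts = rng.integers(1, 500, size=(50, n_s)).astype(float)
            np.testing.assert_allclose(
                tmm_factors(counts), tmm_oracle(counts), atol=1e-9
            )

    def test_geometric_mean_is_one(self, rng):
        counts = rng.integers(1, 500, size=(60, 4)).astype(float)
        f = tmm_factors(counts)
        assert abs(np.exp(np.mean(np.log(f))) - 1.0) < 1e-9

    def test_explicit_library_sizes(self, rng):
        counts = rng.integers(1, 500, size=(50, 3)).astype(float)
        libs = counts.sum(axis=0) * np.array([10.0, 12.0, 9.0])
        np.testing.assert_allclose(
            tmm_factors(counts, library_sizes=libs),
            tmm_oracle(counts, lib_sizes=list(libs)),
            atol=1e-9,
        )


class TestOutlierFilter:
    def _cm(self, *cols):
        cols = [np.asarray(c) for c in cols]
        counts = np.stack(cols, axis=1)
        return CountMatrix(
            [f"w{i}" for i in range(counts.shape[0])],
            [f"inp{j}" for j in range(counts.shape[1])],
            counts,
        )

    def test_high_outlier_discarded(self):
        kept = filter_outlier_windows(self._cm([10, 10, 10, 10, 100]))
        assert kept == ["w0", "w1", "w2", "w3"]

    def test_constant_counts_all_retained(self):
        kept = filter_outlier_windows(self._cm([7, 7, 7, 7]))
        assert len(kept) == 4  # SD = 0, boundary inclusive

    def test_single_window_retained(self):
        kept = filter_outlier_windows(self._cm([42]))
        assert kept == ["w0"]

    def test_all_input_samples_must_pass(self):
        cm = self._cm([10, 10, 10, 10, 10], [10, 10, 10, 10, 200])
        kept = filter_outlier_windows(cm)
        assert "w4" not in kept

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 40))
            cols = [rng.integers(0, 200, size=n).tolist() for _ in range(2)]
            cm = self._cm(*cols)
            kept = filter_outlier_windows(cm)
            expected = [f"w{i}" for i in outlier_filter_oracle(cols)]
            assert kept == expected

    def test_empty_matrix_error(self):
        with pytest.raises(ValueError):
            filter_outlier_windows(
                CountMatrix([], ["a"], np.zeros((0, 1)), [1.0])
            )


def _paired_samples(mark="H3K27me3"):
    return [
        SampleInfo("c1_no", "c1", "noDOX", mark, 0.0),
        SampleInfo("c1_do", "c1", "DOX", mark, 0.5),
        SampleInfo("c2_no", "c2", "noDOX", mark, 0.0),
        SampleInfo("c2_do", "c2", "DOX", mark, 0.5),
    ]


class TestAccumulation:
    def _cm(self, counts, libs=None):
        counts = np.asarray(counts)
        return CountMatrix(
            [f"w{i}" for i in range(counts.shape[0])],
            ["c1_no", "c1_do", "c2_no", "c2_do"],
            counts,
            libs,
        )

    def test_equal_conditions_give_zero(self):
        cm = self._cm([[10, 10, 20, 20], [5, 5, 7, 7]], [100] * 4)
        acc = accumulation_signal(cm, np.ones(4), _paired_samples())
        np.testing.assert_allclose(acc.to_numpy(), 0.0, atol=1e-9)

    def test_subtraction_and_clone_average(self):
        # with equal effective libraries the normalized scale is common
        cm = self._cm([[10, 30, 10, 50]], [1_000_000] * 4)
        acc = accumulation_signal(cm, np.ones(4), _paired_samples())
        scale = 1e7 / 1e6
        assert acc["accum_c1"].iloc[0] == pytest.approx(20 * scale)
        assert acc["accum_c2"].iloc[0] == pytest.approx(40 * scale)
        assert acc["accum_mean"].iloc[0] == pytest.approx(30 * scale)

    def test_antisymmetric_under_condition_swap(self, rng):
        counts = rng.integers(1, 100, size=(10, 4))
        cm = self._cm(counts, [500] * 4)
        acc = accumulation_signal(cm, np.ones(4), _paired_samples())
        swapped_counts = counts[:, [1, 0, 3, 2]]
        cm2 = self._cm(swapped_counts, [500] * 4)
        acc2 = accumulation_signal(cm2, np.ones(4), _paired_samples())
        np.testing.assert_allclose(
            acc["accum_mean"], -acc2["accum_mean"], atol=1e-9
        )

    def test_missing_pair_is_error(self):
        cm = CountMatrix(["w0"], ["c1_no", "c1_do"], np.array([[1, 2]]), [10, 10])
        samples = _paired_samples()[:2]
        samples[0] = SampleInfo("c1_no", "c1", "noDOX", "H3K27me3", 0.0)
        bad = [samples[0], SampleInfo("c1_do", "c2", "DOX", "H3K27me3", 0.5)]
        with pytest.raises(ValueError, match="clone"):
            accumulation_signal(cm, np.ones(2), bad)


class TestChromFraction:
    def test_fraction_arithmetic(self):
        cm = CountMatrix(
            ["x1", "a1"], ["s1"], np.array([[30], [70]]), [100]
        )
        frac = reads_fraction_by_chrom(cm, {"x1": "chrX", "a1": "chr1"}, "chrX")
        assert frac["s1"] == pytest.approx(0.3)

    def test_all_on_target(self):
        cm = CountMatrix(["x1"], ["s1"], np.array([[5]]), [5])
        assert reads_fraction_by_chrom(cm, {"x1": "chrX"}, "chrX")["s1"] == 1.0

    def test_unknown_region_error(self):
        cm = CountMatrix(["x1"], ["s1"], np.array([[5]]), [5])
        with pytest.raises(ValueError):
            reads_fraction_by_chrom(cm, {}, "chrX")
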