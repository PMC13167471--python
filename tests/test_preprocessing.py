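"""Target-matrix construction, normalization, Gini, splitting and Otsu."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crestkit.genomic_io import CoverageTrack, GenomeSequence, GenomicInterval
from crestkit.preprocessing import (
    NormalizationConfig,
    PeakMatrix,
    TopicMatrix,
    annotate_gini,
    apply_scaling,
    binarize_otsu,
    compute_peak_matrix,
    constitutive_scaling_factors,
    cpm_normalize,
    gini_index,
    otsu_threshold,
    resize_regions,
    select_specific_regions,
    split_regions,
)

GENOME = GenomeSequence({"chr1": "A" * 1000, "chr2": "C" * 1000})


def _matrix(values, chrom="chr1"):
    values = np.asarray(values, dtype=float)
    regions = [GenomicInterval(chrom, 10 * i, 10 * i + 10) for i in range(len(values))]
    return PeakMatrix(values, regions, [f"c{j}" for j in range(values.shape[1])])


class TestResize:
    def test_recenter_to_width(self):
        (out,) = resize_regions([GenomicInterval("chr1", 100, 200)], 50, GENOME)
        assert (out.start, out.end) == (125, 175)

    def test_minimal_shift_at_edge(self):
        (out,) = resize_regions([GenomicInterval("chr1", 0, 10)], 100, GENOME)
        assert (out.start, out.end) == (0, 100)

    def test_short_chromosome_flagged(self):
        g = GenomeSequence({"tiny": "ACGT" * 10})
        (out,) = resize_regions([GenomicInterval("tiny", 0, 10)], 100, g)
        assert (out.start, out.end) == (0, 40)
        assert out.name.endswith("|short")


class TestPeakMatrix:
    def test_constant_track_mean(self):
        t = CoverageTrack.from_intervals([("chr1", 0, 1000, 2.0)], "c0")
        m = compute_peak_matrix([t], [GenomicInterval("chr1", 100, 200)],
                                agg="mean", center_window=50)
        assert m.values[0, 0] == 2.0

    def test_zero_track_all_aggs(self):
        t = CoverageTrack(class_label="c0")
        for agg in ("max", "mean", "sum", "logsum"):
            m = compute_peak_matrix([t], [GenomicInterval("chr1", 0, 100)],
                                    agg=agg, center_window=50)
            assert m.values[0, 0] == 0.0

    def test_spike_max(self):
        t = CoverageTrack.from_intervals([("chr1", 148, 152, 7.0)], "c0")
        m = compute_peak_matrix([t], [GenomicInterval("chr1", 100, 200)],
                                agg="max", center_window=50)
        assert m.values[0, 0] == 7.0

    def test_center_window_wider_than_region_rejected(self):
        t = CoverageTrack(class_label="c0")
        with pytest.raises(ValueError, match="center_window"):
            compute_peak_matrix([t], [GenomicInterval("chr1", 0, 100)],
                                center_window=200)


class TestCPM:
    def test_total_1e6_unchanged(self):
        t = CoverageTrack.from_intervals([("chr1", 0, 1_000_000, 1.0)])
        out = cpm_normalize(t)
        assert out.runs["chr1"][2][0] == pytest.approx(1.0)

    def test_total_2e6_halved(self):
        t = CoverageTrack.from_intervals([("chr1", 0, 500_000, 4.0)])
        out = cpm_normalize(t)
        assert out.runs["chr1"][2][0] == pytest.approx(2.0)

    def test_normalized_totals_equal(self):
        t1 = CoverageTrack.from_intervals([("chr1", 0, 100, 3.0)])
        t2 = CoverageTrack.from_intervals([("chr1", 0, 700, 9.0)])
        assert cpm_normalize(t1).total() == pytest.approx(cpm_normalize(t2).total())

    def test_zero_track_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            cpm_normalize(CoverageTrack())


class TestGini:
    def test_equal_vector_is_zero(self):
        assert gini_index(np.array([5.0, 5, 5, 5])) == 0.0

    def test_single_mass_n4(self):
        assert gini_index(np.array([1.0, 0, 0, 0])) == pytest.approx(0.75)

    def test_scale_invariance(self):
        v = np.array([1.0, 3.0, 0.5, 2.0])
        assert gini_index(v) == pytest.approx(gini_index(10 * v))

    def test_all_zero_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert gini_index(np.zeros(4)) == 0.0

    @given(
        v=st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=200),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_pairwise_difference_oracle(self, v):
        v = np.asarray(v)
        if v.sum() == 0:
            return
        n = v.size
        brute = np.abs(v[:, None] - v[None, :]).sum() / (2 * n * n * v.mean())
        assert gini_index(v) == pytest.approx(brute, abs=1e-12)


class TestConstitutiveScaling:
    def test_two_class_arithmetic(self):
        """Constitutive means 10 and 20 with mean reference 15 give 1.5/0.75."""
        values = np.array([[10.0, 20.0]] * 2 + [[1.0, 2.0]] * 8)
        m = _matrix(values)
        cfg = NormalizationConfig(top_frac=0.2, gini_rule=lambda g: np.ones_like(g, bool))
        factors, sets = constitutive_scaling_factors(m, cfg)
        np.testing.assert_allclose(factors, [1.5, 0.75])
        assert all(len(s) == 2 for s in sets)

    def test_identical_columns_give_unit_factors(self):
        values = np.tile(np.arange(1.0, 11.0)[:, None], (1, 3))
        factors, _ = constitutive_scaling_factors(
            _matrix(values), NormalizationConfig(top_frac=0.3))
        np.testing.assert_allclose(factors, 1.0)

    def test_scaling_equalizes_constitutive_means(self):
        rng = np.random.default_rng(0)
        values = rng.random((50, 4)) + 0.1
        values *= np.array([1.0, 2.0, 0.5, 3.0])
        m = _matrix(values)
        cfg = NormalizationConfig(top_frac=0.2)
        factors, sets = constitutive_scaling_factors(m, cfg)
        scaled = apply_scaling(m, factors)
        means = [scaled.values[s, c].mean() for c, s in enumerate(sets)]
        assert max(means) - min(means) < 1e-9

    def test_empty_constitutive_set_reports_rule(self):
        values = np.array([[10.0, 1.0], [1.0, 10.0], [1.0, 1.0]])
        cfg = NormalizationConfig(top_frac=0.34, gini_rule=lambda g: np.zeros_like(g, bool))
        with pytest.raises(ValueError, match="Gini rule"):
            constitutive_scaling_factors(_matrix(values), cfg)


class TestApplyScaling:
    def test_unit_factors_identity(self):
        m = _matrix(np.arange(8.0).reshape(4, 2) + 1)
        out = apply_scaling(m, np.ones(2))
        np.testing.assert_array_equal(out.values, m.values)

    def test_factor_doubles_column(self):
        m = _matrix(np.ones((3, 2)))
        out = apply_scaling(m, np.array([2.0, 1.0]))
        np.testing.assert_array_equal(out.values[:, 0], 2.0)
        np.testing.assert_array_equal(out.values[:, 1], 1.0)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            apply_scaling(_matrix(np.ones((2, 2))), np.array([1.0, 0.0]))


class TestSpecificSelection:
    def test_identical_gini_selects_none(self):
        m = _matrix(np.ones((10, 3)))
        m.obs["gini"] = 0.3
        assert not select_specific_regions(m).any()

    def test_outlier_selected(self):
        m = _matrix(np.ones((21, 3)))
        m.obs["gini"] = [0.1] * 20 + [0.9]
        flags = select_specific_regions(m)
        assert flags[-1] and flags[:-1].sum() == 0

    def test_invariant_under_common_column_scaling(self):
        rng = np.random.default_rng(2)
        values = rng.random((30, 3)) + 0.01
        m1, m2 = _matrix(values), _matrix(values * 7.0)
        annotate_gini(m1), annotate_gini(m2)
        np.testing.assert_array_equal(
            select_specific_regions(m1), select_specific_regions(m2))


class TestSplit:
    def test_fraction_counts(self):
        m = _matrix(np.ones((100, 2)))
        split_regions(m, "fraction", 0.1, 0.1, seed=0)
        counts = m.obs["split"].value_counts()
        assert counts["train"] == 80 and counts["val"] == 10 and counts["test"] == 10

    def test_same_seed_same_assignment(self):
        m1, m2 = _matrix(np.ones((50, 2))), _matrix(np.ones((50, 2)))
        split_regions(m1, "fraction", 0.2, 0.2, seed=5)
        split_regions(m2, "fraction", 0.2, 0.2, seed=5)
        assert (m1.obs["split"] == m2.obs["split"]).all()

    def test_chromosome_mode_keeps_chromosomes_whole(self):
        regions = [GenomicInterval(f"chr{i % 4 + 1}", 10 * i, 10 * i + 10) for i in range(40)]
        m = PeakMatrix(np.ones((40, 2)), regions, ["a", "b"])
        split_regions(m, "chromosome", ["chr2"], ["chr3"])
        df = pd.DataFrame({"chrom": [iv.chrom for iv in m.regions],
                           "split": m.obs["split"]})
        assert (df.groupby("chrom")["split"].nunique() == 1).all()
        assert set(df[df.chrom == "chr2"]["split"]) == {"val"}
        assert set(df[df.chrom == "chr3"]["split"]) == {"test"}

    def test_every_region_in_exactly_one_split(self):
        m = _matrix(np.ones((37, 2)))
        split_regions(m, "fraction", 0.25, 0.25, seed=1)
        assert m.obs["split"].isin(["train", "val", "test"]).all()

    def test_val_test_overlap_rejected(self):
        m = _matrix(np.ones((10, 2)))
        with pytest.raises(ValueError, match="both"):
            split_regions(m, "chromosome", ["chr1"], ["chr1"])

    def test_missing_chromosome_warns(self):
        m = _matrix(np.ones((10, 2)))
        with pytest.warns(UserWarning, match="chr8"):
            split_regions(m, "chromosome", ["chr8"], ["chr9"])


class TestOtsu:
    def _topic(self, col):
        col = np.asarray(col, dtype=float)
        regions = [GenomicInterval("chr1", 10 * i, 10 * i + 10) for i in range(col.size)]
        return TopicMatrix(col[:, None], regions, ["t0"])

    def test_bimodal_column(self):
        t = self._topic([0.1] * 5 + [0.9] * 5)
        out = binarize_otsu(t)
        thr = otsu_threshold(t.probs[:, 0])
        assert 0.1 <= thr < 0.9
        assert out.mask[:, 0].sum() == 5

    def test_constant_column_empty_mask(self):
        with pytest.warns(UserWarning, match="constant"):
            out = binarize_otsu(self._topic([0.5] * 6))
        assert out.mask.sum() == 0

    def test_invariant_to_duplication(self):
        col = np.array([0.05, 0.2, 0.7, 0.9, 0.4, 0.1])
        once = otsu_threshold(col)
        twice = otsu_threshold(np.concatenate([col, col]))
        assert once == twice

    def test_matches_exhaustive_between_class_variance_search(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            col = np.round(rng.random(40), 3)
            if np.unique(col).size < 2:
                continue
            thr = otsu_threshold(col)
            # independent exhaustive search over all distinct candidate cuts
            best_t, best_v = None, -1.0
            for t in np.unique(col)[:-1]:
                lo = col[col <= t]
                hi = col[col > t]
                v = (lo.size / col.size) * (hi.size / col.size) * (lo.mean() - hi.mean()) ** 2
                if v > best_v:
                    best_v, best_t = v, t
            assert thr == best_t
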