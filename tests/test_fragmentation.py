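import numpy as np
import pytest

from plasmafrag.fragmentation import (
    bin_size_counts,
    build_profile,
    cohort_similarity,
    gc_correct,
)
from plasmafrag.fragments import GenomeBins, make_bins

from conftest import make_sample


def bins_with_gc(n=20, size=1_000_000, gc=None):
    gb = make_bins({"chr1": n * size}, size)
    table = gb.bins.copy()
    table["gc"] = np.linspace(0.35, 0.55, n) if gc is None else gc
    return GenomeBins(table, size)


class TestBinSizeCounts:
    def test_150_assigned_to_short(self):
        sf = make_sample(
            [("chr1", 0, 120), ("chr1", 200, 350), ("chr1", 400, 580)]
        )  # lengths 120, 150, 180
        gb = make_bins({"chr1": 5_000_000}, 5_000_000)
        counts = bin_size_counts(sf, gb)
        assert counts.loc[0, "short_count"] == 2
        assert counts.loc[0, "long_count"] == 1

    def test_empty_bin_zero_counts(self):
        sf = make_sample([("chr1", 0, 167)])
        gb = make_bins({"chr1": 10_000_000}, 5_000_000)
        counts = bin_size_counts(sf, gb)
        assert counts.loc[1].tolist() == [0, 0, 0]

    def test_overlapping_ranges_rejected(self):
        sf = make_sample([("chr1", 0, 167)])
        gb = make_bins({"chr1": 5_000_000}, 5_000_000)
        with pytest.raises(ValueError, match="overlap"):
            bin_size_counts(sf, gb, short_range=(100, 160), long_range=(150, 220))

    def test_short_share_matches_mixture(self, small_cohort):
        """Per-bin short/(short+long) tracks the configured mixture mass."""
        cfg = small_cohort.config
        sid = small_cohort.truth.query("label == 'healthy'")["sample_id"].iloc[0]
        counts = bin_size_counts(small_cohort.samples[sid], small_cohort.bins)
        mix = cfg.healthy_mixture
        p_short = mix.mass(100, 151) / (mix.mass(100, 151) + mix.mass(151, 221))
        s, l = counts["short_count"].sum(), counts["long_count"].sum()
        observed = s / (s + l)
        se = np.sqrt(p_short * (1 - p_short) / (s + l))
        assert abs(observed - p_short) < max(4 * se, 0.01)


class TestGCCorrect:
    def test_constant_values_unchanged(self):
        gc = np.linspace(0.3, 0.6, 20)
        values = np.full(20, 100.0)
        assert np.allclose(gc_correct(values, gc), values)

    def test_constant_gc_is_identity(self):
        values = np.arange(20, dtype=float) * 3 + 50
        assert np.allclose(gc_correct(values, np.full(20, 0.45)), values)

    def test_linear_trend_removed_vs_wls_oracle(self):
        gc = np.linspace(0.3, 0.6, 30)
        values = 100 + 200 * (gc - gc.mean())
        corrected = gc_correct(values, gc)
        # independent oracle: ordinary least squares fit of value on gc
        slope, intercept = np.polyfit(gc, values, 1)
        oracle = values - (slope * gc + intercept) + values.mean()
        assert np.abs(corrected - 100).max() < 2
        assert np.abs(corrected - oracle).max() < 2

    def test_total_preserved(self):
        rng = np.random.default_rng(4)
        gc = np.linspace(0.3, 0.6, 50)
        values = rng.poisson(1000, 50) + 500 * gc
        corrected = gc_correct(values, gc)
        assert abs(corrected.sum() - values.sum()) < 1e-3 * values.sum()


class TestProfiles:
    def build(self, small_cohort, sid):
        return build_profile(small_cohort.samples[sid], small_cohort.bins)

    def test_fraction_sums_to_one(self, small_cohort):
        prof = self.build(small_cohort, "healthy_000")
        frac = prof.vector("fraction")
        assert abs(np.nansum(frac) - 1.0) < 1e-9

    def test_normalized_ratio_mean_zero(self, small_cohort):
        prof = self.build(small_cohort, "healthy_000")
        nr = prof.vector("normalized_ratio")
        assert abs(np.nanmean(nr[prof.mask])) < 1e-9

    def test_simple_ratio_value(self):
        rows = [("chr1", 0, 125)] * 50 + [("chr1", 0, 180)] * 100
        sf = make_sample([(c, s + 2 * i, e + 2 * i)
                          for i, (c, s, e) in enumerate(rows)])
        gb = make_bins({"chr1": 5_000_000}, 5_000_000)
        prof = build_profile(sf, gb)
        assert prof.table.loc[0, "ratio"] == pytest.approx(0.5)

    def test_centering_example(self):
        # three bins engineered to ratios 0.2, 0.3, 0.4
        rows = []
        for b, n_short in enumerate([20, 30, 40]):
            base = b * 5_000_000
            rows += [("chr1", base + 4 * i, base + 4 * i + 125)
                     for i in range(n_short)]
            rows += [("chr1", base + 4 * i + 1, base + 4 * i + 181)
                     for i in range(100)]
        gb = make_bins({"chr1": 15_000_000}, 5_000_000)
        prof = build_profile(make_sample(rows), gb)
        assert np.allclose(prof.vector("normalized_ratio"), [-0.1, 0, 0.1])


class TestCohortSimilarity:
    def test_identity_and_symmetry(self, small_cohort):
        ids = ["cancer_000", "cancer_001", "cancer_002",
               "healthy_000", "healthy_001", "healthy_002"]
        profs = [
            build_profile(small_cohort.samples[s], small_cohort.bins)
            for s in ids
        ]
        healthy = [p.sample_id for p in profs if p.sample_id.startswith("healthy")]
        sim = cohort_similarity(profs, healthy)
        m = sim.matrix.to_numpy()
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T, equal_nan=True)
        assert np.nanmax(np.abs(m)) <= 1 + 1e-12

    def test_sample_equal_to_median_has_r_one(self, small_cohort):
        profs = [
            build_profile(small_cohort.samples[s], small_cohort.bins)
            for s in ["healthy_000", "healthy_001", "healthy_002"]
        ]
        # duplicate the median profile as a fake sample
        import copy

        ref = copy.deepcopy(profs[0])
        shared = np.logical_and.reduce([p.mask for p in profs])
        med = np.median(
            np.stack([p.vector("ratio") for p in profs])[:, shared], axis=0
        )
        ref.table.loc[np.flatnonzero(shared), "ratio"] = med
        ref.sample_id = "median_clone"
        sim = cohort_similarity(profs + [ref], [p.sample_id for p in profs])
        assert sim.r_to_reference["median_clone"] == pytest.approx(1.0)

    def test_negated_profile_has_r_minus_one(self, small_cohort):
        profs = [
            build_profile(small_cohort.samples[s], small_cohort.bins)
            for s in ["healthy_000", "healthy_001"]
        ]
        import copy

        neg = copy.deepcopy(profs[0])
        r = neg.table["ratio"].to_numpy()
        neg.table["ratio"] = 2 * np.nanmean(r) - r
        neg.sample_id = "negated"
        sim = cohort_similarity(profs + [neg], ["healthy_000"], on="ratio")
        assert sim.matrix.loc["healthy_000", "negated"] == pytest.approx(-1.0)

    def test_too_few_shared_bins_rejected(self, small_cohort):
        profs = [
            build_profile(small_cohort.samples[s], small_cohort.bins)
            for s in ["healthy_000", "healthy_001"]
        ]
        import copy

        broken = copy.deepcopy(profs[1])
        broken.table["mask"] = False
        with pytest.raises(ValueError, match="shared"):
            cohort_similarity([profs[0], broken], ["healthy_000"])
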