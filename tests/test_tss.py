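import numpy as np
import pandas as pd
import pytest

from plasmafrag.tss import (
    TSSAnnotation,
    classify_chromatin_state,
    expression_concordance,
    region_depth,
    tss_relative_coverages,
)

from conftest import make_sample, uniform_tiling_sample


def annotation(rows):
    return TSSAnnotation.from_frame(
        pd.DataFrame(rows, columns=["gene", "chrom", "strand", "tss"])
    )


class TestRegionDepth:
    def test_no_fragments_zero(self):
        sf = make_sample([("chr2", 0, 100)])
        assert region_depth(sf, "chr1", 0, 100) == 0.0

    def test_full_cover_one(self):
        sf = make_sample([("chr1", 0, 300)])
        assert region_depth(sf, "chr1", 100, 200) == 1.0

    def test_two_half_covers_average_one(self):
        sf = make_sample([("chr1", 0, 100), ("chr1", 100, 200)])
        assert region_depth(sf, "chr1", 0, 200) == 1.0

    def test_zero_length_interval_rejected(self):
        sf = make_sample([("chr1", 0, 100)])
        with pytest.raises(ValueError):
            region_depth(sf, "chr1", 50, 50)


class TestRelativeCoverages:
    def test_uniform_coverage_all_ones(self):
        sf = uniform_tiling_sample(size=20_000, frag_len=100)
        ann = annotation([("g", "chr1", "+", 10_000)])
        cov = tss_relative_coverages(sf, ann, {"chr1": 20_000})
        row = cov.iloc[0]
        assert row["ndr_rc"] == pytest.approx(1.0, abs=0.02)
        assert row["k2_rc"] == pytest.approx(1.0, abs=0.02)
        assert row["conventional_rc"] == pytest.approx(1.0, abs=0.02)

    def test_zero_ndr_nonzero_reference(self):
        # cover the flanks but not the NDR
        rows = [("chr1", s, s + 100)
                for s in range(6_000, 8_900, 100)]
        rows += [("chr1", s, s + 100) for s in range(11_100, 14_000, 100)]
        sf = make_sample(rows)
        ann = annotation([("g", "chr1", "+", 10_000)])
        cov = tss_relative_coverages(sf, ann, {"chr1": 20_000})
        assert cov.iloc[0]["ndr_rc"] == 0.0

    def test_edge_gene_skipped(self):
        sf = uniform_tiling_sample(size=20_000, frag_len=100)
        ann = annotation([("edge", "chr1", "+", 1_000)])
        cov = tss_relative_coverages(sf, ann, {"chr1": 20_000})
        assert np.isnan(cov.iloc[0]["ndr_rc"])
        assert "edge" in cov.iloc[0]["note"]

    def test_strand_mirroring_invariance(self):
        """Mirroring fragments about the TSS and flipping strand leaves all
        three coverages unchanged."""
        rng = np.random.default_rng(12)
        tss_pos = 50_000
        starts = rng.integers(tss_pos - 4000, tss_pos + 4000, 400)
        lens = rng.integers(120, 200, 400)
        fw = make_sample(
            [("chr1", int(s), int(s + l)) for s, l in zip(starts, lens)]
        )
        mirrored = make_sample(
            [
                ("chr1", int(2 * tss_pos - (s + l)), int(2 * tss_pos - s))
                for s, l in zip(starts, lens)
            ]
        )
        sizes = {"chr1": 100_000}
        cov_fw = tss_relative_coverages(
            fw, annotation([("g", "chr1", "+", tss_pos)]), sizes
        )
        cov_rv = tss_relative_coverages(
            mirrored, annotation([("g", "chr1", "-", tss_pos)]), sizes
        )
        for col in ("conventional_rc", "ndr_rc", "k2_rc"):
            assert cov_fw.iloc[0][col] == pytest.approx(cov_rv.iloc[0][col])

    def test_depleted_ndr_recovered(self, tss_dense_cohort):
        """Expressed genes' median NDR coverage lands near the configured
        depletion factor."""
        cohort = tss_dense_cohort
        sf = cohort.samples["healthy_000"]
        ann = TSSAnnotation.from_frame(cohort.genes)
        cov = tss_relative_coverages(
            sf, ann, dict(cohort.config.genome)
        ).set_index("gene")
        up = cohort.genes.query("expression == 'up'")["gene"]
        med = cov.loc[up, "ndr_rc"].median()
        assert 0.3 <= med <= 0.6


class TestTSSAnnotation:
    def test_duplicate_tss_collapsed_most_upstream(self):
        ann = TSSAnnotation.from_frame(
            pd.DataFrame(
                {
                    "gene": ["a", "a", "b", "b"],
                    "chrom": ["chr1"] * 4,
                    "strand": ["+", "+", "-", "-"],
                    "tss": [500, 300, 700, 900],
                }
            )
        )
        t = ann.table.set_index("gene")["tss"]
        assert t["a"] == 300  # + strand: smallest coordinate
        assert t["b"] == 900  # - strand: largest coordinate


class TestClassifyChromatinState:
    def make_tables(self, ndr_rows, k2_rows, genes=None):
        genes = genes or [f"g{i}" for i in range(len(ndr_rows))]
        return (
            pd.DataFrame(ndr_rows, index=genes),
            pd.DataFrame(k2_rows, index=genes),
        )

    def test_majority_open_is_permissive(self):
        ndr, k2 = self.make_tables(
            [[0.5] * 8 + [1.2] * 2], [[0.6] * 8 + [1.2] * 2]
        )
        calls = classify_chromatin_state(ndr, k2)
        assert calls[0].state == "permissive"
        assert calls[0].freq_open == pytest.approx(0.8)

    def test_majority_closed_is_nonpermissive(self):
        ndr, k2 = self.make_tables(
            [[1.6] * 9 + [1.0]], [[1.8] * 9 + [1.0]]
        )
        calls = classify_chromatin_state(ndr, k2)
        assert calls[0].state == "nonpermissive"

    def test_conjunction_required(self):
        ndr, k2 = self.make_tables([[0.5] * 10], [[1.2] * 10])
        assert classify_chromatin_state(ndr, k2)[0].state == "indeterminate"

    def test_exact_majority_is_not_enough(self):
        ndr, k2 = self.make_tables([[0.5] * 5 + [1.2] * 5],
                                   [[0.5] * 5 + [1.2] * 5])
        assert classify_chromatin_state(ndr, k2)[0].state == "indeterminate"

    def test_label_recovery_on_simulation(self, tss_dense_cohort):
        cohort = tss_dense_cohort
        ann = TSSAnnotation.from_frame(cohort.genes)
        sizes = dict(cohort.config.genome)
        ndr_cols, k2_cols = {}, {}
        for sid, sf in cohort.samples.items():
            cov = tss_relative_coverages(sf, ann, sizes).set_index("gene")
            ndr_cols[sid] = cov["ndr_rc"]
            k2_cols[sid] = cov["k2_rc"]
        calls = classify_chromatin_state(
            pd.DataFrame(ndr_cols), pd.DataFrame(k2_cols)
        )
        pred = pd.Series({c.gene: c.state for c in calls})
        truth = cohort.genes.set_index("gene")["chromatin_state"]
        recovered = (pred.loc[truth.index] == truth).mean()
        assert recovered >= 0.95


class TestExpressionConcordance:
    def test_identical_distributions_null(self):
        rng = np.random.default_rng(13)
        vals = pd.Series(rng.normal(size=200))
        groups = pd.Series(["up"] * 100 + ["down"] * 100, index=vals.index)
        res = expression_concordance(vals, groups)
        assert res["p_value"] > 0.01

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(14)
        vals = pd.Series(
            np.concatenate([rng.normal(1, 1, 200), rng.normal(0, 1, 200)])
        )
        groups = pd.Series(["up"] * 200 + ["down"] * 200, index=vals.index)
        res = expression_concordance(vals, groups)
        assert res["p_value"] < 0.01 and res["direction"] == "up>down"

    def test_single_gene_group_skipped(self):
        vals = pd.Series([1.0, 2.0, 3.0])
        groups = pd.Series(["up", "down", "down"])
        with pytest.warns(UserWarning, match="skipped"):
            res = expression_concordance(vals, groups)
        assert res["p_value"] is None
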