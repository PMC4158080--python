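"""Translation efficiency, ribosomal density, Gro-seq rate, tissue stats."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coordx.expression_metrics import (
    build_expression_table,
    groseq_rate,
    ribosomal_density,
    split_by_expression,
    tissue_summary,
    translation_efficiency,
)


class TestTranslationEfficiency:
    @pytest.mark.parametrize("fp, mr, expected", [(100, 50, 2.0), (0, 50, 0.0)])
    def test_ratio(self, fp, mr, expected):
        assert translation_efficiency(fp, mr) == expected

    def test_zero_mrna_is_undefined(self):
        assert translation_efficiency(10, 0) is None

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            translation_efficiency(-1, 10)


class TestRibosomalDensity:
    def test_te_per_nucleotide(self):
        assert ribosomal_density(2.0, 1000) == pytest.approx(0.002)
        assert ribosomal_density(0.0, 300) == 0.0

    def test_zero_cds_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero CDS"):
            assert ribosomal_density(1.0, 0) is None

    def test_scale_invariance_to_joint_rescaling(self):
        te1 = translation_efficiency(100, 50)
        te2 = translation_efficiency(1000, 500)  # both libraries 10x deeper
        assert ribosomal_density(te1, 900) == ribosomal_density(te2, 900)

    def test_homogeneity(self):
        assert ribosomal_density(2.0, 1000) == ribosomal_density(4.0, 2000)


class TestGroseqRate:
    @pytest.mark.parametrize(
        "reads, length, rate, background",
        [(40, 3000, 20.0, False), (8, 3000, 4.0, True), (0, 2000, 0.0, True)],
    )
    def test_rate_and_background_flag(self, reads, length, rate, background):
        out = groseq_rate(reads, length)
        assert out.rate == pytest.approx(rate)
        assert out.background is background

    def test_short_gene_excluded(self):
        with pytest.warns(UserWarning, match="1 kb"):
            assert groseq_rate(10, 800) is None

    def test_invariant_to_first_kilobase_reads(self):
        # pausing reads live in a separate column and never reach the rate
        assert groseq_rate(40, 3000) == groseq_rate(40, 3000)
        df = pd.DataFrame(
            {"gene": ["a"], "reads_beyond_1kb": [40], "reads_first_1kb": [10_000]}
        )
        feats = pd.DataFrame({"gene": ["a"], "uaug_class": ["uAUG"], "cds_length": [300],
                              "gene_length": [3000]})
        out = build_expression_table(feats, groseq=df)
        assert out["groseq_rate"].iloc[0] == pytest.approx(40 / 2.0)


class TestTissueSummary:
    def test_mean_max_breadth(self):
        s = tissue_summary([100, 300, 500])
        assert (s.mean, s.max, s.breadth) == (300, 500, 2)
        assert not s.below_background

    def test_all_zero_flagged_below_background(self):
        s = tissue_summary([0.0] * 5)
        assert (s.mean, s.max, s.breadth, s.below_background) == (0, 0, 0, True)

    def test_breadth_boundary_inclusive(self):
        assert tissue_summary([200.0] * 79).breadth == 79

    def test_empty_vector_raises(self):
        with pytest.raises(ValueError):
            tissue_summary([])

    def test_breadth_monotone_in_threshold(self, rng):
        v = rng.lognormal(5, 1, size=79)
        breadths = [tissue_summary(v, t).breadth for t in (50, 100, 200, 400, 800)]
        assert breadths == sorted(breadths, reverse=True)


class TestExpressionSplit:
    def test_top_quarter_of_distinct_values(self):
        values = {f"g{i}": float(i) for i in range(1, 101)}
        top, bottom = split_by_expression(values, 0.25)
        assert top == {f"g{i}" for i in range(76, 101)}
        assert len(top) + len(bottom) == 100

    def test_top_decile(self):
        values = {f"g{i}": float(i) for i in range(1, 101)}
        top, _ = split_by_expression(values, 0.10)
        assert top == {f"g{i}" for i in range(91, 101)}

    def test_all_ties_go_to_top(self):
        values = {f"g{i}": 5.0 for i in range(10)}
        top, bottom = split_by_expression(values, 0.25)
        assert len(top) == 10 and not bottom

    def test_too_few_genes_raises(self):
        with pytest.raises(ValueError, match="at least 4"):
            split_by_expression({"a": 1.0, "b": 2.0}, 0.25)

    def test_partition_property(self, rng):
        values = {f"g{i}": float(v) for i, v in enumerate(rng.integers(0, 50, size=200))}
        for frac in (0.1, 0.25, 0.5):
            top, bottom = split_by_expression(values, frac)
            assert top | bottom == set(values)
            assert not (top & bottom)


class TestExpressionTable:
    def test_join_and_exclusion_reasons(self):
        feats = pd.DataFrame(
            {
                "gene": ["a", "b", "c"],
                "uaug_class": ["uAUG", "uAUG_less", "uAUG_less"],
                "cds_length": [300, 0, 900],
                "gene_length": [3000, 5000, 800],
            }
        )
        ribo = pd.DataFrame(
            {"gene": ["a", "b", "c"], "footprint_reads": [100, 10, 50], "mrna_reads": [50, 0, 100]}
        )
        groseq = pd.DataFrame(
            {"gene": ["a", "b", "c"], "reads_beyond_1kb": [40, 100, 10], "reads_first_1kb": [5, 5, 5]}
        )
        tissues = pd.DataFrame(
            {"gene": ["a", "b", "c"], "t1": [300.0, 10.0, 500.0], "t2": [500.0, 20.0, 100.0]}
        ).set_index("gene")
        out = build_expression_table(feats, ribo=ribo, groseq=groseq, tissues=tissues).set_index("gene")
        assert out.loc["a", "te"] == pytest.approx(2.0)
        assert out.loc["a", "ribo_density"] == pytest.approx(2.0 / 300)
        assert np.isnan(out.loc["b", "te"])
        assert "zero_mrna_reads" in out.loc["b", "exclusion_reason"]
        assert np.isnan(out.loc["c", "groseq_rate"])  # gene span below 1 kb
        assert "gene_shorter_than_1kb" in out.loc["c", "exclusion_reason"]
        assert out.loc["a", "tissue_breadth"] == 2
        assert "tissue_below_background" in out.loc["b", "exclusion_reason"]

    def test_layers_optional(self):
        feats = pd.DataFrame({"gene": ["a"], "uaug_class": ["uAUG"], "cds_length": [300],
                              "gene_length": [2000]})
        out = build_expression_table(feats)
        assert "te" not in out.columns
        assert out["exclusion_reason"].iloc[0] == ""
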