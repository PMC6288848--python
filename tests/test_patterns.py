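"""Promoter windows, position scoring, pattern construction and Fig-style stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import uprepeats as up
from _oracles import r_squared


def gene(gid, chrom, start, end, strand):
    return up.GeneModel(gid, up.GenomicInterval(chrom, start, end, strand))


def repeat(chrom, start, end, cls="Alu"):
    return up.RepeatAnnotation(cls, up.GenomicInterval(chrom, start, end, "."))


class TestPromoterWindow:
    def test_plus_strand_window_immediately_upstream(self):
        w = up.promoter_window(gene("g", "chr1", 5000, 9000, "+"), rd=1000)
        assert (w.window.start, w.window.end, w.tss, w.truncated) == (4000, 5000, 5000, False)

    def test_minus_strand_window_is_the_mirror(self):
        w = up.promoter_window(gene("g", "chr1", 2000, 6000, "-"), rd=1000)
        assert (w.window.start, w.window.end, w.tss) == (6000, 7000, 6000)

    def test_clipping_at_chromosome_start_sets_truncated(self):
        w = up.promoter_window(gene("g", "chr1", 400, 2000, "+"), rd=1000)
        assert (w.window.start, w.window.end, w.truncated) == (0, 400, True)

    def test_nonpositive_rd_rejected(self):
        with pytest.raises(up.ValidationError):
            up.promoter_window(gene("g", "chr1", 5000, 9000, "+"), rd=0)


class TestPScore:
    def test_fully_upstream_repeat_distance_from_proximal_boundary(self):
        w = up.promoter_window(gene("g", "chr1", 5000, 9000, "+"), rd=1000)
        pl = up.p_score(repeat("chr1", 4200, 4750), w)
        assert pl.p_score == pytest.approx(0.25)
        assert pl.tss_distance == 250 and pl.length == 550

    def test_repeat_spanning_tss_scores_zero_and_is_retained(self):
        w = up.promoter_window(gene("g", "chr1", 5000, 9000, "+"), rd=1000)
        pl = up.p_score(repeat("chr1", 4900, 5100), w)
        assert pl.p_score == 0.0

    def test_repeat_ending_at_window_start_is_excluded(self):
        w = up.promoter_window(gene("g", "chr1", 5000, 9000, "+"), rd=1000)
        assert up.p_score(repeat("chr1", 3000, 4000), w) is None

    def test_minus_strand_mirror(self):
        w = up.promoter_window(gene("g", "chr1", 2000, 6000, "-"), rd=1000)
        pl = up.p_score(repeat("chr1", 6250, 6800), w)
        assert pl.p_score == pytest.approx(0.25)

    def test_chromosome_mismatch_rejected(self):
        w = up.promoter_window(gene("g", "chr1", 5000, 9000, "+"), rd=1000)
        with pytest.raises(up.ValidationError):
            up.p_score(repeat("chr2", 4200, 4750), w)


class TestBuildPattern:
    def make(self, specs):
        return [
            up.RepeatPlacement("g", cls, p, int(round(p * 1000)), ln)
            for cls, p, ln in specs
        ]

    def test_labels_ordered_tss_proximal_first(self):
        g = gene("g", "chr1", 5000, 9000, "+")
        pat = up.build_pattern(g, self.make([("Alu", 0.40, 300), ("MIR", 0.10, 180)]))
        assert pat.canonical == "TSS<>MIR<>Alu"

    def test_repeated_classes_kept(self):
        g = gene("g", "chr1", 5000, 9000, "+")
        pat = up.build_pattern(g, self.make([("Alu", 0.2, 300), ("Alu", 0.6, 280)]))
        assert pat.canonical == "TSS<>Alu<>Alu" and pat.n_repeats == 2

    def test_single_placement(self):
        g = gene("g", "chr1", 5000, 9000, "+")
        assert up.build_pattern(g, self.make([("ERV1", 0.9, 300)])).canonical == "TSS<>ERV1"

    def test_tie_breaks_by_length_then_label(self):
        g = gene("g", "chr1", 5000, 9000, "+")
        pat = up.build_pattern(
            g, self.make([("MIR", 0.3, 200), ("Alu", 0.3, 200), ("ERV1", 0.3, 100)]))
        assert pat.labels == ("ERV1", "Alu", "MIR")

    def test_empty_placements_mean_repeat_free(self):
        assert up.build_pattern(gene("g", "chr1", 5000, 9000, "+"), []) is None


class TestCatalog:
    def test_identical_configurations_aggregate(self):
        genes = [gene(f"g{i}", "chr1", 50000 * (i + 1), 50000 * (i + 1) + 4000, "+")
                 for i in range(3)]
        reps = [repeat("chr1", g.interval.start - 500, g.interval.start - 200)
                for g in genes]
        cat = up.catalog_patterns(genes, reps)
        assert set(cat.patterns) == {"TSS<>Alu"}
        assert cat.patterns["TSS<>Alu"].n_genes == 3

    def test_repeat_free_genes_counted_in_total_only(self):
        genes = [gene("g1", "chr1", 50000, 54000, "+"),
                 gene("g2", "chr1", 200000, 204000, "+")]
        reps = [repeat("chr1", 49500, 49800)]
        cat = up.catalog_patterns(genes, reps)
        assert cat.n_genes_total == 2 and cat.n_genes_with_repeats == 1
        assert cat.repeat_free_gene_ids == {"g2"}
        assert cat.coverage_fraction == 0.5

    def test_empty_repeat_list_yields_zero_coverage(self):
        genes = [gene("g1", "chr1", 50000, 54000, "+")]
        cat = up.catalog_patterns(genes, [])
        assert cat.coverage_fraction == 0.0 and not cat.patterns


class TestStats:
    def _toy_catalog(self):
        patterns = {
            "TSS<>Alu": up.ConfigurationPattern(("Alu",), {"g1", "g2", "g3"}),
            "TSS<>Alu<>Alu": up.ConfigurationPattern(("Alu", "Alu"), {"g4"}),
        }
        return up.PatternCatalog(patterns, set(), 4)

    def test_single_multiple_split_fractions(self):
        assert up.single_multiple_split(self._toy_catalog()) == (0.75, 0.25)

    def test_split_errors_on_empty(self):
        cat = up.PatternCatalog({}, {"g1"}, 1)
        with pytest.raises(up.ValidationError):
            up.single_multiple_split(cat)

    def test_repeat_frequency_counts_genes_and_occurrences(self):
        stats = up.repeat_frequency_stats(self._toy_catalog()).set_index("repeat_class")
        assert stats.loc["Alu", "n_genes"] == 4
        assert stats.loc["Alu", "n_occurrences"] == 5
        assert stats.loc["Alu", "gene_fraction"] == 1.0

    def test_length_vs_count_r2_perfect_fit(self):
        genes = [gene(f"g{i}", "chr1", 10**6 * (i + 1), 10**6 * (i + 1) + 1000 * (i + 1), "+")
                 for i in range(4)]
        patterns = {}
        for i, g in enumerate(genes):
            labels = tuple(["Alu"] * (i + 1))
            patterns[up.canonical_pattern(labels)] = up.ConfigurationPattern(
                labels, {g.gene_id})
        cat = up.PatternCatalog(patterns, set(), 4)
        r2, sign = up.length_vs_count_r2(genes, cat)
        assert r2 == pytest.approx(1.0) and sign == 1

    def test_length_vs_count_r2_matches_closed_form_oracle(self, default_dataset,
                                                           default_catalog):
        r2, sign = up.length_vs_count_r2(default_dataset.genes, default_catalog)
        counts = {g: p.n_repeats for p in default_catalog.patterns.values()
                  for g in p.gene_ids}
        xs, ys = zip(*[(g.length, counts[g.gene_id]) for g in default_dataset.genes
                       if g.gene_id in counts])
        assert r2 == pytest.approx(r_squared(list(map(float, xs)), list(map(float, ys))))
        assert sign == -1  # generator plants the inverse length-count relation

    def test_inverted_comparison_table_and_palindrome(self):
        patterns = {
            "TSS<>MIR<>Alu": up.ConfigurationPattern(("MIR", "Alu"), {f"a{i}" for i in range(10)}),
            "TSS<>Alu<>MIR": up.ConfigurationPattern(("Alu", "MIR"), {f"b{i}" for i in range(4)}),
            "TSS<>Alu<>Alu": up.ConfigurationPattern(("Alu", "Alu"), {"c1", "c2"}),
        }
        cat = up.PatternCatalog(patterns, set(), 16)
        table, _ = up.inverted_comparison(cat)
        row = table.set_index("pattern")
        assert row.loc["TSS<>MIR<>Alu"].tolist() == [10, 4]
        assert row.loc["TSS<>Alu<>MIR"].tolist() == [4, 10]
        assert row.loc["TSS<>Alu<>Alu"].tolist() == [2, 2]  # palindrome: self-compare

    def test_tss_distance_distribution_monotone_ending_at_one(self, default_dataset):
        placements = up.extract_placements(default_dataset.genes, default_dataset.repeats)
        curves = up.tss_distance_distribution(placements, bins=10)
        arr = curves.to_numpy()
        assert (np.diff(arr, axis=1) >= -1e-12).all()
        assert np.allclose(arr[:, -1], 1.0)

    def test_uniform_placements_give_linear_cumulative_curve(self):
        # KS distance to the uniform CDF below the alpha=0.01 critical value
        rng = np.random.default_rng(4)
        n = 2000
        d = rng.integers(0, 1000, size=n)
        placements = pd.DataFrame(
            {"gene_id": "g", "repeat_class": "Alu", "p_score": d / 1000,
             "tss_distance": d, "length": 300})
        curve = up.tss_distance_distribution(placements, bins=20).loc["Alu"]
        edges = np.array(curve.index, dtype=float)
        ks = np.max(np.abs(curve.to_numpy() - edges / 1000.0))
        assert ks < 1.63 / np.sqrt(n)

    def test_near_and_far_classes_separate(self, default_dataset):
        placements = up.extract_placements(default_dataset.genes, default_dataset.repeats)
        curves = up.tss_distance_distribution(placements, bins=10)
        # near-TSS classes are stochastically smaller than far classes
        assert (curves.loc["Low_complexity"] >= curves.loc["ERV1"] - 1e-12).all()

    def test_length_stats_mean_and_ordering(self, default_dataset):
        placements = up.extract_placements(default_dataset.genes, default_dataset.repeats)
        stats = up.length_stats(placements)
        assert stats.loc["ERV1", "mean_length"] > stats.loc["Low_complexity", "mean_length"]

    def test_length_stats_simple_mean(self):
        placements = pd.DataFrame(
            {"gene_id": ["g", "g"], "repeat_class": ["Alu", "Alu"],
             "p_score": [0.1, 0.5], "tss_distance": [100, 500], "length": [100, 300]})
        assert up.length_stats(placements).loc["Alu", "mean_length"] == 200


@given(st.lists(st.sampled_from(["Alu", "MIR", "LINE/L2", "ERV1"]),
                min_size=1, max_size=6))
@settings(max_examples=100, deadline=None)
def test_pattern_inversion_is_an_involution(labels):
    canon = up.canonical_pattern(labels)
    assert up.invert_pattern(up.invert_pattern(canon)) == canon
    if len(labels) == 1:
        assert up.invert_pattern(canon) == canon
    assert up.pattern_labels(canon) == tuple(labels)
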