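"""Cohort analytics: funnel, age trend, summaries, comparisons, overlap."""

import math

import pytest

from chtriage.cohort import (
    AGE_GROUP_LABELS,
    CH_PREFERRED,
    GERMLINE_PREFERRED,
    SOMATIC_PREFERRED,
    UNLABELED,
    CohortSummary,
    actionable_overlap,
    age_group,
    age_trend,
    age_trend_from_counts,
    carrier_ratio,
    classify_preferred,
    compare_cohorts,
    enrich_gene_sets,
    filter_carrier_ratio,
    gene_summary,
    prevalence_compare,
    tumor_crosscheck,
)
from chtriage.io import AnnotationMap
from chtriage.model import (
    Annotation,
    ClassifiedVariant,
    Label,
    Patient,
    Thresholds,
    VariantKey,
)
from chtriage.stats import Table2x2, fisher_oracle

TABLE1_CARRIERS = [179, 512, 1237, 1925, 1025, 217, 5]
TABLE1_TOTALS = [684, 1685, 3207, 4015, 1795, 332, 7]
TABLE1_PERCENTS = [26.17, 30.39, 38.57, 47.95, 57.10, 65.36, 71.43]


def ch(pid, pos, chrom="chr1"):
    return ClassifiedVariant(pid, VariantKey(chrom, pos, "A", "T"),
                             Label.CANDIDATE_CH, p_value=0.8, odds_ratio=1.0,
                             reasons=("ch_concordant",))


class TestCarrierRatio:
    def test_direct_ratio(self):
        # 400 CH-positive patients; one variant carried by exactly one
        records = [ch(f"P{i}", 100 + i) for i in range(400)]
        ratios = carrier_ratio(records)
        assert all(r == pytest.approx(1 / 400) for r in ratios.values())

    def test_ubiquitous_variant_hits_upper_bound(self):
        records = [ch(f"P{i}", 5) for i in range(10)]
        assert carrier_ratio(records)[VariantKey("chr1", 5, "A", "T")] == 1.0

    def test_boundary_is_strict_and_filter_monotone(self):
        # variant at exactly 1/400 = 0.25% is retained
        records = [ch(f"P{i}", 100 + i) for i in range(400)]
        retained, removed, retention = filter_carrier_ratio(records, Thresholds())
        assert removed == [] and len(retained) == 400 and retention == 1.0
        # lowering the threshold never grows the retained set
        tighter = Thresholds(carrier_ratio_max=0.002)
        retained2, removed2, _ = filter_carrier_ratio(records, tighter)
        assert set(r.variant for r in retained2) <= set(r.variant for r in retained)

    def test_recurrent_variant_removed_for_every_carrier(self):
        # one artifact carried by 1% of 400 CH-positive patients; the
        # private variants sit exactly at the 0.25% boundary and stay
        records = [ch(f"P{i}", 100 + i) for i in range(400)]
        records += [ch(f"P{i}", 99) for i in range(0, 4)]
        retained, removed, retention = filter_carrier_ratio(records, Thresholds())
        assert removed == [VariantKey("chr1", 99, "A", "T")]
        assert len(retained) == 400
        assert retention == pytest.approx(400 / 401)

    def test_denominator_computed_once(self):
        # a patient whose only candidate is the removed artifact still
        # counts in the denominator (the filter is not iterated)
        records = [ch(f"P{i}", 100 + i) for i in range(100)]
        records += [ch("P_only_artifact", 99)] + [ch(f"P{i}", 99) for i in range(3)]
        ratios = carrier_ratio(records)
        assert ratios[VariantKey("chr1", 99, "A", "T")] == pytest.approx(4 / 101)

    def test_funnel_arithmetic_on_printed_counts(self):
        # candidate funnel ratios as published: 5949/6023 and 16/5949
        assert round(100 * 5949 / 6023, 1) == 98.8
        assert round(100 * 16 / 5949, 2) == 0.27


class TestTumorCrosscheck:
    def test_matched_sample_scope(self):
        candidates = [ch("P1", 10), ch("P2", 10)]
        tumor = {"P1": [VariantKey("chr1", 10, "A", "T")]}
        final, removed = tumor_crosscheck(candidates, tumor)
        assert [r.patient_id for r in removed] == ["P1"]
        assert [r.patient_id for r in final] == ["P2"]

    def test_patients_without_tumor_pass_through(self):
        candidates = [ch("P3", 11)]
        final, removed = tumor_crosscheck(candidates, {})
        assert final == candidates and removed == []


class TestAgeTrend:
    @pytest.mark.parametrize("age,label", [
        (40, "<=40"), (13, "<=40"), (50, "40-50"), (41, "40-50"),
        (90, "80-90"), (96, ">90"), (91, ">90"),
    ])
    def test_age_group_bins_right_closed(self, age, label):
        assert age_group(age) == label

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            age_group(-1)

    def test_published_prevalence_table(self):
        table, r = age_trend_from_counts(TABLE1_CARRIERS, TABLE1_TOTALS)
        assert [round(p, 2) for p in table["percent"]] == TABLE1_PERCENTS
        assert round(r, 3) == 0.997

    def test_constant_percent_gives_no_correlation(self):
        _, r = age_trend_from_counts([1, 1, 1], [10, 10, 10])
        assert r is None

    def test_fewer_than_three_groups_gives_no_correlation(self):
        _, r = age_trend_from_counts([1, 2], [10, 10])
        assert r is None

    def test_patient_level_aggregation(self):
        patients = [Patient("P1", "LUAD", 35), Patient("P2", "LUAD", 45),
                    Patient("P3", "LUAD", 45), Patient("P4", "LUAD", 83)]
        calls = [ClassifiedVariant("P2", VariantKey("chr1", 1, "A", "T"), Label.CH,
                                   reasons=("ch_concordant",)),
                 ClassifiedVariant("P4", VariantKey("chr1", 2, "A", "T"), Label.CH,
                                   reasons=("ch_concordant",))]
        table, _ = age_trend(patients, calls)
        assert table.loc[table["group"] == "<=40", "carriers"].item() == 0
        assert table.loc[table["group"] == "40-50", "percent"].item() == 50.0
        assert table.loc[table["group"] == "80-90", "percent"].item() == 100.0


class TestGeneSummary:
    ANNS = AnnotationMap({
        VariantKey("chr2", 1, "A", "T"): Annotation(gene="DNMT3A"),
        VariantKey("chr2", 2, "A", "T"): Annotation(gene="DNMT3A"),
        VariantKey("chr4", 3, "A", "T"): Annotation(gene="TET2"),
    })

    def _calls(self):
        mk = lambda pid, chrom, pos: ClassifiedVariant(
            pid, VariantKey(chrom, pos, "A", "T"), Label.CH, reasons=("x",))
        return [mk("P1", "chr2", 1), mk("P1", "chr2", 2), mk("P2", "chr2", 2),
                mk("P2", "chr4", 3)]

    def test_counts_per_gene_and_variant(self):
        patients = [Patient(f"P{i}", "LUAD", 60) for i in range(1, 5)]
        s = gene_summary(self._calls(), patients, self.ANNS)
        assert s.total_samples == 4 and s.ch_positive_samples == 2
        assert s.per_gene == {"DNMT3A": (2, 2), "TET2": (1, 3)}
        assert s.per_variant[VariantKey("chr2", 2, "A", "T")] == 2

    def test_panel_restriction(self):
        patients = [Patient(f"P{i}", "LUAD", 60) for i in range(1, 5)]
        s = gene_summary(self._calls(), patients, self.ANNS, panel=["TET2"])
        assert s.per_gene == {"TET2": (1, 3)}
        assert s.ch_positive_samples == 1

    def test_empty_panel_zeroes_everything(self):
        patients = [Patient("P1", "LUAD", 60)]
        s = gene_summary(self._calls(), patients, self.ANNS, panel=[])
        assert s.per_gene == {} and s.ch_positive_samples == 0

    def test_published_gene_shares(self):
        # hot-gene carrier and site shares recomputed from printed counts
        assert round(100 * 1457 / 5100, 1) == 28.6
        assert round(100 * 574 / 5100, 1) == 11.3
        assert round(100 * 200 / 5100, 1) == 3.9
        assert round(100 * 925 / 5933, 1) == 15.6
        assert round(100 * 507 / 5933, 1) == 8.5


class TestPrevalenceCompare:
    def test_published_cohort_comparison(self):
        asym = CohortSummary(total_samples=30, ch_positive_samples=4)
        cancer = CohortSummary(total_samples=11725, ch_positive_samples=1698)
        ratio, fisher = prevalence_compare(asym, cancer)
        assert round(ratio, 3) == 0.921
        assert fisher.or_sample == pytest.approx((4 * 10027) / (26 * 1698))
        assert fisher.p_two_sided == pytest.approx(1.0, abs=1e-6)

    def test_identical_prevalence_unity(self):
        a = CohortSummary(100, 20)
        ratio, _ = prevalence_compare(a, CohortSummary(50, 10))
        assert ratio == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            prevalence_compare(CohortSummary(0, 0), CohortSummary(10, 1))


class TestClassifyPreferred:
    G = {VariantKey("chr1", i, "A", "T"): "GENE1" for i in range(1, 10)}

    def v(self, i):
        return VariantKey("chr1", i, "A", "T")

    def test_majority_share_labels_mutation(self):
        per_mut, _ = classify_preferred(
            {self.v(1): {"CH": 3, "germline": 1}}, self.G)
        assert per_mut[self.v(1)] == CH_PREFERRED

    def test_exact_half_share_unlabeled(self):
        per_mut, _ = classify_preferred(
            {self.v(1): {"CH": 1, "somatic": 1}}, self.G)
        assert per_mut[self.v(1)] == UNLABELED

    def test_non_polymorphic_variants_excluded(self):
        per_mut, per_gene = classify_preferred(
            {self.v(1): {"CH": 5}, self.v(2): {"somatic": 5}}, self.G)
        assert per_mut == {} and per_gene == {}

    def test_gene_rules(self):
        occurrences = {
            self.v(1): {"CH": 3, "somatic": 1},     # CH-preferred
            self.v(2): {"CH": 4, "germline": 1},    # CH-preferred
            self.v(3): {"CH": 1, "somatic": 4},     # somatic-preferred
        }
        _, per_gene = classify_preferred(occurrences, self.G)
        assert per_gene["GENE1"] == SOMATIC_PREFERRED

    def test_gene_ch_only_and_tie(self):
        genes = {self.v(1): "A", self.v(2): "B", self.v(3): "B", self.v(4): "B"}
        occurrences = {
            self.v(1): {"CH": 2, "somatic": 1},
            self.v(2): {"CH": 3, "germline": 1},
            self.v(3): {"CH": 1, "germline": 4},
            self.v(4): {"CH": 1, "somatic": 4},
        }
        _, per_gene = classify_preferred(occurrences, genes)
        assert per_gene["A"] == CH_PREFERRED
        assert per_gene["B"] == UNLABELED  # 1 germline- vs 1 somatic-preferred

    def test_germline_preferred_gene(self):
        genes = {self.v(1): "G", self.v(2): "G"}
        occurrences = {self.v(1): {"CH": 3, "somatic": 1},
                       self.v(2): {"CH": 1, "germline": 3}}
        _, per_gene = classify_preferred(occurrences, genes)
        assert per_gene["G"] == GERMLINE_PREFERRED


class TestCompareCohorts:
    def test_identical_proportions_null(self):
        a = CohortSummary(100, 50, per_gene={"X": (10, 90)})
        b = CohortSummary(200, 90, per_gene={"X": (20, 180)})
        df = compare_cohorts(a, b)
        row = df.iloc[0]
        assert row["odds_ratio"] == 1.0
        assert row["p"] == pytest.approx(1.0, abs=1e-9)

    def test_toy_enrichment_matches_oracle(self):
        a = CohortSummary(100, 50, per_gene={"X": (10, 90)})
        b = CohortSummary(100, 50, per_gene={"X": (1, 99)})
        df = compare_cohorts(a, b)
        row = df.iloc[0]
        assert row["odds_ratio"] == pytest.approx((10 * 99) / (90 * 1))
        assert row["p"] == pytest.approx(
            fisher_oracle(Table2x2(10, 1, 90, 99)), abs=1e-9)

    def test_default_universe_requires_ch_in_both(self):
        a = CohortSummary(10, 5, per_gene={"X": (1, 9), "Y": (2, 8), "Z": (0, 10)})
        b = CohortSummary(10, 5, per_gene={"X": (1, 9), "Z": (3, 7)})
        df = compare_cohorts(a, b)
        assert df["gene"].tolist() == ["X"]
        df_wide = compare_cohorts(a, b, genes=["X", "Y", "Z"])
        assert df_wide["gene"].tolist() == ["X", "Y", "Z"]


class TestActionableOverlap:
    ANNS = AnnotationMap({
        VariantKey("chr17", 100, "C", "A"): Annotation(gene="TP53"),
        VariantKey("chr12", 200, "G", "T"): Annotation(gene="KRAS"),
        VariantKey("chr12", 300, "G", "A"): Annotation(gene="KRAS"),
    })

    def _final(self):
        mk = lambda pid, chrom, pos, ref, alt: ClassifiedVariant(
            pid, VariantKey(chrom, pos, ref, alt), Label.CH, reasons=("x",))
        return [mk("P1", "chr17", 100, "C", "A"), mk("P2", "chr17", 100, "C", "A"),
                mk("P2", "chr12", 200, "G", "T"), mk("P3", "chr12", 300, "G", "A")]

    def test_exact_position_and_alt_match(self):
        kb = {VariantKey("chr17", 100, "C", "A"): "therapy marker",
              # same position, different alt allele: never a hit
              VariantKey("chr12", 300, "G", "T"): "other"}
        hits, per_gene, summary = actionable_overlap(self._final(), kb, self.ANNS)
        assert [h.variant.pos for h in hits] == [100]
        assert hits[0].patient_ids == ("P1", "P2")
        assert summary["n_hit_variants"] == 1
        assert summary["n_hit_patients"] == 2
        assert summary["pct_hit_patients"] == pytest.approx(100 * 2 / 3)

    def test_published_interference_shares(self):
        assert round(100 * 48 / 5933, 2) == 0.81
        assert round(100 * 92 / 5100, 1) == 1.8
        assert round(100 * 30 / 92, 1) == 32.6

    def test_per_gene_share_of_hit_patients(self):
        kb = {VariantKey("chr17", 100, "C", "A"): "a",
              VariantKey("chr12", 200, "G", "T"): "b"}
        _, per_gene, _ = actionable_overlap(self._final(), kb, self.ANNS)
        tp53 = per_gene[per_gene["gene"] == "TP53"].iloc[0]
        assert tp53["pct_of_hit_patients"] == pytest.approx(100.0)


class TestEnrichGeneSets:
    def test_hand_counted_overlaps(self):
        genes = ["A", "B", "C", "D", "E"]
        background = genes + ["F", "G", "H", "I", "J"]
        sets = {"S1": {"A", "B", "F"}, "S2": {"J"}}
        df = enrich_gene_sets(genes, background, sets).set_index("set")
        assert tuple(df.loc["S1", ["a", "b", "c", "d"]]) == (2, 3, 1, 4)
        assert tuple(df.loc["S2", ["a", "b", "c", "d"]]) == (0, 5, 1, 4)

    def test_saturated_degenerate_set(self):
        genes = ["A", "B"]
        df = enrich_gene_sets(genes, genes, {"S": {"A", "B"}})
        assert df["p"].iloc[0] == 1.0
        assert math.isfinite(df["odds_ratio"].iloc[0])

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            enrich_gene_sets(["A", "Z"], ["A", "B"], {"S": {"A"}})

    def test_set_order_invariance(self):
        genes = ["A", "B"]
        bg = ["A", "B", "C", "D"]
        sets = {"S1": {"A"}, "S2": {"C", "D"}, "S3": {"B", "C"}}
        df1 = enrich_gene_sets(genes, bg, sets).set_index("set")["q"]
        reordered = dict(reversed(list(sets.items())))
        df2 = enrich_gene_sets(genes, bg, reordered).set_index("set")["q"]
        assert df1.sort_index().equals(df2.sort_index())
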