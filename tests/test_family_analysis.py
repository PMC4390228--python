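"""Region grouping, transmission counting, 50:50 bias test, variability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnphase.family_analysis import (
    LENGTH_BINS,
    TransmissionRecord,
    TransmissionTable,
    allelic_variability,
    assign_group,
    de_novo_reports,
    length_bin,
    multiple_testing_adjust,
    summarize_dataset,
    tally_transmissions,
    transmission_bias_test,
    transmission_records,
)
from cnphase.model import Family
from cnphase.phase_engine import phase_region

A, B, AB, AA, BB = (1, 0), (0, 1), (1, 1), (2, 0), (0, 2)


class TestGrouping:
    def test_partition_into_groups(self, region_builder):
        one = region_builder({"FA": 1, "MO": 2, "CH": 2},
                             {"FA": (A,), "MO": (AA,), "CH": (AA,)},
                             {"father"}, {"FA"})
        both = region_builder({"FA": 1, "MO": 1, "CH": 2},
                              {"FA": (A,), "MO": (A,), "CH": (AA,)},
                              {"father", "mother"}, {"FA", "MO"})
        child_only = region_builder({"FA": 2, "MO": 2, "CH": 1},
                                    {"FA": (AA,), "MO": (AA,), "CH": (A,)},
                                    set(), {"CH"})
        assert assign_group(one) == "A"
        assert assign_group(both) == "B"
        assert assign_group(child_only) == "C"

    def test_no_carrier_is_an_error(self, region_builder):
        region = region_builder({"FA": 2, "MO": 2, "CH": 2},
                                {"FA": (AA,), "MO": (AA,), "CH": (AA,)},
                                set(), set())
        with pytest.raises(ValueError):
            assign_group(region)


class TestLengthBins:
    @pytest.mark.parametrize(
        "length,label",
        [
            (1, "<10kb"),
            (9_999, "<10kb"),
            (10_000, "10-30kb"),   # lower edge inclusive
            (29_999, "10-30kb"),
            (30_000, "30-100kb"),
            (100_000, ">100kb"),
            (5_000_000, ">100kb"),
        ],
    )
    def test_half_open_bins(self, length, label):
        assert length_bin(length) == label


class TestTransmissionCounting:
    def _quintet_region(self, region_builder):
        """Father carries a duplication haplotype transmitted to 2 of 5
        children; the others received his normal haplotype."""
        dup_child = ((1, 2), (2, 1))   # dup hap (B,A)x2? see genotypes below
        fam = Family("Q", "FA", "MO", tuple(f"C{i}" for i in range(1, 6)))
        # father (1,2): normal hap (A,A), dup hap (BB, AA); mother (A,B),(A,B)
        genotypes = {
            "FA": ((1, 2), (3, 0)),
            "MO": ((2, 0), (0, 2)),
            "C1": ((1, 2), (2, 1)),   # dup + maternal
            "C2": ((1, 2), (2, 1)),
            "C3": ((2, 0), (1, 1)),   # normal + maternal
            "C4": ((2, 0), (1, 1)),
            "C5": ((2, 0), (1, 1)),
        }
        region = region_builder(
            {"FA": 3, "MO": 2, "C1": 3, "C2": 3, "C3": 2, "C4": 2, "C5": 2},
            genotypes, {"father"}, {"FA", "C1", "C2"},
            start=100, end=15_099,  # 15 kb: second bin
        )
        return region, fam

    def test_quintet_counts(self, region_builder):
        region, fam = self._quintet_region(region_builder)
        result = phase_region(region, fam)
        assert result.unambiguous
        records = transmission_records(region, fam, result)
        assert len(records) == 5
        assert sum(r.transmitted_cnv for r in records) == 2
        assert all(r.cnv_type == "duplication" for r in records)
        table = tally_transmissions([(region, fam, result)])
        assert table.counts("duplication", "10-30kb") == (2, 5)
        assert table.counts() == (2, 5)

    def test_ambiguous_or_non_group_a_rejected(self, denovo_deletion_trio):
        region, fam = denovo_deletion_trio
        result = phase_region(region, fam)
        with pytest.raises(ValueError):
            transmission_records(region, fam, result)

    def test_table_margins_consistent(self):
        rng = np.random.default_rng(42)
        records = [
            TransmissionRecord(
                f"r{i}", "c", "father",
                bool(rng.integers(2)),
                "deletion" if rng.random() < 0.7 else "duplication",
                int(rng.integers(1_000, 500_000)),
            )
            for i in range(200)
        ]
        table = TransmissionTable(records)
        for t in ("deletion", "duplication", None):
            per_bin = [table.counts(t, lab) for lab, _, _ in LENGTH_BINS]
            total = table.counts(t)
            assert sum(c for c, _ in per_bin) == total[0]
            assert sum(n for _, n in per_bin) == total[1]
        for lab, _, _ in LENGTH_BINS:
            dele, dup, comb = (
                table.counts("deletion", lab),
                table.counts("duplication", lab),
                table.counts(None, lab),
            )
            assert dele[0] + dup[0] == comb[0] and dele[1] + dup[1] == comb[1]


class TestBiasTest:
    @pytest.mark.parametrize(
        "n_cnv,n_normal,p_expected",
        [(580, 671, 0.011), (70, 98, 0.037)],
    )
    def test_reproduces_published_group_a_pvalues(self, n_cnv, n_normal, p_expected):
        _, p = transmission_bias_test(n_cnv, n_normal)
        assert abs(p - p_expected) < 5e-4

    def test_uncorrected_variant(self):
        _, p = transmission_bias_test(580, 671, corrected=False)
        assert abs(p - 0.0101) < 5e-4

    def test_perfect_split_gives_p_one(self):
        stat, p = transmission_bias_test(50, 50)
        assert stat == 0.0 and p == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            transmission_bias_test(0, 0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=st.integers(0, 500), b=st.integers(0, 500))
    def test_symmetry_and_range(self, a, b):
        if a + b == 0:
            return
        _, p1 = transmission_bias_test(a, b)
        _, p2 = transmission_bias_test(b, a)
        assert p1 == p2 and 0.0 < p1 <= 1.0


class TestMultipleTesting:
    def test_bonferroni_arithmetic(self):
        ps = [0.004] + [0.5] * 9
        adjusted, sig = multiple_testing_adjust(ps)
        assert adjusted[0] == pytest.approx(0.04) and sig[0]
        ps = [0.02] + [0.5] * 9
        adjusted, sig = multiple_testing_adjust(ps)
        assert adjusted[0] == pytest.approx(0.2) and not sig[0]

    def test_capped_at_one(self):
        adjusted, _ = multiple_testing_adjust([0.5, 0.6, 0.7])
        assert all(p <= 1.0 for p in adjusted)

    @pytest.mark.parametrize("method", ["holm", "bh"])
    def test_alternative_methods_available(self, method):
        adjusted, _ = multiple_testing_adjust([0.01, 0.02, 0.5], method=method)
        assert len(adjusted) == 3

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            multiple_testing_adjust([0.5], method="fisher")


class TestAllelicVariability:
    def test_within_haplotype_heterozygosity(self, duplication_family):
        region, fam = duplication_family
        sol = phase_region(region, fam).solutions[0]
        (report,) = allelic_variability(sol, region.region_id)
        assert report.parent == "mother" and report.hap_cn == 2
        assert report.has_within_informative
        assert report.has_between_informative

    def test_between_only_dosage_polymorphism(self, region_builder):
        # gain hap (A,A) vs other hap (B): distinguishable between, but no
        # heterozygous copy within the gain haplotype
        region = region_builder(
            {"FA": 3, "MO": 2, "CH": 2},
            {"FA": ((2, 1), (3, 0)), "MO": ((2, 0), (2, 0)), "CH": ((1, 1), (2, 0))},
            {"father"}, {"FA"},
        )
        fam = Family("FAM", "FA", "MO", ("CH",))
        result = phase_region(region, fam)
        assert result.unambiguous
        (rep,) = allelic_variability(result.solutions[0], region.region_id)
        assert rep.has_between_informative
        assert not rep.has_within_informative

    def test_monomorphic_region_uninformative(self, region_builder):
        region = region_builder(
            {"FA": 3, "MO": 2, "CH": 2},
            {"FA": (), "MO": (), "CH": ()},
            {"father"}, {"FA"},
        )
        region.marker_ids = ()
        region.marker_pos = ()
        fam = Family("FAM", "FA", "MO", ("CH",))
        sol = phase_region(region, fam).solutions[0]
        for rep in allelic_variability(sol, region.region_id):
            assert not rep.has_between_informative
            assert not rep.has_within_informative


class TestSummary:
    def test_fully_unambiguous_dataset(self, duplication_family, denovo_duplication_trio):
        entries = []
        for region, fam in (duplication_family, denovo_duplication_trio):
            entries.append((region, fam, phase_region(region, fam)))
        summary = summarize_dataset(entries)
        assert summary["all_regions"]["pct_unambiguous"] == 100.0
        assert summary["groups"]["A"]["n_regions"] == 2

    def test_ambiguous_fixture_counted(self, denovo_deletion_trio):
        region, fam = denovo_deletion_trio
        summary = summarize_dataset([(region, fam, phase_region(region, fam))])
        assert summary["groups"]["C"]["n_unambiguous"] == 0
        (rep,) = summary["de_novo"]
        assert rep["parent_of_origin"] == "undetermined"
        assert rep["event"] == "denovo_deletion"

    def test_denovo_report_determined_origin(self, denovo_duplication_trio):
        region, fam = denovo_duplication_trio
        (rep,) = de_novo_reports(region, fam, phase_region(region, fam))
        assert rep.parent_of_origin == "father" and rep.dup_class == "intra"
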