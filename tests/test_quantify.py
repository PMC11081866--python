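import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from bequant.pipeline import align_reads
from bequant.quantify import (AlleleTable, EmptyInputError, build_adenine_index,
                              build_allele_table, desired_only_rate,
                              filter_alleles_for_report, indel_rate,
                              per_adenine_rates, summarize)
from bequant.seqio import Protospacer, make_spec, parse_fastq
from bequant.simulate import (AlleleDef, TruthManifest, expected_outcome_rates,
                              simulate_reads, spiked_truth)


def _quantified(spec, truth, tmp_path, sub="sim"):
    res = simulate_reads(spec, truth, tmp_path / sub)
    alignments = align_reads(parse_fastq(res.fastq1), spec.reference)
    table = build_allele_table(alignments, spec, "s")
    return res, alignments, table


class TestAdenineIndex:
    def test_demo_locus_labels(self, spec, index):
        assert list(index.items()) == [
            ("A_1", 100), ("A_2", 103), ("A_3", 107), ("A_4", 115)
        ]
        assert index.label_of(spec.target_adenine) == "A_2"

    def test_reverse_strand_locus_mirrors_labels(self, spec, index, mirrored_spec):
        mirrored = build_adenine_index(mirrored_spec)
        n = len(spec.reference)
        assert mirrored.labels == index.labels
        assert mirrored.offsets == tuple(n - 1 - o for o in index.offsets)

    def test_two_offset_protospacers_span_the_union(self, spec):
        first = spec.protospacers[0]
        second = Protospacer(
            spec.reference[first.start - 2:first.end - 2],
            first.start - 2, "+", "", "sg2",
        )
        spec2 = make_spec(
            "two_guides", spec.reference, [first, second], spec.target_adenine
        )
        idx = build_adenine_index(spec2)
        lo, hi = spec2.combined_protospacer_interval
        assert (lo, hi) == (first.start - 2, first.end)
        expected = [
            o for o in range(lo, hi) if spec.reference[o] == "A"
        ]
        assert list(idx.offsets) == expected

    def test_adenine_free_protospacer_warns_and_is_empty(self, spec):
        # an A-free reference stretch with the target adenine outside the
        # protospacer but inside a widened quant window
        ref = "CCG" * 20 + "ATT" + "CCG" * 10
        proto = Protospacer(ref[3:23], 3, "+", "", "sg")
        bare = make_spec(
            "bare", ref, [proto], target_adenine=60,
            quant_window=(3, 61), indel_window=(3, 61), nick_offset=20,
        )
        with pytest.warns(UserWarning, match="no adenine"):
            idx = build_adenine_index(bare)
        assert idx.offsets == ()


class TestAlleleTable:
    def test_reference_only_reads_give_single_allele(self, spec, tmp_path):
        truth = TruthManifest(
            alleles=(AlleleDef("wt", (), None, 1.0),), n_reads=50
        )
        _, _, table = _quantified(spec, truth, tmp_path)
        assert len(table) == 1
        assert table.rows.loc[0, "frequency"] == 1.0
        assert table.rows.loc[0, "substitutions"] == ()

    def test_error_free_mixture_recovers_label_counts_exactly(self, spec, tmp_path):
        truth = TruthManifest(
            alleles=(
                AlleleDef("desired", ((spec.target_adenine, "G"),), None, 0.45),
                AlleleDef("wt", (), None, 0.55),
            ),
            n_reads=5000, error_rate=0.0, seed=13,
        )
        res, _, table = _quantified(spec, truth, tmp_path)
        counts = res.label_counts()
        by_subs = {row.substitutions: row.count for row in table.rows.itertuples()}
        assert by_subs[((spec.target_adenine, "G"),)] == counts["desired"]
        assert by_subs[()] == counts["wt"]

    def test_frequencies_sum_to_one(self, spec, tmp_path):
        truth = spiked_truth(spec, error_rate=0.01, n=2000, seed=5)
        _, _, table = _quantified(spec, truth, tmp_path)
        assert table.rows["frequency"].sum() == pytest.approx(1.0, abs=1e-9)
        assert table.rows["count"].sum() == table.n_aligned

    def test_empty_input_names_the_sample(self, spec):
        with pytest.raises(EmptyInputError, match="s77"):
            build_allele_table([], spec, "s77")


class TestDesiredOnlyRate:
    def test_all_reference_gives_zero(self, spec, tmp_path):
        truth = TruthManifest(
            alleles=(AlleleDef("wt", (), None, 1.0),), n_reads=50
        )
        _, _, table = _quantified(spec, truth, tmp_path)
        assert desired_only_rate(table, spec) == 0.0

    def test_single_target_allele_rate_matches_labels(self, spec, tmp_path):
        truth = TruthManifest(
            alleles=(
                AlleleDef("desired", ((spec.target_adenine, "G"),), None, 0.30),
                AlleleDef("wt", (), None, 0.70),
            ),
            n_reads=4000, error_rate=0.0, seed=2,
        )
        res, _, table = _quantified(spec, truth, tmp_path)
        expected = res.label_counts()["desired"] / 4000
        assert desired_only_rate(table, spec) == expected

    def test_study_mixture_exact_by_manifest_oracle(self, spec, tmp_path):
        truth = spiked_truth(
            spec, on_target=0.459, bystander=0.048, indel=0.001,
            error_rate=0.0, n=20_000, seed=0,
        )
        res, alignments, table = _quantified(spec, truth, tmp_path)
        counts = res.label_counts()
        n = truth.n_reads
        summary = summarize(table, spec)
        assert desired_only_rate(table, spec) == counts["desired"] / n
        assert summary.desired_only_rate == counts["desired"] / n
        assert summary.nonsynonymous_bystander_rate == counts["bystander"] / n
        assert summary.indel_rate == counts["indel"] / n
        assert indel_rate(alignments, spec) == counts["indel"] / n


class TestPerAdenineRates:
    def test_all_reference_gives_zeros(self, spec, index, tmp_path):
        truth = TruthManifest(
            alleles=(AlleleDef("wt", (), None, 1.0),), n_reads=30
        )
        _, _, table = _quantified(spec, truth, tmp_path)
        assert set(per_adenine_rates(table, index, spec).values()) == {0.0}

    def test_double_edit_allele_counts_at_both_positions(self, spec, index, tmp_path):
        allele = AlleleDef("dbl", ((100, "G"), (107, "G")), None, 0.05)
        truth = TruthManifest(
            alleles=(allele, AlleleDef("wt", (), None, 0.95)),
            n_reads=4000, error_rate=0.0, seed=8,
        )
        res, _, table = _quantified(spec, truth, tmp_path)
        rates = per_adenine_rates(table, index, spec)
        expected = res.label_counts()["dbl"] / 4000
        assert rates["A_1"] == expected
        assert rates["A_3"] == expected
        assert rates["A_2"] == rates["A_4"] == 0.0

    def test_matches_per_read_count_oracle_with_errors(self, spec, index, tmp_path):
        truth = spiked_truth(
            spec, on_target=0.3, bystander=0.1, indel=0.0,
            error_rate=0.005, n=3000, seed=31,
        )
        res, _, table = _quantified(spec, truth, tmp_path)
        rates = per_adenine_rates(table, index, spec)
        reads = [r.bases for r in parse_fastq(res.fastq1)]
        for label, offset in index.items():
            oracle = sum(b[offset] == "G" for b in reads) / len(reads)
            assert rates[label] == pytest.approx(oracle, abs=1e-12), label

    def test_desired_only_never_exceeds_target_adenine_rate(self, spec, index, tmp_path):
        for seed in range(3):
            truth = spiked_truth(spec, error_rate=0.01, n=1500, seed=seed)
            _, _, table = _quantified(spec, truth, tmp_path, sub=f"s{seed}")
            rates = per_adenine_rates(table, index, spec)
            target_label = index.label_of(spec.target_adenine)
            assert desired_only_rate(table, spec) <= rates[target_label]


class TestIndelRate:
    def test_no_indel_simulation_gives_zero(self, spec, tmp_path):
        truth = spiked_truth(spec, indel=0.0, error_rate=0.0, n=500, seed=1)
        _, alignments, _ = _quantified(spec, truth, tmp_path)
        assert indel_rate(alignments, spec) == 0.0

    def test_nick_site_deletion_counted_exactly(self, spec, tmp_path):
        truth = spiked_truth(
            spec, on_target=0.0, bystander=0.0, indel=0.001,
            error_rate=0.0, n=20_000, seed=4,
        )
        res, alignments, _ = _quantified(spec, truth, tmp_path)
        assert indel_rate(alignments, spec) == res.label_counts()["indel"] / 20_000

    def test_deletion_outside_window_not_counted(self, spec, tmp_path):
        truth = TruthManifest(
            alleles=(
                AlleleDef("far_del", (), (10, 1, "del"), 0.2),
                AlleleDef("wt", (), None, 0.8),
            ),
            n_reads=500, error_rate=0.0, seed=6,
        )
        _, alignments, _ = _quantified(spec, truth, tmp_path)
        assert indel_rate(alignments, spec) == 0.0


class TestReportFilter:
    def _table(self):
        rows = pd.DataFrame(
            {
                "allele": ["wt", "rare", "edge"],
                "count": [9961, 19, 20],
                "frequency": [0.9961, 0.0019, 0.0020],
                "substitutions": [(), ((100, "G"),), ((103, "G"),)],
                "has_indel_in_window": [False, False, False],
            }
        )
        return AlleleTable(rows=rows, n_aligned=10_000)

    def test_display_threshold_is_inclusive(self):
        kept = filter_alleles_for_report(self._table(), min_freq=0.002)
        assert set(kept.rows["allele"]) == {"wt", "edge"}
        assert kept.n_aligned == 10_000  # summary denominator untouched

    def test_zero_threshold_is_identity(self):
        table = self._table()
        kept = filter_alleles_for_report(table, min_freq=0.0)
        pd.testing.assert_frame_equal(kept.rows, table.rows)

    def test_empty_table_stays_empty(self):
        table = self._table()
        empty = AlleleTable(rows=table.rows.iloc[0:0], n_aligned=10_000)
        assert len(filter_alleles_for_report(empty)) == 0


class TestSummaryProperties:
    def test_outcome_classes_partition_aligned_reads(self, spec, tmp_path):
        truth = spiked_truth(spec, error_rate=0.005, n=4000, seed=19)
        _, _, table = _quantified(spec, truth, tmp_path)
        summary = summarize(table, spec)
        assert sum(summary.class_counts.values()) == table.n_aligned
        known = {"wildtype", "on_target_only", "synonymous_bystander",
                 "nonsynonymous_bystander", "indel", "other"}
        assert set(summary.class_counts) <= known

    def test_noisy_recovery_within_four_binomial_se(self, spec, tmp_path):
        n = 3000
        for seed in range(4):
            truth = spiked_truth(spec, error_rate=0.005, n=n, seed=seed)
            _, _, table = _quantified(spec, truth, tmp_path, sub=f"r{seed}")
            summary = summarize(table, spec)
            expected = expected_outcome_rates(spec, truth)
            for key, got in (
                ("desired_only", summary.desired_only_rate),
                ("nonsynonymous_bystander", summary.nonsynonymous_bystander_rate),
                ("indel", summary.indel_rate),
            ):
                p = expected[key]
                se = math.sqrt(p * (1 - p) / n)
                assert abs(got - p) <= 4 * se + 1e-12, (seed, key)

    def test_indel_reads_excluded_from_substitution_classes(self, spec, tmp_path):
        # an allele carrying the desired edit AND a nick-site deletion is
        # counted once, as an indel read
        truth = TruthManifest(
            alleles=(
                AlleleDef(
                    "edit_plus_del",
                    ((spec.target_adenine, "G"),),
                    (spec.nick_offset, 1, "del"),
                    0.5,
                ),
                AlleleDef("wt", (), None, 0.5),
            ),
            n_reads=400, error_rate=0.0, seed=12,
        )
        res, _, table = _quantified(spec, truth, tmp_path)
        summary = summarize(table, spec)
        assert summary.indel_rate == res.label_counts()["edit_plus_del"] / 400
        assert summary.desired_only_rate == 0.0

    def test_denominator_switch_rescales_substitution_classes(self, spec, tmp_path):
        truth = spiked_truth(
            spec, on_target=0.4, bystander=0.0, indel=0.2,
            error_rate=0.0, n=1000, seed=3,
        )
        _, _, table = _quantified(spec, truth, tmp_path)
        full = summarize(table, spec)
        reduced = summarize(table, spec, exclude_indels_from_denominator=True)
        n_indel = full.class_counts["indel"]
        scale = table.n_aligned / (table.n_aligned - n_indel)
        assert reduced.desired_only_rate == pytest.approx(
            full.desired_only_rate * scale
        )
        assert reduced.indel_rate == full.indel_rate
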