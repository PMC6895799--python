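"""Flank-keyed locus aggregation, report files, candidate ranking."""

import random

import pytest

from polyssr import (
    LocusKey,
    aggregate_sequences,
    build_locus_key,
    find_ssrs,
    rank_candidates,
    read_report,
    write_reports,
)


def make_seq(left, motif, reps, right):
    return left + motif * reps + right


LEFT10 = "CCGTACGGTC"
RIGHT10 = "TGCAACGGTT"


def hit_for(seq, seq_id="t"):
    hits = find_ssrs(seq, seq_id)
    assert len(hits) == 1
    return hits[0]


class TestBuildLocusKey:
    def test_key_is_flanks_plus_motif(self):
        seq = make_seq(LEFT10, "AT", 7, RIGHT10)
        key = build_locus_key(hit_for(seq), seq, k=10)
        assert key == LocusKey(LEFT10, "AT", RIGHT10)
        assert key.string_form == LEFT10 + "AT" + RIGHT10
        assert len(key.string_form) == 2 * 10 + 2

    def test_insufficient_left_flank_skipped(self):
        seq = "GTAC" + "AT" * 7 + RIGHT10
        assert build_locus_key(hit_for(seq), seq, k=10) is None

    def test_n_in_flank_skipped(self):
        seq = make_seq("CCGTACGGNC", "AT", 7, RIGHT10)
        assert build_locus_key(hit_for(seq), seq, k=10) is None

    def test_identical_flanks_give_identical_keys_across_samples(self):
        s1 = make_seq(LEFT10, "AT", 7, RIGHT10)
        s2 = make_seq(LEFT10, "AT", 9, RIGHT10)
        k1 = build_locus_key(hit_for(s1, "a"), s1, k=10)
        k2 = build_locus_key(hit_for(s2, "b"), s2, k=10)
        assert k1 == k2

    def test_invalid_k(self):
        seq = make_seq(LEFT10, "AT", 7, RIGHT10)
        with pytest.raises(ValueError, match="k must be >= 1"):
            build_locus_key(hit_for(seq), seq, k=0)


class TestAggregate:
    def sequences(self, repeats):
        return [
            (f"s{i}", make_seq(LEFT10, "AT", r, RIGHT10))
            for i, r in enumerate(repeats)
        ]

    def test_variable_repeats_flag_polymorphic(self):
        records = aggregate_sequences(self.sequences([7, 7, 9, 9, 8]), k=10)
        assert len(records) == 1
        rec = next(iter(records.values()))
        assert rec.n_obs == 5
        assert rec.distinct_repeats == {7, 8, 9}
        assert rec.polymorphic

    def test_constant_repeats_not_polymorphic(self):
        records = aggregate_sequences(self.sequences([6, 6, 6]), k=10)
        rec = next(iter(records.values()))
        assert rec.repeats == [6, 6, 6] and not rec.polymorphic

    def test_same_flanks_different_motif_distinct_records(self):
        seqs = [
            ("a", make_seq(LEFT10, "AT", 7, RIGHT10)),
            ("b", make_seq(LEFT10, "AAT", 6, RIGHT10)),
        ]
        records = aggregate_sequences(seqs, k=10)
        assert len(records) == 2

    def test_conservation_of_observations(self, planted_set):
        merged = planted_set.merged()
        n_keyed = 0
        for seq_id, seq in merged:
            for h in find_ssrs(seq, seq_id):
                if build_locus_key(h, seq, k=10) is not None:
                    n_keyed += 1
        records = aggregate_sequences(merged, k=10)
        assert sum(r.n_obs for r in records.values()) == n_keyed

    def test_order_invariance(self, planted_set):
        merged = planted_set.merged()
        shuffled = merged[:]
        random.Random(7).shuffle(shuffled)
        a = aggregate_sequences(merged, k=10)
        b = aggregate_sequences(shuffled, k=10)
        assert a.keys() == b.keys()
        for key in a:
            assert a[key].observations == b[key].observations

    def test_min_obs_filter(self):
        seqs = self.sequences([7, 9]) + [
            ("x", make_seq("ATCGGCTAAC", "AG", 8, "TTCGAGCATC"))
        ]
        assert len(aggregate_sequences(seqs, k=10)) == 2
        filtered = aggregate_sequences(seqs, k=10, min_obs=2)
        assert len(filtered) == 1

    def test_flank_mutation_splits_locus(self):
        # a single substitution in one sample's flank breaks key identity
        mutated = "A" + LEFT10[1:]
        assert mutated != LEFT10
        seqs = [
            ("a", make_seq(LEFT10, "AT", 7, RIGHT10)),
            ("b", make_seq(mutated, "AT", 9, RIGHT10)),
        ]
        records = aggregate_sequences(seqs, k=10)
        assert len(records) == 2
        assert not any(r.polymorphic for r in records.values())

    def test_merge_revcomp_option(self):
        from polyssr import revcomp
        fwd = make_seq(LEFT10, "AT", 7, RIGHT10)
        rev = revcomp(make_seq(LEFT10, "AT", 9, RIGHT10))
        seqs = [("a", fwd), ("b", rev)]
        assert len(aggregate_sequences(seqs, k=10)) == 2
        merged = aggregate_sequences(seqs, k=10, merge_revcomp=True)
        assert len(merged) == 1
        assert next(iter(merged.values())).distinct_repeats == {7, 9}


class TestReports:
    def records(self):
        seqs = [
            ("a", make_seq(LEFT10, "AT", 7, RIGHT10)),
            ("b", make_seq(LEFT10, "AT", 9, RIGHT10)),
            ("c", make_seq("ATCGGCTAAC", "AG", 8, "TTCGAGCATC")),
            ("d", make_seq("TTCGAGCATC", "AAG", 6, "ATCGGCTAAC")),
        ]
        return aggregate_sequences(seqs, k=10)

    def test_detail_holds_all_result_holds_polymorphic(self, tmp_path):
        records = self.records()
        detail, result = tmp_path / "detail.tsv", tmp_path / "result.tsv"
        write_reports(records, detail, result)
        assert len(read_report(detail)) == 3
        rows = read_report(result)
        assert len(rows) == 1
        assert rows[0].n_obs == 2 and sorted(rows[0].repeats) == [7, 9]

    def test_row_schema(self, tmp_path):
        seqs = [
            (f"s{i}", make_seq(LEFT10, "AT", r, RIGHT10))
            for i, r in enumerate([7, 7, 9, 9, 8])
        ]
        records = aggregate_sequences(seqs, k=10)
        detail = tmp_path / "d.tsv"
        write_reports(records, detail, tmp_path / "r.tsv")
        line = detail.read_text().strip()
        key_s, n, reps = line.split("\t")
        assert key_s == LEFT10 + "AT" + RIGHT10
        assert n == "5" and reps == "7,7,9,9,8"

    def test_round_trip_is_lossless(self, tmp_path):
        records = self.records()
        detail, result = tmp_path / "d.tsv", tmp_path / "r.tsv"
        write_reports(records, detail, result)
        for path in (detail, result):
            first = path.read_text()
            rows = read_report(path)
            rewritten = "".join(
                f"{r.key_string}\t{r.n_obs}\t"
                + ",".join(map(str, r.repeats)) + "\n"
                for r in rows
            )
            assert rewritten == first

    def test_header_flag_round_trip(self, tmp_path):
        records = self.records()
        detail = tmp_path / "d.tsv"
        write_reports(records, detail, tmp_path / "r.tsv", header=True)
        assert detail.read_text().startswith("key\tn_obs\trepeats\n")
        assert len(read_report(detail, header=True)) == 3

    def test_malformed_row_names_line(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("ACGT\t2\t7,9\nACGT\tnot-three-columns\n")
        with pytest.raises(ValueError, match="2"):
            read_report(bad)


class TestRankCandidates:
    def test_ordering_by_distinct_repeat_counts(self):
        right = "CGATCGGCTA"
        seqs = []
        for flank, repeats in [
            ("AAACCCGGGC", [7, 8, 9, 6]),     # 4 distinct
            ("CCCAAATTTG", [7, 8]),           # 2 distinct
            ("GGGTTTAAAC", [7, 8, 9]),        # 3 distinct
        ]:
            for i, r in enumerate(repeats):
                seqs.append((f"{flank}_{i}", flank + "AT" * r + right))
        records = aggregate_sequences(seqs, k=10)
        ranked = rank_candidates(records)
        assert [len(r.distinct_repeats) for r in ranked] == [4, 3, 2]

    def test_tie_broken_by_n_obs_then_key(self):
        seqs = [
            ("a1", "AAACCCGGGC" + "AT" * 7 + "CGGGCCCAAA"),
            ("a2", "AAACCCGGGC" + "AT" * 9 + "CGGGCCCAAA"),
            ("b1", "CCCAAATTTG" + "AT" * 7 + "CGGGCCCAAA"),
            ("b2", "CCCAAATTTG" + "AT" * 9 + "CGGGCCCAAA"),
            ("b3", "CCCAAATTTG" + "AT" * 9 + "CGGGCCCAAA"),
        ]
        ranked = rank_candidates(aggregate_sequences(seqs, k=10))
        assert [r.n_obs for r in ranked] == [3, 2]
        # equal distinct count and equal n_obs: key string ascending
        seqs2 = [
            ("a1", "AAACCCGGGC" + "AT" * 7 + "CGGGCCCAAA"),
            ("a2", "AAACCCGGGC" + "AT" * 9 + "CGGGCCCAAA"),
            ("b1", "CCCAAATTTG" + "AT" * 7 + "CGGGCCCAAA"),
            ("b2", "CCCAAATTTG" + "AT" * 9 + "CGGGCCCAAA"),
        ]
        ranked2 = rank_candidates(aggregate_sequences(seqs2, k=10))
        assert [r.key.string_form for r in ranked2] == sorted(
            r.key.string_form for r in ranked2
        )

    def test_empty(self):
        assert rank_candidates({}) == []
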