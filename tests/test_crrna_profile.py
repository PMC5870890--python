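"""Repeat-anchored qualification, reference counting, and the 3'-end profile."""

import numpy as np
import pytest

from crrnaseq.crrna_profile import (
    build_profile,
    build_reference_index,
    check_fidelity,
    check_junction,
    find_repeat_start,
    is_reference_read,
    profile_reads,
    profile_table,
    qualify_read,
    render_profile,
    select_files_by_keyword,
)
from crrnaseq.formats_io import PipelineParams, SpacerEndSet

ENDS = SpacerEndSet(frozenset({"ACGTA", "TTGCA"}))


class TestFindRepeatStart:
    def test_leftmost_exact_seed_occurrence(self, repeat):
        assert find_repeat_start("AAACGTA" + repeat[:8], repeat) == 7

    def test_absent_seed(self, repeat):
        assert find_repeat_start("CCCCCCCCCC", repeat) is None

    def test_first_of_two_occurrences(self, repeat):
        seed = repeat[:5]
        assert find_repeat_start("AA" + seed + "TT" + seed, repeat) == 2

    def test_n_never_matches(self, repeat):
        insert = "AA" + repeat[:4] + "N" + "TT"
        assert find_repeat_start(insert, repeat) is None


class TestCheckJunction:
    def test_suffix_membership(self):
        assert check_junction("CCACGTA", ENDS) is True

    def test_non_member_suffix(self):
        assert check_junction("CCCCC", ENDS) is False

    def test_short_upstream(self):
        assert check_junction("CGTA", ENDS) is False


class TestCheckFidelity:
    def test_prefix_passes(self, repeat):
        assert check_fidelity(repeat[:12], repeat)

    def test_internal_substitution_fails(self, repeat):
        mutated = repeat[:6] + ("A" if repeat[6] != "A" else "C") + repeat[7:12]
        assert not check_fidelity(mutated, repeat)

    def test_read_through_past_repeat_fails(self, repeat):
        assert not check_fidelity(repeat + "A", repeat)


class TestQualifyRead:
    def test_repeat_length_route(self, repeat):
        m = qualify_read("CCCCC" + repeat[:12], repeat, ENDS)
        assert m.route == "repeat_length" and m.length == 12

    def test_junction_route_at_minimum(self, repeat):
        m = qualify_read("ACGTA" + repeat[:5], repeat, ENDS)
        assert m.route == "junction" and m.length == 5
        assert m.upstream == "ACGTA"

    def test_short_repeat_without_junction_rejected(self, repeat):
        m = qualify_read("CCCCC" + repeat[:11], repeat, ENDS)
        assert m.route == "rejected" and m.reject_reason == "too_short_no_junction"

    def test_rule_order_junction_rescues_eleven_base_repeat(self, repeat):
        # length 11 < 12 triggers the junction check, which passes
        m = qualify_read("ACGTA" + repeat[:11], repeat, ENDS)
        assert m.route == "junction" and m.length == 11

    def test_short_upstream_cannot_take_junction_route(self, repeat):
        m = qualify_read("GTA" + repeat[:8], repeat, ENDS)
        assert m.route == "rejected" and m.reject_reason == "upstream_too_short"

    def test_no_seed_rejected(self, repeat):
        m = qualify_read("CCCCCCCCCCCC", repeat, ENDS)
        assert m.reject_reason == "no_seed"

    def test_fidelity_failure_rejected(self, repeat):
        bad = repeat[:10] + ("A" if repeat[10] != "A" else "C") + repeat[11:14]
        m = qualify_read("CCCCC" + bad, repeat, ENDS)
        assert m.reject_reason == "fidelity_fail"

    def test_qualification_monotone_in_repeat_length(self, repeat):
        """If length l qualifies via the repeat route, every longer prefix does."""
        lengths = range(12, len(repeat) + 1)
        routes = [qualify_read("CCCCC" + repeat[:l], repeat, ENDS).route for l in lengths]
        assert routes == ["repeat_length"] * len(list(lengths))

    def test_qualified_processed_repeat_is_always_a_repeat_prefix(self, repeat):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        for _ in range(500):
            insert = "".join(rng.choice(bases, int(rng.integers(5, 50))))
            m = qualify_read(insert, repeat, ENDS)
            if m.qualified:
                assert repeat.startswith(m.processed_repeat)


class TestReferenceCounting:
    def test_window_counts(self):
        assert len(build_reference_index("A" * 25).kmers) == 1
        idx30 = build_reference_index("ACGTG" * 6)
        assert len(idx30.kmers) <= 6
        assert len(build_reference_index("A" * 30).kmers) == 1

    def test_too_short_reference_is_an_error(self):
        with pytest.raises(ValueError):
            build_reference_index("A" * 24)

    def test_exact_fragment_detection(self, params):
        idx = build_reference_index(params.reference)
        assert is_reference_read(params.reference[2:27], idx)
        assert not is_reference_read(params.reference[2:26], idx)  # 24 nt
        frag = params.reference[2:27]
        mutated = frag[:10] + ("A" if frag[10] != "A" else "C") + frag[11:]
        assert not is_reference_read(mutated, idx)

    def test_agrees_with_double_loop_oracle(self, params):
        ref = params.reference
        idx = build_reference_index(ref)

        def oracle(read):
            for i in range(len(read) - 24):
                window = read[i : i + 25]
                found = False
                for j in range(len(ref) - 24):
                    if ref[j : j + 25] == window:
                        found = True
                        break
                if found:
                    return True
            return False

        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        for _ in range(500):
            n = int(rng.integers(10, 60))
            if rng.random() < 0.5:
                start = int(rng.integers(0, max(1, len(ref) - n)))
                read = ref[start : start + n]
            else:
                read = "".join(rng.choice(bases, n))
            assert is_reference_read(read, idx) == oracle(read)


class TestBuildProfile:
    def _matches(self, lengths, repeat):
        return [
            qualify_read("CCCCC" + repeat[:l], repeat, ENDS) for l in lengths
        ]

    def test_normalized_heights(self, params):
        matches = self._matches([12] * 3 + [20] * 7, params.repeat)
        prof = build_profile(matches, n_reference=10, params=params)
        assert prof.counts == {12: 3, 20: 7}
        assert prof.heights == {12: 0.3, 20: 0.7}
        assert prof.n_qualified == 10

    def test_y_scale_rescales_linearly(self, params):
        scaled = PipelineParams(params.repeat, params.reference, 2.0)
        matches = self._matches([12] * 3 + [20] * 7, params.repeat)
        prof = build_profile(matches, n_reference=10, params=scaled)
        assert prof.heights == {12: 0.6, 20: 1.4}

    def test_zero_reference_is_an_explicit_error(self, params):
        with pytest.raises(ValueError, match="reference gene"):
            build_profile([], n_reference=0, params=params)

    def test_rejected_matches_are_excluded(self, params):
        matches = self._matches([12], params.repeat) + [
            qualify_read("CCCCCCCC", params.repeat, ENDS)
        ]
        prof = build_profile(matches, n_reference=5, params=params)
        assert prof.n_qualified == 1


class TestRenderProfile:
    def test_tsv_has_one_row_per_repeat_position(self, tmp_path, params):
        matches = [qualify_read("CCCCC" + params.repeat[:20], params.repeat, ENDS)]
        prof = build_profile(matches, n_reference=4, params=params)
        png, tsv = render_profile(prof, params.repeat, tmp_path / "p.png")
        import pandas as pd

        table = pd.read_csv(tsv, sep="\t")
        assert len(table) == len(params.repeat)
        assert list(table["base"]) == list(params.repeat)
        assert table.loc[table["position"] == 20, "raw_count"].item() == 1
        assert table.loc[table["position"] == 20, "normalized_height"].item() == 0.25
        assert (table.loc[table["position"] != 20, "raw_count"] == 0).all()
        import os

        assert os.path.getsize(png) > 0

    def test_empty_profile_renders_all_zero_bars(self, tmp_path, params):
        prof = build_profile([], n_reference=1, params=params)
        table = profile_table(prof, params.repeat)
        assert (table["raw_count"] == 0).all()
        png, tsv = render_profile(prof, params.repeat, tmp_path / "z.png")
        assert (tmp_path / "z.tsv").exists()


class TestKeywordSelection:
    @pytest.fixture()
    def fasta_dir(self, tmp_path):
        for i in range(5, 9):
            (tmp_path / f"sample{i}.fasta").write_text(f">r1\nACGT\n")
        return tmp_path

    @pytest.mark.parametrize("keyword,expected", [("8", 1), ("mpl", 4), ("sem", 0)])
    def test_substring_selection(self, fasta_dir, keyword, expected):
        files = select_files_by_keyword(fasta_dir, keyword)
        assert len(files) == expected
        if keyword == "8":
            assert files[0].endswith("sample8.fasta")

    def test_missing_directory_is_an_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            select_files_by_keyword(tmp_path / "nope", "x")


def test_profile_reads_conserves_counts(params, spacer_ends, repeat):
    records = [
        ("q1", "CCCCC" + repeat[:20]),
        ("q2", "CCCCC" + repeat[:20]),
        ("ref1", params.reference[10:40]),
        ("junk", "CCCCCCCCCCCC"),
    ]
    prof, log, matches = profile_reads(records, params, spacer_ends)
    assert prof.n_qualified == sum(prof.counts.values()) == 2
    assert prof.n_reference == 1
    assert log.n_total == 4
    assert log.n_rejected == {"no_seed": 2}
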