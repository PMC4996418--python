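"""Column profiles, pattern construction, refinement, class-specific columns."""

import itertools

import pytest

from twistmotif import constants as C
from twistmotif.motif_discovery import (
    AnyOf,
    Literal,
    ProfileError,
    PrositePattern,
    RefinementError,
    Wildcard,
    build_profile,
    find_class_specific_columns,
    pattern_matches,
    profile_to_pattern,
    refine_discriminative_motif,
)
from twistmotif.seq_io import Msa, SequenceRecord


def rec(residues, rid="s"):
    return SequenceRecord(id=rid, residues=residues)


def msa(*rows):
    return Msa(tuple((f"r{i}", row) for i, row in enumerate(rows)))


class TestBuildProfile:
    def test_identical_rows_fully_conserved(self):
        m = msa("MKVL", "MKVL", "MKVL", "MKVL")
        prof = build_profile(m)
        assert all(prof.conservation(c) == 1.0 for c in range(1, 5))

    def test_direct_counts(self):
        prof = build_profile(msa("AS", "AG"))
        assert prof.columns[0] == {"A": 2}
        assert prof.columns[1] == {"S": 1, "G": 1}

    def test_frequencies_on_a_33_row_group(self):
        rows = ["V"] * 30 + ["E"] * 3
        m = Msa(tuple((f"r{i}", ch) for i, ch in enumerate(rows)))
        prof = build_profile(m)
        freqs = prof.frequencies(1)
        assert freqs["V"] == pytest.approx(30 / 33)
        assert freqs["E"] == pytest.approx(3 / 33)

    def test_counts_sum_to_rows_and_frequencies_to_one(self, family):
        prof = build_profile(family.true_msa)
        for c in range(1, prof.n_cols + 1):
            assert sum(prof.columns[c - 1].values()) == prof.n_rows
            assert sum(prof.frequencies(c).values()) == pytest.approx(1.0)

    def test_row_subset_and_col_range(self, family):
        a_ids = [i for i in family.true_msa.ids if i.endswith("_A")]
        prof = build_profile(family.true_msa, row_subset=a_ids, col_range=(5, 22))
        assert prof.n_rows == len(a_ids)
        assert prof.source_columns == tuple(range(5, 23))

    def test_empty_subset_rejected(self, family):
        with pytest.raises(ProfileError):
            build_profile(family.true_msa, row_subset=[])


class TestProfileToPattern:
    def test_uniform_rows_give_all_literal_pattern(self):
        m = Msa(tuple((f"r{i}", C.T1_MAMMAL_MOTIF) for i in range(4)))
        pat = profile_to_pattern(build_profile(m))
        assert pat.serialize() == "-".join(C.T1_MAMMAL_MOTIF)

    def test_two_residue_column_tie_broken_by_row_order(self):
        pat = profile_to_pattern(build_profile(msa("SA", "SG")))
        assert pat.serialize() == "S-[AG]"
        pat = profile_to_pattern(build_profile(msa("SG", "SA")))
        assert pat.serialize() == "S-[GA]"

    def test_too_many_residues_become_wildcard(self):
        m = msa("S", "G", "N", "R", "A")
        pat = profile_to_pattern(build_profile(m), max_set_size=4)
        assert pat.elements == (Wildcard(1, 1),)

    def test_gap_policies(self):
        m = msa("A-C", "AGC")
        with pytest.raises(ProfileError, match="column 2"):
            profile_to_pattern(build_profile(m), gap_policy="forbid")
        pat = profile_to_pattern(build_profile(m), gap_policy="skip-column")
        assert pat.serialize() == "A-C"

    def test_completeness_on_simulated_group(self, family):
        """With min_freq=0 the pattern matches every training row."""
        m = family.true_msa
        a_ids = [i for i in m.ids if i.endswith("_A")]
        prof = build_profile(m, row_subset=a_ids, col_range=(5, 22))
        pat = profile_to_pattern(prof)
        for rid in a_ids:
            row = m.row(rid)[4:22].replace("-", "")
            assert pattern_matches(pat, rec(row, rid))


class TestRefinement:
    def exhaustive_minimal(self, pattern, pos, neg):
        """Oracle: all end-trims (i, j) that stay discriminative."""
        els = pattern.elements
        ok = []
        for i in range(len(els)):
            for j in range(i, len(els)):
                sub = PrositePattern(els[i : j + 1])
                if all(pattern_matches(sub, p) for p in pos) and not any(
                    pattern_matches(sub, n) for n in neg
                ):
                    ok.append((i, j))
        return ok

    def test_result_is_discriminative_and_end_trim_minimal(self, family):
        m = family.true_msa
        a_ids = [i for i in m.ids if i.endswith("_A")]
        pat = profile_to_pattern(build_profile(m, row_subset=a_ids, col_range=(5, 22)))
        pos = list(family.records_by_label("group-A"))
        neg = list(family.records_by_label("group-B"))
        core = refine_discriminative_motif(pat, pos, neg)
        assert all(pattern_matches(core, p) for p in pos)
        assert not any(pattern_matches(core, n) for n in neg)
        # minimality: dropping either extreme breaks discrimination
        if len(core) > 1:
            for trial in (core.elements[1:], core.elements[:-1]):
                t = PrositePattern(trial)
                assert not (
                    all(pattern_matches(t, p) for p in pos)
                    and not any(pattern_matches(t, n) for n in neg)
                )

    def test_fixed_point_of_printed_motif_toy_corpus(self):
        """With the two printed 17/18-mer motifs as the whole corpus, the
        double aspartate alone separates the groups, so end-trimming
        reduces the combined pattern all the way to D-D (confirmed by
        exhaustive end-trim enumeration)."""
        pos = [rec(C.T1_MAMMAL_MOTIF, "m1")]
        neg = [rec(C.T2_MAMMAL_MOTIF, "m2")]
        core = refine_discriminative_motif(C.COMBINED_PATTERN, pos, neg)
        assert core.serialize() == "D-D"
        assert ((8, 9)) in self.exhaustive_minimal(C.COMBINED_PATTERN, pos, neg)

    def test_single_discriminator_toy(self):
        # only 'E' separates the sets, so trimming converges onto it
        pat = PrositePattern(tuple(Literal(c) for c in "ACDE"))
        pos = [rec("ACDE", "p1"), rec("XACDEX", "p2")]
        neg = [rec("ACDQ", "n1")]
        core = refine_discriminative_motif(pat, pos, neg)
        assert core.serialize() == "E"

    def test_not_discriminative_at_start_is_an_error(self):
        pat = PrositePattern(tuple(Literal(c) for c in "AC"))
        same = [rec("ACDE", "p"), ]
        with pytest.raises(RefinementError, match="not discriminative"):
            refine_discriminative_motif(pat, same, same)


class TestClassSpecificColumns:
    def test_printed_motifs_aligned_pair(self):
        m = Msa((("t1", "SSSPVSPADDSLSNSEEE"), ("t2", "SSSPVSPVD-SLGTSEEE")))
        classes = find_class_specific_columns(m, {"A": ["t1"], "B": ["t2"]})
        assert [c + 1 for c in range(18) if classes[c] == "class-specific"] == [8, 13, 14]
        assert classes[9] == "gapped"
        assert all(classes[c] == "conserved" for c in range(7))

    def test_identical_rows_all_conserved(self):
        m = msa("MKVL", "MKVL", "MKVL", "MKVL")
        groups = {"A": ["r0", "r1"], "B": ["r2", "r3"]}
        assert set(find_class_specific_columns(m, groups)) == {"conserved"}

    def test_planted_n_t_column_is_class_specific(self):
        rows = ["ANA"] * 3 + ["ATA"] * 3
        m = Msa(tuple((f"r{i}", r) for i, r in enumerate(rows)))
        groups = {"A": [f"r{i}" for i in range(3)], "B": [f"r{i}" for i in range(3, 6)]}
        assert find_class_specific_columns(m, groups) == [
            "conserved", "class-specific", "conserved",
        ]

    def test_mixed_group_column_is_unconserved(self):
        m = msa("AN", "AT", "AN", "AN")
        groups = {"A": ["r0", "r1"], "B": ["r2", "r3"]}
        assert find_class_specific_columns(m, groups)[1] == "unconserved"

    def test_invalid_partition_rejected(self):
        m = msa("AC", "AC")
        with pytest.raises(ValueError):
            find_class_specific_columns(m, {"A": ["r0"], "B": ["r0", "r1"]})
        with pytest.raises(ValueError):
            find_class_specific_columns(m, {"A": ["r0", "r1"]})
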