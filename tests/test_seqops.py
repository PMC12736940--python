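"""Sequence layer: CpG accounting, modifications, shuffles, contexts."""

import itertools
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucwrap import seqops as S
from nucwrap.seqops import ModSequence

dna = st.text(alphabet="ACGT", min_size=2, max_size=60)


@pytest.mark.parametrize("bases,expected", [
    ("ACGT", 1),
    ("CGCG", 2),
    ("CG" * 73 + "C", 73),
    ("AATT", 0),
])
def test_count_cpg(bases, expected):
    assert S.count_cpg(ModSequence(bases)) == expected


def test_invalid_letters_rejected():
    with pytest.raises(ValueError):
        ModSequence("ACGN")


class TestModification:
    def test_methylates_every_cpg(self):
        m = S.apply_symmetric_modification(ModSequence("ACGT"), "methyl")
        assert m.mods == {(2, "methyl")}
        assert S.apply_symmetric_modification(ModSequence("AATT"), "methyl").mods == frozenset()
        h = S.apply_symmetric_modification(ModSequence("CGCG"), "hydroxymethyl")
        assert h.mods == {(1, "hydroxymethyl"), (3, "hydroxymethyl")}

    def test_mod_count_equals_cpg_count(self):
        for seed in range(5):
            s = S.random_sequence_with_cpg_range(100, 5, 20, seed)
            m = S.apply_symmetric_modification(s, "methyl")
            assert len(m.mods) == S.count_cpg(s) == S.count_cpg(m)

    def test_mixed_kind_rejected(self):
        m = S.apply_symmetric_modification(ModSequence("ACGT"), "methyl")
        with pytest.raises(ValueError):
            S.apply_symmetric_modification(m, "hydroxymethyl")

    def test_annotation_must_sit_on_cpg(self):
        with pytest.raises(ValueError):
            ModSequence("AATT", {(1, "methyl")})


class TestReverseComplement:
    def test_examples(self):
        assert S.reverse_complement(ModSequence("ACG")).bases == "CGT"
        m = ModSequence("ACGT", {(2, "methyl")})
        rc = S.reverse_complement(m)
        assert rc.bases == "ACGT" and rc.mods == {(2, "methyl")}

    @settings(deadline=None, max_examples=60)
    @given(dna)
    def test_involution_and_counts(self, bases):
        s = ModSequence(bases)
        rc = S.reverse_complement(s)
        assert S.reverse_complement(rc) == s
        assert S.count_cpg(rc) == S.count_cpg(s)

    def test_modification_map_bijective(self):
        s = S.apply_symmetric_modification(
            S.random_sequence_with_cpg_range(80, 8, 15, 3), "methyl")
        rc = S.reverse_complement(s)
        assert len(rc.mods) == len(s.mods)
        assert S.reverse_complement(rc) == s


class TestRandomSequence:
    def test_count_in_range_and_reproducible(self):
        a = S.random_sequence_with_cpg_range(147, 0, 4, 42)
        b = S.random_sequence_with_cpg_range(147, 0, 4, 42)
        assert a == b
        assert 0 <= S.count_cpg(a) <= 4

    @pytest.mark.parametrize("lo,hi", [(0, 4), (5, 14), (15, 24), (25, 34)])
    def test_all_study_bins_reachable(self, lo, hi):
        s = S.random_sequence_with_cpg_range(147, lo, hi, 7)
        assert lo <= S.count_cpg(s) <= hi

    def test_infeasible_target(self):
        with pytest.raises(ValueError):
            S.random_sequence_with_cpg_range(147, 74, 74, 0)

    def test_letter_frequencies_near_uniform_when_unconstrained(self):
        counts = Counter()
        for seed in range(40):
            counts.update(S.random_sequence_with_cpg_range(147, 0, 73, seed).bases)
        total = sum(counts.values())
        freqs = np.array([counts[b] / total for b in "ACGT"])
        assert np.all(np.abs(freqs - 0.25) < 0.03)


class TestDinucleotideCounts:
    def test_example(self):
        c = S.dinucleotide_counts(ModSequence("AATT"))
        assert c["AA"] == 1 and c["AT"] == 1 and c["TT"] == 1
        assert sum(c.values()) == 3

    @settings(deadline=None, max_examples=40)
    @given(dna)
    def test_sum_is_n_minus_1(self, bases):
        assert sum(S.dinucleotide_counts(ModSequence(bases)).values()) == len(bases) - 1

    def test_complement_folding_over_all_4mers(self):
        # brute force: counts of s and of RC(s) agree after folding each
        # step with its complement
        from nucwrap.model import complement_label
        for tup in itertools.product("ACGT", repeat=4):
            s = ModSequence("".join(tup))
            c1 = S.dinucleotide_counts(s)
            c2 = S.dinucleotide_counts(S.reverse_complement(s))
            for step in c1:
                comp = complement_label(step)
                assert c1[step] + c1[comp] == c2[step] + c2[comp]


def _enumerate_valid_shuffles(bases):
    """All distinct sequences with the same dinucleotide counts, same
    first base (brute force over junction orderings)."""
    target = S.dinucleotide_counts(bases)
    found = set()

    def walk(prefix, remaining):
        if not any(remaining.values()):
            found.add(prefix)
            return
        for step, cnt in remaining.items():
            if cnt and step[0] == prefix[-1]:
                remaining[step] -= 1
                walk(prefix + step[1], remaining)
                remaining[step] += 1

    walk(bases[0], dict(target))
    return found


class TestShuffle:
    def test_unique_shuffle(self):
        assert _enumerate_valid_shuffles("AATT") == {"AATT"}
        assert S.altschul_erickson_shuffle(ModSequence("AATT"), 0).bases == "AATT"

    def test_counts_preserved_on_random_147mers(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            s = ModSequence("".join(rng.choice(list("ACGT"), 147)))
            sh = S.altschul_erickson_shuffle(s, rng)
            assert S.dinucleotide_counts(sh) == S.dinucleotide_counts(s)

    def test_uniform_over_valid_shuffles(self):
        bases = "ACAGAT"
        valid = _enumerate_valid_shuffles(bases)
        assert len(valid) > 1
        n_draws = 6000
        rng = np.random.default_rng(1)
        counts = Counter(
            S.altschul_erickson_shuffle(ModSequence(bases), rng).bases
            for _ in range(n_draws))
        assert set(counts) == valid
        expected = n_draws / len(valid)
        chi2 = sum((c - expected) ** 2 / expected for c in counts.values())
        # df = len(valid) - 1; generous 99.9% cut-off
        from scipy.stats import chi2 as chi2_dist
        assert chi2 < chi2_dist.ppf(0.999, len(valid) - 1)

    def test_modified_input_rejected(self):
        m = S.apply_symmetric_modification(ModSequence("ACGT"), "methyl")
        with pytest.raises(ValueError):
            S.altschul_erickson_shuffle(m, 0)


class TestTetramerContext:
    def test_single_step_all_a(self):
        t = S.tetramer_context_counts([ModSequence("AAAACGAAAA")])
        assert t["n_steps"] == 1 and t["n_skipped"] == 0
        assert t["upstream"][0].tolist() == [1, 1, 1, 1]  # row A
        assert t["downstream"][0].tolist() == [1, 1, 1, 1]

    def test_step_near_end_skipped(self):
        t = S.tetramer_context_counts([ModSequence("ACGT")])
        assert t["n_steps"] == 0 and t["n_skipped"] == 1

    def test_column_sums_equal_step_count(self):
        seqs = [S.random_sequence_with_cpg_range(60, 2, 10, s) for s in range(10)]
        t = S.tetramer_context_counts(seqs)
        assert np.all(t["upstream"].sum(axis=0) == t["n_steps"])
        assert np.all(t["downstream"].sum(axis=0) == t["n_steps"])


class TestExtendedFasta:
    def test_roundtrip_with_modifications(self, tmp_path):
        seqs = [
            ModSequence("ACGTCG", {(2, "methyl"), (5, "methyl")}, name="m"),
            ModSequence("CGCG", {(1, "hydroxymethyl")}, name="h"),
            ModSequence("AATT", name="plain"),
        ]
        p = tmp_path / "x.fa"
        S.write_fasta(seqs, p)
        text = p.read_text()
        assert "AMNTMN" in text and "HKCG" in text
        back = S.read_fasta(p)
        assert [b.bases for b in back] == [s.bases for s in seqs]
        assert [b.mods for b in back] == [s.mods for s in seqs]

    def test_orphan_modified_letter(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">x\nAMCT\n")
        with pytest.raises(ValueError):
            S.read_fasta(p)
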