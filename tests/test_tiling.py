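"""PAM-tiling generation and constraint filters against independent oracles."""

import itertools
import math
import random
import re

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crisprakit.seqcore import NucSequence, reverse_complement
from crisprakit.tiling import (
    DEFAULT_BASE_UNIT,
    DesignExhaustedError,
    DesignParams,
    anchored_pam_positions,
    design_array,
    fill_base_units,
    genome_homology_filter,
    homopolymer_filter,
    n_position_probabilities,
    read_tf_sites,
    select_fragment,
    tf_site_filter,
)


def gc_fraction(bases):
    return sum(1 for b in bases if b in "GC") / len(bases)


class TestFillBaseUnits:
    def test_pattern_positions_forced_single_unit(self):
        params = DesignParams(candidate_length=10, n_candidates=1, fragment_length=10)
        seq = fill_base_units(params, np.random.default_rng(123))
        assert len(seq) == 10
        assert seq.bases[3:5] == "CC" and seq.bases[8:10] == "GG"

    def test_all_constrained_positions_in_500mer(self):
        params = DesignParams(candidate_length=500)
        seq = fill_base_units(params, np.random.default_rng(7))
        assert len(seq) == 500
        for rep in range(50):  # positional oracle over all 200 fixed bases
            unit = seq.bases[rep * 10 : rep * 10 + 10]
            assert unit[3] == "C" and unit[4] == "C"
            assert unit[8] == "G" and unit[9] == "G"

    def test_truncation_warns_on_non_multiple_length(self):
        params = DesignParams(candidate_length=505)
        with pytest.warns(UserWarning, match="truncating to 500"):
            seq = fill_base_units(params, np.random.default_rng(0))
        assert len(seq) == 500

    def test_probability_closed_form(self):
        probs = n_position_probabilities(DEFAULT_BASE_UNIT, 0.508)
        # (10*0.508 - 4)/6 = 0.18 total GC mass split equally
        assert probs["G"] == pytest.approx(0.09)
        assert probs["C"] == pytest.approx(0.09)
        assert probs["A"] == pytest.approx(0.41)
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_gc_target_below_fixed_base_floor_rejected(self):
        with pytest.raises(ValueError, match="fixed-base floor"):
            n_position_probabilities(DEFAULT_BASE_UNIT, 0.3)

    def test_mean_gc_matches_target_within_3se(self):
        params = DesignParams(candidate_length=500, gc_target=0.508)
        rng = np.random.default_rng(2024)
        n = 2000
        fracs = [gc_fraction(fill_base_units(params, rng).bases) for _ in range(n)]
        p = 0.18  # per-N GC probability at this target
        se = math.sqrt(300 * p * (1 - p)) / 500 / math.sqrt(n)
        assert abs(np.mean(fracs) - 0.508) < 3 * se


class TestHomopolymerFilter:
    def test_run_of_three_passes(self):
        assert homopolymer_filter(NucSequence("CGAAATCG", "s")).passed

    def test_run_of_four_fails_with_interval(self):
        result = homopolymer_filter(NucSequence("CAAAAG", "s"))
        assert not result.passed
        assert result.data == (1, 5)
        assert "[1, 5)" in result.detail

    @given(st.text(alphabet="ACGT", min_size=1, max_size=120))
    def test_agrees_with_run_length_encoding_oracle(self, bases):
        runs = [len(list(g)) for _, g in itertools.groupby(bases)]
        expected = max(runs) <= 3
        assert homopolymer_filter(NucSequence(bases, "s")).passed is expected

    def test_configurable_run_length(self):
        seq = NucSequence("GGGGG", "s")
        assert not homopolymer_filter(seq, max_run=3).passed
        assert homopolymer_filter(seq, max_run=5).passed


class TestTfSiteFilter:
    def test_empty_list_always_passes(self):
        assert tf_site_filter(NucSequence("ACGTACGT", "s"), []).passed

    def test_reverse_strand_match_reported_by_id(self):
        site = "ATCGATCGATCG"
        seq = NucSequence("TTTT" + reverse_complement(site) + "TTTT", "s")
        result = tf_site_filter(seq, [("soxbox", site)])
        assert not result.passed and result.data == ["soxbox"]

    def test_site_longer_than_sequence_passes(self):
        assert tf_site_filter(NucSequence("ACGT", "s"), [("long", "A" * 30)]).passed

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_two_strand_substring_oracle(self, seed):
        rng = random.Random(seed)
        bases = "".join(rng.choices("ACGT", k=200))
        sites = [
            (f"s{i}", "".join(rng.choices("ACGT", k=rng.randint(4, 10))))
            for i in range(6)
        ]
        expected = [
            sid
            for sid, s in sites
            if s in bases or s in reverse_complement(bases)
        ]
        result = tf_site_filter(NucSequence(bases, "q"), sites)
        assert result.passed is (not expected)
        if expected:
            assert result.data == expected

    def test_reader_rejects_non_nucleotide_site(self, tmp_path):
        path = tmp_path / "tf.tsv"
        path.write_text("ok\tACGT\nbad\tAXGT\n")
        with pytest.raises(ValueError, match="bad"):
            read_tf_sites(path)


class TestGenomeHomologyFilter:
    def test_self_match_count(self):
        seq = NucSequence("ACGTACGGTTCAGGCATCAGTTCA", "q")
        result = genome_homology_filter(seq, [seq], k=15)
        assert not result.passed
        count, first = result.data
        assert count >= len(seq) - 15 + 1
        assert first == seq.bases[:15]

    def test_all_a_genome_passes_disjoint_query(self):
        genome = NucSequence("A" * 500, "g")
        query = NucSequence("ACG" * 10, "q")
        assert genome_homology_filter(query, [genome], k=15).passed

    def test_planted_kmer_fails_with_count_one(self):
        rng = random.Random(3)
        query = NucSequence("".join(rng.choices("ACGT", k=60)), "q")
        kmer = query.bases[20:35]
        genome = NucSequence(kmer, "g")  # exactly one plantable 15-mer
        result = genome_homology_filter(query, [genome], k=15)
        assert not result.passed and result.data == (1, kmer)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_set_intersection_oracle(self, seed):
        rng = random.Random(seed)
        k = rng.randint(4, 8)
        query = "".join(rng.choices("ACGT", k=40))
        genome = "".join(rng.choices("ACGT", k=150))
        genome_kmers = {
            genome[i : i + k] for i in range(len(genome) - k + 1)
        } | {
            reverse_complement(genome)[i : i + k] for i in range(len(genome) - k + 1)
        }
        query_kmers = {query[i : i + k] for i in range(len(query) - k + 1)}
        expected_pass = not (query_kmers & genome_kmers)
        result = genome_homology_filter(NucSequence(query, "q"), [NucSequence(genome, "g")], k=k)
        assert result.passed is expected_pass

    def test_k_longer_than_query_rejected(self):
        with pytest.raises(ValueError, match="exceeds query length"):
            genome_homology_filter(NucSequence("ACGT", "q"), [NucSequence("ACGT", "g")], k=10)


class TestDesignArray:
    def test_returns_first_homopolymer_passer_under_permissive_params(self):
        params = DesignParams(n_candidates=50, rng_seed=42)
        run = design_array(params)
        # re-simulate the candidate stream: every earlier candidate must fail
        rng = np.random.default_rng(42)
        for index in range(run.design.candidate_index + 1):
            candidate = fill_base_units(params, rng, seq_id=f"candidate{index}")
            passed = homopolymer_filter(candidate).passed
            if index < run.design.candidate_index:
                assert not passed
            else:
                assert passed and candidate.bases == run.design.seq.bases

    def test_seeded_determinism_byte_identical(self):
        params = DesignParams(n_candidates=100, rng_seed=7)
        a, b = design_array(params), design_array(params)
        assert a.design == b.design and a.attrition == b.attrition

    def test_attrition_counts_sum_to_rejections(self):
        params = DesignParams(n_candidates=100, rng_seed=1)
        run = design_array(params)
        assert sum(run.attrition.values()) == run.n_evaluated - 1

    def test_exhaustion_reports_attrition_table(self):
        # a TF "site" matching the fixed GG of every repeat rejects all candidates
        params = DesignParams(n_candidates=5, rng_seed=0)
        with pytest.raises(DesignExhaustedError, match="all 5 candidates rejected"):
            design_array(params, tf_sites=[("ubiquitous", "CC")])

    def test_filter_verdict_independent_of_order(self):
        """Filters are independent predicates: the verdict of a candidate
        does not depend on application order, only attrition attribution does."""
        rng = np.random.default_rng(5)
        params = DesignParams(n_candidates=1)
        genome = [NucSequence("ACGT" * 50, "g")]
        sites = [("a", "ATCGATCGATCG")]
        for _ in range(20):
            cand = fill_base_units(params, rng)
            verdicts = [
                homopolymer_filter(cand).passed,
                tf_site_filter(cand, sites).passed,
                genome_homology_filter(cand, genome, 8).passed,
            ]
            assert all(verdicts) == all(reversed(verdicts))

    def test_every_repeat_of_passing_design_has_both_strand_pams(self):
        run = design_array(DesignParams(n_candidates=200, rng_seed=9))
        plus, minus = anchored_pam_positions(run.design.seq)
        assert len(plus) == 50 and len(minus) == 50
        assert all(b - a == 10 for a, b in zip(plus, plus[1:]))
        assert all(b - a == 10 for a, b in zip(minus, minus[1:]))


class TestSelectFragment:
    def test_full_length_is_identity(self):
        seq = NucSequence("ACGTACGTAC", "s")
        assert select_fragment(seq, 10).bases == seq.bases

    def test_three_prime_fragment_is_promoter_proximal_end(self):
        seq = fill_base_units(DesignParams(candidate_length=500), np.random.default_rng(1))
        frag = select_fragment(seq, 170, "three_prime")
        assert frag.bases == seq.bases[330:500]  # 1-based 331..500

    def test_five_prime_fragment(self):
        seq = fill_base_units(DesignParams(candidate_length=500), np.random.default_rng(1))
        assert select_fragment(seq, 170, "five_prime").bases == seq.bases[:170]

    def test_offset_placement_and_bounds(self):
        seq = NucSequence("ACGTACGTAC", "s")
        assert select_fragment(seq, 4, 3).bases == "TACG"
        with pytest.raises(ValueError, match="out of bounds"):
            select_fragment(seq, 4, 7)
        with pytest.raises(ValueError, match="exceeds sequence length"):
            select_fragment(seq, 11)
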