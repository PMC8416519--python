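"""Clustering, profile alignment, consensus, PSSM search, footprint rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import msa_from_strings, random_protein, records_from_strings
from vartig.alphabet import decode
from vartig.cogs import (
    FootprintMatch,
    Msa,
    SequenceRecord,
    align_cluster,
    build_pssm,
    classify_match,
    consensus_of,
    greedy_cluster,
    merge_profiles,
    pairwise_identity,
    profile_search,
    split_by_footprint,
)
from vartig.simulate import _evolve, _random_seq


class TestGreedyCluster:
    def test_identical_sequences_form_one_cluster(self, rng):
        s = random_protein(rng, 120)
        clusters = greedy_cluster(records_from_strings(*([s] * 5)))
        assert len(clusters) == 1 and len(clusters[0]) == 5

    def test_dissimilar_pair_stays_apart(self, rng):
        # two random length-200 proteins: oracle identity well below 0.5
        a, b = random_protein(rng, 200), random_protein(rng, 200)
        assert pairwise_identity(a, b) < 0.35
        clusters = greedy_cluster(records_from_strings(a, b), id_threshold=0.5)
        assert len(clusters) == 2

    def test_threshold_one_separates_single_mismatch(self, rng):
        s = random_protein(rng, 80)
        t = s[:40] + ("A" if s[40] != "A" else "C") + s[41:]
        clusters = greedy_cluster(records_from_strings(s, t), id_threshold=1.0)
        assert len(clusters) == 2

    def test_every_sequence_assigned_once(self, rng):
        recs = records_from_strings(*[random_protein(rng, 90) for _ in range(12)])
        clusters = greedy_cluster(recs, id_threshold=0.5)
        ids = [m.id for c in clusters for m in c]
        assert sorted(ids) == sorted(r.id for r in recs)

    def test_empty_input_gives_empty_partition(self):
        assert greedy_cluster([]) == []


class TestAlignCluster:
    def test_single_member_returned_gapless(self, rng):
        s = random_protein(rng, 60)
        aln = align_cluster(records_from_strings(s))
        assert aln.n_rows == 1 and aln.rows[0][2] == s

    def test_identical_pair_aligns_without_gaps(self, rng):
        s = random_protein(rng, 60)
        aln = align_cluster(records_from_strings(s, s))
        assert aln.n_cols == 60
        assert all("-" not in row[2] for row in aln.rows)

    def test_alignment_at_least_as_long_as_longest_member(self, rng):
        recs = records_from_strings(
            random_protein(rng, 50), random_protein(rng, 80), random_protein(rng, 65)
        )
        aln = align_cluster(recs)
        assert aln.n_cols >= 80

    def test_related_family_aligns_compactly(self, rng):
        root = _random_seq(rng, 100)
        seqs = [decode(_evolve(root, 0.1, 0.5, rng)) for _ in range(6)]
        aln = align_cluster(records_from_strings(*seqs))
        assert aln.n_cols <= 110


class TestConsensusAndPssm:
    def test_single_row_consensus_is_the_sequence(self, rng):
        s = random_protein(rng, 40)
        assert consensus_of(msa_from_strings(s)).residues == s

    def test_plurality_residue_wins(self):
        aln = msa_from_strings("A", "A", "A", "C")
        assert consensus_of(aln).residues == "A"

    def test_low_occupancy_column_skipped(self):
        aln = msa_from_strings("AC", "A-", "A-", "A-")
        assert consensus_of(aln).residues == "A"

    def test_conserved_column_scores_highest_for_its_residue(self):
        pssm = build_pssm(msa_from_strings("A", "A", "A"))
        assert np.argmax(pssm.scores[0]) == 0  # A is index 0

    def test_absent_residue_scores_finite_negative(self):
        pssm = build_pssm(msa_from_strings("A", "A", "A"))
        assert np.isfinite(pssm.scores).all()
        assert pssm.scores[0, 1] < 0  # C never observed

    def test_log_odds_vanish_as_pseudocount_dominates_zero(self, rng):
        # background-proportional columns: scores -> 0 as pseudocount -> 0
        from vartig.alphabet import BACKGROUND

        rows = [
            ("r%d" % i, "g", random_protein(rng, 1) * 1)
            for i in range(5000)
        ]
        aln = Msa(rows=rows)
        pssm = build_pssm(aln, pseudocount=1e-6)
        # column composition ~ background, so |score| stays small
        assert np.abs(pssm.scores).max() < 1.5
        assert BACKGROUND.shape == (20,)


class TestProfileSearch:
    def test_self_hit_covers_profile(self, rng):
        s = random_protein(rng, 200)
        pssm = build_pssm(msa_from_strings(s), name="q")
        hits = profile_search(pssm, records_from_strings(s), seed=0)
        assert hits and hits[0].target == "r0"
        cover = (hits[0].query_end - hits[0].query_start + 1) / pssm.n_cols
        assert cover >= 0.95

    def test_decoys_score_below_self_hit(self, rng):
        from vartig._align import sw_pssm
        from vartig.alphabet import encode
        from vartig.cogs import GAP_EXT, GAP_OPEN

        s = random_protein(rng, 200)
        pssm = build_pssm(msa_from_strings(s), name="q")
        enc = encode(s)
        self_score = sw_pssm(pssm.scores, enc, GAP_OPEN, GAP_EXT)[0]
        decoys = [
            sw_pssm(pssm.scores, rng.permutation(enc), GAP_OPEN, GAP_EXT)[0]
            for _ in range(50)
        ]
        assert np.mean(decoys) < self_score

    def test_random_database_rarely_hits(self, rng):
        s = random_protein(rng, 150)
        pssm = build_pssm(msa_from_strings(s), name="q")
        n_empty = 0
        for seed in range(10):
            db = records_from_strings(*[random_protein(rng, 150) for _ in range(5)])
            if not profile_search(pssm, db, evalue_cutoff=1e-4, seed=seed):
                n_empty += 1
        assert n_empty >= 9

    def test_too_few_decoys_rejected(self, rng):
        s = random_protein(rng, 50)
        pssm = build_pssm(msa_from_strings(s))
        with pytest.raises(ValueError):
            profile_search(pssm, records_from_strings(s), n_decoys=5)


class TestFootprintRules:
    def test_exact_75_percent_is_full_length(self):
        m = FootprintMatch("q", "t", 1, 75, 1, 75, 50.0, 1e-9)
        assert classify_match(m, 100) == "full_length"

    def test_74_percent_is_partial(self):
        m = FootprintMatch("q", "t", 1, 74, 1, 74, 50.0, 1e-9)
        assert classify_match(m, 100) == "partial"

    def test_whole_query_is_full_length(self):
        m = FootprintMatch("q", "t", 1, 100, 1, 100, 50.0, 1e-9)
        assert classify_match(m, 100) == "full_length"

    @given(st.integers(1, 100), st.integers(0, 99))
    @settings(max_examples=60, derandomize=True)
    def test_coverage_monotone_in_footprint_length(self, end, shrink):
        # growing a footprint can never flip full_length -> partial
        start = 1
        short_end = max(start, end - shrink)
        long_m = FootprintMatch("q", "t", start, end, start, end, 1.0, 0.0)
        short_m = FootprintMatch("q", "t", start, short_end, start, short_end, 1.0, 0.0)
        if classify_match(short_m, 100) == "full_length":
            assert classify_match(long_m, 100) == "full_length"

    def test_split_three_blocks(self, rng):
        aln = msa_from_strings(random_protein(rng, 300))
        segs = split_by_footprint(aln, (50, 150))
        assert [s.n_cols for s in segs] == [49, 101, 150]

    def test_split_whole_footprint_single_block(self, rng):
        aln = msa_from_strings(random_protein(rng, 300))
        assert [s.n_cols for s in split_by_footprint(aln, (1, 300))] == [300]

    def test_split_prefix_footprint_two_blocks(self, rng):
        aln = msa_from_strings(random_protein(rng, 300))
        assert [s.n_cols for s in split_by_footprint(aln, (1, 100))] == [100, 200]

    def test_inverted_interval_rejected(self, rng):
        aln = msa_from_strings(random_protein(rng, 50))
        with pytest.raises(ValueError):
            split_by_footprint(aln, (30, 10))


class TestMergeProfiles:
    def test_self_merge_doubles_rows_keeps_columns(self, rng):
        aln = align_cluster(records_from_strings(
            random_protein(rng, 80), random_protein(rng, 80)))
        merged = merge_profiles(aln, aln)
        assert merged.n_rows == 2 * aln.n_rows
        assert merged.n_cols == aln.n_cols

    def test_identical_single_rows_align_gapless(self, rng):
        s = random_protein(rng, 70)
        merged = merge_profiles(msa_from_strings(s), msa_from_strings(s))
        assert merged.n_rows == 2 and merged.n_cols == 70
        assert all("-" not in r[2] for r in merged.rows)

    def test_column_count_bounded_by_sum(self, rng):
        a = msa_from_strings(random_protein(rng, 60))
        b = msa_from_strings(random_protein(rng, 90))
        merged = merge_profiles(a, b)
        assert merged.n_cols <= 150

    def test_commutative_column_count(self, rng):
        a = align_cluster(records_from_strings(*[random_protein(rng, 60)] * 2))
        b = msa_from_strings(random_protein(rng, 75))
        assert merge_profiles(a, b).n_cols == merge_profiles(b, a).n_cols


class TestSequenceRecordValidation:
    def test_lowercase_residues_uppercased(self):
        assert SequenceRecord("a", "g", "acdef").residues == "ACDEF"

    def test_invalid_residues_rejected(self):
        with pytest.raises(ValueError):
            SequenceRecord("a", "g", "ACD1F")
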