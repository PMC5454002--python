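import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

import mitecompare as mc
from mitecompare._seq import revcomp, hamming_identity, encode, kmer_codes
from mitecompare.detect import (
    DetectionParams,
    TIRCandidate,
    count_full_length_copies,
    detect_canonical_mites,
    enumerate_tir_candidates,
    revalidate,
    validate_tsd,
)
from conftest import random_dna
from oracles import (
    brute_force_detect,
    brute_force_tir_candidates,
    brute_force_tsd,
    brute_force_copy_count,
)

PARAMS = DetectionParams()


def plant(background: str, element: str, sites, tsd_len=3):
    """Insert an element at several background positions with TSD duplication."""
    seq = background
    shift = 0
    intervals = []
    for site in sorted(sites):
        s = site + shift
        tsd = seq[s : s + tsd_len]
        seq = seq[: s + tsd_len] + element + seq[s:]
        intervals.append((s + tsd_len + 1, s + tsd_len + len(element)))
        shift += tsd_len + len(element)
    return seq, intervals


class TestSeqPrimitives:
    @given(st.text(alphabet="ACGTN", max_size=200))
    def test_revcomp_involution(self, s):
        assert revcomp(revcomp(s)) == s

    def test_kmer_codes_match_naive(self):
        s = "ACGTNACGTACG"
        codes = kmer_codes(encode(s), 3)
        naive = []
        val = {"A": 0, "C": 1, "G": 2, "T": 3}
        for i in range(len(s) - 2):
            w = s[i : i + 3]
            naive.append(
                -1 if "N" in w else val[w[0]] * 16 + val[w[1]] * 4 + val[w[2]]
            )
        assert codes.tolist() == naive

    def test_hamming_identity(self):
        assert hamming_identity("ACGT", "ACGA") == 0.75


class TestEnumerateTIRCandidates:
    def test_homopolymer_has_no_tir(self):
        assert enumerate_tir_candidates("A" * 1000, PARAMS) == []

    def test_planted_perfect_tir_found_and_agrees_with_brute_force(self):
        rng = np.random.default_rng(5)
        elem, _ = mc.make_mite_family(300, 14, rng)
        seq, [(s, e)] = plant(random_dna(3000, 17), elem, [1500])
        cands = enumerate_tir_candidates(seq, PARAMS)
        assert cands == brute_force_tir_candidates(seq, PARAMS)
        mine = [c for c in cands if (c.start, c.end) == (s, e)]
        assert len(mine) == 1
        # the maximal qualifying TIR is at least the planted length
        assert mine[0].tir_length >= 14
        assert mine[0].tir_mismatches <= 0.1 * mine[0].tir_length

    def test_one_mismatch_within_budget_still_reported(self):
        rng = np.random.default_rng(8)
        elem, _ = mc.make_mite_family(300, 14, rng)
        # break one TIR pair (fraction 1/14 = 0.071 <= 0.1)
        broken = _mutate_at(elem, 3)
        seq, [(s, e)] = plant(random_dna(2000, 23), broken, [900])
        hits = [
            c for c in enumerate_tir_candidates(seq, PARAMS)
            if (c.start, c.end) == (s, e)
        ]
        assert hits and hits[0].tir_mismatches >= 1

    def test_candidates_overlapping_n_runs_discarded(self):
        rng = np.random.default_rng(5)
        elem, _ = mc.make_mite_family(120, 12, rng)
        elem = elem[:60] + "N" + elem[61:]
        seq, [(s, e)] = plant(random_dna(1500, 3), elem, [700])
        assert not any(
            (c.start, c.end) == (s, e) for c in enumerate_tir_candidates(seq, PARAMS)
        )

    @hyp_settings(max_examples=12)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_sequence_agrees_with_brute_force(self, seed):
        seq = random_dna(1200, seed)
        assert enumerate_tir_candidates(seq, PARAMS) == brute_force_tir_candidates(
            seq, PARAMS
        )


def _mutate_at(seq: str, pos: int) -> str:
    other = {"A": "C", "C": "G", "G": "T", "T": "A"}
    return seq[:pos] + other[seq[pos]] + seq[pos + 1 :]


class TestValidateTSD:
    def _cand(self, s, e):
        return TIRCandidate(start=s, end=e, tir_length=10, tir_mismatches=0)

    def test_taa_flanks(self):
        seq = "G" * 50 + "TAA" + "C" * 100 + "TAA" + "G" * 50
        cand = self._cand(54, 153)
        assert validate_tsd(seq, cand, PARAMS) == "TAA"

    def test_longest_tsd_wins(self):
        # CATTG also matches at k=2 ("TG"); the longest must be returned
        seq = "A" * 50 + "CATTG" + "C" * 90 + "CATTG" + "A" * 50
        cand = self._cand(56, 145)
        assert validate_tsd(seq, cand, PARAMS) == "CATTG"
        assert brute_force_tsd(seq, cand, PARAMS) == "CATTG"

    def test_no_agreement_returns_none(self):
        seq = random_dna(400, 42)
        cand = self._cand(101, 300)
        assert validate_tsd(seq, cand, PARAMS) == brute_force_tsd(seq, cand, PARAMS)

    def test_chromosome_edge_insufficient_flank(self):
        seq = "TA" + "G" * 100 + "TA"
        cand = self._cand(1, 104)  # element spans everything: no flank at all
        assert validate_tsd(seq, cand, PARAMS) is None


class TestCopyCount:
    def test_three_dispersed_copies_counted(self):
        rng = np.random.default_rng(2)
        elem, _ = mc.make_mite_family(200, 12, rng)
        seq, ivs = plant(random_dna(9000, 7), elem, [1000, 4000, 7500])
        g = mc.GenomeAccession("t", {"Chr1": seq})
        assert count_full_length_copies(g, elem, PARAMS) == 3
        assert brute_force_copy_count(g, elem, PARAMS) == 3

    def test_tandem_triplication_collapses_to_one(self):
        rng = np.random.default_rng(3)
        elem, _ = mc.make_mite_family(200, 12, rng)
        block = random_dna(800, 9) + elem + random_dna(800, 10)
        seq = random_dna(500, 11) + block * 3 + random_dna(500, 12)
        g = mc.GenomeAccession("t", {"Chr1": seq})
        assert count_full_length_copies(g, elem, PARAMS) == 1
        assert brute_force_copy_count(g, elem, PARAMS) == 1

    def test_reverse_complement_copy_counts(self):
        rng = np.random.default_rng(4)
        elem, _ = mc.make_mite_family(150, 11, rng)
        seq = (
            random_dna(1000, 13) + elem + random_dna(1000, 14)
            + revcomp(elem) + random_dna(1000, 15) + elem + random_dna(500, 16)
        )
        g = mc.GenomeAccession("t", {"Chr1": seq})
        assert count_full_length_copies(g, elem, PARAMS) == 3


class TestDetectCanonical:
    def test_planted_elements_recovered_exactly(self, small_dataset):
        tf = small_dataset.truth_frame()
        for acc in small_dataset.accession_names[:2]:
            genome = small_dataset.accessions[acc]
            mites = detect_canonical_mites(genome)
            detected = {
                (m.interval.chromosome, m.interval.start, m.interval.end)
                for m in mites
            }
            canon = tf[(tf.accession == acc) & (tf.category == "canonical")]
            truth = {(r.chromosome, r.start, r.end) for r in canon.itertuples()}
            assert detected == truth
            # TSD strings match the planted duplications
            by_pos = {(r.chromosome, r.start): r.tsd_sequence for r in canon.itertuples()}
            for m in mites:
                planted = by_pos[(m.interval.chromosome, m.interval.start)]
                assert m.tsd_sequence.endswith(planted) or planted.endswith(
                    m.tsd_sequence
                )

    def test_every_record_revalidates_and_lengths_in_range(self, small_dataset):
        acc = small_dataset.accession_names[0]
        genome = small_dataset.accessions[acc]
        for m in detect_canonical_mites(genome):
            assert 50 <= m.interval.length <= 800
            assert revalidate(m, genome, PARAMS)
            assert m.copy_count >= PARAMS.min_copies

    def test_pure_random_genome_matches_oracle(self):
        g = mc.GenomeAccession("r", {"Chr1": random_dna(30_000, 99)})
        mine = detect_canonical_mites(g, PARAMS)
        oracle = brute_force_detect(g, PARAMS)
        assert _records_equal(mine, oracle)

    def test_deterministic_order(self, small_dataset):
        acc = small_dataset.accession_names[0]
        genome = small_dataset.accessions[acc]
        mites = detect_canonical_mites(genome)
        keys = [(m.interval.chromosome, m.interval.start) for m in mites]
        assert keys == sorted(keys)


def _records_equal(a, b):
    def key(m):
        return (
            m.interval.chromosome, m.interval.start, m.interval.end,
            m.tir_length, m.tir_mismatches, m.tsd_sequence, m.copy_count,
        )

    return [key(m) for m in a] == [key(m) for m in b]
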