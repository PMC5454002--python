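import numpy as np
import pytest

import mitecompare as mc
from mitecompare._seq import revcomp
from mitecompare.homology import (
    MITEHit,
    ScanParams,
    build_homolog_groups,
    categorize_hit,
    categorize_hits,
    hits_from_frame,
    hits_to_frame,
    scan_genome,
)
from conftest import random_dna


def _reps(seqs):
    return {f"MC{i:04d}": (s, None, "unclassified") for i, s in enumerate(seqs)}


def _decay(seq, rate, seed):
    rng = np.random.default_rng(seed)
    other = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    out = list(seq)
    for i in rng.choice(len(seq), size=int(round(rate * len(seq))), replace=False):
        out[i] = other[out[i]][rng.integers(0, 3)]
    return "".join(out)


class TestScanGenome:
    def test_exact_copy_full_identity_and_coverage(self):
        rng = np.random.default_rng(1)
        rep, _ = mc.make_mite_family(300, 14, rng)
        seq = random_dna(2000, 2) + rep + random_dna(2000, 3)
        g = mc.GenomeAccession("t", {"Chr1": seq})
        hits = scan_genome(g, _reps([rep]))
        assert len(hits) == 1
        h = hits[0]
        assert (h.interval.start, h.interval.end) == (2001, 2300)
        assert h.percent_identity == 1.0
        assert h.coverage_of_representative == 1.0
        assert h.strand == "+"

    def test_reverse_complement_copy_found_on_minus_strand(self):
        rng = np.random.default_rng(2)
        rep, _ = mc.make_mite_family(250, 12, rng)
        seq = random_dna(1500, 4) + revcomp(rep) + random_dna(1500, 5)
        hits = scan_genome(mc.GenomeAccession("t", {"Chr1": seq}), _reps([rep]))
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].percent_identity == 1.0

    def test_decayed_copy_identity_matches_planted_decay(self):
        rng = np.random.default_rng(3)
        rep, _ = mc.make_mite_family(400, 14, rng)
        copy = _decay(rep, 0.08, 6)
        seq = random_dna(1500, 7) + copy + random_dna(1500, 8)
        hits = scan_genome(mc.GenomeAccession("t", {"Chr1": seq}), _reps([rep]))
        assert len(hits) == 1
        true_identity = np.mean([a == b for a, b in zip(rep, copy)])
        # the reported identity is over the trimmed aligned segment, which
        # can only shed flanking mismatches
        assert hits[0].percent_identity >= true_identity - 1e-9
        assert abs(hits[0].percent_identity - true_identity) < 0.02

    def test_truncated_copy_partial_coverage(self):
        rng = np.random.default_rng(4)
        rep, _ = mc.make_mite_family(400, 14, rng)
        frag = rep[: int(0.4 * len(rep))]
        seq = random_dna(1200, 9) + frag + random_dna(1200, 10)
        hits = scan_genome(mc.GenomeAccession("t", {"Chr1": seq}), _reps([rep]))
        assert len(hits) == 1
        assert abs(hits[0].coverage_of_representative - 0.4) < 0.02

    def test_below_thresholds_dropped(self):
        rng = np.random.default_rng(5)
        rep, _ = mc.make_mite_family(300, 14, rng)
        g = mc.GenomeAccession("t", {"Chr1": random_dna(5000, 11)})
        assert scan_genome(g, _reps([rep])) == []

    def test_overlapping_clusters_resolve_to_higher_identity(self):
        rng = np.random.default_rng(6)
        rep, _ = mc.make_mite_family(300, 14, rng)
        similar = _decay(rep, 0.15, 12)  # same locus matches both reps
        seq = random_dna(1000, 13) + rep + random_dna(1000, 14)
        hits = scan_genome(
            mc.GenomeAccession("t", {"Chr1": seq}),
            {"MC0000": (rep, None, "unclassified"),
             "MC0001": (similar, None, "unclassified")},
        )
        assert len(hits) == 1
        assert hits[0].cluster_id == "MC0000"


class TestCategorize:
    def test_planted_categories_recovered(self, small_dataset):
        ds = small_dataset
        tf = ds.truth_frame()
        acc = ds.accession_names[0]
        genome = ds.accessions[acc]
        mites = mc.detect_canonical_mites(genome)
        # representatives straight from the planted consensus truth
        fam_rep = {}
        for t in ds.truth:
            if t.category == "canonical":
                fam_rep.setdefault(t.family_id, t.element_sequence)
        reps = {fid: (seq, None, "unclassified") for fid, seq in fam_rep.items()}
        hits = scan_genome(genome, reps)
        categorize_hits(hits, genome)
        truth = tf[tf.accession == acc]

        def overlapping(r):
            out = [
                h for h in hits
                if h.cluster_id == r.family_id
                and h.interval.chromosome == r.chromosome
                and h.interval.start <= r.end and r.start <= h.interval.end
            ]
            return out[0] if out else None

        n_checked = 0
        for r in truth.itertuples():
            h = overlapping(r)
            if h is None:
                continue
            n_checked += 1
            if r.category == "canonical":
                assert h.category == "canonical"
            elif r.category == "partial" and r.fraction < 0.75:
                assert h.category == "partial"
            elif r.category == "diverse":
                assert h.category == "diverse"
        assert n_checked >= 0.95 * len(truth)

    def test_full_length_copy_with_broken_tsd_is_diverse(self):
        rng = np.random.default_rng(7)
        rep, _ = mc.make_mite_family(300, 14, rng)
        # insert with non-duplicated flanks: no TSD at the locus
        seq = random_dna(1000, 15) + rep + random_dna(1000, 16)
        g = mc.GenomeAccession("t", {"Chr1": seq})
        hits = categorize_hits(scan_genome(g, _reps([rep])), g)
        assert hits[0].category == "diverse"


class TestHomologGroups:
    def test_presence_design_recovered(self, small_dataset):
        ds = small_dataset
        tf = ds.truth_frame()
        fam_rep = {}
        for t in ds.truth:
            if t.category == "canonical":
                fam_rep.setdefault(t.family_id, t.element_sequence)
        reps = {fid: (seq, None, "unclassified") for fid, seq in fam_rep.items()}
        hits_by_acc = {}
        for acc in ds.accession_names:
            g = ds.accessions[acc]
            hits_by_acc[acc] = scan_genome(g, reps)
        groups = build_homolog_groups(hits_by_acc, ds.genes)
        # gene-anchored groups must reproduce the planted presence design
        gene_groups = {
            (g.cluster_id, g.anchor): g for g in groups if g.anchor[0] != "intergenic"
        }
        planted = tf[tf.gene_id != ""]
        for (fam, gene), sub in planted.groupby(["family_id", "gene_id"]):
            present = set(sub.accession)
            matching = [
                g for (cid, anchor), g in gene_groups.items()
                if cid == fam and anchor[0] == gene
            ]
            assert len(matching) == 1
            assert set(matching[0].hits) == present

    def test_two_families_in_one_region_stay_separate(self):
        rng = np.random.default_rng(8)
        rep_a, _ = mc.make_mite_family(200, 12, rng)
        rep_b, _ = mc.make_mite_family(220, 12, rng)
        seq = (random_dna(1000, 20) + rep_a + random_dna(300, 21)
               + rep_b + random_dna(1000, 22))
        g = mc.GenomeAccession("col", {"Chr1": seq})
        hits = scan_genome(g, {"A": (rep_a, None, "u"), "B": (rep_b, None, "u")})
        groups = build_homolog_groups({"col": hits}, {"col": []})
        assert len(groups) == 2


class TestHitRoundtrip:
    def test_frame_roundtrip_preserves_hits(self, small_dataset):
        ds = small_dataset
        acc = ds.accession_names[0]
        fam_rep = {}
        for t in ds.truth:
            fam_rep.setdefault(t.family_id, t.element_sequence)
        reps = {fid: (seq, "famX", "hAT") for fid, seq in fam_rep.items()}
        g = ds.accessions[acc]
        hits = categorize_hits(scan_genome(g, reps), g)
        frame = hits_to_frame(hits)
        back = hits_from_frame(frame)
        assert hits_to_frame(back).equals(frame)
        # categories partition the hit set
        assert all(h.category in ("canonical", "diverse", "partial") for h in back)

    def test_self_consistency_canonical_recovered_at_own_locus(self, small_dataset):
        ds = small_dataset
        acc = ds.accession_names[1]
        g = ds.accessions[acc]
        mites = mc.detect_canonical_mites(g)
        reps = {f"c{i}": (m.sequence, None, "u") for i, m in enumerate(mites)}
        hits = scan_genome(g, reps)
        loci = {(h.interval.chromosome, h.interval.start, h.interval.end): h
                for h in hits}
        for m in mites:
            key = (m.interval.chromosome, m.interval.start, m.interval.end)
            assert key in loci
            assert loci[key].percent_identity >= 0.99
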