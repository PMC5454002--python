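import numpy as np
import pandas as pd
import pytest

import mitecompare as mc
from mitecompare._seq import revcomp
from mitecompare.simulate import (
    MiteFamilyConfig,
    SimulationConfig,
    _materialize_element,
    generate_accession_set,
    make_mite_family,
    plant_insertion,
)


class TestMakeMiteFamily:
    def test_tir_structure(self):
        rng = np.random.default_rng(0)
        seq, (t5, t3) = make_mite_family(289, 14, rng)
        assert len(seq) == 289
        assert seq[:14] == revcomp(seq[-14:])
        assert t5 == seq[:14] and t3 == seq[-14:]

    def test_minimal_element(self):
        rng = np.random.default_rng(1)
        seq, _ = make_mite_family(50, 10, rng)
        assert len(seq) == 50
        assert seq[:10] == revcomp(seq[-10:])

    def test_same_seed_identical(self):
        a, _ = make_mite_family(200, 12, np.random.default_rng(42))
        b, _ = make_mite_family(200, 12, np.random.default_rng(42))
        assert a == b

    def test_infeasible_lengths_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            make_mite_family(40, 10, rng)
        with pytest.raises(ValueError):
            make_mite_family(100, 60, rng)


class TestPlantInsertion:
    def test_tsd_duplicated_on_both_flanks(self):
        seq = "G" * 50 + "TAA" + "C" * 50
        new, iv, tsd = plant_insertion(seq, "ACGTACGTAC", 50, 3)
        assert tsd == "TAA"
        assert new[iv.start - 4 : iv.start - 1] == "TAA"
        assert new[iv.end : iv.end + 3] == "TAA"
        assert new[iv.start - 1 : iv.end] == "ACGTACGTAC"
        # the element interval excludes the TSDs
        assert iv.length == 10

    def test_site_outside_rejected(self):
        with pytest.raises(ValueError):
            plant_insertion("ACGT", "AAA", 10, 2)


class TestMaterialize:
    def _fam(self, decay, trunc=0.5):
        return MiteFamilyConfig(
            family_id="MF001", element_length=200, tir_length=12, tsd_length=3,
            copy_number=3, extra_copies=2, decay_rate=decay,
            truncation_probability=trunc, classified=True, superfamily="hAT",
        )

    def test_diverse_at_zero_decay_identical_to_canonical(self):
        rng = np.random.default_rng(3)
        seq, _ = make_mite_family(200, 12, rng)
        elem, tsd_mut, frac = _materialize_element(
            seq, "diverse", self._fam(0.0), np.random.default_rng(4), 60
        )
        assert elem == seq and tsd_mut == [] and frac == 1.0

    def test_diverse_with_decay_breaks_tir(self):
        rng = np.random.default_rng(5)
        seq, _ = make_mite_family(200, 12, rng)
        elem, tsd_mut, _ = _materialize_element(
            seq, "diverse", self._fam(0.05), np.random.default_rng(6), 60
        )
        assert elem != seq
        assert len(tsd_mut) == 1
        # at least 3 of the first 10 TIR pairs broken
        mismatches = sum(
            1 for i in range(10) if elem[i] != revcomp(elem[-12:])[i]
        )
        assert mismatches >= 3

    def test_partial_fraction_and_floor(self):
        rng = np.random.default_rng(7)
        seq, _ = make_mite_family(200, 12, rng)
        lengths = set()
        for s in range(30):
            elem, _, frac = _materialize_element(
                seq, "partial", self._fam(0.0), np.random.default_rng(s), 60
            )
            assert 60 <= len(elem) <= 200
            assert abs(len(elem) - frac * 200) < 1
            lengths.add(len(elem))
        assert len(lengths) > 5  # fractions actually vary


class TestGenerateAccessionSet:
    def test_seed_determinism_byte_identical(self):
        cfg = SimulationConfig(
            n_accessions=2, chromosome_lengths=(40_000,), n_gene_families=8,
            n_mite_families=2, extra_copies_range=(2, 3), seed=5,
        )
        d1 = generate_accession_set(cfg)
        d2 = generate_accession_set(cfg)
        assert d1.accessions["col"].chromosomes == d2.accessions["col"].chromosomes
        pd.testing.assert_frame_equal(d1.truth_frame(), d2.truth_frame())
        pd.testing.assert_frame_equal(d1.expression.frame, d2.expression.frame)

    def test_truth_and_outputs_consistent(self, small_dataset):
        ds = small_dataset
        # every planted element has exactly one truth record per carrier
        tf = ds.truth_frame()
        assert not tf.duplicated(["accession", "insertion_id"]).any()
        for t in ds.truth[::7]:
            assert ds.accessions[t.accession].sequence(t.interval) == t.element_sequence
            # left flank carries the TSD
            chrom = ds.accessions[t.accession].chromosomes[t.interval.chromosome]
            k = len(t.tsd_sequence)
            assert chrom[t.interval.start - 1 - k : t.interval.start - 1] == t.tsd_sequence

    def test_gene_models_shared_ids_and_valid_subregions(self, small_dataset):
        ds = small_dataset
        ids = {acc: {g.gene_id for g in genes} for acc, genes in ds.genes.items()}
        first = next(iter(ids.values()))
        assert all(s == first for s in ids.values())
        for genes in ds.genes.values():
            for g in genes[::5]:
                for _, iv in g.subregions():
                    assert g.locus.start <= iv.start <= iv.end <= g.locus.end

    def test_relation_placements_verified_against_gene_models(self, small_dataset):
        ds = small_dataset
        genes_by = {
            acc: {g.gene_id: g for g in genes} for acc, genes in ds.genes.items()
        }
        for t in ds.truth:
            if t.relation == "intron":
                gene = genes_by[t.accession][t.associated_gene_id]
                assert any(
                    iv.start <= t.interval.start and t.interval.end <= iv.end
                    for iv in gene.introns
                )
            elif t.relation == "last-exon-spanning":
                gene = genes_by[t.accession][t.associated_gene_id]
                last = gene.last_exon
                utr3 = gene.three_prime_utr[0]
                assert t.interval.overlaps(last) and t.interval.overlaps(utr3)
            elif t.relation == "upstream":
                gene = genes_by[t.accession][t.associated_gene_id]
                assert 0 < t.interval.distance_to(gene.locus) <= 40

    def test_full_presence_gives_single_sharing_class(self):
        cfg = SimulationConfig(
            n_accessions=3, chromosome_lengths=(60_000,), n_gene_families=12,
            n_mite_families=2, presence_probability=1.0,
            extra_copies_range=(2, 3), seed=9,
        )
        ds = generate_accession_set(cfg)
        tf = ds.truth_frame()
        gene_assoc = tf[tf.gene_id != ""]
        k = gene_assoc.groupby(["gene_id"]).accession.nunique()
        assert (k == 3).all()

    def test_expression_effect_applied_to_associated_pairs(self, small_dataset):
        ds = small_dataset
        tf = ds.truth_frame()
        assoc = tf[tf.gene_id != ""]
        with_vals = []
        without_vals = []
        pairs = {(r.gene_id, r.accession) for r in assoc.itertuples()}
        for gene in assoc.gene_id.unique():
            for acc in ds.accession_names:
                v = ds.expression.value(gene, acc)
                (with_vals if (gene, acc) in pairs else without_vals).append(v)
        if with_vals and without_vals:
            assert np.mean(np.log(with_vals)) > np.mean(np.log(without_vals))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(presence_probability=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(decay_rate=1.0)
        with pytest.raises(ValueError):
            MiteFamilyConfig(
                family_id="x", element_length=900, tir_length=10, tsd_length=3,
                copy_number=3, extra_copies=0, decay_rate=0.0,
                truncation_probability=0.0, classified=True, superfamily="hAT",
            )

    def test_library_covers_classified_subset(self, small_dataset):
        ds = small_dataset
        n_classified = int(round(
            ds.config.classified_fraction * ds.config.n_mite_families
        ))
        assert len(ds.library) == n_classified
        assert all(r["superfamily"] for r in ds.library)
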