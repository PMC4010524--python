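import numpy as np
import pytest

import enrichmeta as em
from enrichmeta.binning import UNASSIGNED


def _contig(cid, length, base="A"):
    return em.SeqRecord(id=cid, sequence=base * length)


def _genes(cid, n, label="T", length=500):
    return [
        em.GeneCall(cid, i * (length + 10), i * (length + 10) + length, "+", label, gene_id=f"{cid}_g{i}")
        for i in range(n)
    ]


class TestFilterContigs:
    def test_length_boundary_inclusive_at_5kb(self):
        contigs = [_contig("short", 4999), _contig("kept", 5000)]
        genes = _genes("short", 3) + _genes("kept", 3)
        retained, report = em.filter_contigs(contigs, genes)
        assert [c.id for c in retained] == ["kept"]
        assert report.n_below_min_len == 1

    def test_fewer_than_three_genes_discarded(self):
        contigs = [_contig("c", 6000)]
        retained, report = em.filter_contigs(contigs, _genes("c", 2))
        assert retained == []
        assert report.n_below_min_genes == 1

    def test_empty_input(self):
        retained, report = em.filter_contigs([], [])
        assert retained == [] and report.n_input == 0

    def test_rule_order_independence(self):
        """Applying the length rule then the gene rule equals the reverse order."""
        contigs = [
            _contig("a", 4000), _contig("b", 8000), _contig("c", 5000), _contig("d", 9000)
        ]
        genes = _genes("a", 5) + _genes("b", 1) + _genes("c", 3)
        both, _ = em.filter_contigs(contigs, genes)
        by_len = [c for c in contigs if len(c.sequence) >= 5000]
        then_genes, _ = em.filter_contigs(by_len, genes, min_len=0)
        by_genes, _ = em.filter_contigs(contigs, genes, min_len=0)
        then_len = [c for c in by_genes if len(c.sequence) >= 5000]
        assert [c.id for c in both] == [c.id for c in then_genes] == [c.id for c in then_len]


class TestTaxonomicUniformity:
    def test_all_agree(self):
        c = _contig("c", 2000)
        genes = _genes("c", 3, label="Thaumarchaeota")
        assert em.taxonomic_uniformity(c, genes) == "Thaumarchaeota"

    def test_conflict_unassigned_in_strict_mode(self):
        c = _contig("c", 2000)
        genes = _genes("c", 2, "Thaumarchaeota") + _genes("c2", 1, "Epsilonproteobacteria")
        for g in genes:
            g.contig_id = "c"
        assert em.taxonomic_uniformity(c, genes) == UNASSIGNED

    def test_tolerant_mode_accepts_majority(self):
        c = _contig("c", 2000)
        genes = _genes("c", 3, "Thaumarchaeota") + _genes("c2", 1, "Epsilonproteobacteria")
        assert em.taxonomic_uniformity(c, genes, min_agreement=0.7) == "Thaumarchaeota"

    def test_all_unknown_unassigned(self):
        c = _contig("c", 2000)
        assert em.taxonomic_uniformity(c, _genes("c", 2, "unknown")) == UNASSIGNED

    def test_no_genes_warns_and_unassigns(self):
        with pytest.warns(UserWarning, match="no gene calls"):
            assert em.taxonomic_uniformity(_contig("c", 2000), []) == UNASSIGNED


def _projected(ds, contigs=None):
    contigs = contigs if contigs is not None else ds.contigs
    profiles = em.profile_contigs(contigs)
    projections, _, _ = em.pca_project(profiles, n_components=2)
    return profiles, projections


class TestAssignBins:
    def test_single_cluster_holds_everything(self, community_dataset):
        contigs = community_dataset.contigs[:20]
        profiles, projections = _projected(community_dataset, contigs)
        labels = {c.id: community_dataset.truth.contig_taxon[c.id] for c in contigs}
        (bin_,) = em.assign_bins(projections, profiles, labels, n_clusters=1, seed=0)
        assert sorted(bin_.contig_ids) == sorted(c.id for c in contigs)

    def test_rerun_same_seed_identical(self, community_dataset):
        profiles, projections = _projected(community_dataset)
        labels = community_dataset.truth.contig_taxon
        a = em.assign_bins(projections, profiles, labels, 3, seed=5)
        b = em.assign_bins(projections, profiles, labels, 3, seed=5)
        assert [x.contig_ids for x in a] == [x.contig_ids for x in b]

    def test_k_exceeding_contigs_rejected(self, community_dataset):
        profiles, projections = _projected(community_dataset, community_dataset.contigs[:4])
        with pytest.raises(ValueError, match="exceeds"):
            em.assign_bins(projections, profiles, {}, n_clusters=5)

    def test_noise_free_labels_give_pure_bins(self, community_dataset):
        """With exact gene labels every cluster is taxonomically pure."""
        ds = community_dataset
        profiles, projections = _projected(ds)
        labels = ds.truth.contig_taxon
        bins = em.assign_bins(projections, profiles, labels, 3, seed=0)
        for b in bins:
            assert b.flagged == []
            assert {labels[cid] for cid in b.contig_ids} == {b.taxon_label}


class TestBinStats:
    def test_coding_percent_arithmetic(self):
        contigs = {"c": _contig("c", 10_000)}
        genes = [em.GeneCall("c", 0, 9_000, "+", "T", gene_id="g")]
        b = em.GenomeBin("b0", "T", ["c"])
        stats = em.bin_stats(b, contigs, genes, {"c": 10.0})
        assert stats.coding_percent == pytest.approx(90.0)
        assert stats.n_genes == 1 and stats.n_contigs == 1

    def test_length_weighted_gc(self):
        ten = em.SeqRecord("a", "G" * 3000 + "A" * 7000)  # GC 0.30, 10 kb
        thirty = em.SeqRecord("b", "G" * 12_000 + "A" * 18_000)  # GC 0.40, 30 kb
        b = em.GenomeBin("b0", "T", ["a", "b"])
        stats = em.bin_stats(b, {"a": ten, "b": thirty}, [], {"a": 1.0, "b": 2.0})
        assert stats.avg_gc_percent == pytest.approx(37.5)
        assert stats.coverage_x == pytest.approx((1.0 * 10 + 2.0 * 30) / 40)

    def test_size_is_sum_of_member_lengths(self):
        contigs = {f"c{i}": _contig(f"c{i}", 110_000) for i in range(15)}
        b = em.GenomeBin("b0", "T", list(contigs))
        stats = em.bin_stats(b, contigs, [], {k: 1.0 for k in contigs})
        assert stats.size_mbp == pytest.approx(1.65)
        assert stats.n_contigs == 15
        assert stats.avg_contig_kb == pytest.approx(110.0)

    def test_empty_bin_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            em.bin_stats(em.GenomeBin("b0", "T", []), {}, [], {})


def test_bin_sizes_partition_retained_length(community_dataset):
    """When every contig is assigned, bin sizes sum to the total length."""
    ds = community_dataset
    profiles, projections = _projected(ds)
    bins = em.assign_bins(projections, profiles, ds.truth.contig_taxon, 3, seed=0)
    total = sum(len(c.sequence) for c in ds.contigs)
    contig_map = {c.id: c for c in ds.contigs}
    binned = sum(
        len(contig_map[cid].sequence) for b in bins for cid in b.contig_ids
    )
    assert binned == total
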