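import numpy as np
import pytest

import enrichmeta as em
from enrichmeta.synthetic import ConfigurationError


def _uniform_model(length=100_000, order=2):
    n_ctx = 4**order
    return em.TaxonModel(
        name="uniform", gc_target=0.5, genome_length=length, markov_order=order,
        transition_weights=np.full((n_ctx, 4), 0.25),
    )


class TestGenerateGenome:
    def test_equal_weights_gc_near_half(self):
        genome = em.generate_genome(_uniform_model(), seed=7)
        assert len(genome) == 100_000
        assert 0.48 <= em.compute_gc(genome) <= 0.52

    def test_degenerate_weights_all_g(self):
        w = np.zeros((16, 4))
        w[:, 2] = 1.0  # G only
        model = em.TaxonModel("gonly", 1.0, 10_000, 2, w)
        genome = em.generate_genome(model, seed=1)
        assert genome == "G" * 10_000

    def test_deterministic_given_seed(self):
        m = _uniform_model(12_000)
        assert em.generate_genome(m, seed=5) == em.generate_genome(m, seed=5)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigurationError, match="sum to 1"):
            em.TaxonModel("bad", 0.5, 10_000, 1, np.full((4, 4), 0.3))
        with pytest.raises(ConfigurationError, match="negative"):
            w = np.full((4, 4), 0.25)
            w[0] = [1.5, -0.5, 0, 0]
            em.TaxonModel("bad", 0.5, 10_000, 1, w)

    @pytest.mark.parametrize("gc", [0.34, 0.43, 0.53])
    def test_realized_gc_within_two_points_of_target(self, gc):
        m = em.TaxonModel.with_signature("t", gc, 100_000, signature_seed=4)
        genome = em.generate_genome(m, seed=2)
        assert abs(em.compute_gc(genome) - gc) <= 0.02


class TestMutateGenome:
    def test_zero_rate_is_identity(self):
        g = em.generate_genome(_uniform_model(10_000), seed=1)
        mutated, n = em.mutate_genome(g, 0.0, seed=2)
        assert mutated == g and n == 0

    def test_rate_one_changes_every_base(self):
        g = em.generate_genome(_uniform_model(10_000), seed=1)
        mutated, n = em.mutate_genome(g, 1.0, seed=2)
        assert n == len(g)
        assert all(a != b for a, b in zip(g, mutated))

    def test_realized_fraction_matches_rate(self):
        g = em.generate_genome(_uniform_model(200_000), seed=3)
        mutated, n = em.mutate_genome(g, 0.05, seed=4)
        assert len(mutated) == len(g)
        assert 0.047 <= n / len(g) <= 0.053  # 99.9% binomial interval
        assert sum(a != b for a, b in zip(g, mutated)) == n


class TestPlantIslands:
    def test_empty_plan_is_identity(self):
        g = em.generate_genome(_uniform_model(20_000), seed=1)
        out, coords = em.plant_islands(g, [], seed=2)
        assert out == g and coords == []

    def test_island_length_bookkeeping(self):
        host = em.TaxonModel.with_signature("host", 0.34, 200_000, signature_seed=1)
        donor = em.TaxonModel.with_signature("donor", 0.60, 200_000, signature_seed=2)
        g = em.generate_genome(host, seed=3)
        out, coords = em.plant_islands(g, [(20_000, donor)], seed=4)
        assert len(out) == len(g)
        (s, e), = coords
        assert e - s == 20_000
        # outside the island the host genome is untouched
        assert out[:s] == g[:s] and out[e:] == g[e:]

    def test_high_gc_donor_island_raises_window_gc(self):
        host = em.TaxonModel.with_signature("host", 0.34, 200_000, signature_seed=1)
        donor = em.TaxonModel.with_signature("donor", 0.60, 200_000, signature_seed=2)
        g = em.generate_genome(host, seed=3)
        out, ((s, e),) = em.plant_islands(g, [(20_000, donor)], seed=4)
        island_gc = em.compute_gc(out[s:e])
        flank = (out[max(0, s - 20_000) : s] + out[e : e + 20_000]) or out[:20_000]
        assert island_gc > em.compute_gc(flank)

    def test_oversized_plan_rejected(self):
        donor = em.TaxonModel.with_signature("donor", 0.60, 200_000, signature_seed=2)
        g = em.generate_genome(_uniform_model(20_000), seed=1)
        with pytest.raises(ConfigurationError, match="50%"):
            em.plant_islands(g, [(10_000, donor), (5_000, donor)], seed=2)


class TestShredAndSample:
    def test_single_taxon_community_labels(self):
        t = em.TaxonModel.with_signature("Solo", 0.40, 50_000, signature_seed=1)
        spec = em.CommunitySpec(taxa=[t], abundances=[1.0], n_contigs=10)
        ds = em.shred_and_sample(spec, seed=3, n_reads=50)
        assert set(ds.truth.contig_taxon.values()) == {"Solo"}
        assert all(g.taxon_label == "Solo" for g in ds.gene_calls)

    def test_zero_label_noise_means_true_labels(self, community_dataset):
        truth = community_dataset.truth.contig_taxon
        assert all(g.taxon_label == truth[g.contig_id] for g in community_dataset.gene_calls)

    def test_bad_abundances_rejected(self):
        t = em.TaxonModel.with_signature("Solo", 0.40, 50_000, signature_seed=1)
        with pytest.raises(ConfigurationError, match="abundances"):
            em.CommunitySpec(taxa=[t], abundances=[0.9])

    def test_water_column_reads_never_overlap_islands(self):
        donor = em.TaxonModel.with_signature("donor", 0.60, 60_000, signature_seed=2)
        spec = em.default_community(genome_length=60_000, n_contigs=30)
        spec.island_plan = [("Thaumarchaeota", 20_000, donor)]
        ds = em.shred_and_sample(spec, seed=5, n_reads=2000, water_column=True)
        islands = ds.truth.islands["Thaumarchaeota"]
        assert len(islands) == 1
        for rid, (taxon, start, end) in ds.truth.read_source.items():
            if taxon == "Thaumarchaeota":
                assert all(end <= s or start >= e for s, e in islands), rid

    def test_determinism_byte_identical(self, tmp_path):
        spec = em.default_community(genome_length=40_000, n_contigs=12)
        a = em.shred_and_sample(spec, seed=9, n_reads=40)
        b = em.shred_and_sample(spec, seed=9, n_reads=40)
        for out, ds in ((tmp_path / "a.fa", a), (tmp_path / "b.fa", b)):
            em.write_fasta(ds.contigs + ds.reads, out)
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_gc_separability_follows_targets(self, community_dataset):
        ds = community_dataset
        by_taxon = {}
        for c in ds.contigs:
            by_taxon.setdefault(ds.truth.contig_taxon[c.id], []).append(em.compute_gc(c.sequence))
        means = {t: np.mean(v) for t, v in by_taxon.items()}
        assert means["Thaumarchaeota"] < means["Epsilonproteobacteria"] < means["Gammaproteobacteria"]


def test_tile_gene_intervals_are_codon_sized_and_disjoint():
    intervals = em.tile_gene_intervals(50_000, seed=3)
    assert intervals
    for (s, e), (s2, _) in zip(intervals, intervals[1:]):
        assert e <= s2
    assert all((e - s) % 3 == 0 for s, e in intervals)
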