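from types import SimpleNamespace

import pytest

import enrichmeta as em


@pytest.fixture(scope="session")
def community_dataset():
    """Three-taxon community (GC 34/43/53%), ~300 contigs, known truth."""
    spec = em.default_community(genome_length=150_000, n_contigs=300)
    return em.shred_and_sample(spec, seed=101, n_reads=300, water_column=True)


@pytest.fixture(scope="session")
def island_fixture():
    """Host genome with one planted 20 kb donor-composition island and a
    20x water-column read pool that excludes the island."""
    host = em.TaxonModel.with_signature("Thaumarchaeota", 0.34, 120_000, signature_seed=11)
    donor = em.TaxonModel.with_signature("Gammaproteobacteria", 0.53, 120_000, signature_seed=13)
    genome = em.generate_genome(host, seed=21)
    genome, islands = em.plant_islands(genome, [(20_000, donor)], seed=22)
    n_reads = round(20 * len(genome) / 280)
    reads, _ = em.sample_reads(
        {"host": genome}, {"host": 1.0}, n_reads,
        read_length_mean=280, read_length_sd=12.0, seed=23,
        exclude={"host": islands},
    )
    profile = em.recruit(reads, genome, genome_id="host")
    return SimpleNamespace(
        genome=genome, islands=islands, reads=reads, profile=profile,
        host=host, donor=donor,
    )
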