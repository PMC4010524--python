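"""Pipeline configuration: every tunable threshold with its documented
domain, loadable from YAML with strict validation (unknown keys rejected).
"""

from __future__ import annotations

import os

import yaml
from pydantic import BaseModel, ConfigDict, Field


class PipelineConfig(BaseModel):
    """All pipeline thresholds and synthetic-community parameters.

    Defaults are the pipeline's standard operating point: the 5 kb /
    3-gene contig filter, tetranucleotide profiles, 50%/70% alignment
    cutoffs, the 94% ANI species boundary, >15 kb islands and the
    100-base / 95% rRNA rules.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    outdir: str = "enrichmeta_out"

    # input paths (optional; the synthetic generator fills them for `all`)
    contigs_fasta: str | None = None
    reads_fasta: str | None = None
    genes_gff3: str | None = None
    rrna_refs_fasta: str | None = None

    # contig filter
    min_len: int = Field(5000, ge=0)
    min_genes: int = Field(3, ge=0)
    min_agreement: float = Field(1.0, gt=0.0, le=1.0)

    # composition / binning
    k: int = Field(4, ge=1, le=8)
    n_components: int = Field(2, ge=1)
    n_clusters: int = Field(3, ge=1)

    # ANI
    frag_len: int = Field(1020, ge=100)
    ani_min_identity: float = Field(50.0, ge=0.0, le=100.0)
    ani_min_cov: float = Field(0.7, gt=0.0, le=1.0)
    species_cutoff: float = Field(94.0, ge=0.0, le=100.0)

    # recruitment / islands
    recruit_min_identity: float = Field(50.0, ge=0.0, le=100.0)
    recruit_min_cov: float = Field(0.7, gt=0.0, le=1.0)
    recruit_window: int = Field(1000, ge=100)
    recruit_step: int = Field(500, ge=1)
    island_min_len: int = Field(15_000, ge=0)
    island_density_ratio: float = Field(0.2, gt=0.0, lt=1.0)
    island_merge_gap: int = Field(2000, ge=0)
    skew_window: int = Field(25_000, ge=100)
    skew_step: int = Field(1000, ge=1)

    # rRNA classification
    rrna_min_aln_len: int = Field(100, ge=0)
    rrna_genus_identity: float = Field(95.0, ge=0.0, le=100.0)
    rrna_floor_identity: float = Field(80.0, ge=0.0, le=100.0)

    # synthetic community (used by `simulate` / `all`)
    genome_length: int = Field(120_000, ge=10_000)
    n_contigs: int = Field(120, ge=2)
    n_reads: int = Field(2000, ge=1)
    read_length_mean: int = Field(280, ge=50)
    signature_strength: float = Field(0.5, ge=0.0, le=1.0)
    label_noise: float = Field(0.0, ge=0.0, lt=1.0)
    island_length: int = Field(20_000, ge=0)
    divergence: float = Field(0.05, ge=0.0, lt=0.3)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)
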