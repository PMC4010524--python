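"""Synthetic enrichment-community generator with known ground truth.

Emulates a three-taxon enrichment culture (an archaeal low-GC genome, an
epsilonproteobacterial mid-GC genome and a gammaproteobacterial high-GC
genome) in which every downstream stage — composition binning, ANI between
strain pairs, fragment recruitment and island calling, 16S read
classification — can be checked against planted truth:

* genomes are order-``m`` Markov chains whose per-context emission weights
  carry a taxon-specific oligonucleotide signature;
* the signature redistributes probability only within {A,T} and within
  {G,C}, so P(G or C) equals ``gc_target`` in every context and realized
  genome GC is a plain binomial around the target;
* strain pairs are created by independent per-site substitution at a known
  rate ``d``;
* genomic islands are segments generated from a donor taxon model and
  spliced into a host genome; a "water-column" read pool is drawn from the
  genomes *excluding* island intervals, so islands are depleted in
  recruitment by construction.

No sequencing-error model, no paired ends, no chimeras: contigs are exact
genome substrings, which is what makes planted truth exactly recoverable.
"""

from __future__ import annotations

import math
import zlib
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np

from .seqio import GeneCall, SeqRecord

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}


class ConfigurationError(ValueError):
    pass


class PlacementError(RuntimeError):
    """Raised when requested islands cannot be placed without overlap."""


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


def _stable_hash(name: str) -> int:
    """Process-independent hash for deriving per-taxon random substreams."""
    return zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# taxon models


@dataclass
class TaxonModel:
    """Order-``markov_order`` Markov model of a genome's composition."""

    name: str
    gc_target: float
    genome_length: int
    markov_order: int = 2
    transition_weights: np.ndarray | None = None  # (4^order, 4), rows sum to 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_target <= 1.0):
            raise ConfigurationError(f"{self.name}: gc_target {self.gc_target} not in [0,1]")
        if self.markov_order < 0:
            raise ConfigurationError(f"{self.name}: markov_order must be >= 0")
        n_ctx = 4**self.markov_order
        if self.transition_weights is None:
            p = self._base_probs()
            self.transition_weights = np.tile(p, (n_ctx, 1))
        self.transition_weights = np.asarray(self.transition_weights, dtype=float)
        if self.transition_weights.shape != (n_ctx, 4):
            raise ConfigurationError(
                f"{self.name}: transition_weights shape {self.transition_weights.shape}, "
                f"expected {(n_ctx, 4)}"
            )
        if np.any(self.transition_weights < 0):
            raise ConfigurationError(f"{self.name}: negative transition weights")
        sums = self.transition_weights.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ConfigurationError(f"{self.name}: transition weight rows must sum to 1")

    def _base_probs(self) -> np.ndarray:
        gc = self.gc_target
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T

    @classmethod
    def with_signature(
        cls,
        name: str,
        gc_target: float,
        genome_length: int,
        markov_order: int = 2,
        signature_strength: float = 0.5,
        signature_seed: int = 0,
    ) -> "TaxonModel":
        """Build a model whose contexts carry a taxon-specific k-mer signature.

        Per context, a fraction of up to ``signature_strength`` of the A/T
        mass is shifted between A and T, and likewise between G and C, so
        GC content is untouched while short-word structure becomes
        taxon-specific.  ``signature_strength`` near 0 gives a marginal,
        stress-test signature; the default separates taxa comfortably.
        """
        if not (0.0 <= signature_strength <= 1.0):
            raise ConfigurationError("signature_strength must be in [0,1]")
        n_ctx = 4**markov_order
        rng = _rng(signature_seed, _stable_hash(name))
        gc = gc_target
        at_half, gc_half = (1 - gc) / 2, gc / 2
        W = np.empty((n_ctx, 4))
        delta_at = rng.uniform(-signature_strength, signature_strength, n_ctx) * at_half
        delta_gc = rng.uniform(-signature_strength, signature_strength, n_ctx) * gc_half
        W[:, 0] = at_half + delta_at  # A
        W[:, 3] = at_half - delta_at  # T
        W[:, 1] = gc_half + delta_gc  # C
        W[:, 2] = gc_half - delta_gc  # G
        return cls(
            name=name,
            gc_target=gc_target,
            genome_length=genome_length,
            markov_order=markov_order,
            transition_weights=W,
        )


def generate_genome(model: TaxonModel, seed: int) -> str:
    """Sample a genome of exactly ``model.genome_length`` bases from the model."""
    L = model.genome_length
    if L < 10_000:
        raise ConfigurationError(f"{model.name}: genome_length {L} < 10 kb")
    rng = _rng(seed, 1)
    W = model.transition_weights
    cum = np.cumsum(W, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    m = model.markov_order
    u = rng.random(L).tolist()
    rows = [row.tolist() for row in cum]
    out = bytearray(L)
    ctx = 0
    mod = 4**m if m > 0 else 1
    bases = b"ACGT"
    for i in range(L):
        b = bisect_right(rows[ctx], u[i])
        if b > 3:
            b = 3
        out[i] = bases[b]
        if m > 0:
            ctx = (ctx * 4 + b) % mod
    return out.decode("ascii")


def mutate_genome(genome: str, d: float, seed: int) -> tuple[str, int]:
    """Substitute each site independently with probability ``d``.

    Substituted sites receive a uniformly chosen *different* base.  Returns
    the mutated sequence and the realized substitution count.
    """
    if not (0.0 <= d <= 1.0):
        raise ConfigurationError(f"substitution probability {d} not in [0,1]")
    codes = np.frombuffer(genome.encode("ascii"), dtype=np.uint8).copy()
    code_map = np.zeros(256, dtype=np.int8)
    for b, i in _CODE.items():
        code_map[ord(b)] = i
    idx = code_map[codes]
    rng = _rng(seed, 2)
    mask = rng.random(len(genome)) < d
    n_sub = int(mask.sum())
    offsets = rng.integers(1, 4, size=n_sub)
    new_idx = idx.copy()
    new_idx[mask] = (idx[mask] + offsets) % 4
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[new_idx.astype(np.intp)].tobytes().decode("ascii"), n_sub


def plant_islands(
    genome: str,
    plan: list[tuple[int, TaxonModel]],
    seed: int,
    max_tries: int = 200,
) -> tuple[str, list[tuple[int, int]]]:
    """Splice donor-composition segments into a host genome.

    ``plan`` is a list of (island_length, donor model) requests.  Island
    segments are generated from the donor's Markov model and replace host
    segments at random non-overlapping positions.  Returns the modified
    genome and the 0-based half-open island coordinates, in genome order.
    """
    L = len(genome)
    total = sum(length for length, _ in plan)
    if total >= L // 2:
        raise ConfigurationError(f"total island length {total} >= 50% of genome {L}")
    for length, _ in plan:
        if length <= 0:
            raise ConfigurationError("island lengths must be positive")
    rng = _rng(seed, 3)
    placed: list[tuple[int, int]] = []
    out = genome
    for k, (length, donor) in enumerate(plan):
        ok = False
        for _ in range(max_tries):
            start = int(rng.integers(0, L - length + 1))
            iv = (start, start + length)
            if all(iv[1] <= s or iv[0] >= e for s, e in placed):
                ok = True
                break
        if not ok:
            raise PlacementError(f"could not place island {k} of length {length}")
        donor_model = TaxonModel(
            name=donor.name,
            gc_target=donor.gc_target,
            genome_length=max(length, 10_000),
            markov_order=donor.markov_order,
            transition_weights=donor.transition_weights,
        )
        segment = generate_genome(donor_model, seed=int(rng.integers(0, 2**31)))[:length]
        out = out[: iv[0]] + segment + out[iv[1] :]
        placed.append(iv)
    return out, sorted(placed)


# ---------------------------------------------------------------------------
# community spec and sampling


@dataclass
class CommunitySpec:
    """Parameters of the synthetic enrichment community.

    Defaults follow the study conditions being emulated: three taxa at
    GC 34/43/53% with distinct order-2 signatures, ~280 bp reads
    (enrichment pyrosequencing scale), log-normal contig lengths with a
    20 kb median truncated to [1 kb, 200 kb].
    """

    taxa: list[TaxonModel]
    abundances: list[float]
    read_length_mean: int = 280
    read_length_sd: float = 12.0
    contig_length_median: int = 20_000
    contig_length_sigma: float = 0.7
    contig_length_min: int = 1_000
    contig_length_max: int = 200_000
    n_contigs: int = 300
    gene_length_mean: float = 800.0
    gene_length_sd: float = 150.0
    label_noise: float = 0.0
    island_plan: list[tuple[str, int, TaxonModel]] = field(default_factory=list)
    divergence_plan: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.abundances):
            raise ConfigurationError("taxa and abundances must have equal length")
        if abs(sum(self.abundances) - 1.0) > 1e-8:
            raise ConfigurationError(f"abundances sum to {sum(self.abundances)}, not 1")
        names = {t.name for t in self.taxa}
        for host, length, _donor in self.island_plan:
            if host not in names:
                raise ConfigurationError(f"island host {host!r} not in community")
            if length <= 0:
                raise ConfigurationError("island lengths must be > 0")
        for name, d in self.divergence_plan:
            if name not in names:
                raise ConfigurationError(f"divergence taxon {name!r} not in community")
            if not (0.0 <= d < 0.3):
                raise ConfigurationError(f"divergence {d} not in [0, 0.3)")


def default_community(
    genome_length: int = 200_000,
    signature_strength: float = 0.5,
    **overrides,
) -> CommunitySpec:
    """The default three-taxon community (GC 34 / 43 / 53%)."""
    taxa = [
        TaxonModel.with_signature("Thaumarchaeota", 0.34, genome_length, signature_seed=11),
        TaxonModel.with_signature("Epsilonproteobacteria", 0.43, genome_length, signature_seed=12),
        TaxonModel.with_signature("Gammaproteobacteria", 0.53, genome_length, signature_seed=13),
    ]
    for t in taxa:
        if signature_strength != 0.5:
            t.transition_weights = TaxonModel.with_signature(
                t.name, t.gc_target, genome_length,
                signature_strength=signature_strength,
                signature_seed={"Thaumarchaeota": 11, "Epsilonproteobacteria": 12,
                                "Gammaproteobacteria": 13}[t.name],
            ).transition_weights
    return CommunitySpec(taxa=taxa, abundances=[0.6, 0.2, 0.2], **overrides)


@dataclass
class GroundTruth:
    contig_taxon: dict[str, str] = field(default_factory=dict)
    islands: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    strain_divergence: dict[str, tuple[float, int]] = field(default_factory=dict)  # planted d, realized subs
    read_source: dict[str, tuple[str, int, int]] = field(default_factory=dict)  # taxon, start, end
    contig_span: dict[str, tuple[str, int, int]] = field(default_factory=dict)  # genome, start, end


@dataclass
class SyntheticDataset:
    spec: CommunitySpec
    genomes: dict[str, str]
    strain_genomes: dict[str, str]
    contigs: list[SeqRecord]
    depths: dict[str, float]
    gene_calls: list[GeneCall]
    reads: list[SeqRecord]
    truth: GroundTruth


def sample_reads(
    genomes: dict[str, str],
    abundances: dict[str, float],
    n_reads: int,
    read_length_mean: int,
    read_length_sd: float,
    seed: int,
    exclude: dict[str, list[tuple[int, int]]] | None = None,
    id_prefix: str = "read",
) -> tuple[list[SeqRecord], dict[str, tuple[str, int, int]]]:
    """Draw reads uniformly from genomes in proportion to abundance.

    With ``exclude`` (per-genome interval lists) no sampled read overlaps an
    excluded interval — the "water-column" pool that lacks the islands.
    """
    rng = _rng(seed, 4)
    names = sorted(genomes)
    probs = np.array([abundances[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    counts = rng.multinomial(n_reads, probs)
    reads: list[SeqRecord] = []
    source: dict[str, tuple[str, int, int]] = {}
    i = 0
    for name, cnt in zip(names, counts):
        genome = genomes[name]
        forbidden = sorted((exclude or {}).get(name, []))
        for _ in range(cnt):
            for _attempt in range(1000):
                length = int(np.clip(round(rng.normal(read_length_mean, read_length_sd)),
                                     50, len(genome)))
                start = int(rng.integers(0, len(genome) - length + 1))
                end = start + length
                if all(end <= s or start >= e for s, e in forbidden):
                    break
            else:
                raise PlacementError(f"cannot sample read avoiding islands in {name}")
            rid = f"{id_prefix}{i}"
            reads.append(SeqRecord(id=rid, sequence=genome[start:end]))
            source[rid] = (name, start, end)
            i += 1
    return reads, source


def _sample_gene_calls(
    contig: SeqRecord,
    taxon: str,
    all_taxa: list[str],
    spec: CommunitySpec,
    rng: np.random.Generator,
) -> list[GeneCall]:
    calls = []
    pos = int(rng.integers(0, 120))
    gi = 0
    while pos < len(contig.sequence) - 200:
        length = int(np.clip(round(rng.normal(spec.gene_length_mean, spec.gene_length_sd)),
                             200, 2000))
        end = min(pos + length, len(contig.sequence))
        label = taxon
        if spec.label_noise > 0 and rng.random() < spec.label_noise:
            others = [t for t in all_taxa if t != taxon]
            label = others[int(rng.integers(0, len(others)))]
        calls.append(
            GeneCall(
                contig_id=contig.id,
                start=pos,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                taxon_label=label,
                gene_id=f"{contig.id}_g{gi}",
            )
        )
        gi += 1
        pos = end + int(rng.integers(30, 150))
    return calls


def tile_gene_intervals(
    length: int,
    seed: int,
    mean: float = 800.0,
    sd: float = 150.0,
    gap_min: int = 30,
    gap_max: int = 150,
) -> list[tuple[int, int]]:
    """Non-overlapping synthetic gene intervals tiling a sequence of ``length``.

    Gene lengths are rounded to multiples of 3 so every interval holds whole
    codons.  Stand-in for gene prediction, which is outside this pipeline.
    """
    rng = _rng(seed, 8)
    intervals: list[tuple[int, int]] = []
    pos = int(rng.integers(0, 120))
    while pos < length - 200:
        glen = int(np.clip(round(rng.normal(mean, sd)), 200, 2000))
        glen -= glen % 3
        end = min(pos + glen, length)
        end -= (end - pos) % 3
        if end > pos:
            intervals.append((pos, end))
        pos = end + int(rng.integers(gap_min, gap_max))
    return intervals


def shred_and_sample(
    spec: CommunitySpec,
    seed: int,
    n_reads: int = 2000,
    water_column: bool = True,
    depth_scale: float = 30.0,
) -> SyntheticDataset:
    """Generate genomes, strain pairs, contigs, gene calls and a read pool.

    Contigs are exact substrings of the (island-bearing) genomes, allocated
    to taxa in proportion to abundance, each carrying a depth proportional
    to its taxon's abundance.  The read pool excludes planted island
    intervals when ``water_column`` is true.  Everything is deterministic
    given ``seed``.
    """
    truth = GroundTruth()
    genomes: dict[str, str] = {}
    rng = _rng(seed, 5)

    for t in spec.taxa:
        g = generate_genome(t, seed=int(_rng(seed, 6, _stable_hash(t.name)).integers(0, 2**31)))
        plan = [(length, donor) for host, length, donor in spec.island_plan if host == t.name]
        if plan:
            g, coords = plant_islands(g, plan, seed=int(rng.integers(0, 2**31)))
            truth.islands[t.name] = coords
        else:
            truth.islands[t.name] = []
        genomes[t.name] = g

    strain_genomes: dict[str, str] = {}
    for name, d in spec.divergence_plan:
        mutated, n_sub = mutate_genome(genomes[name], d, seed=int(rng.integers(0, 2**31)))
        strain_genomes[f"{name}_strain"] = mutated
        truth.strain_divergence[name] = (d, n_sub)

    # contigs per taxon in proportion to abundance
    n_per = np.maximum(1, np.round(np.array(spec.abundances) * spec.n_contigs)).astype(int)
    contigs: list[SeqRecord] = []
    depths: dict[str, float] = {}
    gene_calls: list[GeneCall] = []
    taxa_names = [t.name for t in spec.taxa]
    for t, cnt, ab in zip(spec.taxa, n_per, spec.abundances):
        genome = genomes[t.name]
        mu = math.log(spec.contig_length_median)
        for j in range(cnt):
            length = int(np.clip(rng.lognormal(mu, spec.contig_length_sigma),
                                 spec.contig_length_min,
                                 min(spec.contig_length_max, len(genome))))
            start = int(rng.integers(0, len(genome) - length + 1))
            cid = f"{t.name}_c{j}"
            rec = SeqRecord(id=cid, sequence=genome[start : start + length])
            contigs.append(rec)
            truth.contig_taxon[cid] = t.name
            truth.contig_span[cid] = (t.name, start, start + length)
            depths[cid] = depth_scale * ab
            gene_calls.extend(_sample_gene_calls(rec, t.name, taxa_names, spec, rng))

    abundance_map = {t.name: a for t, a in zip(spec.taxa, spec.abundances)}
    reads, read_source = sample_reads(
        genomes,
        abundance_map,
        n_reads=n_reads,
        read_length_mean=spec.read_length_mean,
        read_length_sd=spec.read_length_sd,
        seed=int(rng.integers(0, 2**31)),
        exclude=truth.islands if water_column else None,
    )
    truth.read_source = read_source

    return SyntheticDataset(
        spec=spec,
        genomes=genomes,
        strain_genomes=strain_genomes,
        contigs=contigs,
        depths=depths,
        gene_calls=gene_calls,
        reads=reads,
        truth=truth,
    )
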