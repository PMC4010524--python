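"""Contig filtering, taxonomic-uniformity screening, composition-space
clustering and per-bin summary statistics.

The binning path mirrors the enrichment-metagenome workflow: discard
contigs shorter than 5 kb or carrying fewer than three genes, require each
retained contig's gene best-hits to agree on a single high-level taxon,
cluster contigs on their first two oligonucleotide-frequency principal
components augmented with standardized GC, and label each cluster with the
majority taxon of its members.  Contigs whose own label conflicts with
their cluster's label are flagged, never silently reassigned.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .composition import CompositionProfile, PCProjection
from .seqio import GeneCall, SeqRecord

UNASSIGNED = "unassigned"


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    n_below_min_len: int
    n_below_min_genes: int


@dataclass
class BinStats:
    size_mbp: float
    n_genes: int
    n_contigs: int
    avg_contig_kb: float
    avg_gc_percent: float
    avg_gene_length_bp: float
    coding_percent: float
    coverage_x: float


@dataclass
class GenomeBin:
    bin_id: str
    taxon_label: str
    contig_ids: list[str]
    flagged: list[str] = field(default_factory=list)  # members conflicting with bin label
    stats: BinStats | None = None


def genes_by_contig(gene_calls: list[GeneCall]) -> dict[str, list[GeneCall]]:
    by: dict[str, list[GeneCall]] = {}
    for g in gene_calls:
        by.setdefault(g.contig_id, []).append(g)
    return by


def filter_contigs(
    contigs: list[SeqRecord],
    gene_calls: list[GeneCall],
    min_len: int = 5_000,
    min_genes: int = 3,
) -> tuple[list[SeqRecord], FilterReport]:
    """Retain contigs with length >= min_len and gene count >= min_genes.

    The 5 kb boundary is inclusive (a contig of exactly 5,000 bp is kept;
    shorter ones are discarded), and "fewer than three genes" discards
    contigs with 2 or fewer.  Counts discarded by each rule are reported
    (a contig failing both rules is counted under both).
    """
    by_contig = genes_by_contig(gene_calls)
    retained = []
    n_short = n_few = 0
    for c in contigs:
        short = len(c.sequence) < min_len
        few = len(by_contig.get(c.id, [])) < min_genes
        n_short += short
        n_few += few
        if not short and not few:
            retained.append(c)
    return retained, FilterReport(
        n_input=len(contigs),
        n_retained=len(retained),
        n_below_min_len=n_short,
        n_below_min_genes=n_few,
    )


def taxonomic_uniformity(
    contig: SeqRecord,
    gene_calls: list[GeneCall],
    min_agreement: float = 1.0,
) -> str:
    """Taxon label of a contig from its gene best-hit labels.

    Strict mode (``min_agreement=1.0``, the default) returns the taxon only
    when every non-"unknown" gene label agrees; a tolerant mode accepts a
    majority label whose support among non-"unknown" labels reaches
    ``min_agreement``.  All-"unknown" (or no genes at all) yields
    ``"unassigned"``.
    """
    if not gene_calls:
        warnings.warn(f"contig {contig.id} has no gene calls; unassigned")
        return UNASSIGNED
    labels = [g.taxon_label for g in gene_calls if g.taxon_label != "unknown"]
    if not labels:
        return UNASSIGNED
    (top, top_n), = Counter(labels).most_common(1)
    return top if top_n / len(labels) >= min_agreement else UNASSIGNED


def assign_bins(
    projections: list[PCProjection],
    profiles: list[CompositionProfile],
    taxon_labels: dict[str, str],
    n_clusters: int,
    seed: int = 0,
) -> list[GenomeBin]:
    """Cluster contigs on (PC1, PC2, standardized GC) and label clusters.

    Each cluster's taxon is the majority uniformity label of its members
    (ignoring "unassigned"); members whose own label conflicts with the
    cluster label are flagged.  Deterministic given the seed.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > len(projections):
        raise ValueError(f"n_clusters {n_clusters} exceeds contig count {len(projections)}")
    order = {p.contig_id: i for i, p in enumerate(projections)}
    gc = np.empty(len(projections))
    for p in profiles:
        if p.contig_id in order:
            gc[order[p.contig_id]] = p.gc
    gc_std = gc.std()
    gc_z = (gc - gc.mean()) / gc_std if gc_std > 0 else np.zeros_like(gc)
    pcs = np.vstack([p.coordinates[:2] for p in projections])
    X = np.column_stack([pcs, gc_z])
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=int(seed) & 0x7FFFFFFF)
    membership = km.fit_predict(X)

    bins = []
    for k in range(n_clusters):
        member_ids = [projections[i].contig_id for i in np.flatnonzero(membership == k)]
        labels = [taxon_labels.get(cid, UNASSIGNED) for cid in member_ids]
        informative = [l for l in labels if l != UNASSIGNED]
        taxon = Counter(informative).most_common(1)[0][0] if informative else UNASSIGNED
        flagged = [
            cid
            for cid, lab in zip(member_ids, labels)
            if lab not in (UNASSIGNED, taxon)
        ]
        bins.append(
            GenomeBin(bin_id=f"bin{k}", taxon_label=taxon, contig_ids=member_ids, flagged=flagged)
        )
    return bins


def bin_stats(
    bin_: GenomeBin,
    contigs: dict[str, SeqRecord],
    gene_calls: list[GeneCall],
    depths: dict[str, float],
) -> BinStats:
    """Summary statistics of a genome bin.

    Size is the sum of member contig lengths; coding percentage is total
    gene length over total contig length; GC and coverage are
    length-weighted means over member contigs.
    """
    if not bin_.contig_ids:
        raise ValueError(f"bin {bin_.bin_id} is empty")
    members = [contigs[cid] for cid in bin_.contig_ids]
    lengths = np.array([len(c.sequence) for c in members], dtype=float)
    total = lengths.sum()
    from .composition import compute_gc

    gcs = np.array([compute_gc(c.sequence) for c in members])
    genes = [g for g in gene_calls if g.contig_id in set(bin_.contig_ids)]
    gene_lengths = np.array([g.length for g in genes], dtype=float)
    depth_arr = np.array([depths.get(c.id, 0.0) for c in members])
    return BinStats(
        size_mbp=total / 1e6,
        n_genes=len(genes),
        n_contigs=len(members),
        avg_contig_kb=float(lengths.mean()) / 1e3,
        avg_gc_percent=100.0 * float(np.average(gcs, weights=lengths)),
        avg_gene_length_bp=float(gene_lengths.mean()) if len(genes) else 0.0,
        coding_percent=100.0 * float(gene_lengths.sum()) / total,
        coverage_x=float(np.average(depth_arr, weights=lengths)),
    )
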