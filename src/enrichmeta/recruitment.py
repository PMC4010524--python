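"""Fragment recruitment of an environmental read pool onto a genome, with
genomic-island detection, GC/GC-skew tracks and codon-usage deviation.

A read is recruited at its best local-alignment locus when it passes the
identity and coverage cutoffs (defaults 50% identity over 70% of the read
length).  Recruitment is summarized over sliding windows; regions whose
recruitment density falls far below the genome-wide median and that exceed
a minimum length (>15 kb) are called genomic islands — genome segments
present in the resident organism but depleted in the environmental pool,
the classic signature of horizontally acquired, niche-specific DNA.  Genes
inside islands are additionally scored for codon-usage deviation from the
recruitment-supported core.

Window bookkeeping: a recruited read is counted in every window whose
interval contains its alignment start, so with non-overlapping windows
(step == window) the window counts partition the recruited reads exactly;
density is the overlap-adjusted per-base coverage of the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np

from .pairwise import AlignmentScoring, DEFAULT_SCORING, SubjectIndex, best_local_hit

_BASES = "ACGT"

CODONS = ["".join(c) for c in product(_BASES, repeat=3)]
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}


@dataclass
class RecruitmentProfile:
    genome_id: str
    genome_length: int
    window_size: int
    step: int
    window_starts: np.ndarray  # window start positions, in order
    window_ends: np.ndarray
    counts: np.ndarray  # recruited read starts per window
    density: np.ndarray  # per-base coverage depth per window
    n_reads_total: int
    n_reads_recruited: int

    @property
    def median_density(self) -> float:
        return float(np.median(self.density))


@dataclass
class GenomicIsland:
    genome_id: str
    start: int  # 0-based half-open
    end: int
    mean_density: float
    density_ratio: float  # vs genome-wide median
    codon_deviation: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CodonUsageTable:
    fractions: np.ndarray  # 64 codon fractions, lexicographic order
    n_codons: int


@dataclass
class SkewWindow:
    start: int
    end: int
    gc: float
    skew: float
    undefined: bool = False  # window had G + C == 0 (skew reported as 0)


def recruit(
    reads,
    genome: str,
    genome_id: str = "genome",
    min_identity: float = 50.0,
    min_cov: float = 0.7,
    window: int = 1000,
    step: int = 500,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> RecruitmentProfile:
    """Map reads onto a genome and summarize recruitment per sliding window."""
    if not reads:
        raise ValueError("read pool is empty")
    index = SubjectIndex(genome, subject_id=genome_id)
    starts: list[int] = []
    coverage = np.zeros(len(genome) + 1)
    n_recruited = 0
    for read in reads:
        hit = best_local_hit(read.sequence, index, scoring=scoring, query_id=read.id)
        if hit is None:
            continue
        if hit.identity_percent < min_identity or hit.aligned_length < min_cov * len(read.sequence):
            continue
        n_recruited += 1
        s, e = hit.subject_span
        starts.append(s)
        coverage[s] += 1
        coverage[e] -= 1
    depth = np.cumsum(coverage[:-1])

    w_starts = np.arange(0, max(len(genome) - window, 0) + 1, step)
    if len(w_starts) == 0:
        w_starts = np.array([0])
    w_ends = np.minimum(w_starts + window, len(genome))
    start_arr = np.sort(np.array(starts, dtype=int)) if starts else np.array([], dtype=int)
    counts = np.searchsorted(start_arr, w_ends) - np.searchsorted(start_arr, w_starts)
    cum_depth = np.concatenate([[0.0], np.cumsum(depth)])
    density = (cum_depth[w_ends] - cum_depth[w_starts]) / (w_ends - w_starts)
    return RecruitmentProfile(
        genome_id=genome_id,
        genome_length=len(genome),
        window_size=window,
        step=step,
        window_starts=w_starts,
        window_ends=w_ends,
        counts=counts.astype(int),
        density=density,
        n_reads_total=len(reads),
        n_reads_recruited=n_recruited,
    )


def detect_islands(
    profile: RecruitmentProfile,
    min_len: int = 15_000,
    density_ratio_threshold: float = 0.2,
    merge_gap: int = 2_000,
) -> list[GenomicIsland]:
    """Call genomic islands as long runs of under-recruited windows.

    Windows with density below ``density_ratio_threshold`` x the
    genome-wide median form candidate runs; runs separated by less than
    ``merge_gap`` bases are merged; an island is emitted when its length is
    strictly greater than ``min_len``.
    """
    if len(profile.window_starts) == 0:
        raise ValueError("profile has no windows")
    median = profile.median_density
    if median == 0:
        warnings.warn("genome-wide median recruitment density is 0; no islands callable")
        return []
    low = profile.density < density_ratio_threshold * median
    runs: list[tuple[int, int]] = []  # base-coordinate intervals
    i = 0
    n = len(low)
    while i < n:
        if low[i]:
            j = i
            while j + 1 < n and low[j + 1]:
                j += 1
            runs.append((int(profile.window_starts[i]), int(profile.window_ends[j])))
            i = j + 1
        else:
            i += 1
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    islands = []
    for s, e in merged:
        if e - s > min_len:
            in_run = (profile.window_starts >= s) & (profile.window_ends <= e)
            mean_density = float(profile.density[in_run].mean()) if in_run.any() else 0.0
            islands.append(
                GenomicIsland(
                    genome_id=profile.genome_id,
                    start=s,
                    end=e,
                    mean_density=mean_density,
                    density_ratio=mean_density / median,
                )
            )
    return islands


def gc_skew(genome: str, window: int = 25_000, step: int = 1_000) -> list[SkewWindow]:
    """GC content and GC skew, (G - C) / (G + C), over sliding windows.

    Windows containing N contribute their non-N bases only; a window with
    no G or C reports skew 0 with ``undefined=True``.  A genome shorter
    than the window yields a single whole-genome value with a warning.
    """
    if len(genome) < window:
        warnings.warn(
            f"genome length {len(genome)} < window {window}; reporting one whole-genome value"
        )
        window = len(genome)
        starts = [0]
    else:
        starts = list(range(0, len(genome) - window + 1, step))
    seq = genome.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_g = np.concatenate([[0], np.cumsum(arr == ord("G"))])
    is_c = np.concatenate([[0], np.cumsum(arr == ord("C"))])
    is_a = np.concatenate([[0], np.cumsum(arr == ord("A"))])
    is_t = np.concatenate([[0], np.cumsum(arr == ord("T"))])
    out = []
    for s in starts:
        e = s + window
        g = int(is_g[e] - is_g[s])
        c = int(is_c[e] - is_c[s])
        at = int(is_a[e] - is_a[s]) + int(is_t[e] - is_t[s])
        acgt = g + c + at
        gc = (g + c) / acgt if acgt else 0.0
        if g + c == 0:
            out.append(SkewWindow(start=s, end=e, gc=gc, skew=0.0, undefined=True))
        else:
            out.append(SkewWindow(start=s, end=e, gc=gc, skew=(g - c) / (g + c)))
    return out


# ---------------------------------------------------------------------------
# codon usage


def codon_usage(gene_sequences: list[str]) -> CodonUsageTable:
    """Pooled codon fractions over a gene set, read in frame from position 0.

    Trailing partial codons are dropped with a warning; codons containing N
    are skipped.
    """
    if not gene_sequences:
        raise ValueError("codon usage of an empty gene set is undefined")
    counts = np.zeros(64)
    warned = False
    for seq in gene_sequences:
        s = seq.upper()
        if len(s) % 3 != 0 and not warned:
            warnings.warn("gene length not divisible by 3; trailing partial codon dropped")
            warned = True
        for i in range(0, len(s) - len(s) % 3, 3):
            idx = _CODON_INDEX.get(s[i : i + 3])
            if idx is not None:
                counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no countable codons in gene set")
    return CodonUsageTable(fractions=counts / total, n_codons=int(total))


def codon_deviation(table_a: CodonUsageTable, table_b: CodonUsageTable) -> float:
    """Squared-difference distance between two codon-usage tables.

    Symmetric; 0 iff the tables are identical.  High values flag gene sets
    with anomalous codon usage relative to a reference set — the signature
    used to corroborate horizontal acquisition of island genes.
    """
    return float(np.sum((table_a.fractions - table_b.fractions) ** 2))


@dataclass
class IslandCodonAnomaly:
    score: float  # island genes vs core genes
    null_scores: np.ndarray  # same-size random core subsets vs remaining core
    percentile_95: float

    @property
    def exceeds_null(self) -> bool:
        return self.score > self.percentile_95


def island_codon_anomaly(
    genome: str,
    islands: list[tuple[int, int]],
    gene_intervals: list[tuple[int, int]],
    n_resample: int = 200,
    seed: int = 0,
) -> IslandCodonAnomaly:
    """Compare island-gene codon usage against the core-gene null.

    Genes fully inside an island interval form the island set; all others
    the core.  The observed deviation of pooled island genes from pooled
    core genes is compared with a permutation null: deviations of
    ``n_resample`` random core subsets of the same size from the remaining
    core genes.
    """
    island_genes = []
    core_genes = []
    for s, e in gene_intervals:
        seq = genome[s:e]
        if any(s >= is_ and e <= ie for is_, ie in islands):
            island_genes.append(seq)
        else:
            core_genes.append(seq)
    if not island_genes or not core_genes:
        raise ValueError("need at least one island gene and one core gene")
    core_table = codon_usage(core_genes)
    score = codon_deviation(codon_usage(island_genes), core_table)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 7])
    k = min(len(island_genes), len(core_genes) - 1)
    null = np.empty(n_resample)
    core_arr = np.array(core_genes, dtype=object)
    for r in range(n_resample):
        pick = rng.choice(len(core_arr), size=k, replace=False)
        rest = np.setdiff1d(np.arange(len(core_arr)), pick)
        null[r] = codon_deviation(
            codon_usage(list(core_arr[pick])), codon_usage(list(core_arr[rest]))
        )
    return IslandCodonAnomaly(
        score=score,
        null_scores=null,
        percentile_95=float(np.percentile(null, 95)),
    )
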