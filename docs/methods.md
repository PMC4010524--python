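# Methods

This note documents the models, conventions and numerical choices behind
`enrichmeta`, and what validation on the synthetic communities does and does
not demonstrate about real enrichment metagenomes.

## Synthetic community model

Genomes are order-*m* Markov chains over {A,C,G,T} (default *m* = 2: a
distinct trinucleotide bias is the smallest signal that separates taxa at
tetranucleotide word size). Each taxon's per-context emission weights start
from the base composition implied by its GC target (p(A)=p(T)=(1−GC)/2,
p(G)=p(C)=GC/2) and receive a context-dependent, taxon-specific perturbation
that redistributes probability **only within {A,T} and within {G,C}**.
Consequently P(G or C | context) equals the GC target in every context, the
realized genome GC is a plain binomial around the target (the ±2-point
invariant holds by construction for ≥100 kb genomes), while short-word
structure becomes taxon-specific. The perturbation magnitude
(`signature_strength`, default 0.5 of the within-pair mass) is the free
"signature strength" dial; near 0 it provides a deliberately marginal
stress-test profile.

The default community mirrors the enrichment setting the package targets:
three taxa at GC 34/43/53% with abundances 0.6/0.2/0.2, reads of mean
280 bp (sd 12) matching pyrosequencing-era read lengths of ~266–291 bp,
and log-normal contig lengths (median 20 kb, σ=0.7, truncated to
[1 kb, 200 kb]) — scaled down from the tens-to-hundreds-of-kb contigs of a
real assembly so the full pipeline runs at desk scale. Strain pairs are
produced by independent per-site substitution at rate *d* (uniform over the
three alternative bases; no transition/transversion bias, since only mean
identity is targeted). Islands are segments generated from a donor taxon's
Markov model, spliced at random non-overlapping positions. The
"water-column" read pool samples genome positions uniformly **excluding**
island intervals, so islands are depleted by construction, emulating genome
regions absent from an open-ocean reference metagenome.

Deliberately absent: sequencing error, paired ends, chimeric contigs and
assembly artifacts. Contigs are exact genome substrings. Passing tests
therefore demonstrate that each algorithm recovers planted signal under its
own model assumptions — not robustness to assembly noise, uneven coverage or
contamination in real data.

Gene calls are synthetic non-overlapping intervals (mean 800 bp, sd 150,
codon-sized when tiled on genomes) labeled with the true taxon plus an
optional label-noise rate; gene *prediction* is out of scope, as in the
workflow this mirrors, where an external predictor supplies gene calls.

## Coordinates and formats

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted only at the I/O boundary. Sequences are restricted
to {A,C,G,T,N}; N is excluded from GC (numerator and denominator), k-mer
words containing N are skipped, and GC-skew windows count only their non-N
bases.

## Composition and PCA

Oligonucleotide frequencies use overlapping single-strand words (default
k = 4, the field standard for composition binning), normalized to sum to 1;
an optional flag pools reverse-complement word pairs. The frequency matrix
is column-centered (no variance scaling — the columns share a scale) and
decomposed by SVD. Component signs are fixed so each component's
largest-magnitude loading is positive, making projections run-to-run
reproducible; explained-variance fractions come from the full spectrum and
sum to 1. Reference profiles can be projected post hoc without influencing
the fit. Correctness is pinned in tests to an independent
eigendecomposition-of-covariance oracle at 1e-8.

## Binning

The contig filter keeps length ≥ 5,000 bp (inclusive boundary) and gene
count ≥ 3. Taxonomic uniformity is strict by default — every non-"unknown"
gene label must agree — with a tolerant majority-fraction mode for noisy
benchmarks. Clustering is k-means (fixed seed, `n_init=10`) on PC1, PC2 and
z-scored GC; k-means was chosen for determinism and because the clusters
this emulates were well separated enough to read off a PCA plot. Cluster
taxon labels come from the majority of member uniformity labels; members
conflicting with their cluster label are flagged, never silently
reassigned. Bin statistics: size = Σ member lengths; coding % = Σ gene
lengths / Σ contig lengths; GC and coverage are length-weighted means.

## Alignment and ANI

Pairwise alignment is exact affine-gap local (Smith–Waterman/Gotoh) with
match +1, mismatch −1, gap open −2, gap extend −1; a gap of length L scores
open + (L−1)·extend. The production aligner is Biopython's
`PairwiseAligner`; tests define correctness against an independent
pure-Python Gotoh dynamic program. Among co-optimal alignments the
aligner's first (deterministic) traceback is reported; scores, the
oracle-checked quantity, are unaffected by this choice. Identity =
matches / alignment columns (gap columns included).

Mapping a short query onto a long subject uses, in order: an exact
substring check (leftmost occurrence), exact 15-mer seeding with candidate
diagonals resolved by exact alignment of the query against a padded subject
window (pad = max(32, |q|/8)), and an edit-distance (edlib) infix screen
when no seed exists. This is a search-space restriction in the spirit of
seeded aligners; the exact DP remains the definition of the result.

ANI fragments are 1,020 bp (the classical fragment length for this
scheme), terminal remainders ≥ half a fragment kept. Default cutoffs are
50% identity / 70% coverage — the thresholds used for the nucleotide
comparisons this pipeline mirrors; note the original ANI definition used
30%/70%, available via `min_identity=30`. One-directional ANI is reported
by default; `symmetric=True` averages both directions. Zero passing
fragments yields an explicitly undefined ANI (never 0). The species
boundary is ANI ≥ 94.0, inclusive. On planted substitution-only
divergence the local aligner's end-trimming biases identity upward by
≲0.15 points at d ≤ 0.1, comfortably inside the ±1-point recovery target.

## Recruitment and islands

A read is recruited at its best locus if it passes 50%/70%. Windows
(default 1 kb, step 500 bp) record two things: `count` — reads whose
alignment **start** falls in the window, so that with non-overlapping
windows counts partition the recruited reads exactly — and `density`, the
overlap-adjusted per-base coverage used for island calling. Island calling
takes maximal runs of windows with density < 0.2× the genome-wide median,
merges runs separated by < 2 kb, and emits runs strictly longer than
15 kb. The 0.2 threshold is not part of the original island definition
(which was read off recruitment plots); it is chosen so fully read-excluded
islands are always called while Poisson dips at ≥10× coverage are not —
at 20× a 1-kb window holds ~70 read starts, and P(< 0.2×median) is
negligible, which the 20-replicate island-free control verifies. Island
boundaries snap to window edges, so reported coordinates carry ±(read
length + step) slack; recovery is therefore assessed by reciprocal
overlap, not exact endpoints.

GC and GC skew (G−C)/(G+C) use 25-kb sliding windows (step 1 kb) — the
window size conventional for replication-strand skew plots. Codon usage is
counted in frame from position 0 of each gene, pooled; deviation between
two tables is Σ over 64 codons of the squared fraction difference
(symmetric, 0 iff identical). Island-vs-core anomaly compares pooled
island genes against pooled core genes and situates the score in a
200-resample null of same-size random core subsets vs the remaining core;
recruitment defines island coordinates, codon deviation annotates them.

## 16S classification

Best reference hit per read; any assignment needs alignment length
strictly > 100 bases and identity ≥ the 80% floor; genus needs ≥ 95%.
The conventional e-value acceptance criterion is replaced by the identity
floor because e-values presuppose a database-size model; the floor plays
the same role of rejecting spurious short matches. Ties are broken by
longer alignment, then lexicographic reference id. Taxonomy is two flat
fields (`high_level=`, `genus=`) carried in reference FASTA headers.
Community profiles are fractions over assigned reads per high-level taxon,
plus an unclassified fraction over all reads.

## Determinism and problem sizes

All randomness flows from one integer seed through named numpy substreams
(taxon-specific streams use a CRC32 of the taxon name, never Python's
salted `hash`). Identical config + seed reproduces byte-identical FASTA/TSV
artifacts. Default validation sizes — 150–200 kb genomes, ~300 contigs,
20× read pools, 20 control replicates — were chosen as the smallest scales
at which the statistical criteria (binomial intervals on GC and divergence
recovery, Poisson dispersion of coverage, permutation nulls) are
comfortably separated from their thresholds.

## Known limitations

- The seeded mapper can in principle miss the optimal locus for a query
  with no exact 15-mer seed and a misleading edit-distance optimum; at the
  divergences this package targets (d ≤ 0.1) seeds are abundant and the
  exhaustive-DP cross-checks pass, but adversarial inputs exist.
- Codon-usage deviation uses nucleotide gene sequences without
  strand-orienting or translating them; it measures compositional anomaly,
  not amino-acid-level usage.
- Ortholog pairing operates on nucleotide CDS identity (no translation);
  at the 50%/70% cutoffs this is stricter than protein-level pairing for
  diverged pairs.
- Depth is carried as a per-contig annotation from the simulator; the
  binning CLI assigns uniform depth when real per-contig depths are not
  supplied.
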