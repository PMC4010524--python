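"""Per-contig GC and oligonucleotide-frequency profiles and their PCA projection.

Contigs from different organisms separate in the space of normalized k-mer
frequencies (tetranucleotides by default, the field standard for
composition-based binning).  Profiles are column-centered and decomposed by
SVD; reference genomes can be projected into a fitted space post hoc without
influencing it.

Conventions: single-strand counting (no reverse-complement collapsing, with
an optional flag to collapse), words containing N are skipped, and GC
excludes N from both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

_BASES = "ACGT"


class CompositionError(ValueError):
    pass


def kmer_words(k: int) -> list[str]:
    """All 4^k words over ACGT in lexicographic order."""
    return ["".join(p) for p in product(_BASES, repeat=k)]


@dataclass
class CompositionProfile:
    contig_id: str
    gc: float
    kmer_freq: np.ndarray  # length 4^k, lexicographic word order
    length: int


@dataclass
class PCProjection:
    contig_id: str
    coordinates: np.ndarray  # first P principal components
    explained_variance: np.ndarray  # per-component fraction, full spectrum


def compute_gc(sequence: str) -> float:
    """GC fraction, (#G + #C) / (#A + #C + #G + #T); N bases are excluded.

    A sequence containing no A/C/G/T at all has no defined GC and raises
    :class:`CompositionError`.
    """
    if not sequence:
        raise CompositionError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    denom = gc + s.count("A") + s.count("T")
    if denom == 0:
        raise CompositionError("GC undefined: sequence contains only N")
    return gc / denom


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def kmer_freqs(sequence: str, k: int = 4, collapse_revcomp: bool = False) -> np.ndarray:
    """Normalized overlapping k-mer frequencies in lexicographic order.

    Words containing N (or any non-ACGT base) are skipped.  With
    ``collapse_revcomp`` each word's count is pooled with its reverse
    complement's (strand-symmetric signature).
    """
    if k < 1:
        raise CompositionError(f"k must be >= 1, got {k}")
    s = sequence.upper()
    if len(s) < k:
        raise CompositionError(f"sequence length {len(s)} < k={k}")
    codes = np.array([_CODE.get(c, -1) for c in s], dtype=np.int64)
    valid = codes >= 0
    # windowed word codes via base-4 positional encoding
    n_words = len(s) - k + 1
    word_codes = np.zeros(n_words, dtype=np.int64)
    word_valid = np.ones(n_words, dtype=bool)
    for j in range(k):
        word_codes = word_codes * 4 + np.where(valid[j : j + n_words], codes[j : j + n_words], 0)
        word_valid &= valid[j : j + n_words]
    counts = np.bincount(word_codes[word_valid], minlength=4**k).astype(float)
    if collapse_revcomp:
        rc = _revcomp_index(k)
        counts = counts + counts[rc]
    total = counts.sum()
    if total == 0:
        raise CompositionError("no valid k-mer windows (all contain N)")
    return counts / total


def _revcomp_index(k: int) -> np.ndarray:
    """index i -> index of the reverse complement of word i."""
    idx = np.arange(4**k)
    rc = np.zeros_like(idx)
    for j in range(k):
        digit = (idx // 4**j) % 4
        rc += (3 - digit) * 4 ** (k - 1 - j)
    return rc


def profile_contigs(records, k: int = 4) -> list[CompositionProfile]:
    """Composition profiles (GC + k-mer frequency vector) for sequence records."""
    return [
        CompositionProfile(
            contig_id=r.id,
            gc=compute_gc(r.sequence),
            kmer_freq=kmer_freqs(r.sequence, k=k),
            length=len(r.sequence),
        )
        for r in records
    ]


class PCAModel:
    """Centered-SVD principal components of a profile matrix.

    No variance scaling is applied to the frequency columns (they share a
    scale); centering only.  Component signs are fixed so that each
    component's largest-magnitude loading is positive, making projections
    reproducible across runs.
    """

    def __init__(self, mean: np.ndarray, components: np.ndarray, explained_variance: np.ndarray):
        self.mean = mean
        self.components = components  # (n_components, n_features)
        self.explained_variance = explained_variance  # fraction per component, full spectrum

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project rows of X (post hoc; does not influence the fit)."""
        return (np.asarray(X, dtype=float) - self.mean) @ self.components.T


def fit_pca(X: np.ndarray) -> PCAModel:
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise CompositionError("PCA requires at least 2 profiles")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    var = s**2
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    return PCAModel(mean=mean, components=vt, explained_variance=ratio)


def pca_project(
    profiles: list[CompositionProfile],
    n_components: int = 2,
    reference_profiles: list[CompositionProfile] | None = None,
) -> tuple[list[PCProjection], list[PCProjection], PCAModel]:
    """Fit PCA on contig k-mer profiles and project them onto the first
    ``n_components`` axes.

    ``reference_profiles`` (e.g. published genomes) are projected into the
    fitted space without influencing it.  Returns (contig projections,
    reference projections, fitted model).
    """
    if len(profiles) < 2:
        raise CompositionError("PCA requires at least 2 profiles")
    n_feat = profiles[0].kmer_freq.shape[0]
    if not (1 <= n_components <= min(len(profiles) - 1, n_feat)):
        raise CompositionError(
            f"n_components={n_components} out of range for "
            f"{len(profiles)} profiles x {n_feat} features"
        )
    X = np.vstack([p.kmer_freq for p in profiles])
    model = fit_pca(X)
    coords = model.transform(X)[:, :n_components]
    ev = model.explained_variance
    projections = [
        PCProjection(contig_id=p.contig_id, coordinates=coords[i], explained_variance=ev)
        for i, p in enumerate(profiles)
    ]
    ref_projections = []
    if reference_profiles:
        R = np.vstack([p.kmer_freq for p in reference_profiles])
        rcoords = model.transform(R)[:, :n_components]
        ref_projections = [
            PCProjection(contig_id=p.contig_id, coordinates=rcoords[i], explained_variance=ev)
            for i, p in enumerate(reference_profiles)
        ]
    return projections, ref_projections, model
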