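"""Threshold-based classification of 16S rRNA reads against a labeled
reference set.

A read is assignable when its best reference alignment spans more than 100
bases and reaches a minimum-identity floor; it is assigned to the
reference's genus at >= 95% identity, otherwise only to the reference's
high-level taxon (class or above).  Reference taxonomy is carried in FASTA
headers as ``high_level=<taxon> genus=<genus>`` key-value fields.

The classic e-value criterion for accepting rRNA hits is replaced here by
the identity floor (default 80%) combined with the alignment-length rule,
since e-values presuppose a database-size model; the floor plays the same
role of rejecting spurious short-word matches.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

from .pairwise import AlignmentScoring, DEFAULT_SCORING, SubjectIndex, best_local_hit
from .seqio import SeqRecord

UNCLASSIFIED = "unclassified"


@dataclass
class RrnaReference:
    record: SeqRecord
    high_level: str
    genus: str


@dataclass
class RrnaAssignment:
    read_id: str
    best_ref_id: str | None
    identity_percent: float | None
    aligned_length: int | None
    assigned_rank: str  # "genus", "high_level" or "unclassified"
    taxon: str


def parse_taxon_header(description: str) -> tuple[str, str]:
    """Extract high_level= and genus= fields from a reference FASTA header."""
    fields = dict(re.findall(r"(\w+)=([^;\s]+)", description))
    if "high_level" not in fields or "genus" not in fields:
        raise ValueError(f"reference header lacks high_level=/genus= fields: {description!r}")
    return fields["high_level"], fields["genus"]


def load_references(records: list[SeqRecord]) -> list[RrnaReference]:
    if not records:
        raise ValueError("empty rRNA reference set")
    refs = []
    for rec in records:
        high, genus = parse_taxon_header(rec.description)
        refs.append(RrnaReference(record=rec, high_level=high, genus=genus))
    return refs


def classify_reads(
    reads: list[SeqRecord],
    references: list[RrnaReference],
    min_aln_len: int = 100,
    genus_identity: float = 95.0,
    floor_identity: float = 80.0,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> list[RrnaAssignment]:
    """Assign reads to genus or high-level taxon by best reference hit.

    Any assignment requires aligned length strictly greater than
    ``min_aln_len`` and identity >= ``floor_identity``; genus additionally
    requires identity >= ``genus_identity``.  Ties between references at
    equal score are broken by longer alignment, then lexicographic
    reference id.
    """
    if not references:
        raise ValueError("empty rRNA reference set")
    indexes = [
        (ref, SubjectIndex(ref.record.sequence, subject_id=ref.record.id))
        for ref in references
    ]
    out = []
    for read in reads:
        best = None  # (score, aligned_length, neg-lex ref id) maximized
        best_ref = None
        for ref, idx in indexes:
            hit = best_local_hit(read.sequence, idx, scoring=scoring, query_id=read.id)
            if hit is None:
                continue
            if best is None or (
                (hit.score, hit.aligned_length) > (best.score, best.aligned_length)
                or (
                    (hit.score, hit.aligned_length) == (best.score, best.aligned_length)
                    and ref.record.id < best_ref.record.id
                )
            ):
                best, best_ref = hit, ref
        if (
            best is None
            or best.aligned_length <= min_aln_len
            or best.identity_percent < floor_identity
        ):
            out.append(
                RrnaAssignment(
                    read_id=read.id,
                    best_ref_id=best.subject_id if best else None,
                    identity_percent=best.identity_percent if best else None,
                    aligned_length=best.aligned_length if best else None,
                    assigned_rank=UNCLASSIFIED,
                    taxon=UNCLASSIFIED,
                )
            )
            continue
        if best.identity_percent >= genus_identity:
            rank, taxon = "genus", best_ref.genus
        else:
            rank, taxon = "high_level", best_ref.high_level
        out.append(
            RrnaAssignment(
                read_id=read.id,
                best_ref_id=best.subject_id,
                identity_percent=best.identity_percent,
                aligned_length=best.aligned_length,
                assigned_rank=rank,
                taxon=taxon,
            )
        )
    return out


def community_profile(
    assignments: list[RrnaAssignment],
    references: list[RrnaReference] | None = None,
) -> dict[str, float]:
    """Per-high-level-taxon fractions over assigned reads.

    Genus-level assignments are rolled up to their reference's high-level
    taxon when ``references`` is given.  Fractions are over assigned reads;
    the returned ``"unclassified"`` entry is the unclassified fraction over
    *all* reads.
    """
    if not assignments:
        raise ValueError("no assignments to profile")
    genus_to_high = {}
    if references:
        genus_to_high = {r.genus: r.high_level for r in references}
    counts: Counter[str] = Counter()
    n_unclassified = 0
    for a in assignments:
        if a.assigned_rank == UNCLASSIFIED:
            n_unclassified += 1
        elif a.assigned_rank == "genus":
            counts[genus_to_high.get(a.taxon, a.taxon)] += 1
        else:
            counts[a.taxon] += 1
    n_assigned = sum(counts.values())
    profile = {
        taxon: n / n_assigned for taxon, n in sorted(counts.items())
    } if n_assigned else {}
    profile[UNCLASSIFIED] = n_unclassified / len(assignments)
    return profile
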