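"""Readers and writers for the formats the pipeline touches.

All internal coordinates are 0-based, half-open.  GFF3's 1-based inclusive
convention is converted at this boundary and nowhere else.  Sequences are
uppercased on load and restricted to the {A, C, G, T, N} alphabet; anything
else is a format error naming the offending record.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import gffutils
from Bio import SeqIO as _BioSeqIO

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates a format invariant."""


@dataclass
class SeqRecord:
    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneCall:
    """A gene interval on a contig, 0-based half-open, with its taxon best-hit label."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"
    taxon_label: str = "unknown"
    besthit_identity: float | None = None
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id or '?'} on {self.contig_id}: "
                f"invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene on {self.contig_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def _validate_record(rec_id: str, seq: str) -> str:
    if not rec_id:
        raise FormatError("record with empty id")
    if not seq:
        raise FormatError(f"record {rec_id!r}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise FormatError(
            f"record {rec_id!r}: non-IUPAC characters {sorted(bad)!r} "
            "(only A, C, G, T, N allowed)"
        )
    return seq


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read a multi-record FASTA file, preserving record order.

    Sequences are uppercased; ``N`` is allowed.  Duplicate ids, empty
    sequences and characters outside {A,C,G,T,N} raise :class:`FormatError`.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _validate_record(rec.id, str(rec.seq))
        records.append(SeqRecord(id=rec.id, sequence=seq, description=rec.description))
    return records


def write_fasta(records: list[SeqRecord], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else (
                f"{rec.id} {rec.description}".rstrip()
            )
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _parse_gff_db(path: str | os.PathLike) -> gffutils.FeatureDB:
    return gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def read_gene_calls(
    path: str | os.PathLike,
    contig_lengths: dict[str, int] | None = None,
) -> list[GeneCall]:
    """Read gene calls from a GFF3 file with ``taxon=`` attributes.

    Coordinates are converted from GFF3 1-based inclusive to internal
    0-based half-open.  A missing ``taxon`` attribute yields the label
    ``"unknown"``.  When ``contig_lengths`` is given, genes referencing an
    unknown contig or extending past its end are format errors.
    """
    calls: list[GeneCall] = []
    db = _parse_gff_db(path)
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.end < feat.start:
            raise FormatError(
                f"gene {feat.id} on {feat.seqid}: end {feat.end} < start {feat.start}"
            )
        start0, end0 = feat.start - 1, feat.end  # GFF3 -> half-open
        if contig_lengths is not None:
            if feat.seqid not in contig_lengths:
                raise FormatError(f"gene {feat.id}: unknown contig {feat.seqid!r}")
            if end0 > contig_lengths[feat.seqid]:
                raise FormatError(
                    f"gene {feat.id} on {feat.seqid}: end {end0} beyond contig "
                    f"length {contig_lengths[feat.seqid]}"
                )
        taxon = feat.attributes.get("taxon", ["unknown"])[0]
        ident = feat.attributes.get("besthit_identity", [None])[0]
        calls.append(
            GeneCall(
                contig_id=feat.seqid,
                start=start0,
                end=end0,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                taxon_label=taxon or "unknown",
                besthit_identity=float(ident) if ident is not None else None,
                gene_id=feat.id or "",
            )
        )
    return calls


def write_gene_calls(calls: list[GeneCall], path: str | os.PathLike) -> None:
    """Write gene calls as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(calls):
            attrs = [f"ID={g.gene_id or f'gene{i}'}", f"taxon={g.taxon_label}"]
            if g.besthit_identity is not None:
                attrs.append(f"besthit_identity={g.besthit_identity:g}")
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        "enrichmeta",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def write_tsv(rows: list[dict], path: str | os.PathLike, columns: list[str]) -> None:
    """Write tabular output with a header row; missing values rendered as '.'."""
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    "." if row.get(c) is None else str(row.get(c)) for c in columns
                )
                + "\n"
            )
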