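"""Readers and writers for the external formats the toolkit touches.

All internal coordinates are 0-based half-open.  Conversion to and from the
1-based inclusive conventions of BLAST tabular output and GFF3 happens only
here, at the format boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO
from gffutils.feature import feature_from_line

__all__ = [
    "SequenceRecord",
    "BlastTabRow",
    "SamAlignment",
    "GffFeature",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "parse_blast_tab",
    "write_blast_tab",
    "normalize_hit",
    "read_gff3",
    "write_gff3",
    "read_gff3_loci",
    "write_gff3_loci",
    "read_sam",
]

_VALID_BASES = set("ACGTN")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True)
class SequenceRecord:
    """A DNA sequence with a unique identifier.

    ``seq`` is uppercase over the alphabet A, C, G, T, N; any other IUPAC
    ambiguity code is coerced to N on input (with a warning) and U is mapped
    to T.
    """

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class BlastTabRow:
    """One line of 12-column BLAST tabular output (``-outfmt 6``).

    Coordinates are kept exactly as BLAST reports them: 1-based inclusive,
    with ``sstart > send`` signalling a minus-strand subject alignment.
    """

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class SamAlignment:
    """A single SAM record reduced to the fields the toolkit consumes."""

    qname: str
    flag: int
    rname: str
    pos: int  # 1-based leftmost reference position
    mapq: int
    cigar: tuple[tuple[str, int], ...]

    @property
    def is_mapped(self) -> bool:
        return not self.flag & 0x4

    @property
    def is_primary(self) -> bool:
        return not self.flag & 0x900


@dataclass(frozen=True)
class GffFeature:
    """One GFF3 feature line; ``start``/``end`` are 1-based inclusive."""

    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: float | None
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"invalid GFF interval {self.start}..{self.end} on {self.seqid}"
            )


def _clean_seq(raw: str, record_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    if not set(seq) <= _VALID_BASES:
        bad = sorted(set(seq) - _VALID_BASES)
        warnings.warn(
            f"record {record_id!r}: ambiguity codes {bad} coerced to N",
            stacklevel=3,
        )
        seq = "".join(c if c in _VALID_BASES else "N" for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Sequences are uppercased, U is mapped to T and ambiguity codes other
    than N are coerced to N.  Duplicate identifiers and empty files raise
    :class:`FormatError`.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise FormatError(f"{path}: line 1: expected FASTA header, got {first[:40]!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty identifier")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, seq=_clean_seq(str(rec.seq), rec.id)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


_BLAST_TYPES = (str, str, float, int, int, int, int, int, int, int, float, float)


def parse_blast_tab(path: str | Path) -> list[BlastTabRow]:
    """Parse 12-column BLAST tabular output, preserving row order.

    Lines starting with ``#`` are ignored.  A line with the wrong column
    count or an unparsable numeric field raises :class:`FormatError` naming
    the offending line.
    """
    rows: list[BlastTabRow] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                vals = [typ(p) for typ, p in zip(_BLAST_TYPES, parts)]
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            row = BlastTabRow(*vals)
            if not 0.0 <= row.pident <= 100.0:
                raise FormatError(f"{path}: line {lineno}: pident {row.pident} outside [0,100]")
            if row.length < 1:
                raise FormatError(f"{path}: line {lineno}: alignment length {row.length} < 1")
            rows.append(row)
    return rows


def write_blast_tab(rows: Iterable[BlastTabRow], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for r in rows:
            fh.write(
                f"{r.qseqid}\t{r.sseqid}\t{r.pident:.2f}\t{r.length}\t{r.mismatch}\t"
                f"{r.gapopen}\t{r.qstart}\t{r.qend}\t{r.sstart}\t{r.send}\t"
                f"{r.evalue:.2g}\t{r.bitscore:.1f}\n"
            )


def normalize_hit(row: BlastTabRow, organelle_label: str):
    """Convert a BLAST row into an :class:`~orginsert.insertion_detect.OrganelleHit`.

    The scaffold (subject) interval becomes 0-based half-open
    ``[min(sstart, send) - 1, max(sstart, send))``; strand is ``-`` iff
    ``sstart > send``.  Organelle (query) coordinates are normalized the
    same way.
    """
    from .insertion_detect import OrganelleHit

    if organelle_label not in ("plastid", "mito"):
        raise ValueError(f"organelle_label must be 'plastid' or 'mito', got {organelle_label!r}")
    start = min(row.sstart, row.send) - 1
    end = max(row.sstart, row.send)
    o_start = min(row.qstart, row.qend) - 1
    o_end = max(row.qstart, row.qend)
    return OrganelleHit(
        scaffold=row.sseqid,
        start=start,
        end=end,
        organelle=organelle_label,
        o_start=o_start,
        o_end=o_end,
        strand="-" if row.sstart > row.send else "+",
        pident=row.pident,
        aln_length=row.length,
        bitscore=row.bitscore,
    )


# --- GFF3 ------------------------------------------------------------------


def read_gff3(path: str | Path) -> list[GffFeature]:
    """Read GFF3 feature lines (directives and comments are skipped)."""
    feats: list[GffFeature] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                f = feature_from_line(line)
            except Exception as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            attrs = {k: ",".join(v) for k, v in f.attributes.items()}
            score = None if f.score in (".", "", None) else float(f.score)
            feats.append(
                GffFeature(
                    seqid=f.seqid,
                    source=f.source,
                    type=f.featuretype,
                    start=f.start,
                    end=f.end,
                    score=score,
                    strand=f.strand if f.strand else ".",
                    attributes=attrs,
                )
            )
    return feats


def _fmt_attrs(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_gff3(features: Iterable[GffFeature], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            score = "." if f.score is None else repr(f.score)
            fh.write(
                f"{f.seqid}\t{f.source}\t{f.type}\t{f.start}\t{f.end}\t"
                f"{score}\t{f.strand}\t.\t{_fmt_attrs(f.attributes)}\n"
            )


def write_gff3_loci(loci, path: str | Path) -> None:
    """Write insertion loci as GFF3, one feature per locus.

    The feature type is the locus class (NUPT, NUMT or NUMPT); attributes
    carry the confirmation status, length-weighted mean identity, and hit
    count.  Internal half-open coordinates are shifted to 1-based inclusive.
    """
    seen_ids: set[str] = set()
    feats = []
    for loc in loci:
        lid = loc.locus_id
        if lid in seen_ids:
            raise FormatError(f"duplicate locus ID {lid!r}")
        seen_ids.add(lid)
        feats.append(
            GffFeature(
                seqid=loc.scaffold,
                source="orginsert",
                type=loc.cls,
                start=loc.start + 1,
                end=loc.end,
                score=None,
                strand=".",
                attributes={
                    "ID": lid,
                    "status": loc.status,
                    "mean_pident": repr(float(loc.mean_pident)),
                    "n_hits": str(len(loc.hits)),
                    "total_hit_bp": str(loc.total_hit_bp),
                },
            )
        )
    write_gff3(feats, path)


def read_gff3_loci(path: str | Path):
    """Read loci written by :func:`write_gff3_loci`.

    Component hits are not stored in GFF3, so the returned loci carry an
    empty hit list; class, interval, status, mean identity and the hit-bp
    tally round-trip exactly.
    """
    from .insertion_detect import InsertionLocus

    loci = []
    for f in read_gff3(path):
        if f.type not in ("NUPT", "NUMT", "NUMPT"):
            raise FormatError(f"unexpected feature type {f.type!r} in locus file")
        loci.append(
            InsertionLocus(
                scaffold=f.seqid,
                start=f.start - 1,
                end=f.end,
                cls=f.type,
                hits=(),
                mean_pident=float(f.attributes["mean_pident"]),
                status=f.attributes.get("status", "untested"),
                total_hit_bp=int(f.attributes.get("total_hit_bp", 0)),
                locus_id=f.attributes.get("ID"),
            )
        )
    return loci


# --- SAM -------------------------------------------------------------------

_CIGAR_OPS = "MIDNSHP=X"


def read_sam(path: str | Path) -> Iterator[SamAlignment]:
    """Iterate over a plain-text SAM file as :class:`SamAlignment` records.

    Unmapped records are yielded too (callers filter on ``is_mapped``);
    this keeps the reader a faithful view of the file.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as af:
        for rec in af:
            cig = tuple((_CIGAR_OPS[op], ln) for op, ln in (rec.cigartuples or ()))
            yield SamAlignment(
                qname=rec.query_name or "",
                flag=rec.flag,
                rname=rec.reference_name or "*",
                pos=(rec.reference_start + 1) if rec.reference_start is not None and rec.reference_start >= 0 else 0,
                mapq=rec.mapping_quality,
                cigar=cig,
            )
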