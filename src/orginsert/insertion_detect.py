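"""Detection of organellar DNA insertions from homology hits.

The pipeline is: filter hits on alignment length and identity, drop hits
nested inside longer ones, merge nearby survivors into loci, and classify
each locus as NUPT (plastid-derived), NUMT (mitochondrion-derived) or NUMPT
(containing both).  Loci can then be intersected with gene models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import groupby
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "OrganelleHit",
    "InsertionLocus",
    "filter_hits",
    "remove_nested",
    "merge_loci",
    "intersect_genes",
    "detect_loci",
    "class_bp_totals",
]


@dataclass(frozen=True)
class OrganelleHit:
    """A filtered homology hit of organelle DNA on a nuclear scaffold.

    ``start``/``end`` (scaffold) and ``o_start``/``o_end`` (organelle) are
    0-based half-open.
    """

    scaffold: str
    start: int
    end: int
    organelle: str  # "plastid" | "mito"
    o_start: int
    o_end: int
    strand: str  # "+" | "-"
    pident: float
    aln_length: int
    bitscore: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty hit interval [{self.start},{self.end})")
        if self.aln_length <= 0:
            raise ValueError("aln_length must be positive")
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"pident {self.pident} outside [0,100]")


@dataclass(frozen=True)
class InsertionLocus:
    """A merged, classified insertion locus on a nuclear scaffold."""

    scaffold: str
    start: int
    end: int
    cls: str  # "NUPT" | "NUMT" | "NUMPT"
    hits: tuple[OrganelleHit, ...]
    mean_pident: float
    status: str = "untested"  # "confirmed" | "unconfirmed" | "untested"
    total_hit_bp: int = 0
    locus_id: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def filter_hits(
    hits: Sequence[OrganelleHit],
    min_len: int = 100,
    min_pident: float = 85.0,
) -> list[OrganelleHit]:
    """Keep hits longer than ``min_len`` (strict) at identity >= ``min_pident``.

    The length threshold is exclusive and the identity threshold inclusive:
    a 100 bp hit is dropped, an 85.0% hit is kept.  Input order is
    preserved.
    """
    if min_len < 0 or min_pident < 0:
        raise ValueError("thresholds must be non-negative")
    return [h for h in hits if h.aln_length > min_len and h.pident >= min_pident]


def _tie_key(h: OrganelleHit, idx: int):
    # identical-interval ties: best bitscore, then pident, then input order
    return (-h.bitscore, -h.pident, idx)


def remove_nested(hits: Sequence[OrganelleHit]) -> list[OrganelleHit]:
    """Drop every hit whose scaffold interval is contained in another hit's.

    Containment is evaluated per scaffold and ignores the organelle label,
    so a short mitochondrial hit inside a long plastid hit is removed.
    Among identical intervals exactly one survives (highest bitscore, then
    highest pident, then earliest input position).  Output preserves input
    order.
    """
    keep_idx: set[int] = set()
    indexed = list(enumerate(hits))
    indexed.sort(key=lambda t: t[1].scaffold)
    for _, group in groupby(indexed, key=lambda t: t[1].scaffold):
        entries = list(group)
        # one survivor per distinct interval
        by_interval: dict[tuple[int, int], tuple[int, OrganelleHit]] = {}
        for idx, h in entries:
            key = (h.start, h.end)
            if key not in by_interval or _tie_key(h, idx) < _tie_key(*reversed(by_interval[key])):
                by_interval[key] = (idx, h)
        # sweep: with intervals sorted by (start asc, end desc), an interval
        # is contained iff some earlier interval ends at or beyond it
        distinct = sorted(by_interval.items(), key=lambda kv: (kv[0][0], -kv[0][1]))
        max_end = -1
        for (_, end), (idx, _) in distinct:
            if end > max_end:
                keep_idx.add(idx)
                max_end = end
    return [h for i, h in enumerate(hits) if i in keep_idx]


def _weighted_mean_pident(hits: Sequence[OrganelleHit], weighted: bool) -> float:
    if weighted:
        tot = sum(h.aln_length for h in hits)
        return sum(h.pident * h.aln_length for h in hits) / tot
    return sum(h.pident for h in hits) / len(hits)


def _union_bp(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def merge_loci(
    hits: Sequence[OrganelleHit],
    max_gap: int = 500,
    weighted_identity: bool = True,
) -> list[InsertionLocus]:
    """Group hits into loci and classify each as NUPT, NUMT or NUMPT.

    Hits on one scaffold whose intervals overlap or lie within ``max_gap``
    bp of each other are transitively merged; the locus interval is the
    hull of its member hits.  A locus containing only plastid hits is a
    NUPT, only mitochondrial hits a NUMT, and both a NUMPT.  Mean identity
    is alignment-length weighted by default.  Loci are returned sorted by
    (scaffold, start) with deterministic IDs, status "untested".
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    ordered = sorted(hits, key=lambda h: (h.scaffold, h.start, h.end))
    loci: list[InsertionLocus] = []
    group: list[OrganelleHit] = []

    def _flush() -> None:
        if not group:
            return
        organelles = {h.organelle for h in group}
        cls = "NUMPT" if len(organelles) == 2 else ("NUPT" if "plastid" in organelles else "NUMT")
        loci.append(
            InsertionLocus(
                scaffold=group[0].scaffold,
                start=min(h.start for h in group),
                end=max(h.end for h in group),
                cls=cls,
                hits=tuple(group),
                mean_pident=_weighted_mean_pident(group, weighted_identity),
                total_hit_bp=_union_bp((h.start, h.end) for h in group),
            )
        )

    cur_end = None
    for h in ordered:
        if group and h.scaffold == group[-1].scaffold and h.start - cur_end <= max_gap:
            group.append(h)
            cur_end = max(cur_end, h.end)
        else:
            _flush()
            group = [h]
            cur_end = h.end
    _flush()
    loci.sort(key=lambda l: (l.scaffold, l.start))
    return [
        replace(loc, locus_id=f"{loc.cls}_{loc.scaffold}_{loc.start+1}")
        for loc in loci
    ]


def detect_loci(
    plastid_rows,
    mito_rows,
    min_len: int = 100,
    min_pident: float = 85.0,
    max_gap: int = 500,
    weighted_identity: bool = True,
) -> list[InsertionLocus]:
    """Full detection pipeline from normalized BLAST rows to loci."""
    from .io_formats import normalize_hit

    hits = [normalize_hit(r, "plastid") for r in plastid_rows]
    hits += [normalize_hit(r, "mito") for r in mito_rows]
    hits = filter_hits(hits, min_len=min_len, min_pident=min_pident)
    hits = remove_nested(hits)
    return merge_loci(hits, max_gap=max_gap, weighted_identity=weighted_identity)


def intersect_genes(
    loci: Sequence[InsertionLocus],
    gene_features,
) -> list[tuple[InsertionLocus, str, str]]:
    """Relate insertion loci to gene models.

    Emits ``(locus, relation, gene_id)`` with relation
    ``locus_within_gene`` when the locus lies inside the gene,
    ``gene_within_locus`` when the gene lies inside the locus, and
    ``overlap`` for any other intersection.  Disjoint pairs are omitted.
    Gene features are GFF3 records of type ``gene`` (1-based inclusive).
    """
    trees: dict[str, IntervalTree] = {}
    for f in gene_features:
        if f.type != "gene":
            continue
        gid = f.attributes.get("ID", f"{f.seqid}:{f.start}-{f.end}")
        trees.setdefault(f.seqid, IntervalTree()).addi(f.start - 1, f.end, gid)
    out: list[tuple[InsertionLocus, str, str]] = []
    for loc in loci:
        tree = trees.get(loc.scaffold)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(loc.start, loc.end)):
            g_start, g_end, gid = iv.begin, iv.end, iv.data
            if g_start <= loc.start and loc.end <= g_end:
                rel = "locus_within_gene"
            elif loc.start <= g_start and g_end <= loc.end:
                rel = "gene_within_locus"
            else:
                rel = "overlap"
            out.append((loc, rel, gid))
    return out


def class_bp_totals(
    loci: Sequence[InsertionLocus],
    by_status: bool = False,
    measure: str = "span",
):
    """Total bp per insertion class, mirroring a per-category summary table.

    ``measure`` is ``span`` (locus hull length) or ``hit_union`` (union of
    member hit intervals).  With ``by_status`` the totals are further keyed
    by confirmation status.
    """
    if measure not in ("span", "hit_union"):
        raise ValueError("measure must be 'span' or 'hit_union'")
    totals: dict = {}
    for loc in loci:
        val = loc.length if measure == "span" else loc.total_hit_bp
        key = (loc.cls, loc.status) if by_status else loc.cls
        totals[key] = totals.get(key, 0) + val
    return totals
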