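"""Junction-spanning read validation of insertion loci.

An insertion present in the sequenced genome leaves short reads whose
alignments contiguously cross the organelle-nuclear boundary; an insertion
introduced by a chimeric long read does not, because reads from the true
genome are clipped or split at that boundary.  Each locus is therefore
classified confirmed / unconfirmed / untested from the spanning-read counts
at its two junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from scipy import stats

from .insertion_detect import InsertionLocus

__all__ = [
    "JunctionEvidence",
    "ConfirmationConfig",
    "AnovaResult",
    "junctions_of",
    "count_spanning_reads",
    "confirm_locus",
    "confirm_loci_sam",
    "compare_identity_anova",
]


@dataclass(frozen=True)
class JunctionEvidence:
    """Spanning-read count at one junction of a locus."""

    locus_id: str
    junction_pos: int  # 0-based boundary between nuclear flank and insertion
    side: str  # "left" | "right"
    spanning_reads: int


@dataclass(frozen=True)
class ConfirmationConfig:
    """Thresholds governing when a junction counts as read-supported.

    ``min_reads`` spanning reads (each overhanging the junction by at least
    ``min_overhang`` bp on both sides, at mapping quality >=
    ``min_mapq``) are required per junction; with ``require_all_junctions``
    every testable junction must be supported, otherwise any one suffices.
    Internal deletions up to ``max_internal_deletion`` bp within the
    spanning window are tolerated as indel sequencing error.
    """

    min_reads: int = 1
    min_overhang: int = 20
    min_mapq: int = 20
    require_all_junctions: bool = True
    max_internal_deletion: int = 5

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.min_overhang <= 0:
            raise ValueError("min_overhang must be positive")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


def junctions_of(locus: InsertionLocus, scaffold_length: int) -> list[int]:
    """Testable junction positions of a locus.

    These are the locus boundaries, excluding any boundary that coincides
    with a scaffold terminus (position 0 or the scaffold length): a
    junction at the end of a scaffold has no nuclear flank to span.
    """
    if locus.start < 0 or locus.end > scaffold_length:
        raise ValueError(
            f"locus [{locus.start},{locus.end}) outside scaffold of length {scaffold_length}"
        )
    return [p for p in (locus.start, locus.end) if 0 < p < scaffold_length]


_REF_CONSUMING_MATCH = {"M", "=", "X"}


def _aligned_blocks(pos0: int, cigar, max_del: int) -> list[tuple[int, int]]:
    """Reference blocks contiguously aligned, merging deletions <= max_del.

    ``cigar`` is a sequence of (op, length) with op a CIGAR character.
    Insertions and clips consume no reference; deletions longer than
    ``max_del`` and reference skips (N) break contiguity.
    """
    blocks: list[tuple[int, int]] = []
    ref = pos0
    cur_start = None
    for op, ln in cigar:
        if op in _REF_CONSUMING_MATCH:
            if cur_start is None:
                cur_start = ref
            ref += ln
        elif op == "D":
            if ln <= max_del:
                if cur_start is None:
                    cur_start = ref
                ref += ln
            else:
                if cur_start is not None:
                    blocks.append((cur_start, ref))
                    cur_start = None
                ref += ln
        elif op == "N":
            if cur_start is not None:
                blocks.append((cur_start, ref))
                cur_start = None
            ref += ln
        # I, S, H, P consume no reference
    if cur_start is not None:
        blocks.append((cur_start, ref))
    return blocks


def count_spanning_reads(
    junction_pos: int,
    alignments: Iterable,
    min_overhang: int = 20,
    min_mapq: int = 20,
    max_internal_deletion: int = 5,
) -> int:
    """Count primary mapped reads contiguously covering the junction window.

    A read spans the junction when one of its aligned reference blocks
    covers ``[junction_pos - min_overhang, junction_pos + min_overhang)``
    without interruption; clipped portions contribute nothing.
    """
    if min_overhang <= 0:
        raise ValueError("min_overhang must be positive")
    lo, hi = junction_pos - min_overhang, junction_pos + min_overhang
    n = 0
    for a in alignments:
        if not a.is_mapped or not a.is_primary or a.mapq < min_mapq:
            continue
        for bs, be in _aligned_blocks(a.pos - 1, a.cigar, max_internal_deletion):
            if bs <= lo and be >= hi:
                n += 1
                break
    return n


def confirm_locus(
    locus: InsertionLocus,
    alignments: Sequence,
    scaffold_length: int,
    config: ConfirmationConfig = ConfirmationConfig(),
) -> tuple[InsertionLocus, list[JunctionEvidence]]:
    """Set a locus's confirmation status from junction-spanning reads.

    A locus with no testable junction (it spans the whole scaffold) is
    "untested"; otherwise it is "confirmed" when every (or, with
    ``require_all_junctions=False``, any) junction carries at least
    ``config.min_reads`` spanning reads, else "unconfirmed".
    """
    junctions = junctions_of(locus, scaffold_length)
    if not junctions:
        return replace(locus, status="untested"), []
    evidence = []
    for pos in junctions:
        n = count_spanning_reads(
            pos,
            alignments,
            min_overhang=config.min_overhang,
            min_mapq=config.min_mapq,
            max_internal_deletion=config.max_internal_deletion,
        )
        side = "left" if pos == locus.start else "right"
        evidence.append(JunctionEvidence(locus.locus_id or "", pos, side, n))
    supported = [e.spanning_reads >= config.min_reads for e in evidence]
    ok = all(supported) if config.require_all_junctions else any(supported)
    return replace(locus, status="confirmed" if ok else "unconfirmed"), evidence


def confirm_loci_sam(
    loci: Sequence[InsertionLocus],
    sam_path: str | Path,
    scaffold_lengths: Mapping[str, int],
    config: ConfirmationConfig = ConfirmationConfig(),
) -> tuple[list[InsertionLocus], list[JunctionEvidence]]:
    """Confirm many loci by streaming a SAM file once.

    Equivalent to calling :func:`confirm_locus` per locus with the file's
    alignments, but reads the file a single time, which matters at
    whole-genome coverage.
    """
    # junction windows per scaffold, sorted by window start
    windows: dict[str, list[tuple[int, int, int]]] = {}  # (lo, hi, junction_idx)
    junction_meta: list[tuple[int, int, int]] = []  # (locus_idx, pos, testable)
    counts: list[int] = []
    for li, loc in enumerate(loci):
        slen = scaffold_lengths[loc.scaffold]
        for pos in junctions_of(loc, slen):
            jidx = len(counts)
            counts.append(0)
            junction_meta.append((li, pos, jidx))
            windows.setdefault(loc.scaffold, []).append(
                (pos - config.min_overhang, pos + config.min_overhang, jidx)
            )
    starts: dict[str, np.ndarray] = {}
    for scaf, wlist in windows.items():
        wlist.sort()
        starts[scaf] = np.array([w[0] for w in wlist])

    ops = "MIDNSHP=X"
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < config.min_mapq:
                continue
            scaf = rec.reference_name
            wlist = windows.get(scaf)
            if not wlist:
                continue
            ref_start = rec.reference_start
            ref_end = rec.reference_end
            # candidate windows intersecting [ref_start, ref_end)
            arr = starts[scaf]
            i0 = int(np.searchsorted(arr, ref_start - 2 * config.min_overhang, side="left"))
            blocks = None
            for lo, hi, jidx in wlist[i0:]:
                if lo >= ref_end:
                    break
                if hi > ref_end or lo < ref_start:
                    continue
                if blocks is None:
                    cig = [(ops[o], ln) for o, ln in (rec.cigartuples or ())]
                    blocks = _aligned_blocks(ref_start, cig, config.max_internal_deletion)
                if any(bs <= lo and be >= hi for bs, be in blocks):
                    counts[jidx] += 1

    evidence: list[JunctionEvidence] = []
    per_locus: dict[int, list[JunctionEvidence]] = {}
    for li, pos, jidx in junction_meta:
        loc = loci[li]
        side = "left" if pos == loc.start else "right"
        ev = JunctionEvidence(loc.locus_id or "", pos, side, counts[jidx])
        evidence.append(ev)
        per_locus.setdefault(li, []).append(ev)
    out: list[InsertionLocus] = []
    for li, loc in enumerate(loci):
        evs = per_locus.get(li)
        if not evs:
            out.append(replace(loc, status="untested"))
            continue
        supported = [e.spanning_reads >= config.min_reads for e in evs]
        ok = all(supported) if config.require_all_junctions else any(supported)
        out.append(replace(loc, status="confirmed" if ok else "unconfirmed"))
    return out, evidence


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    group_means: tuple[float, ...]
    df_between: int
    df_within: int


def compare_identity_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA across identity groups.

    Used to ask whether confirmed insertions have lower identity to the
    organellar reference than unconfirmed ones, as expected if confirmed
    loci are genuinely old insertions and unconfirmed ones are artifacts
    whose divergence is mostly sequencing error.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    n_total = sum(a.size for a in arrays)
    if n_total <= len(arrays):
        raise ValueError("total N must exceed the number of groups")
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0.0:
        raise ValueError("zero within-group variance: ANOVA untestable on this input")
    f, p = stats.f_oneway(*arrays)
    return AnovaResult(
        F=float(f),
        p=float(p),
        group_means=tuple(float(a.mean()) for a in arrays),
        df_between=len(arrays) - 1,
        df_within=n_total - len(arrays),
    )
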