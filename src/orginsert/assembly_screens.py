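"""Assembly hygiene screens: minimum contig length and k-mer entropy.

Simple-repeat contigs (homopolymer or short tandem repeats) carry almost no
k-mer diversity, so their Shannon entropy over the empirical k-mer
distribution is far below that of genuine genomic sequence.  Contigs whose
normalized entropy falls under a threshold are flagged for exclusion, after
first dropping contigs below a minimum length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import SequenceRecord

__all__ = ["EntropyReport", "kmer_entropy", "screen_contigs"]

_BASE_CODE = np.full(256, 4, dtype=np.int64)
for i, b in enumerate(b"ACGT"):
    _BASE_CODE[b] = i


@dataclass(frozen=True)
class EntropyReport:
    """Entropy screen result for one contig."""

    contig_id: str
    length: int
    k: int
    entropy_bits: float | None
    max_entropy_bits: float | None
    normalized_entropy: float | None
    flagged: bool
    excluded_by_length: bool = False


def _kmer_counts(seq: str, k: int) -> np.ndarray:
    """Counts of all overlapping k-mers; windows containing N are skipped."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k = {k}")
    codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n_windows = len(seq) - k + 1
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win < 4).all(axis=1)
    if not valid.any():
        raise ValueError("all k-mer windows contain ambiguous bases; entropy undefined")
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    kmers = win[valid] @ powers
    return np.bincount(kmers)


def kmer_entropy(seq: str, k: int) -> float:
    """Shannon entropy in bits of the empirical k-mer distribution.

    H = -sum_i p_i log2 p_i over the frequencies of all overlapping
    k-mers of ``seq`` (windows containing N are skipped).  0 for a
    homopolymer; approaches 2k bits for long uniform-random DNA.
    """
    counts = _kmer_counts(seq, k)
    return float(stats.entropy(counts[counts > 0], base=2))


def screen_contigs(
    contigs: Sequence[SequenceRecord],
    k: int = 5,
    min_len: int = 1000,
    norm_entropy_threshold: float = 0.3,
) -> list[EntropyReport]:
    """Flag simple-repeat contigs by normalized k-mer entropy.

    Contigs shorter than ``min_len`` are marked excluded-by-length and get
    no entropy.  For the rest, entropy is normalized by the maximum
    attainable value min(2k, log2(#counted windows)); a contig is flagged
    when the normalized entropy falls below ``norm_entropy_threshold``.
    """
    if k >= min_len:
        raise ValueError("k must be smaller than min_len")
    reports: list[EntropyReport] = []
    for rec in contigs:
        if rec.length < min_len:
            reports.append(
                EntropyReport(rec.id, rec.length, k, None, None, None, False, True)
            )
            continue
        counts = _kmer_counts(rec.seq, k)
        n_windows = int(counts.sum())
        h = float(stats.entropy(counts[counts > 0], base=2))
        h_max = min(2.0 * k, math.log2(n_windows))
        norm = h / h_max if h_max > 0 else 0.0
        reports.append(
            EntropyReport(
                contig_id=rec.id,
                length=rec.length,
                k=k,
                entropy_bits=h,
                max_entropy_bits=h_max,
                normalized_entropy=norm,
                flagged=norm < norm_entropy_threshold,
            )
        )
    return reports
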