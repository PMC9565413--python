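"""Screen contigs for simple repeats with k-mer Shannon entropy.

A contig made of a homopolymer or a short tandem repeat has only a handful
of distinct k-mers, so its entropy collapses; real genomic sequence sits
near the maximum.  Contigs under 1 kb are excluded outright.
"""

import numpy as np

from orginsert import SequenceRecord, screen_contigs

rng = np.random.default_rng(8)
contigs = [
    SequenceRecord("homopolymer", "A" * 2000),
    SequenceRecord("dinucleotide", "AT" * 1000),
    SequenceRecord("trinucleotide", "ACG" * 700),
    SequenceRecord("genomic_like", "".join(rng.choice(list("ACGT"), size=2000))),
    SequenceRecord("too_short", "".join(rng.choice(list("ACGT"), size=900))),
]

for r in screen_contigs(contigs, k=5, min_len=1000, norm_entropy_threshold=0.3):
    if r.excluded_by_length:
        print(f"{r.contig_id:14s} length {r.length:5d}  excluded (< 1000 bp)")
    else:
        verdict = "FLAGGED as simple repeat" if r.flagged else "kept"
        print(
            f"{r.contig_id:14s} length {r.length:5d}  "
            f"H = {r.entropy_bits:6.3f} bits (normalized {r.normalized_entropy:.3f})  {verdict}"
        )
# Normalized entropy compares H to the maximum attainable for the contig's
# k and window count; values near 0 mean the contig is a simple repeat.
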