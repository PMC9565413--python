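"""Fully deterministic synthetic inputs for every pipeline stage.

The generator builds a nuclear "sample genome" with planted organellar
insertions of controlled divergence, then an "assembly" that additionally
carries artifact insertions the sample genome lacks (emulating chimeric
long-read misassemblies).  Short reads are drawn from the sample genome and
written as a truth SAM against assembly coordinates: reads crossing an
artifact breakpoint are soft-clipped at the junction, exactly as a real
mapper would place reads from the true genome onto a chimeric assembly.
Hit tables with exact coordinates and realized identities stand in for a
homology search.

Every output is a pure function of :class:`SimulationConfig`, including its
seed; derived random streams use distinct child seeds so the stages are
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import BlastTabRow, GffFeature, SequenceRecord, write_blast_tab, write_fasta

__all__ = [
    "SimulationConfig",
    "TruthSegment",
    "SyntheticTruth",
    "Simulation",
    "simulate_genome",
    "make_artifact_assembly",
    "simulate_reads",
    "emit_truth_hits",
    "write_truth_table",
    "make_gene_features",
    "simulate_annotation_tables",
    "SimulatedAnnotations",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic genome and read set.

    Defaults describe a desk-scale experiment: three 1 Mb nuclear
    scaffolds at the assembly's G+C of 36.1%, thirty genuine insertions
    (ten each plastid-only, mitochondrion-only and composite) of 300-3,000
    bp at 2-10% divergence, ten chimeric artifacts, and 30x paired 150 bp
    reads with a 350 bp insert.
    """

    seed: int
    n_scaffolds: int = 3
    scaffold_length: int = 1_000_000
    gc: float = 0.361
    plastid_length: int = 150_000
    mito_length: int = 250_000
    n_nupt: int = 10
    n_numt: int = 10
    n_numpt: int = 10
    insertion_length_range: tuple[int, int] = (300, 3000)
    divergence_range: tuple[float, float] = (0.02, 0.10)
    n_artifacts: int = 10
    artifact_divergence_range: tuple[float, float] | None = None
    coverage: float = 30.0
    read_length: int = 150
    insert_size: int = 350
    read_error_rate: float = 0.002
    min_spacing: int = 5_000
    edge_margin: int = 5_000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "n_scaffolds", "scaffold_length", "plastid_length", "mito_length",
            "read_length", "insert_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be a fraction in (0,1)")
        lo, hi = self.divergence_range
        if not (0 <= lo <= hi <= 0.3):
            raise ValueError("divergence_range must lie within [0, 0.3]")
        if self.insertion_length_range[0] < 1:
            raise ValueError("insertion lengths must be >= 1")
        if self.insert_size < self.read_length:
            raise ValueError("insert_size must be >= read_length")


@dataclass(frozen=True)
class TruthSegment:
    """One planted organelle segment inside an insertion."""

    organelle: str  # "plastid" | "mito"
    o_start: int
    o_end: int
    start: int  # scaffold coordinates, 0-based half-open
    end: int
    strand: str
    n_sub: int
    realized_pident: float


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one planted insertion or artifact (assembly coords)."""

    insertion_id: str
    scaffold: str
    start: int
    end: int
    source: str  # "plastid" | "mito" | "composite"
    divergence: float
    is_artifact: bool
    segments: tuple[TruthSegment, ...] = ()

    @property
    def expected_class(self) -> str:
        return {"plastid": "NUPT", "mito": "NUMT", "composite": "NUMPT"}[self.source]


@dataclass
class Simulation:
    """All synthetic state: organelles, sample genome, assembly, truth."""

    config: SimulationConfig
    organelles: dict[str, str]
    scaffolds: dict[str, str]  # the sample (read-generating) genome
    assembly: dict[str, str]  # what the detection pipeline sees
    truth: list[SyntheticTruth]
    # per scaffold: (position in sample coords, inserted length) of artifacts
    artifact_map: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def assembly_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(k, v) for k, v in self.assembly.items()]

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.assembly.items()}

    def write_assembly(self, path: str | Path) -> None:
        write_fasta(self.assembly_records, path)

    def write_organelles(self, path: str | Path) -> None:
        write_fasta([SequenceRecord(k, v) for k, v in self.organelles.items()], path)


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _mutate(rng: np.random.Generator, codes: np.ndarray, d: float) -> tuple[np.ndarray, int]:
    """Apply i.i.d. substitutions at rate d; every substitution changes the base."""
    out = codes.copy()
    n_sub = int(rng.binomial(len(codes), d))
    if n_sub:
        pos = rng.choice(len(codes), size=n_sub, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, size=n_sub).astype(np.uint8)) % 4
    return out, n_sub


def _pick_sites(
    rng: np.random.Generator,
    scaffold_length: int,
    n: int,
    min_spacing: int,
    edge_margin: int,
    occupied: Sequence[tuple[int, int]] = (),
) -> list[int]:
    """Insertion points keeping min_spacing from each other and from occupied intervals."""
    sites: list[int] = []
    tries = 0
    while len(sites) < n:
        tries += 1
        if tries > 200 * n + 1000:
            raise ValueError("cannot place insertions: scaffold capacity exceeded")
        cand = int(rng.integers(edge_margin, scaffold_length - edge_margin))
        if any(abs(cand - s) < min_spacing for s in sites):
            continue
        if any(s - min_spacing < cand < e + min_spacing for s, e in occupied):
            continue
        sites.append(cand)
    return sorted(sites)


def _draw_segment(
    rng: np.random.Generator,
    organelle_codes: dict[str, np.ndarray],
    organelle: str,
    length: int,
    divergence: float,
) -> tuple[np.ndarray, TruthSegment]:
    org = organelle_codes[organelle]
    if length > len(org):
        raise ValueError("insertion longer than organelle genome")
    o_start = int(rng.integers(0, len(org) - length + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    seg = org[o_start : o_start + length]
    if strand == "-":
        seg = _revcomp_codes(seg)
    seg, n_sub = _mutate(rng, seg, divergence)
    meta = TruthSegment(
        organelle=organelle,
        o_start=o_start,
        o_end=o_start + length,
        start=-1,
        end=-1,
        strand=strand,
        n_sub=n_sub,
        realized_pident=100.0 * (1.0 - n_sub / length),
    )
    return seg, meta


def simulate_genome(config: SimulationConfig) -> Simulation:
    """Generate organelles, nuclear scaffolds and planted genuine insertions.

    Returns a :class:`Simulation` whose ``assembly`` equals the sample
    genome (no artifacts yet; see :func:`make_artifact_assembly`).  Fully
    deterministic given the config.
    """
    rng = np.random.default_rng([config.seed, 0])
    organelle_codes = {
        "plastid": _random_codes(rng, config.plastid_length, config.gc),
        "mito": _random_codes(rng, config.mito_length, config.gc),
    }
    base = {
        f"scaffold_{i+1}": _random_codes(rng, config.scaffold_length, config.gc)
        for i in range(config.n_scaffolds)
    }
    scaffold_ids = list(base)

    # plan insertions, spread round-robin over scaffolds
    kinds = ["plastid"] * config.n_nupt + ["mito"] * config.n_numt + ["composite"] * config.n_numpt
    rng.shuffle(kinds)
    per_scaffold: dict[str, list[str]] = {sid: [] for sid in scaffold_ids}
    for i, kind in enumerate(kinds):
        per_scaffold[scaffold_ids[i % len(scaffold_ids)]].append(kind)

    lo_len, hi_len = config.insertion_length_range
    lo_d, hi_d = config.divergence_range
    truth: list[SyntheticTruth] = []
    scaffolds: dict[str, str] = {}
    counter = 0
    for sid in scaffold_ids:
        plan = per_scaffold[sid]
        sites = _pick_sites(
            rng, config.scaffold_length, len(plan), config.min_spacing, config.edge_margin
        )
        pieces: list[np.ndarray] = []
        prev = 0
        offset = 0
        for site, kind in zip(sites, plan):
            counter += 1
            total_len = int(rng.integers(lo_len, hi_len + 1))
            d = float(rng.uniform(lo_d, hi_d))
            segs: list[tuple[np.ndarray, TruthSegment]] = []
            if kind == "composite":
                frac = float(rng.uniform(0.4, 0.6))
                l1 = max(1, int(round(total_len * frac)))
                l2 = max(1, total_len - l1)
                segs.append(_draw_segment(rng, organelle_codes, "plastid", l1, d))
                segs.append(_draw_segment(rng, organelle_codes, "mito", l2, d))
            else:
                segs.append(_draw_segment(rng, organelle_codes, kind, total_len, d))
            pieces.append(base[sid][prev:site])
            ins_start = site + offset
            pos = ins_start
            seg_meta: list[TruthSegment] = []
            for codes, meta in segs:
                pieces.append(codes)
                seg_meta.append(replace(meta, start=pos, end=pos + len(codes)))
                pos += len(codes)
            truth.append(
                SyntheticTruth(
                    insertion_id=f"ins_{counter}",
                    scaffold=sid,
                    start=ins_start,
                    end=pos,
                    source=kind,
                    divergence=d,
                    is_artifact=False,
                    segments=tuple(seg_meta),
                )
            )
            offset += pos - ins_start
            prev = site
        pieces.append(base[sid][prev:])
        scaffolds[sid] = _decode(np.concatenate(pieces))

    return Simulation(
        config=config,
        organelles={k: _decode(v) for k, v in organelle_codes.items()},
        scaffolds=scaffolds,
        assembly=dict(scaffolds),
        truth=truth,
    )


def make_artifact_assembly(sim: Simulation) -> Simulation:
    """Insert chimeric-artifact segments into the assembly only.

    The returned simulation's ``assembly`` contains ``n_artifacts``
    organellar insertions absent from the read-generating sample genome;
    truth coordinates (including the genuine insertions') are lifted to
    assembly coordinates and the sample-to-assembly breakpoint map is
    recorded for the read simulator.
    """
    config = sim.config
    rng = np.random.default_rng([config.seed, 1])
    organelle_codes = {k: _encode(v) for k, v in sim.organelles.items()}
    lo_len, hi_len = config.insertion_length_range
    d_range = config.artifact_divergence_range or config.divergence_range

    scaffold_ids = list(sim.scaffolds)
    per_scaffold: dict[str, int] = {sid: 0 for sid in scaffold_ids}
    for i in range(config.n_artifacts):
        per_scaffold[scaffold_ids[i % len(scaffold_ids)]] += 1

    new_assembly: dict[str, str] = {}
    artifact_map: dict[str, list[tuple[int, int]]] = {}
    new_truth: list[SyntheticTruth] = []
    counter = 0
    for sid in scaffold_ids:
        sample_codes = _encode(sim.scaffolds[sid])
        occupied = [(t.start, t.end) for t in sim.truth if t.scaffold == sid]
        n_here = per_scaffold[sid]
        sites = _pick_sites(
            rng, len(sample_codes), n_here, config.min_spacing, config.edge_margin, occupied
        ) if n_here else []
        pieces: list[np.ndarray] = []
        prev = 0
        offset = 0
        art_entries: list[tuple[int, int]] = []
        art_truth: list[SyntheticTruth] = []
        for site in sites:
            counter += 1
            organelle = "plastid" if counter % 2 else "mito"
            length = int(rng.integers(lo_len, hi_len + 1))
            d = float(rng.uniform(*d_range))
            codes, meta = _draw_segment(rng, organelle_codes, organelle, length, d)
            pieces.append(sample_codes[prev:site])
            start = site + offset
            pieces.append(codes)
            art_truth.append(
                SyntheticTruth(
                    insertion_id=f"art_{counter}",
                    scaffold=sid,
                    start=start,
                    end=start + length,
                    source=organelle,
                    divergence=d,
                    is_artifact=True,
                    segments=(replace(meta, start=start, end=start + length),),
                )
            )
            art_entries.append((site, length))
            offset += length
            prev = site
        pieces.append(sample_codes[prev:])
        new_assembly[sid] = _decode(np.concatenate(pieces)) if pieces else sim.scaffolds[sid]
        artifact_map[sid] = art_entries

        # lift genuine truth on this scaffold to assembly coordinates
        art_pos = np.array([p for p, _ in art_entries], dtype=np.int64)
        art_cum = np.concatenate([[0], np.cumsum([l for _, l in art_entries])]).astype(np.int64)
        for t in sim.truth:
            if t.scaffold != sid:
                continue
            shift = int(art_cum[np.searchsorted(art_pos, t.start, side="right")])
            new_truth.append(
                replace(
                    t,
                    start=t.start + shift,
                    end=t.end + shift,
                    segments=tuple(
                        replace(s, start=s.start + shift, end=s.end + shift)
                        for s in t.segments
                    ),
                )
            )
        new_truth.extend(art_truth)

    new_truth.sort(key=lambda t: (t.scaffold, t.start))
    return Simulation(
        config=config,
        organelles=dict(sim.organelles),
        scaffolds=dict(sim.scaffolds),
        assembly=new_assembly,
        truth=new_truth,
        artifact_map=artifact_map,
    )


def simulate_reads(
    sim: Simulation,
    sam_path: str | Path,
    fastq1: str | Path | None = None,
    fastq2: str | Path | None = None,
) -> int:
    """Draw paired reads from the sample genome; write a truth SAM.

    Reads are placed uniformly at the configured coverage with i.i.d.
    substitution errors.  Alignments are reported against assembly
    coordinates: a read whose fragment crosses an artifact breakpoint is
    soft-clipped at the junction (keeping the longer aligned part), so by
    construction no read spans an artifact junction while genuine-insertion
    junctions are covered like any other position.  Returns the number of
    pairs written.
    """
    config = sim.config
    rng = np.random.default_rng([config.seed, 2])
    rl, isize = config.read_length, config.insert_size
    if rl > min(len(s) for s in sim.scaffolds.values()):
        raise ValueError("read_length exceeds the shortest scaffold")

    sam_path = Path(sam_path)
    fq1 = Path(fastq1).open("w") if fastq1 else None
    fq2 = Path(fastq2).open("w") if fastq2 else None
    n_pairs_total = 0
    comp = str.maketrans("ACGT", "TGCA")
    with sam_path.open("w") as out:
        out.write("@HD\tVN:1.6\tSO:unsorted\n")
        for sid, seq in sim.assembly.items():
            out.write(f"@SQ\tSN:{sid}\tLN:{len(seq)}\n")
        out.write("@PG\tID:orginsert\tPN:orginsert-simulate\n")
        for scaf_idx, (sid, sample_seq) in enumerate(sim.scaffolds.items()):
            codes = _encode(sample_seq)
            L = len(codes)
            if isize > L:
                raise ValueError("insert_size exceeds scaffold length")
            n_pairs = int(round(L * config.coverage / (2 * rl)))
            starts = rng.integers(0, L - isize + 1, size=n_pairs)
            starts.sort()
            r2_starts = starts + isize - rl
            idx = np.arange(rl)
            frag1 = codes[starts[:, None] + idx]
            frag2 = codes[r2_starts[:, None] + idx]
            # i.i.d. substitution errors over all read bases at once
            for frag in (frag1, frag2):
                n_err = int(rng.binomial(frag.size, config.read_error_rate))
                if n_err:
                    flat = rng.choice(frag.size, size=n_err, replace=False)
                    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                    frag.ravel()[flat] = (frag.ravel()[flat] + shift) % 4

            arts = sim.artifact_map.get(sid, [])
            art_pos = np.array([p for p, _ in arts], dtype=np.int64)
            art_cum = np.concatenate([[0], np.cumsum([l for _, l in arts])]).astype(np.int64)

            def lift(pos: np.ndarray) -> np.ndarray:
                return pos + art_cum[np.searchsorted(art_pos, pos, side="right")]

            lines: list[str] = []
            pos1_all = lift(starts)
            pos2_all = lift(r2_starts)
            for mate, (fr, st, pos_out, mate_pos_all) in enumerate(
                (
                    (frag1, starts, pos1_all, pos2_all),
                    (frag2, r2_starts, pos2_all, pos1_all),
                ),
                start=1,
            ):
                ends = st + rl
                n_breaks = np.searchsorted(art_pos, ends, side="left") - np.searchsorted(
                    art_pos, st, side="right"
                )
                seqs = _BASES[fr]
                flag = 99 if mate == 1 else 147
                for i in range(n_pairs):
                    s = int(st[i])
                    cigar = f"{rl}M"
                    p = int(pos_out[i])
                    if n_breaks[i]:
                        j = int(np.searchsorted(art_pos, s, side="right"))
                        bp = int(art_pos[j])  # first breakpoint inside the read
                        a, b = bp - s, s + rl - bp
                        if a >= b:
                            cigar = f"{a}M{b}S"
                        else:
                            cigar = f"{a}S{b}M"
                            p = bp + int(art_cum[j + 1])
                    qname = f"r{scaf_idx}_{i}"
                    tlen = isize if mate == 1 else -isize
                    lines.append(
                        f"{qname}\t{flag}\t{sid}\t{p + 1}\t60\t{cigar}\t=\t"
                        f"{int(mate_pos_all[i]) + 1}\t{tlen}\t{seqs[i].tobytes().decode()}\t*"
                    )
                if mate == 1 and fq1 is not None:
                    for i in range(n_pairs):
                        fq1.write(f"@r{scaf_idx}_{i}/1\n{seqs[i].tobytes().decode()}\n+\n{'I'*rl}\n")
                if mate == 2 and fq2 is not None:
                    for i in range(n_pairs):
                        rc = seqs[i].tobytes().decode().translate(comp)[::-1]
                        fq2.write(f"@r{scaf_idx}_{i}/2\n{rc}\n+\n{'I'*rl}\n")
            out.write("\n".join(lines) + "\n")
            n_pairs_total += n_pairs
    if fq1:
        fq1.close()
    if fq2:
        fq2.close()
    return n_pairs_total


def emit_truth_hits(
    sim: Simulation,
    path: str | Path | None = None,
    inject_nested: bool = False,
    inject_subthreshold: bool = False,
) -> tuple[list[BlastTabRow], list[BlastTabRow]]:
    """Emit a BLAST-tabular hit table from the truth (assembly coordinates).

    Returns ``(plastid_rows, mito_rows)`` and optionally writes a combined
    file.  ``inject_nested`` adds rows strictly contained in true rows (the
    de-nesting step must remove them without changing the locus set);
    ``inject_subthreshold`` adds short (<=100 bp) and low-identity rows
    that the default hit filter must drop.
    """
    rng = np.random.default_rng([sim.config.seed, 3])
    plastid_rows: list[BlastTabRow] = []
    mito_rows: list[BlastTabRow] = []

    def _row(seg: TruthSegment, scaffold: str, start: int, end: int,
             o_start: int, o_end: int, pident: float, n_sub: int) -> BlastTabRow:
        length = end - start
        if seg.strand == "+":
            sstart, send = start + 1, end
        else:
            sstart, send = end, start + 1
        return BlastTabRow(
            qseqid=seg.organelle,
            sseqid=scaffold,
            pident=round(pident, 2),
            length=length,
            mismatch=n_sub,
            gapopen=0,
            qstart=o_start + 1,
            qend=o_end,
            sstart=sstart,
            send=send,
            evalue=0.0,
            bitscore=round(1.8 * length, 1),
        )

    for t in sim.truth:
        for seg in t.segments:
            row = _row(seg, t.scaffold, seg.start, seg.end, seg.o_start, seg.o_end,
                       seg.realized_pident, seg.n_sub)
            (plastid_rows if seg.organelle == "plastid" else mito_rows).append(row)
            if inject_nested and seg.end - seg.start >= 200:
                pad = int(rng.integers(10, 40))
                ns, ne = seg.start + pad, seg.end - pad
                if ne - ns > 100:
                    sub = _row(seg, t.scaffold, ns, ne,
                               seg.o_start + pad, seg.o_end - pad,
                               seg.realized_pident, max(0, seg.n_sub - 1))
                    (plastid_rows if seg.organelle == "plastid" else mito_rows).append(sub)

    if inject_subthreshold:
        scaffold_ids = list(sim.assembly)
        for k in range(8):
            sid = scaffold_ids[int(rng.integers(len(scaffold_ids)))]
            slen = len(sim.assembly[sid])
            pos = int(rng.integers(0, slen - 600))
            short = BlastTabRow(
                "plastid", sid, 95.0, 80, 4, 0, 1, 80, pos + 1, pos + 80, 1e-20, 140.0
            )
            lowid = BlastTabRow(
                "mito", sid, 70.0, 500, 150, 0, 1, 500, pos + 1, pos + 500, 1e-30, 300.0
            )
            plastid_rows.append(short)
            mito_rows.append(lowid)

    if path is not None:
        write_blast_tab(plastid_rows + mito_rows, path)
    return plastid_rows, mito_rows


def write_truth_table(sim: Simulation, path: str | Path) -> None:
    """Write the truth as a TSV (assembly coordinates, 0-based half-open)."""
    with Path(path).open("w") as fh:
        fh.write(
            "insertion_id\tscaffold\tstart\tend\tsource\tdivergence\tis_artifact\tsegments\n"
        )
        for t in sim.truth:
            segs = ";".join(
                f"{s.organelle}:{s.o_start}-{s.o_end}:{s.start}-{s.end}:{s.strand}"
                f":{s.realized_pident:.2f}"
                for s in t.segments
            )
            fh.write(
                f"{t.insertion_id}\t{t.scaffold}\t{t.start}\t{t.end}\t{t.source}\t"
                f"{t.divergence:.4f}\t{int(t.is_artifact)}\t{segs}\n"
            )


@dataclass(frozen=True)
class RecoveryRecord:
    """How one truth entry fared in detection and confirmation."""

    insertion_id: str
    is_artifact: bool
    expected_class: str
    recovered: bool
    class_correct: bool
    boundary_error: int | None  # max of |start error|, |end error|; None if missed
    status: str | None  # confirmation status of the matched locus


def match_loci_to_truth(loci, truth: Sequence[SyntheticTruth]) -> list[RecoveryRecord]:
    """Match detected loci to planted truth entries by interval overlap.

    Each truth entry is matched to the detected locus on its scaffold with
    the largest overlap (if any).  The boundary error is the larger of the
    start and end discrepancies in bp.
    """
    by_scaffold: dict[str, list] = {}
    for loc in loci:
        by_scaffold.setdefault(loc.scaffold, []).append(loc)
    records: list[RecoveryRecord] = []
    for t in truth:
        best = None
        best_ov = 0
        for loc in by_scaffold.get(t.scaffold, []):
            ov = min(t.end, loc.end) - max(t.start, loc.start)
            if ov > best_ov:
                best, best_ov = loc, ov
        if best is None:
            records.append(
                RecoveryRecord(t.insertion_id, t.is_artifact, t.expected_class,
                               False, False, None, None)
            )
        else:
            records.append(
                RecoveryRecord(
                    insertion_id=t.insertion_id,
                    is_artifact=t.is_artifact,
                    expected_class=t.expected_class,
                    recovered=True,
                    class_correct=best.cls == t.expected_class,
                    boundary_error=max(abs(best.start - t.start), abs(best.end - t.end)),
                    status=best.status,
                )
            )
    return records


# --- toy annotation fixtures ----------------------------------------------


def make_gene_features(
    loci,
    scaffold_lengths: dict[str, int],
    seed: int,
) -> list[GffFeature]:
    """Gene models exercising every locus/gene relation.

    For each locus in turn this plants (cycling) a gene containing the
    locus, a gene inside it (when it is long enough), a gene overlapping
    one boundary, and a distant disjoint gene.
    """
    rng = np.random.default_rng([seed, 4])
    feats: list[GffFeature] = []
    for i, loc in enumerate(loci):
        slen = scaffold_lengths[loc.scaffold]
        kind = i % 4
        if kind == 0:
            s, e = max(0, loc.start - 500), min(slen, loc.end + 500)
        elif kind == 1:
            if loc.length < 40:
                continue
            s, e = loc.start + 10, loc.end - 10
        elif kind == 2:
            s, e = max(0, loc.start - 300), min(slen, loc.start + max(1, loc.length // 2))
        else:
            s = min(slen - 200, loc.end + 2000 + int(rng.integers(0, 500)))
            e = s + 150
        feats.append(
            GffFeature(
                seqid=loc.scaffold,
                source="synthetic",
                type="gene",
                start=s + 1,
                end=e,
                score=None,
                strand="+" if rng.random() < 0.5 else "-",
                attributes={"ID": f"gene_{i+1}"},
            )
        )
    return feats


_INNOCUOUS_DESCRIPTIONS = (
    "Protein kinase domain",
    "Zinc finger, C3HC4 type",
    "Leucine rich repeat",
    "Cytochrome P450",
    "WD domain, G-beta repeat",
    "Myb-like DNA-binding domain",
)

_TRANSPOSON_DESCRIPTIONS = (
    "Transposase DDE domain",
    "RNA-directed DNA polymerase (reverse transcriptase)",
    "Retroviral aspartyl protease",
    "GAG-polyprotein putative aspartyl protease",
    "Integrase core domain of retrotransposon",
)


@dataclass
class SimulatedAnnotations:
    """Toy gene-annotation tables with planted signal."""

    domain_annotations: list
    transposon_gene_ids: set[str]
    evidence: list
    unsupported_gene_ids: set[str]
    matrix: "object"  # DomainCountMatrix
    expanded_domains: set[str]
    contracted_domains: set[str]
    study_genes: set[str]
    background_genes: set[str]
    term_map: dict[str, set[str]]
    enriched_term: str


def simulate_annotation_tables(
    seed: int,
    n_genes: int = 120,
    n_transposon: int = 12,
    n_unsupported: int = 15,
    n_species: int = 16,
    n_domains: int = 40,
    n_expanded: int = 4,
    n_contracted: int = 3,
) -> SimulatedAnnotations:
    """Deterministic annotation fixtures with known planted signal.

    Plants ``n_transposon`` genes whose Pfam descriptions are mostly
    transposon-related, ``n_unsupported`` genes lacking both external
    support and functional annotation, ``n_expanded``/``n_contracted``
    domains whose focal count sits far outside the cross-species spread,
    and one term strongly over-represented in the study gene set.
    """
    import pandas as pd

    from .annotation_stats import (
        DomainCountMatrix,
        GeneDomainAnnotation,
        GeneEvidence,
    )

    rng = np.random.default_rng([seed, 5])
    gene_ids = [f"g{i+1:04d}" for i in range(n_genes)]

    te_ids = set(rng.choice(gene_ids, size=n_transposon, replace=False).tolist())
    annotations = []
    for gid in gene_ids:
        n_dom = int(rng.integers(1, 5))
        if gid in te_ids:
            n_te = n_dom // 2 + 1  # strictly more than half
            descs = [str(rng.choice(_TRANSPOSON_DESCRIPTIONS)) for _ in range(n_te)]
            descs += [str(rng.choice(_INNOCUOUS_DESCRIPTIONS)) for _ in range(n_dom - n_te)]
        else:
            descs = [str(rng.choice(_INNOCUOUS_DESCRIPTIONS)) for _ in range(n_dom)]
        annotations.append(
            GeneDomainAnnotation(
                gene_id=gid,
                domains=tuple((f"PF{rng.integers(10000):05d}", d) for d in descs),
            )
        )

    unsupported = set(rng.choice(gene_ids, size=n_unsupported, replace=False).tolist())
    evidence = []
    for gid in gene_ids:
        if gid in unsupported:
            evidence.append(GeneEvidence(gid, False, False))
        else:
            # genes outside the planted set always retain some evidence
            support = bool(rng.random() < 0.8)
            annotation = True if not support else bool(rng.random() < 0.9)
            evidence.append(GeneEvidence(gid, support, annotation))

    species = [f"sp{i+1}" for i in range(n_species - 1)] + ["focal"]
    domains = [f"PF{i+1:05d}" for i in range(n_domains)]
    counts = rng.poisson(6.0, size=(n_species, n_domains)).astype(int)
    df = pd.DataFrame(counts, index=species, columns=domains)
    expanded = set(domains[:n_expanded])
    contracted = set(domains[n_expanded : n_expanded + n_contracted])
    for dom in expanded:
        base = df.loc[df.index != "focal", dom]
        df.loc["focal", dom] = int(base.mean() + 5 * max(base.std(ddof=1), 1.0))
    for dom in contracted:
        df.loc["focal", dom] = 0
        df.loc[df.index != "focal", dom] = rng.integers(8, 12, size=n_species - 1)
    matrix = DomainCountMatrix(counts=df, focal_species="focal")

    terms = [f"KO{i+1:03d}" for i in range(8)]
    enriched_term = terms[0]
    term_map: dict[str, set[str]] = {}
    carriers = set(rng.choice(gene_ids, size=n_genes // 4, replace=False).tolist())
    for gid in gene_ids:
        assigned = {t for t in terms[1:] if rng.random() < 0.15}
        if gid in carriers:
            assigned.add(enriched_term)
        term_map[gid] = assigned
    carrier_list = sorted(carriers)
    non_carriers = sorted(set(gene_ids) - carriers)
    study = set(carrier_list[: len(carrier_list) * 2 // 3])
    study |= set(rng.choice(non_carriers, size=5, replace=False).tolist())

    return SimulatedAnnotations(
        domain_annotations=annotations,
        transposon_gene_ids=te_ids,
        evidence=evidence,
        unsupported_gene_ids=unsupported,
        matrix=matrix,
        expanded_domains=expanded,
        contracted_domains=contracted,
        study_genes=study,
        background_genes=set(gene_ids),
        term_map=term_map,
        enriched_term=enriched_term,
    )
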