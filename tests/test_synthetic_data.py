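import numpy as np
import pytest

from orginsert import (
    ConfirmationConfig,
    SimulationConfig,
    confirm_loci_sam,
    count_spanning_reads,
    detect_loci,
    emit_truth_hits,
    flag_transposon_genes,
    filter_hits,
    filter_unsupported_genes,
    hypergeometric_enrichment,
    intersect_genes,
    junctions_of,
    make_artifact_assembly,
    match_loci_to_truth,
    normalize_hit,
    pfam_zscores,
    read_sam,
    simulate_annotation_tables,
    simulate_genome,
    simulate_reads,
)
from orginsert.synthetic_data import make_gene_features


def tiny_config(**kw):
    defaults = dict(
        seed=7,
        n_scaffolds=2,
        scaffold_length=60_000,
        n_nupt=1,
        n_numt=1,
        n_numpt=1,
        n_artifacts=2,
        coverage=15.0,
        min_spacing=3000,
        edge_margin=3000,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestSimulateGenome:
    def test_same_seed_is_byte_identical(self, tmp_path):
        sims = [make_artifact_assembly(simulate_genome(tiny_config())) for _ in range(2)]
        assert sims[0].assembly == sims[1].assembly
        assert sims[0].organelles == sims[1].organelles
        assert sims[0].truth == sims[1].truth
        paths = []
        for i, sim in enumerate(sims):
            p = tmp_path / f"r{i}.sam"
            simulate_reads(sim, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_genome(tiny_config(seed=1))
        b = simulate_genome(tiny_config(seed=2))
        assert a.assembly != b.assembly

    def test_zero_divergence_plants_exact_organelle_copy(self):
        sim = simulate_genome(tiny_config(divergence_range=(0.0, 0.0)))
        for t in sim.truth:
            for seg in t.segments:
                planted = sim.assembly[t.scaffold][seg.start : seg.end]
                source = sim.organelles[seg.organelle][seg.o_start : seg.o_end]
                if seg.strand == "-":
                    source = source.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                assert planted == source
                assert seg.realized_pident == 100.0

    def test_realized_identity_concentrates_at_one_minus_d(self):
        cfg = tiny_config(
            seed=19,
            insertion_length_range=(2000, 2000),
            divergence_range=(0.05, 0.05),
            n_numpt=0,
        )
        sim = simulate_genome(cfg)
        for t in sim.truth:
            for seg in t.segments:
                assert seg.realized_pident == pytest.approx(95.0, abs=1.5)

    def test_gc_content_honoured(self):
        sim = simulate_genome(tiny_config(seed=23, scaffold_length=200_000, gc=0.361))
        seq = sim.scaffolds["scaffold_1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.361, abs=0.01)

    def test_capacity_exceeded_raises(self):
        with pytest.raises(ValueError, match="capacity"):
            simulate_genome(
                tiny_config(scaffold_length=8000, n_nupt=20, min_spacing=2000, edge_margin=2000)
            )


class TestTruthHits:
    def test_hit_intervals_match_truth_after_normalization(self):
        sim = make_artifact_assembly(simulate_genome(tiny_config()))
        pt, mt = emit_truth_hits(sim)
        hits = [normalize_hit(r, "plastid") for r in pt] + [normalize_hit(r, "mito") for r in mt]
        truth_segments = {
            (s.start, s.end, t.scaffold, s.organelle)
            for t in sim.truth
            for s in t.segments
        }
        got = {(h.start, h.end, h.scaffold, h.organelle) for h in hits}
        assert got == truth_segments

    def test_nested_noise_does_not_change_detected_loci(self):
        sim = make_artifact_assembly(simulate_genome(tiny_config()))
        clean = detect_loci(*emit_truth_hits(sim))
        noisy = detect_loci(*emit_truth_hits(sim, inject_nested=True))
        assert noisy == clean

    def test_subthreshold_noise_is_filtered_out(self):
        sim = make_artifact_assembly(simulate_genome(tiny_config()))
        pt_clean, mt_clean = emit_truth_hits(sim)
        pt, mt = emit_truth_hits(sim, inject_subthreshold=True)
        assert len(pt) > len(pt_clean)
        normalized = [normalize_hit(r, "plastid") for r in pt]
        normalized += [normalize_hit(r, "mito") for r in mt]
        kept = filter_hits(normalized)
        clean = [normalize_hit(r, "plastid") for r in pt_clean]
        clean += [normalize_hit(r, "mito") for r in mt_clean]
        assert kept == filter_hits(clean)


class TestSimulateReads:
    def test_mean_coverage_near_target(self, tmp_path):
        cfg = SimulationConfig(
            seed=3, n_scaffolds=1, scaffold_length=100_000, n_nupt=1, n_numt=0,
            n_numpt=0, n_artifacts=0, coverage=30.0,
        )
        sim = simulate_genome(cfg)
        sam = tmp_path / "r.sam"
        n_pairs = simulate_reads(sim, sam)
        total_bases = n_pairs * 2 * cfg.read_length
        realized = total_bases / len(sim.scaffolds["scaffold_1"])
        assert realized == pytest.approx(30.0, abs=2.0)

    def test_zero_error_reads_are_exact_substrings(self, tmp_path):
        cfg = tiny_config(seed=5, read_error_rate=0.0, coverage=2.0)
        sim = simulate_genome(cfg)
        sam = tmp_path / "r.sam"
        fq1 = tmp_path / "r1.fastq"
        simulate_reads(sim, sam, fastq1=fq1)
        genome = "".join(sim.scaffolds.values())
        seqs = [l for i, l in enumerate(fq1.read_text().splitlines()) if i % 4 == 1]
        assert seqs
        for seq in seqs[:200]:
            assert seq in genome

    def test_truth_sam_parses_and_stays_in_bounds(self, small_sim, small_sim_sam):
        lengths = small_sim.scaffold_lengths
        n = 0
        for a in read_sam(small_sim_sam):
            n += 1
            assert a.is_mapped and a.mapq == 60
            ref_len = sum(l for op, l in a.cigar if op in "MDN=X")
            assert 1 <= a.pos and a.pos - 1 + ref_len <= lengths[a.rname]
        assert n > 1000

    def test_read_length_longer_than_scaffold_rejected(self):
        cfg = SimulationConfig(
            seed=1, n_scaffolds=1, scaffold_length=200, read_length=150, insert_size=150,
            n_nupt=0, n_numt=0, n_numpt=0, edge_margin=10, min_spacing=10,
        )
        sim = simulate_genome(cfg)
        sim.scaffolds["scaffold_1"] = sim.scaffolds["scaffold_1"][:100]
        with pytest.raises(ValueError):
            simulate_reads(sim, "/dev/null")


class TestArtifacts:
    def test_artifact_junctions_have_zero_spanning_reads(self, small_sim, small_sim_sam):
        alignments = list(read_sam(small_sim_sam))
        by_scaffold = {}
        for a in alignments:
            by_scaffold.setdefault(a.rname, []).append(a)
        lengths = small_sim.scaffold_lengths
        for t in small_sim.truth:
            if not t.is_artifact:
                continue
            for pos in (t.start, t.end):
                if 0 < pos < lengths[t.scaffold]:
                    assert count_spanning_reads(pos, by_scaffold[t.scaffold]) == 0

    def test_genuine_junctions_are_read_supported(self, small_sim, small_sim_sam):
        alignments = list(read_sam(small_sim_sam))
        by_scaffold = {}
        for a in alignments:
            by_scaffold.setdefault(a.rname, []).append(a)
        lengths = small_sim.scaffold_lengths
        for t in small_sim.truth:
            if t.is_artifact:
                continue
            for pos in (t.start, t.end):
                if 0 < pos < lengths[t.scaffold]:
                    assert count_spanning_reads(pos, by_scaffold[t.scaffold]) >= 1

    def test_end_to_end_recovery_separates_genuine_from_artifact(
        self, small_sim, small_sim_sam
    ):
        loci = detect_loci(*emit_truth_hits(small_sim))
        confirmed, _ = confirm_loci_sam(
            loci, small_sim_sam, small_sim.scaffold_lengths, ConfirmationConfig()
        )
        records = match_loci_to_truth(confirmed, small_sim.truth)
        for r in records:
            assert r.recovered and r.class_correct and r.boundary_error == 0
            assert r.status == ("unconfirmed" if r.is_artifact else "confirmed")

    def test_streaming_and_in_memory_confirmation_agree(self, small_sim, small_sim_sam):
        from orginsert import confirm_locus

        loci = detect_loci(*emit_truth_hits(small_sim))
        streamed, _ = confirm_loci_sam(loci, small_sim_sam, small_sim.scaffold_lengths)
        by_scaffold = {}
        for a in read_sam(small_sim_sam):
            by_scaffold.setdefault(a.rname, []).append(a)
        for loc, got in zip(loci, streamed):
            ref, _ = confirm_locus(
                loc, by_scaffold[loc.scaffold], small_sim.scaffold_lengths[loc.scaffold]
            )
            assert got.status == ref.status


@pytest.fixture(scope="module")
def tables():
    return simulate_annotation_tables(seed=11)


class TestAnnotationFixtures:
    def test_planted_transposon_genes_recovered_exactly(self, tables):
        assert flag_transposon_genes(tables.domain_annotations) == tables.transposon_gene_ids

    def test_planted_unsupported_genes_recovered_exactly(self, tables):
        assert filter_unsupported_genes(tables.evidence) == tables.unsupported_gene_ids

    def test_planted_domain_shifts_called(self, tables):
        df = pfam_zscores(tables.matrix)
        assert set(df.index[df["call"] == "expanded"]) >= tables.expanded_domains
        assert set(df.index[df["call"] == "contracted"]) >= tables.contracted_domains

    def test_planted_term_is_top_enriched(self, tables):
        results = hypergeometric_enrichment(
            tables.study_genes, tables.background_genes, tables.term_map
        )
        assert results[0].term_id == tables.enriched_term
        assert results[0].significant

    def test_gene_features_cover_every_relation(self, small_sim):
        loci = detect_loci(*emit_truth_hits(small_sim))
        genes = make_gene_features(loci, small_sim.scaffold_lengths, seed=2)
        relations = {rel for _, rel, _ in intersect_genes(loci, genes)}
        assert {"locus_within_gene", "gene_within_locus", "overlap"} <= relations
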