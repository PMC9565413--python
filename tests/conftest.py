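import pytest

from orginsert import OrganelleHit, SimulationConfig, make_artifact_assembly, simulate_genome


def make_hit(
    scaffold="s1",
    start=0,
    end=200,
    organelle="plastid",
    o_start=0,
    o_end=None,
    strand="+",
    pident=95.0,
    aln_length=None,
    bitscore=100.0,
):
    length = end - start
    return OrganelleHit(
        scaffold=scaffold,
        start=start,
        end=end,
        organelle=organelle,
        o_start=o_start,
        o_end=o_end if o_end is not None else o_start + length,
        strand=strand,
        pident=pident,
        aln_length=aln_length if aln_length is not None else length,
        bitscore=bitscore,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulation: 2 x 120 kb scaffolds, 6 genuine
    insertions, 4 artifacts, 20x reads."""
    cfg = SimulationConfig(
        seed=42,
        n_scaffolds=2,
        scaffold_length=120_000,
        n_nupt=2,
        n_numt=2,
        n_numpt=2,
        n_artifacts=4,
        coverage=20.0,
        min_spacing=4000,
        edge_margin=4000,
    )
    return make_artifact_assembly(simulate_genome(cfg))


@pytest.fixture(scope="session")
def small_sim_sam(small_sim, tmp_path_factory):
    from orginsert import simulate_reads

    path = tmp_path_factory.mktemp("sam") / "truth.sam"
    simulate_reads(small_sim, path)
    return path
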