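import random

import numpy as np
import pytest

from orginsert import (
    GffFeature,
    class_bp_totals,
    filter_hits,
    intersect_genes,
    merge_loci,
    remove_nested,
)

from conftest import make_hit


def brute_force_denest(hits):
    """O(n^2) reference: drop any hit contained in another on the same
    scaffold; among identical intervals keep best (bitscore, pident, order)."""
    keep = []
    for i, h in enumerate(hits):
        contained = False
        for j, g in enumerate(hits):
            if i == j or h.scaffold != g.scaffold:
                continue
            if g.start <= h.start and h.end <= g.end:
                if (h.start, h.end) == (g.start, g.end):
                    if (-g.bitscore, -g.pident, j) < (-h.bitscore, -h.pident, i):
                        contained = True
                        break
                else:
                    contained = True
                    break
        if not contained:
            keep.append(h)
    return keep


def interval_union_bp(intervals):
    covered = set()
    for s, e in intervals:
        covered.update(range(s, e))
    return len(covered)


class TestFilterHits:
    @pytest.mark.parametrize(
        "length,pident,kept",
        [
            (100, 99.0, False),  # length threshold is strict
            (101, 85.0, True),  # identity threshold is inclusive
            (101, 84.99, False),
            (5000, 100.0, True),
        ],
    )
    def test_printed_thresholds(self, length, pident, kept):
        hit = make_hit(end=length, pident=pident, aln_length=length)
        assert (filter_hits([hit]) == [hit]) is kept

    def test_empty_input(self):
        assert filter_hits([]) == []

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_hits([], min_len=-1)

    def test_order_preserved_and_monotone(self):
        rng = np.random.default_rng(0)
        hits = [
            make_hit(start=i * 1000, end=i * 1000 + int(rng.integers(50, 400)),
                     pident=float(rng.uniform(80, 100)))
            for i in range(40)
        ]
        kept = filter_hits(hits)
        assert kept == [h for h in hits if h in kept]
        for min_len in (100, 150, 200):
            for min_pid in (85.0, 90.0, 95.0):
                stricter = filter_hits(hits, min_len=min_len, min_pident=min_pid)
                assert len(stricter) <= len(kept)


class TestRemoveNested:
    def test_strict_containment_removed(self):
        a = make_hit(start=100, end=500)
        b = make_hit(start=200, end=300)
        assert remove_nested([a, b]) == [a]

    def test_containment_ignores_organelle_label(self):
        a = make_hit(start=100, end=500, organelle="plastid")
        b = make_hit(start=150, end=400, organelle="mito")
        assert remove_nested([b, a]) == [a]

    def test_identical_intervals_tie_on_bitscore(self):
        a = make_hit(start=100, end=500, bitscore=200.0)
        b = make_hit(start=100, end=500, bitscore=150.0)
        assert remove_nested([b, a]) == [a]

    def test_partial_overlap_both_kept(self):
        a = make_hit(start=100, end=500)
        b = make_hit(start=300, end=700)
        assert remove_nested([a, b]) == [a, b]

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n = int(rng.integers(1, 51))
            hits = []
            for _ in range(n):
                s = int(rng.integers(0, 500))
                e = s + int(rng.integers(1, 200))
                hits.append(
                    make_hit(
                        scaffold=f"s{int(rng.integers(1, 4))}",
                        start=s,
                        end=e,
                        bitscore=float(rng.integers(50, 300)),
                        pident=float(np.round(rng.uniform(85, 100), 1)),
                    )
                )
            assert remove_nested(hits) == brute_force_denest(hits)


class TestMergeLoci:
    def test_adjacent_plastid_and_mito_form_numpt(self):
        hits = [
            make_hit(start=1000, end=1400, organelle="plastid"),
            make_hit(start=1350, end=1700, organelle="mito"),
        ]
        (locus,) = merge_loci(hits)
        assert (locus.start, locus.end, locus.cls) == (1000, 1700, "NUMPT")

    def test_single_mito_hit_is_numt(self):
        (locus,) = merge_loci([make_hit(start=10, end=200, organelle="mito")])
        assert (locus.start, locus.end, locus.cls) == (10, 200, "NUMT")

    def test_gap_beyond_max_gap_splits_loci(self):
        hits = [make_hit(start=0, end=200), make_hit(start=2000, end=2200)]
        loci = merge_loci(hits, max_gap=500)
        assert [l.cls for l in loci] == ["NUPT", "NUPT"]
        assert len(loci) == 2

    def test_gap_within_max_gap_merges(self):
        hits = [make_hit(start=0, end=200), make_hit(start=650, end=900)]
        assert len(merge_loci(hits, max_gap=500)) == 1

    def test_mean_identity_is_length_weighted(self):
        hits = [
            make_hit(start=0, end=100, pident=90.0),  # length 100
            make_hit(start=50, end=350, pident=96.0),  # length 300
        ]
        (locus,) = merge_loci(hits)
        assert locus.mean_pident == pytest.approx((90 * 100 + 96 * 300) / 400)
        (unweighted,) = merge_loci(hits, weighted_identity=False)
        assert unweighted.mean_pident == pytest.approx(93.0)

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_loci([], max_gap=-1)

    def test_pipeline_is_permutation_invariant(self):
        rng = np.random.default_rng(9)
        hits = []
        for i in range(60):
            s = int(rng.integers(0, 50_000))
            e = s + int(rng.integers(101, 2000))
            hits.append(
                make_hit(
                    scaffold=f"s{int(rng.integers(1, 3))}",
                    start=s,
                    end=e,
                    organelle="plastid" if rng.random() < 0.5 else "mito",
                    pident=float(np.round(rng.uniform(85, 100), 1)),
                    bitscore=float(rng.integers(100, 500)),
                )
            )
        ref = merge_loci(remove_nested(filter_hits(hits)))
        for shuffle_seed in range(5):
            shuffled = hits[:]
            random.Random(shuffle_seed).shuffle(shuffled)
            got = merge_loci(remove_nested(filter_hits(shuffled)))
            assert got == ref

    def test_loci_disjoint_and_monotone_in_max_gap(self):
        rng = np.random.default_rng(11)
        hits = [
            make_hit(start=int(s), end=int(s) + int(rng.integers(101, 1500)))
            for s in rng.integers(0, 100_000, size=50)
        ]
        hits = remove_nested(hits)
        prev_n = None
        for gap in (0, 100, 500, 2000, 10_000):
            loci = merge_loci(hits, max_gap=gap)
            for a, b in zip(loci, loci[1:]):
                if a.scaffold == b.scaffold:
                    assert a.end <= b.start
            if prev_n is not None:
                assert len(loci) <= prev_n
            prev_n = len(loci)

    def test_hit_union_totals_match_oracle(self):
        rng = np.random.default_rng(13)
        hits = [
            make_hit(
                start=int(s),
                end=int(s) + int(rng.integers(101, 800)),
                organelle="plastid" if rng.random() < 0.5 else "mito",
            )
            for s in rng.integers(0, 20_000, size=30)
        ]
        hits = remove_nested(hits)
        loci = merge_loci(hits)
        totals = class_bp_totals(loci, measure="hit_union")
        expected = {}
        for loc in loci:
            bp = interval_union_bp([(h.start, h.end) for h in loc.hits])
            expected[loc.cls] = expected.get(loc.cls, 0) + bp
        assert totals == expected


class TestIntersectGenes:
    def _gene(self, start0, end0, gid="g1"):
        return GffFeature("s1", "test", "gene", start0 + 1, end0, None, "+", {"ID": gid})

    @pytest.mark.parametrize(
        "gene_iv,relation",
        [
            ((4000, 9000), "locus_within_gene"),
            ((6000, 6500), "gene_within_locus"),
            ((7000, 9500), "overlap"),
        ],
    )
    def test_relations(self, gene_iv, relation):
        (locus,) = merge_loci([make_hit(start=5000, end=8000)])
        ((_, rel, gid),) = intersect_genes([locus], [self._gene(*gene_iv)])
        assert rel == relation and gid == "g1"

    def test_disjoint_pairs_omitted(self):
        (locus,) = merge_loci([make_hit(start=5000, end=8000)])
        assert intersect_genes([locus], [self._gene(9000, 9500)]) == []

    def test_non_gene_features_ignored(self):
        (locus,) = merge_loci([make_hit(start=5000, end=8000)])
        exon = GffFeature("s1", "t", "exon", 5001, 8000, None, "+", {"ID": "e1"})
        assert intersect_genes([locus], [exon]) == []
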