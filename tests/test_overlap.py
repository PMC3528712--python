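import numpy as np
import pytest

from gapbridge import dna
from gapbridge.model import Contig, ContigSet, make_gap
from gapbridge.overlap import (EdgeSeq, GapResolver, SearchParams,
                               extract_edge, find_overlaps, resolve_gap)


@pytest.fixture(scope="module")
def planted():
    """A little genome with a planted bridge: L and R flank a middle contig
    overlapping each by 100 bp."""
    rng = np.random.default_rng(0)
    g = dna.random_dna(rng, 9000)
    db = ContigSet([
        Contig("cL", g[:3100], 70.0),
        Contig("cB", g[3000:6100], 70.0),
        Contig("cR", g[6000:9000], 70.0),
        Contig("junk", dna.random_dna(rng, 2000), 14.0),
    ])
    return g, db


class TestExtractEdge:
    def test_three_prime_edge_is_last_kilobase(self):
        c = Contig("c", "ACGT" * 1250)  # 5000 bp
        e = extract_edge(c, "3p")
        assert e.side_tag == "W" and len(e.seq) == 1000
        assert e.seq == c.seq[-1000:]

    def test_short_contig_clamps_to_whole_sequence(self):
        c = Contig("c", "ACGTAC" * 100)  # 600 bp
        for side, tag in (("5p", "E"), ("3p", "W")):
            e = extract_edge(c, side)
            assert e.seq == c.seq and e.side_tag == tag

    def test_exact_length_boundary(self):
        c = Contig("c", "ACGT" * 250)  # 1000 bp
        e = extract_edge(c, "5p")
        assert e.seq == c.seq and e.side_tag == "E"


class TestFindOverlaps:
    def test_exact_dovetail(self, planted):
        g, db = planted
        edge = extract_edge(db.lookup("cL"), "3p")
        hits = find_overlaps(edge, db)
        assert hits and hits[0].subject_id == "cB"
        h = hits[0]
        assert h.identity == 1.0 and h.reaches_edge
        assert h.subject_interval == (0, 100)

    def test_mismatches_within_threshold_kept(self, planted):
        g, db = planted
        L = db.lookup("cL").seq
        suffix = list(L[-200:])
        for i in (20, 90, 170):
            suffix[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[suffix[i]]
        subj = "".join(suffix) + dna.random_dna(np.random.default_rng(5), 800)
        db2 = ContigSet([Contig("cL", L), Contig("s", subj)])
        hits = find_overlaps(extract_edge(db2.lookup("cL"), "3p"), db2)
        assert hits and hits[0].identity >= 0.95
        assert hits[0].identity == pytest.approx(197 / 200, abs=1e-9)

    def test_low_identity_filtered(self, planted):
        g, db = planted
        L = db.lookup("cL").seq
        suffix = dna.mutate(np.random.default_rng(1), L[-200:], 0.10)
        subj = suffix + dna.random_dna(np.random.default_rng(2), 800)
        db2 = ContigSet([Contig("cL", L), Contig("s", subj)])
        hits = find_overlaps(extract_edge(db2.lookup("cL"), "3p"), db2)
        assert not hits

    def test_symmetry_of_dovetails(self, planted):
        g, db = planted
        fwd = find_overlaps(extract_edge(db.lookup("cL"), "3p"), db)
        h = next(x for x in fwd if x.subject_id == "cB")
        # the mirrored search: cB's 5' edge against cL, reversed roles
        rev_edge = EdgeSeq("cB", "W", dna.revcomp(db.lookup("cB").seq)[-1000:])
        back = find_overlaps(rev_edge, db)
        mirror = next(x for x in back if x.subject_id == "cL")
        overlap_f = h.subject_interval[1] - h.subject_interval[0]
        overlap_b = mirror.subject_interval[1] - mirror.subject_interval[0]
        assert overlap_f == overlap_b == 100

    def test_empty_database(self):
        db = ContigSet([Contig("only", "ACGT" * 300)])
        hits = find_overlaps(extract_edge(db.lookup("only"), "3p"), db)
        assert hits == []


class TestResolveGap:
    def test_direct_flank_overlap(self, planted):
        g, _db = planted
        db = ContigSet([Contig("a", g[:3100]), Contig("b", g[3000:6000])])
        paths = resolve_gap(make_gap("a", "b", estimated_length=20), db)
        assert len(paths) == 1
        assert [c for c, _o in paths[0].contigs] == ["a", "b"]
        assert paths[0].junctions[0].overlap == 100

    def test_single_intermediate_bridge(self, planted):
        g, db = planted
        paths = resolve_gap(make_gap("cL", "cR", estimated_length=3000), db)
        assert [c for c, _o in paths[0].contigs] == ["cL", "cB", "cR"]
        assert paths[0].consensus == g

    def test_reverse_complement_bridge(self, planted):
        g, _old = planted
        db = ContigSet([Contig("cL", g[:3100]), Contig("cB", dna.revcomp(g[3000:6100])),
                        Contig("cR", g[6000:9000])])
        paths = resolve_gap(make_gap("cL", "cR", estimated_length=3000), db)
        assert paths[0].contigs[1] == ("cB", "reverse")
        assert paths[0].consensus == g

    def test_two_homologous_bridges_give_two_paths(self, planted):
        g, _old = planted
        alt = dna.mutate(np.random.default_rng(9), g[3000:6100], 0.02)
        db = ContigSet([Contig("cL", g[:3100]), Contig("cB1", g[3000:6100]),
                        Contig("cB2", alt), Contig("cR", g[6000:9000])])
        paths = resolve_gap(make_gap("cL", "cR", estimated_length=3000), db)
        mids = sorted(p.contigs[1][0] for p in paths)
        assert mids == ["cB1", "cB2"]

    def test_unresolvable_gap_returns_empty(self, planted):
        g, _old = planted
        db = ContigSet([Contig("cL", g[:3000]), Contig("cR", g[6000:9000])])
        assert resolve_gap(make_gap("cL", "cR", estimated_length=3000), db) == []

    def test_deterministic(self, planted):
        g, db = planted
        gap = make_gap("cL", "cR", estimated_length=3000)
        p1 = resolve_gap(gap, db)
        p2 = resolve_gap(gap, db)
        assert [p.contigs for p in p1] == [p.contigs for p in p2]
        assert [p.consensus for p in p1] == [p.consensus for p in p2]

    def test_threshold_monotonicity(self, planted):
        """Relaxing identity/e-value thresholds never removes a path."""
        g, _old = planted
        alt = dna.mutate(np.random.default_rng(9), g[3000:6100], 0.02)
        db = ContigSet([Contig("cL", g[:3100]), Contig("cB1", g[3000:6100]),
                        Contig("cB2", alt), Contig("cR", g[6000:9000])])
        gap = make_gap("cL", "cR", estimated_length=3000)
        strict = {p.key() for p in resolve_gap(
            gap, db, SearchParams(min_identity=0.98, max_evalue=1e-30))}
        relaxed = {p.key() for p in resolve_gap(
            gap, db, SearchParams(min_identity=0.90, max_evalue=1e-5))}
        assert strict <= relaxed

    def test_consensus_length_conservation(self, planted):
        """len(consensus) = sum(contig lengths) - sum(overlaps) - sum(trims)."""
        g, db = planted
        paths = resolve_gap(make_gap("cL", "cR", estimated_length=3000), db)
        p = paths[0]
        total = sum(db.lookup(c).length for c, _o in p.contigs)
        consumed = sum(j.overlap + j.trim_left + j.trim_right for j in p.junctions)
        assert len(p.consensus) == total - consumed

    def test_foreign_subject_edge_is_trimmed(self, planted):
        """A bridge with a chimeric head segment still dovetails; the
        foreign bases are recorded as trim and excluded from the merge."""
        g, _old = planted
        foreign = dna.random_dna(np.random.default_rng(4), 80)
        db = ContigSet([Contig("cL", g[:3100]), Contig("cB", foreign + g[3000:6100]),
                        Contig("cR", g[6000:9000])])
        paths = resolve_gap(make_gap("cL", "cR", estimated_length=3000), db)
        assert paths and paths[0].consensus == g
        assert paths[0].junctions[0].trim_right == 80
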