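import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gapbridge import dna
from gapbridge.model import (Contig, ContigPlacement, ContigSet, DepthBands,
                             InputError, ScaffoldLayout, enumerate_gaps,
                             make_gap, read_contigs, read_scaffolds,
                             write_scaffolds)


def _layout(sid, n_contigs, contig_len=100, gap=100, prefix=None):
    prefix = prefix or sid
    contigs = [Contig(f"{prefix}_c{i}", "ACGT" * (contig_len // 4))
               for i in range(n_contigs)]
    placements = [ContigPlacement(c.id, "forward", i)
                  for i, c in enumerate(contigs)]
    return contigs, ScaffoldLayout(sid, placements, [gap] * (n_contigs - 1))


class TestContigIO:
    def test_round_trip_with_depths(self, tmp_path):
        fa = tmp_path / "c.fasta"
        fa.write_text(">a\nACGTACGT\n>b\nggttaacc\n")
        tsv = tmp_path / "d.tsv"
        tsv.write_text("contig_id\tdepth\na\t70.5\nb\t35.0\nunknown\t1.0\n")
        cs = read_contigs(fa, tsv)
        assert len(cs) == 2
        assert cs.lookup("a").depth == 70.5
        # lowercase input is uppercased on load
        assert cs.lookup("b").seq == "GGTTAACC"

    def test_duplicate_ids_rejected(self, tmp_path):
        fa = tmp_path / "c.fasta"
        fa.write_text(">a\nACGT\n>a\nACGT\n")
        with pytest.raises(InputError):
            read_contigs(fa)

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            Contig("x", "")

    def test_invalid_characters_rejected(self):
        with pytest.raises(dna.SequenceError):
            dna.clean("ACGTX")


class TestAGP:
    def test_three_component_scaffold(self, tmp_path):
        contigs, layout = _layout("s1", 3)
        cs = ContigSet(contigs)
        agp = tmp_path / "s.agp"
        write_scaffolds([layout], cs, agp)
        back = read_scaffolds(agp, cs)
        assert len(back) == 1
        assert [p.contig_id for p in back[0].placements] == \
            [p.contig_id for p in layout.placements]
        assert back[0].gap_estimates == [100, 100]

    def test_round_trip_preserves_orientation_and_gaps(self, tmp_path):
        contigs, layout = _layout("s1", 4, gap=250)
        layout.placements[2].orientation = "reverse"
        cs = ContigSet(contigs)
        agp = tmp_path / "s.agp"
        write_scaffolds([layout], cs, agp)
        back = read_scaffolds(agp, cs)[0]
        assert [p.orientation for p in back.placements] == \
            ["forward", "forward", "reverse", "forward"]
        assert back.gap_estimates == layout.gap_estimates

    def test_gap_below_scaffolder_floor_clamped(self, tmp_path):
        contigs, layout = _layout("s1", 2)
        layout.gap_estimates[0] = 5
        cs = ContigSet(contigs)
        agp = tmp_path / "s.agp"
        write_scaffolds([layout], cs, agp)
        assert read_scaffolds(agp, cs)[0].gap_estimates == [20]

    def test_unknown_component_is_hard_error(self, tmp_path):
        contigs, layout = _layout("s1", 2)
        cs = ContigSet(contigs[:1])
        agp = tmp_path / "s.agp"
        write_scaffolds([layout], ContigSet(contigs), agp)
        with pytest.raises(InputError):
            read_scaffolds(agp, cs)

    def test_single_component_scaffold_has_no_gaps(self, tmp_path):
        contigs, layout = _layout("s1", 1)
        cs = ContigSet(contigs)
        agp = tmp_path / "s.agp"
        write_scaffolds([layout], cs, agp)
        assert read_scaffolds(agp, cs)[0].gap_estimates == []


class TestGapEnumeration:
    def test_names_follow_flank_ids(self):
        contigs, layout = _layout("s1", 3)
        gaps = enumerate_gaps([layout])
        assert [g.name for g in gaps] == ["s1_c0-G-s1_c1", "s1_c1-G-s1_c2"]

    def test_gap_name_style(self):
        g = make_gap("contig00290", "contig00291")
        assert g.name == "contig00290-G-contig00291"

    def test_count_over_nine_scaffolds(self):
        # a draft with 9 scaffolds containing 41/29/17/10/2/3/4/2/2 contigs
        per_scaffold = [41, 29, 17, 10, 2, 3, 4, 2, 2]
        layouts = []
        for i, n in enumerate(per_scaffold):
            _c, lay = _layout(f"sc{i:03d}", n)
            layouts.append(lay)
        gaps = enumerate_gaps(layouts)
        assert len(gaps) == 101
        assert len(gaps) == sum(n - 1 for n in per_scaffold)

    def test_sides_derive_from_orientation(self):
        g = make_gap("a", "b", "reverse", "forward")
        assert g.left_side == "5p" and g.right_side == "5p"


class TestDepthBands:
    def test_invalid_ordering_rejected(self):
        with pytest.raises(InputError):
            DepthBands(shared_depth=70, strain_lo=0.8)


@settings(derandomize=True, max_examples=50)
@given(st.text(alphabet="ACGTN", min_size=1, max_size=300))
def test_revcomp_involution(s):
    assert dna.revcomp(dna.revcomp(s)) == s


@settings(derandomize=True, max_examples=20)
@given(st.lists(st.integers(min_value=1, max_value=8), min_size=1, max_size=6))
def test_gap_count_is_sum_of_placements_minus_one(sizes):
    layouts = []
    for i, n in enumerate(sizes):
        _c, lay = _layout(f"s{i}", n)
        layouts.append(lay)
    assert len(enumerate_gaps(layouts)) == sum(n - 1 for n in sizes)
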