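import numpy as np
import pytest

from gapbridge import dna
from gapbridge.model import Contig, ContigSet, DepthBands, make_gap
from gapbridge.overlap import BridgePath, Junction
from gapbridge.simulate import make_ordering_fixture
from gapbridge.solver import (GapSolution, classify_depth, compare_distances,
                              estimate_shared_depth, gap_distance,
                              order_scaffolds, solve_gaps)


def _cs(entries):
    return ContigSet([Contig(i, "ACGT" * max(1, l // 4), d)
                      for i, l, d in entries])


class TestDepthClassification:
    def test_regions_at_field_typical_depths(self):
        # shared depth 69.5: a 277x transposase contig is multi-copy, a 31x
        # contig is strain-specific, a 14x contig belongs to the background
        cs = _cs([("t", 2361, 277.4), ("s", 1148, 30.86), ("b", 2000, 14.0),
                  ("sh", 5000, 71.4)])
        bands = DepthBands(shared_depth=69.5)
        regions = {d.contig_id: d.region for d in classify_depth(cs, bands)}
        assert regions == {"t": "A_multicopy", "s": "C_strain",
                           "b": "D_background", "sh": "B_shared"}

    def test_missing_depth_left_unset(self):
        cs = ContigSet([Contig("x", "ACGT" * 100)])
        out = classify_depth(cs, DepthBands(shared_depth=70))
        assert out[0].region is None

    def test_ambiguous_band_noted(self):
        cs = _cs([("m", 1000, 70 * 0.32)])  # between background and strain band
        d = classify_depth(cs, DepthBands(shared_depth=70))[0]
        assert d.region == "D_background" and d.note == "ambiguous"


class TestSharedDepthEstimate:
    def test_trimodal_planted_depths(self, rng):
        entries = []
        for i in range(30):
            entries.append((f"sh{i}", int(rng.integers(2000, 6000)),
                            70 * rng.uniform(0.93, 1.07)))
        for i in range(12):
            entries.append((f"st{i}", int(rng.integers(800, 2000)),
                            35 * rng.uniform(0.9, 1.1)))
        for i in range(5):
            entries.append((f"mc{i}", 1500, 140 * rng.uniform(0.9, 1.1)))
        est = estimate_shared_depth(_cs(entries))
        assert abs(est - 70) / 70 < 0.10

    def test_uniform_depths_return_that_depth(self):
        est = estimate_shared_depth(_cs([(f"c{i}", 1000, 55.0) for i in range(12)]))
        assert est == pytest.approx(55.0)

    def test_too_few_depths_error(self):
        with pytest.raises(ValueError):
            estimate_shared_depth(_cs([("a", 1000, 70)]))


def _fake_solution(name, group, dist, est, bridge_len=None, flags=()):
    left, right = name.split("-G-")
    contigs = [Contig(left, "A" * 1000), Contig(right, "A" * 1000)]
    chain = [(left, "forward")]
    if bridge_len:
        contigs.append(Contig("bridge", "A" * bridge_len))
        chain.append(("bridge", "forward"))
    chain.append((right, "forward"))
    db = ContigSet(contigs)
    cons_len = 2000 + dist
    path = BridgePath(chain, [Junction(100, 1.0, 0, 0)] * (len(chain) - 1),
                      "A" * cons_len, score=100)
    sol = GapSolution(gap=make_gap(left, right, estimated_length=est),
                      group=group, paths=[path],
                      computed_distance_per_path=[dist], flags=set(flags))
    return sol, db


class TestDistances:
    def test_direct_overlap_distance_is_negative_overlap(self):
        rng = np.random.default_rng(0)
        g = dna.random_dna(rng, 5000)
        db = ContigSet([Contig("a", g[:2650]), Contig("b", g[2500:])])
        from gapbridge.overlap import resolve_gap

        p = resolve_gap(make_gap("a", "b", estimated_length=20), db)[0]
        assert gap_distance(p, db) == -150

    def test_intermediate_distance_arithmetic(self):
        # one 2000 bp intermediate, junction overlaps 300 and 250, no trims
        sol, db = _fake_solution("l-G-r", "B", 2000 - 300 - 250, 1450,
                                 bridge_len=2000)
        assert sol.computed_distance_per_path[0] == 1450

    def test_tandem_deficit_flags_candidate(self):
        # a 2287 bp multi-copy element bridging a gap: computed 1106 vs the
        # mate-pair estimate 3111 implies a second tandem copy
        sol, db = _fake_solution("c39-G-c40", "B", 1106, 3111,
                                 bridge_len=2287, flags={"multi_copy_bridge"})
        compare_distances([sol], db)
        assert "distance_discrepant" in sol.flags
        assert "tandem_candidate" in sol.flags

    def test_matching_distance_not_flagged(self):
        sol, db = _fake_solution("l-G-r", "B", 1450, 1460, bridge_len=2000)
        compare_distances([sol], db)
        assert "distance_discrepant" not in sol.flags

    def test_group_d_insertion_bias_not_flagged(self):
        # insertion path distance far above the averaged estimate: expected
        sol, db = _fake_solution("l-G-r", "D", 5000, 2600, bridge_len=5000)
        compare_distances([sol], db)
        assert "distance_discrepant" not in sol.flags

    def test_negative_distance_with_floored_estimate_not_flagged(self):
        sol, db = _fake_solution("l-G-r", "A", -620, 20)
        compare_distances([sol], db)
        assert "distance_discrepant" not in sol.flags


class TestFixtureClassification:
    def test_group_labels_match_planted_truth(self, fixture42, solved42, truth42):
        n = len(solved42.solutions)
        correct = sum(s.group == truth42[s.gap.name].group
                      for s in solved42.solutions)
        assert correct == n

    def test_alternative_pairs_recorded_for_polymorphic_gaps(
            self, solved42, truth42):
        for s in solved42.solutions:
            gt = truth42[s.gap.name]
            if gt.group == "C":
                expect = {tuple(sorted((gt.bridges["strain1"][0],
                                        gt.bridges["strain2"][0])))}
                assert set(s.alternative_pairs) == expect

    def test_alternative_scaffold_proposed(self, fixture42, solved42):
        assert [p.alt_scaffold_id for p in solved42.proposals] == \
            [fixture42.truth.alt_scaffold_id]
        sub_pairs = {(a, b) for a, b, _g in solved42.proposals[0].substitutions}
        assert sub_pairs == set(fixture42.truth.alt_scaffold_pairs)


class TestScaffoldOrdering:
    def test_circular_genome_cut_into_three_scaffolds(self):
        cs, scaffolds, _genome = make_ordering_fixture(0, n_scaffolds=3)
        order = order_scaffolds(scaffolds, cs)
        assert order.closed_circle
        assert order.components[0]["scaffolds"] == ["oscaf0", "oscaf1", "oscaf2"]

    def test_unrelated_scaffolds_have_no_edge(self):
        rng = np.random.default_rng(1)
        from gapbridge.model import ContigPlacement, ScaffoldLayout

        contigs = [Contig(f"u{i}", dna.random_dna(rng, 4000)) for i in range(2)]
        cs = ContigSet(contigs)
        scaffolds = [ScaffoldLayout(f"s{i}", [ContigPlacement(f"u{i}", "forward", 0)], [])
                     for i in range(2)]
        order = order_scaffolds(scaffolds, cs)
        assert order.edges == [] and not order.closed_circle
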