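import numpy as np
import pytest

from gapbridge import dna
from gapbridge.mapping import (InsertModel, ReadPair, low_coverage_regions,
                               map_pairs, tandem_test, write_sam)
from gapbridge.simulate import simulate_pairs


@pytest.fixture(scope="module")
def genome():
    return dna.random_dna(np.random.default_rng(2), 40000)


@pytest.fixture(scope="module")
def im():
    return InsertModel(647, 60)


@pytest.fixture(scope="module")
def mapped(genome, im):
    pairs = simulate_pairs(genome, im, 50, 76, seed=5, circular=False)
    return pairs, map_pairs(pairs, genome, im)


class TestMapPairs:
    def test_error_free_pairs_place_nearly_all(self, mapped):
        pairs, res = mapped
        assert res.n_placed / res.n_pairs >= 0.99
        interior = res.profile.total[1000:-1000]
        assert abs(interior.mean() - 50) / 50 < 0.10

    def test_depth_conservation(self, mapped):
        _pairs, res = mapped
        assert res.profile.total.sum() == 2 * res.n_placed * 76

    def test_true_positions_recovered(self, genome, im):
        pairs = simulate_pairs(genome, im, 2, 76, seed=8, circular=False)
        res = map_pairs(pairs, genome, im)
        for pl in res.placements[:50]:
            lo = min(pl.mate1.start, pl.mate2.start)
            frag = genome[lo:lo + pl.insert]
            assert frag.startswith(pl.mate1.seq) or frag.startswith(pl.mate2.seq)

    def test_insert_far_outside_gate_rejected(self, genome, im):
        m1 = genome[100:176]
        m2 = dna.revcomp(genome[5000:5076])  # implied insert ~4976 >> gate
        res = map_pairs([ReadPair("x", m1, m2)], genome, im)
        assert res.n_placed == 0 and res.n_discordant == 1

    def test_repeat_ambiguity_rejected_but_recorded(self, im):
        rng = np.random.default_rng(3)
        unit = dna.random_dna(rng, 3000)
        ref = unit + dna.random_dna(rng, 2000) + unit
        pairs = simulate_pairs(unit, im, 20, 76, seed=9, circular=False)
        res = map_pairs(pairs, ref, im)
        assert res.n_ambiguous > 0 and res.n_placed == 0
        # ambiguous coverage still registers where the copies are
        assert res.profile.depth_ambiguous[1500] > 0

    def test_sam_export_parses(self, mapped, genome, tmp_path):
        import pysam

        _pairs, res = mapped
        path = tmp_path / "out.sam"
        write_sam(res, "ref", len(genome), path)
        with pysam.AlignmentFile(str(path)) as sam:
            reads = list(sam)
        assert len(reads) == 2 * res.n_placed
        assert all(r.is_paired and r.is_proper_pair for r in reads[:20])


class TestLowCoverage:
    def test_uniform_coverage_has_no_intervals(self, mapped):
        _pairs, res = mapped
        lows = low_coverage_regions(res.profile)
        # only the reference ends, where coverage necessarily ramps
        assert all(iv.start < 1000 or iv.end > len(res.profile.total) - 1000
                   for iv in lows)

    def test_foreign_splice_produces_interval(self, genome, im):
        rng = np.random.default_rng(7)
        spliced = genome[:20000] + dna.random_dna(rng, 300) + genome[20000:]
        pairs = simulate_pairs(genome, im, 40, 76, seed=10, circular=False)
        res = map_pairs(pairs, spliced, im)
        lows = low_coverage_regions(res.profile)
        assert any(iv.start < 20300 and iv.end > 20000 for iv in lows)

    def test_zero_min_depth_is_vacuous(self, mapped):
        _pairs, res = mapped
        assert low_coverage_regions(res.profile, min_depth=0) == []


class TestTandemTest:
    def test_planted_tandem_detected(self, im):
        rng = np.random.default_rng(11)
        elem = dna.random_dna(rng, 1300)
        genome = (dna.random_dna(rng, 8000) + elem + elem
                  + dna.random_dna(rng, 8000))
        pairs = simulate_pairs(genome, im, 40, 76, seed=12, circular=False)
        out = tandem_test(elem, pairs, im)
        assert out["call"] == "tandem" and out["spanning_pairs"] >= 3

    def test_single_copy_element_is_single(self, im):
        rng = np.random.default_rng(13)
        elem = dna.random_dna(rng, 1300)
        genome = dna.random_dna(rng, 8000) + elem + dna.random_dna(rng, 8000)
        pairs = simulate_pairs(genome, im, 40, 76, seed=14, circular=False)
        out = tandem_test(elem, pairs, im)
        assert out["call"] == "single" and out["spanning_pairs"] == 0

    def test_dispersed_copies_are_single(self, im):
        rng = np.random.default_rng(15)
        elem = dna.random_dna(rng, 1300)
        genome = (dna.random_dna(rng, 6000) + elem + dna.random_dna(rng, 6000)
                  + elem + dna.random_dna(rng, 6000))
        pairs = simulate_pairs(genome, im, 40, 76, seed=16, circular=False)
        out = tandem_test(elem, pairs, im)
        assert out["call"] == "single"

    def test_unspannable_spacer_is_inconclusive(self):
        im = InsertModel(60, 5)  # gate cannot cover spacer + anchors
        out = tandem_test("ACGT" * 100, [], im, spacer_len=50)
        assert out["call"] == "inconclusive"
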