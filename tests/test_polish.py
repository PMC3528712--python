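import edlib
import numpy as np
import pytest

from gapbridge import dna
from gapbridge.mapping import InsertModel
from gapbridge.polish import (decide_snp_column, polish_homopolymers,
                              resolve_snps)
from gapbridge.simulate import simulate_pairs


@pytest.fixture(scope="module")
def im():
    return InsertModel(647, 60)


@pytest.fixture(scope="module")
def hp_case(homopolymer_case):
    """Repeat-free genome with 30 planted homopolymer-length errors."""
    return homopolymer_case


class TestHomopolymerPolish:
    def test_planted_errors_corrected(self, hp_case, im):
        g, draft, pairs, n = hp_case
        polished, edits = polish_homopolymers(draft, pairs, im)
        residual = edlib.align(polished, g, mode="NW")["editDistance"]
        assert residual <= 0.01 * n       # >= 99% corrected
        assert len(edits) <= n            # and nothing beyond the planted set

    def test_no_spurious_edits_on_clean_genome(self, hp_case, im):
        g, _draft, pairs, _n = hp_case
        _polished, edits = polish_homopolymers(g, pairs, im)
        assert edits == []

    def test_runs_without_spanning_reads_untouched(self, im):
        rng = np.random.default_rng(1)
        g = dna.random_dna(rng, 5000)
        polished, edits = polish_homopolymers(g, [], im)
        assert polished == g and edits == []

    def test_split_support_below_fraction_untouched(self, im):
        rng = np.random.default_rng(2)
        g = dna.random_dna(rng, 20000)
        draft = g
        # half the reads from each of two run-length variants
        runs = list(dna.homopolymer_runs(g, min_len=5))
        s, e, base = runs[0]
        alt = g[:s] + base * (e - s + 1) + g[e:]
        pairs = (simulate_pairs(g, im, 20, 76, seed=3, circular=False)
                 + simulate_pairs(alt, im, 20, 76, seed=4, circular=False))
        _polished, edits = polish_homopolymers(draft, pairs, im)
        assert all(ed.position != s for ed in edits)


class TestSnpRules:
    # hand-computed outcomes for a pileup of columns: (counts, draft base,
    # partner base) -> (new draft base, new partner base, kind)
    CASES = [
        ({"A": 95, "T": 5}, "T", "T", ("A", "A", "majority")),
        ({"A": 40, "T": 60}, "T", "T", ("A", "T", "polymorphic")),
        ({"C": 92, "A": 4, "G": 4}, "C", "C", ("C", "C", "not_snp")),
        ({"A": 50, "T": 50}, "A", "T", ("A", "T", "not_snp")),
        ({"A": 50, "T": 50}, "T", "A", ("T", "A", "not_snp")),
        ({"G": 91, "T": 9}, "T", "T", ("G", "G", "majority")),
        # drafts already carry complementary observed alleles: leave alone
        ({"G": 89, "T": 11}, "T", "G", ("T", "G", "not_snp")),
        # the partner (polished) genome keeps its allele; the draft flips
        ({"A": 60, "T": 40}, "A", "A", ("T", "A", "polymorphic")),
        ({"A": 34, "T": 33, "C": 33}, "A", "A", ("A", "A", "ambiguous")),
        ({"A": 100}, "A", "A", ("A", "A", "not_snp")),
        ({"T": 100}, "A", "A", ("T", "T", "majority")),
        ({"A": 45, "C": 55}, "G", "G", ("C", "A", "polymorphic")),
        ({"A": 88, "T": 12}, "A", "A", ("T", "A", "polymorphic")),
        ({"C": 40, "G": 60}, "C", "C", ("G", "C", "polymorphic")),
        ({"C": 40, "G": 60}, "G", "G", ("C", "G", "polymorphic")),
        ({"A": 95, "T": 5}, "A", "A", ("A", "A", "not_snp")),
        ({"T": 60, "A": 40}, "T", "T", ("A", "T", "polymorphic")),
        ({"G": 9, "C": 91}, "C", "C", ("C", "C", "not_snp")),
        ({"G": 11, "C": 89}, "C", "C", ("G", "C", "polymorphic")),
        ({}, "A", "A", ("A", "A", "not_snp")),
    ]

    @pytest.mark.parametrize("counts,b1,b2,expect", CASES)
    def test_twenty_column_fixture(self, counts, b1, b2, expect):
        assert decide_snp_column(counts, b1, b2) == expect

    def test_ten_percent_boundary_not_a_snp(self):
        # variant frequency exactly 10% is not above the threshold
        out = decide_snp_column({"C": 90, "A": 10}, "C", "C")
        assert out == ("C", "C", "not_snp")


class TestResolveSnps:
    def test_wrong_draft_alleles_repaired(self, im):
        rng = np.random.default_rng(5)
        base = dna.random_dna(rng, 12000)
        g1, g2 = list(base), list(base)
        sites = sorted(rng.choice(np.arange(500, 11400, 120), size=10,
                                  replace=False))
        truth = {}
        for p in sites:
            for q in (p, p + 18):
                a = base[q]
                b = "ACGT"[("ACGT".index(a) + 1) % 4]
                g1[q], g2[q] = a, b
                truth[q] = (a, b)
        g1, g2 = "".join(g1), "".join(g2)
        d1 = list(g1)
        for p in sites[::2]:
            d1[p] = truth[p][1]  # draft wrongly carries the other strain's allele
        d1 = "".join(d1)
        pairs = (simulate_pairs(g1, im, 30, 76, seed=1, error_rate=0.001,
                                circular=False)
                 + simulate_pairs(g2, im, 30, 76, seed=2, error_rate=0.001,
                                  circular=False))
        n1, n2, decisions = resolve_snps(d1, g2, pairs, im, spacer=20000)
        before = edlib.align(d1, g1, mode="NW")["editDistance"]
        after = edlib.align(n1, g1, mode="NW")["editDistance"]
        assert after < before          # most wrong alleles repaired
        assert n2 == g2                # the polished genome is never corrupted
        kinds = {d.kind for d in decisions}
        assert kinds <= {"majority", "polymorphic", "not_snp", "ambiguous"}
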