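import time

import numpy as np
import pytest

from gapbridge import dna
from gapbridge.mapping import InsertModel
from gapbridge.simulate import make_fixture, simulate_pairs
from gapbridge.solver import solve_gaps


@pytest.fixture(scope="session")
def fixture42():
    """The default synthetic two-strain fixture."""
    return make_fixture(42)


@pytest.fixture(scope="session")
def truth42(fixture42):
    return {g.name: g for g in fixture42.truth.gaps}


@pytest.fixture(scope="session")
def solved42(fixture42):
    """Gap resolution over the default fixture (shared across tests)."""
    t0 = time.time()
    result = solve_gaps(fixture42.contig_set, fixture42.scaffolds)
    result.elapsed = time.time() - t0
    return result


@pytest.fixture(scope="session")
def short_model():
    return InsertModel(647, 60)


@pytest.fixture(scope="session")
def strain1_pairs(fixture42, short_model):
    """Short-insert pairs from strain 1 only (the single-strain community)."""
    return simulate_pairs(fixture42.truth.strain1_genome, short_model, 40, 76,
                          seed=11, error_rate=0.002)


@pytest.fixture(scope="session")
def community_pairs42(fixture42, short_model):
    """Pairs from both strains at equal abundance."""
    t = fixture42.truth
    return (simulate_pairs(t.strain1_genome, short_model, 25, 76, seed=6)
            + simulate_pairs(t.strain2_genome, short_model, 25, 76, seed=7))


@pytest.fixture(scope="session")
def separated42(fixture42, solved42, strain1_pairs, short_model):
    """Tandem confirmation + chimeric reference + progressive separation."""
    from gapbridge.phasing import build_chimeric_reference, progressive_separation
    from gapbridge.solver import resolve_tandem_candidates

    resolve_tandem_candidates(solved42.solutions, fixture42.contig_set,
                              strain1_pairs, short_model)
    skip = [p.alt_scaffold_id for p in solved42.proposals]
    phased = build_chimeric_reference(solved42.solutions, fixture42.scaffolds,
                                      fixture42.contig_set, skip_scaffolds=skip)
    t0 = time.time()
    sep = progressive_separation(phased, strain1_pairs, short_model)
    sep.elapsed = time.time() - t0
    return phased, sep


@pytest.fixture(scope="session")
def homopolymer_case(short_model):
    """A repeat-free genome with 30 planted run-length errors plus accurate
    short-read pairs simulated from the true sequence."""
    rng = np.random.default_rng(42)
    g = dna.random_dna(rng, 50000)
    runs = [r for r in dna.homopolymer_runs(g, min_len=4)]
    rng.shuffle(runs)
    draft = g
    for s, e, base in sorted(runs[:30], key=lambda r: -r[0]):
        delta = 1 if rng.random() < 0.5 else -1
        draft = draft[:s] + base * (e - s + delta) + draft[e:]
    pairs = simulate_pairs(g, short_model, 40, 76, seed=9, error_rate=0.002,
                           circular=False)
    return g, draft, pairs, 30


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
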