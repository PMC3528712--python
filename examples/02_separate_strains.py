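"""Separate the two strain genomes by progressive read mapping.

The gap solutions define a chimeric reference with alternative sites at
every polymorphic gap.  Read pairs from a community containing only strain 1
are mapped pairs-only; low-coverage regions mark wrongly chosen
alternatives, which are switched until the mapping is clean.  Strain 2 then
takes the complementary option at every two-option site.
"""

import edlib

from gapbridge import (InsertModel, assign_second_strain,
                       build_chimeric_reference, make_fixture,
                       progressive_separation, resolve_tandem_candidates,
                       simulate_pairs, solve_gaps)

fx = make_fixture(seed=42)
result = solve_gaps(fx.contig_set, fx.scaffolds)

im = InsertModel(647, 60)   # short-insert Illumina-style library
pairs = simulate_pairs(fx.truth.strain1_genome, im, depth=40, read_len=76,
                       seed=11, error_rate=0.002)
# confirm tandem candidates first so the backbone carries both copies
resolve_tandem_candidates(result.solutions, fx.contig_set, pairs, im)

skip = [p.alt_scaffold_id for p in result.proposals]  # alternative scaffolds
phased = build_chimeric_reference(result.solutions, fx.scaffolds,
                                  fx.contig_set, skip_scaffolds=skip)
print(f"chimeric reference: {len(phased.sites)} alternative sites")

sep = progressive_separation(phased, pairs, im)
print(f"separation: {sep.rounds} rounds, {sep.switches} switches, "
      f"converged={sep.converged}")

genome2, choices2, flagged = assign_second_strain(phased, sep.choices)


def identity(a, b):
    d = edlib.align(a, b, mode="NW")["editDistance"]
    return 1 - d / max(len(a), len(b))


print(f"strain 1 vs truth: {identity(sep.genome, fx.truth.strain1_genome):.6f}")
print(f"strain 2 vs truth: {identity(genome2, fx.truth.strain2_genome):.6f}")
# Identities near 1.0 mean both genomes were recovered exactly up to a
# handful of bases; every two-option site received complementary choices.
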