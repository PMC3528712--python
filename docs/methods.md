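# Methods

This note documents the models, algorithms, parameter choices and
limitations of `gapbridge`. It states no empirical result that the test
suite and `scripts/acceptance.py` do not themselves compute.

## Overlap search

Gap flanks are represented by their terminal **edge sequences** (default
1000 bp; tag `W` for the last kilobase of a contig's 3′ end, `E` for the
first kilobase of the 5′ end). An edge is searched against both strands of
every other contig by exact k-mer seeding (k = 11), diagonal clustering,
and banded affine-gap Smith–Waterman extension (band 16 around the seeded
diagonals). Scoring is the conventional nucleotide scheme for ~95%-identity
targets: match +1, mismatch −2, gap open −2, gap extend −1 (gap of length
*g* costs 2 + *g*). E-values use ungapped Karlin–Altschul parameters applied
to the gapped score: λ solves Σ pᵢpⱼ·exp(λ·sᵢⱼ) = 1 under uniform base
composition (bisection to 1e−12; for +1/−2, λ ≈ 1.3327), and K uses the
coarse approximation K ≈ (1 − e^(−λ))² / H with H the relative entropy of
the aligned-pair distribution. This K is accurate only to within a small
factor, which is sufficient because e ≤ 1e−10 acts as a gate, not an
estimate. The full-matrix Smith–Waterman (same kernel, all diagonals) is
kept as the exhaustive route and compared against seed-and-extend in the
test suite.

A hit qualifies as a **dovetail** only if the alignment (a) reaches within
`slack` = 10 bp of the gap-facing end of the query edge, (b) starts within
`max_trim` = 150 bp of the leading terminus of the oriented subject, and
(c) leaves the subject extending beyond the overlap. The asymmetry is
deliberate: multi-copy contigs are consensus sequences over several loci
and frequently carry a short foreign terminal segment from one locus; that
segment must be trimmable on the *bridge* side (hence the generous
`max_trim`), while the flank's own gap-facing end is trusted (hence the
tight `slack`). Several seed clusters are always evaluated per subject,
because an internal repeat match can outscore the true junction without
being a dovetail.

**Gap walk.** From the left flank, each newly reached contig's far edge is
re-extracted and re-searched (frontier search, default 6 iterations, at
most 2 copies of a contig per path, frontier capped at 64 chains with
lexicographic pruning); a mirrored walk runs from the right flank in
reverse-complement space. Paths are emitted where the two reachable sets
meet, including the degenerate direct flank–flank overlap, and every path
is re-validated junction by junction while its consensus is merged. Two
pruning rules keep the walk honest: a contig *placed in the same scaffold
as the gap* is never used as a bridge (it already has a location), and a
path's implied span may not exceed 2 × estimate + 4 kb (8 kb when the gap
has no estimate) — the mate-pair constraint that scaffolded the gap in the
first place. Paths are ordered by (number of contigs, −score, ids):
parsimony first, because longer chains accumulate junction score without
being more plausible. All tie-breaks are deterministic.

**Consensus.** Junction merging keeps the left partner's bases across the
overlap unless the left partner is multi-copy and the right is not, in
which case the junction splices to the subject's bases (multi-copy
consensus edges are the chimera-prone ones). The conservation identity
len(consensus) = Σ contig lengths − Σ (overlap + trims) holds exactly and
is asserted in tests. The signed gap distance is
len(consensus) − len(left flank) − len(right flank); a pure flank overlap
therefore gives the negative of the overlap length.

## Gap classification

Read-depth regions are ratios of the modal depth *D* of two-strain shared
contigs (estimated as the length-weighted KDE mode, bandwidth 10% of the
current mode, iterated above the background cutoff): multi-copy > 1.3 *D*,
shared [0.75, 1.3] *D*, strain-specific [0.35, 0.75) *D*, background
≤ 0.29 *D*; the residual band is assigned to background with an
"ambiguous" note. Ratios rather than absolute depths make the bands
portable across coverage levels; at *D* ≈ 70× they reproduce absolute
cutoffs of >91×, ~70×, ~35×, <20×.

Decision rules, in order of evidence specificity:

1. **Insertion/deletion (D)** — exactly two paths, one equal to the other
   with one contiguous block of strain-specific or multi-copy contigs
   removed, flanks both shared. Checked *before* the direct-overlap rule
   because the deletion path of a D gap is itself a direct overlap; the
   two-path structure is the stronger evidence. The insertion path is
   ordered first (insertion-first rule: a real insertion flanked by
   duplicated target sites produces a deletion consensus that read mapping
   cannot refute, so the insertion must be tested first).
2. **Direct overlap (A)** — the best path has no intermediates.
3. **Alternative contigs (C)** — ≥ 2 paths whose intermediates pair up as
   homologs: identity ≥ 95% over ≥ 80% of the shorter, lengths within
   ±20%, both strain-depth. The thresholds quantify "similar length and
   similar read depth" and are exposed as parameters.
4. **Multi-copy bridge (B)** — the best path crosses a multi-copy contig.
5. Otherwise a unique non-overlapping bridge is recorded as A with a note,
   and no path at all as UNRESOLVED.

**Distance comparison.** A path is flagged `distance_discrepant` when
|computed − estimated| > max(500 bp, 3 × insert SD if supplied); 500 bp
reflects the few-hundred-bp scatter of scaffolder estimates. Two expected
biases are never flagged: a negative computed distance when the estimate
sits at the scaffolder floor of 20 bp (scaffolders do not emit negative
estimates), and a Group D insertion distance above the estimate (the
scaffolder averages the two strains). A discrepant multi-copy gap whose
estimate exceeds the computed distance by ≈ 1 copy length (within the same
tolerance) is additionally marked `tandem_candidate`.

**Alternative scaffolds and ordering.** A scaffold is proposed as a strain
alternative when all its contigs are strain-depth and each is one member
of an alternative pair whose partner bridges adjacent gaps of a single
host scaffold. Scaffold order is determined by resolving trial gaps
between every pair of scaffold termini (same thresholds as intra-scaffold
gaps — no looser), building a terminus graph weighted by best-path score,
taking a maximum-weight matching (networkx), and reporting a closed circle
when the matching plus the scaffolds form one cycle covering everything;
equal-weight conflicting edges are reported as ambiguous.

## Pair-constrained read mapping

The mapper is deliberately minimal and bespoke: the contract — *pairs
only, innie orientation, unique best locus, insert within mean ± 4 SD* —
is what gives verification its power, and a small deterministic
implementation satisfies it exactly. Mates are seeded with exact 17-mers
(three offsets per read), candidate loci verified by edit distance (edlib)
with at most 4% edits, and all concordant mate combinations enumerated;
the best combination is kept only when it is strictly unique (ties are
either rejected or, for deliberately duplicated artificial references,
resolved leftmost). N in the reference never matches and seeds containing
N are skipped, which makes the poly-N constructions literal. Coverage is
tracked per strand, from validated pairs only; the depth-conservation
identity Σ depth = 2 × pairs × read length holds exactly for uniform
reads. Concordant-but-multi-mapped pairs are counted in a separate
`depth_ambiguous` track: a repeat interior that unique mapping cannot
cover is distinguishable from a sequence no read supports at all. SAM and
BED exports are provided for inspection.

**Verification.** Each path's consensus (which embeds the full flank
contigs as context) is mapped against; a low-coverage interval
(depth < 5, intervals < 50 bp apart merged) intersecting the gap span
fails the path, low-covered flanks make it inconclusive, and intervals
within one insert-gate width of the reference ends are ignored (coverage
necessarily ramps there).

**Tandem test.** Two copies of an element joined by 50 bp of poly-N are
mapped against; ≥ 3 pairs with mates on opposite sides of the spacer at a
gated insert prove tandem copies, zero spanning pairs with the element
itself covered ≥ 5× support a single/dispersed arrangement. The
spanning-pair insert counts the spacer literally, so the +50 bp bias sits
well inside the ±4 SD gate. The stated precondition is the physically
meaningful one — the insert gate must span the spacer plus two mate
anchors — rather than a bound on element length: field-typical elements
(≈ 2.3 kb transposases) are longer than a short-insert pair span yet
perfectly testable, since spanning pairs only need to straddle the
junction. False positives from dispersed copies are structurally excluded:
a pair wholly inside one copy, cross-assigned to both copies, implies an
insert inflated by element + spacer, far outside the gate for any element
longer than the gate width. Confirmed candidates have their consensus
rewritten with the second copy (`resolve_tandem_candidates`), which also
restores the distance agreement.

## Strain separation

`build_chimeric_reference` splices unique solutions directly into the
scaffold backbone and turns each C/D gap into an `AlternativeSite` whose
options are the per-path consensus middles plus a 160 bp shared anchor on
each side (the anchor exceeds the largest junction overlap, so the
deletion option of an indel site is never empty). Initial choices follow
the solver's path order; for insertion/deletion sites that is the longest
option (insertion first). Unresolved gaps remain as N-runs of the
estimated length.

`progressive_separation` then loops: realize the current choices, map the
single-strain pairs, find low-coverage intervals (counting ambiguous
coverage, so repeat shadows do not trigger switches; excluding one
insert-gate width at the reference ends), and switch **all** sites whose
span intersects a low interval to their next untried option in the same
round. The paper-style manual process is serialized; batch switching
converges in 2–3 rounds and is made safe by a visited-configuration memo —
on revisiting a configuration the one with the smallest low-coverage
footprint wins and remaining intersecting sites are reported unresolved.
Convergence means no low interval touches any site; a converged state is a
fixed point (re-running switches nothing). The second strain takes the
complementary option at every two-option site; sites with more than two
options are flagged for user input, never guessed.

Why switching works on the fixture's data: polymorphic blocks carry one
dense hypervariable patch (~16 differences in 40 bp), so reads from the
wrong strain fail the 4% edit gate across the patch and coverage collapses
there; wrong insertions are uncovered wholesale; wrong deletions leave an
uncoverable junction. A block whose differences were all isolated SNPs
below the per-read gate would map cleanly in either version — such sites
cannot be separated by coverage and are the province of SNP polishing.

## Polishing

**Homopolymers.** For every run ≥ 3 bp, reads spanning the run plus 12 bp
flanks are collected; a read's run length is measured between exact flank
anchors (no alignment heuristics — accurate short reads either contain
both anchors verbatim or are not counted). With ≥ 5 supporting reads and
≥ 90% agreement on a different length, the run is rewritten; edits are
applied right-to-left and logged with position, old/new length and
support. Runs without spanning unique coverage (e.g. inside identical
repeat copies) are left untouched — correcting those requires long-insert
anchoring.

**SNPs.** The two genomes are concatenated with a 20 kb poly-N bridge —
longer than any pair span, so no pair bridges the copies and reads settle
on the copy whose local alleles they carry. For each column with variant
frequency > 10%: if one base exceeds 90% it is fixed **in the draft
genome only** (the partner is already polished and is never rewritten by
the majority rule); otherwise a biallelic column is subspecies
polymorphism — the strain already carrying one observed allele keeps it
and the other strain receives the other allele; tri-allelic columns are
flagged and left unchanged. Corresponding columns of the two copies are
paired by exact 30 bp flank context and their counts merged. The decision
logic is a pure function (`decide_snp_column`) validated against a
20-column hand-computed fixture. Ties at 50/50 in the chimeric consensus
are resolved by keeping the first option and letting separation correct it.

## The synthetic fixture

The generator emulates the output of a pyrosequencing-era overlap
assembler run on a two-strain community at equal abundance — per-strain
depth 35× so shared contigs sit near 70× — over a ~200 kb ancestor.
Defaults: 4 transposon families (600–2500 bp, target-site duplications of
4–12 bp; the tandem family 1100–1600 bp so whole short-insert pairs fit
inside a copy), 3 copies of a 5 kb rRNA-operon-like unit, 4 paralog pairs
(500–700 bp at 90–98% identity, each causing a pair of Group A gaps),
3 plain direct overlaps, 4 polymorphic blocks (1.2–1.8 kb, ~2.2% internal
divergence concentrated into one dense patch plus dispersed SNPs — the cap
keeps alternative contigs above the 95% homology threshold), one 5 kb and
two ~1 kb strain-specific insertions plus two strain-specific transposon
insertions (Group D), a two-contig strain-specific mini-scaffold
(alternative-scaffold case), five ~14× background contigs, and 20 single-
copy 1.4 kb control elements for the tandem test. Read libraries mirror a
short-insert library (647 ± 60 bp, 76 bp reads) and a long-insert model
(8.6 kb ± 0.9 kb, 198 bp reads, with a homopolymer error channel).

Fragmentation is rule-based rather than a re-run of a real assembler:
contigs are cut at every repeat-copy boundary and inter-strain difference,
shared fragments are collapsed (depth 2 × 35), repeat families collapse to
one consensus contig per family (depth = total copies × 35) carrying a
40–120 bp foreign edge from one randomly chosen locus, flanking contigs
retain 110–150 bp overhangs into the interleaving feature (as boundary-
crossing reads would provide), depths are jittered ±10%, and scaffold gap
estimates are the true distances plus N(0, 100 bp) noise floored at the
scaffolder minimum of 20. This guarantees an exact, labelled ground truth
for every emitted gap — the point of the fixture is to test gap
resolution, not assembly.

What the fixture does **not** model, and what passing therefore does not
show: sequencing error in contig consensus sequences, intra-family repeat
divergence (family copies are identical by default; real multi-copy
contigs carry internal polymorphism that only long-insert mapping
resolves), isolated inter-strain SNPs inside shared contigs (real
assemblers collapse them into the consensus; they surface later as SNP
columns, which the polishing rules handle, not separation), more than two
strains, uneven strain abundance, and chimeric reads. Default sizes keep
the full pipeline to a few minutes on one CPU; the acceptance script
states the problem sizes used alongside every quantity.

## Numerical and degenerate-input choices

Sequences are uppercased on load and restricted to A/C/G/T/N; N never
matches anything, including N. Internal coordinates are 0-based half-open
on the forward strand; AGP I/O converts at the boundary. Gap estimates
below 20 are clamped to 20 with a warning. Depth is carried as input
metadata, never recomputed by the solver (the mapper can recompute it).
The shared-depth estimator requires ≥ 10 depths and returns the common
value directly when depths are constant; with fewer it instructs the user
to pass an explicit shared depth. All randomness flows from a single seed
per entry point; identical inputs and parameters produce byte-identical
reports and FASTA output.

## Known limitations

* Gaps inside long multi-copy regions (nested rRNA-operon ambiguities)
  are resolved only to their overall layout; copy-internal choices beyond
  the reach of short-insert anchoring stay ambiguous, as do homopolymer
  errors inside identical repeat copies.
* Separation assumes exactly two strains and a read set containing exactly
  one of them; >2-option sites are flagged, not resolved.
* The e-value is a gate computed from ungapped statistics applied to
  gapped scores; it is not a calibrated significance estimate.
* Self-repetitive gap content (continuous oligonucleotide repetition
  longer than a read) is detected as discrepant but cannot be sized
  without longer reads.
* The scaffold-order matching reports ambiguity but does not enumerate
  alternative orders.
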