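"""Genome polishing with pair-validated read mapping.

Two corrections, matching the error profile of pyrosequencing-derived
consensus sequences:

* homopolymer run lengths are re-estimated from accurate short reads: a run
  is rewritten when at least ``min_fraction`` of the spanning reads support
  a different length;
* residual SNP columns (variant frequency above 10%) are resolved against a
  concatenation of the two strain genomes joined by a poly-N bridge longer
  than any pair span: columns dominated (>90%) by one base are fixed to it,
  and remaining biallelic columns are treated as subspecies polymorphism —
  the strain already carrying one allele keeps it and the other strain
  receives the other allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from . import dna
from .mapping import InsertModel, MapParams, ReferenceIndex, map_pairs

log = logging.getLogger("gapbridge")


@dataclass
class PileupColumn:
    """Base counts of pair-validated reads at one reference position."""

    position: int
    counts: dict = field(default_factory=dict)   # base -> count
    total: int = 0


@dataclass
class HomopolymerEdit:
    position: int
    base: str
    old_len: int
    new_len: int
    support: int
    depth: int


def _read_run_length(read: str, left_anchor: str, right_anchor: str,
                     base: str) -> int | None:
    """The length of the homopolymer of ``base`` between two exact anchor
    strings in a read, or None when the anchors are absent or the bases
    between them are not pure ``base``."""
    i = read.find(left_anchor)
    if i < 0:
        return None
    j = read.find(right_anchor, i + len(left_anchor))
    if j < 0:
        return None
    middle = read[i + len(left_anchor):j]
    if middle.strip(base):
        return None
    return len(middle)


def polish_homopolymers(genome: str, pairs, insert_model: InsertModel,
                        map_params: MapParams = None, min_fraction: float = 0.9,
                        min_depth: int = 5, min_run: int = 3,
                        flank: int = 12) -> tuple[str, list[HomopolymerEdit]]:
    """Correct homopolymer run lengths from spanning pair-validated reads."""
    import bisect

    map_params = map_params or MapParams()
    res = map_pairs(pairs, genome, insert_model, map_params)
    mate_reads = sorted(
        ((mp.start, mp.end, mp.seq)
         for pl in res.placements for mp in (pl.mate1, pl.mate2)),
        key=lambda t: t[0])
    starts = [m[0] for m in mate_reads]
    max_mate = max((e - s for s, e, _q in mate_reads), default=0) + 10

    edits = []
    for run_s, run_e, base in dna.homopolymer_runs(genome, min_len=min_run):
        lo = run_s - flank
        hi = run_e + flank
        if lo < 0 or hi > len(genome):
            continue
        left_anchor = genome[lo:run_s]
        right_anchor = genome[run_e:hi]
        i = bisect.bisect_right(starts, lo)
        j = bisect.bisect_left(starts, lo - max_mate)
        support: dict[int, int] = {}
        depth = 0
        for s, e, seq in mate_reads[j:i]:
            if s <= lo and e >= hi:
                run_len = _read_run_length(seq, left_anchor, right_anchor, base)
                if run_len is None:
                    continue
                depth += 1
                support[run_len] = support.get(run_len, 0) + 1
        if depth < min_depth:
            continue
        best_len = max(support, key=lambda k: (support[k], k))
        if best_len != (run_e - run_s) and support[best_len] >= min_fraction * depth:
            edits.append(HomopolymerEdit(run_s, base, run_e - run_s, best_len,
                                         support[best_len], depth))
    # apply edits right to left so positions stay valid
    g = genome
    for ed in sorted(edits, key=lambda e: -e.position):
        g = g[:ed.position] + ed.base * ed.new_len + g[ed.position + ed.old_len:]
    return g, edits


# ---------------------------------------------------------------------------
# SNP resolution between two strain genomes
# ---------------------------------------------------------------------------

@dataclass
class SnpDecision:
    position1: int | None
    position2: int | None
    kind: str           # "majority" | "polymorphic" | "ambiguous" | "not_snp"
    new_base1: str | None
    new_base2: str | None
    counts: dict


def decide_snp_column(counts: dict, base1: str, base2: str,
                      snp_freq: float = 0.10, majority: float = 0.90):
    """The per-column decision rules.

    ``counts`` are pair-validated base counts at a locus; ``base1``/``base2``
    are the bases the two draft genomes currently carry there.  Returns
    (new_base1, new_base2, kind).
    """
    total = sum(counts.values())
    if total == 0:
        return base1, base2, "not_snp"
    freqs = {b: c / total for b, c in counts.items()}
    top = max(sorted(freqs), key=lambda b: freqs[b])
    variant_freq = 1.0 - max(freqs.get(base1, 0.0), freqs.get(base2, 0.0))
    if variant_freq <= snp_freq and freqs.get(top, 0) and top in (base1, base2):
        return base1, base2, "not_snp"
    if freqs[top] > majority:
        kind = "not_snp" if (top == base1 and top == base2) else "majority"
        return top, top, kind
    alleles = sorted(b for b, f in freqs.items() if f > snp_freq)
    if len(alleles) == 2:
        a, b = alleles
        if base1 in alleles and base2 in alleles and base1 != base2:
            return base1, base2, "not_snp"
        if base2 in alleles:
            return (a if base2 == b else b), base2, "polymorphic"
        if base1 in alleles:
            return base1, (a if base1 == b else b), "polymorphic"
        # neither draft carries an observed allele: assign by frequency
        hi = max(alleles, key=lambda x: (freqs[x], x))
        lo = a if hi == b else b
        return hi, lo, "polymorphic"
    return base1, base2, "ambiguous"


def resolve_snps(genome1: str, genome2: str, pairs, insert_model: InsertModel,
                 map_params: MapParams = None, spacer: int = 20000,
                 snp_freq: float = 0.10, majority: float = 0.90,
                 min_depth: int = 5, context: int = 30):
    """Resolve residual SNP columns on a poly-N concatenation of the two
    genomes.

    The spacer is longer than any read-pair span, so no pair bridges the two
    genome copies; reads settle on the copy whose local alleles they carry.
    Columns in the first genome's copy are paired with the corresponding
    position of the second genome (located by exact context match) and the
    decision rules applied to both strains at once.
    """
    map_params = map_params or MapParams()
    ref = genome1 + "N" * spacer + genome2
    res = map_pairs(pairs, ref, insert_model, map_params)
    counts = _pileup_counts(ref, res)
    off2 = len(genome1) + spacer
    g1 = list(genome1)
    g2 = list(genome2)
    decisions = []
    for pos in sorted(counts):
        if pos >= len(genome1):
            continue  # genome-2 columns are handled via their genome-1 twin
        col = counts[pos]
        total = sum(col.values())
        if total < min_depth:
            continue
        b1 = genome1[pos]
        top = max(sorted(col), key=lambda b: col[b])
        if col.get(b1, 0) / total >= 1.0 - snp_freq and top == b1:
            continue
        # find the corresponding genome-2 position by context
        ctx = genome1[pos - context:pos + context + 1]
        p2 = _twin_position(genome2, ctx, context)
        b2 = genome2[p2] if p2 is not None else b1
        # merge counts from the twin column when known
        if p2 is not None:
            twin = counts.get(off2 + p2, {})
            col = {b: col.get(b, 0) + twin.get(b, 0)
                   for b in set(col) | set(twin)}
        n1, n2, kind = decide_snp_column(col, b1, b2, snp_freq, majority)
        if kind in ("majority", "polymorphic"):
            g1[pos] = n1
        # only the subspecies-polymorphism rule touches the polished genome
        if kind == "polymorphic" and p2 is not None:
            g2[p2] = n2
        decisions.append(SnpDecision(pos, p2, kind, n1, n2, col))
    return "".join(g1), "".join(g2), decisions


def _twin_position(genome2: str, ctx: str, context: int) -> int | None:
    if len(ctx) != 2 * context + 1:
        return None
    # allow the focal base to differ: anchor on the flanks
    left, right = ctx[:context], ctx[context + 1:]
    i = genome2.find(left)
    while i >= 0:
        pos = i + context
        if genome2[pos + 1:pos + 1 + context] == right:
            return pos
        i = genome2.find(left, i + 1)
    return None


def _pileup_counts(ref: str, mapping_result) -> dict[int, dict[str, int]]:
    """Match-column base counts from the mapped pairs."""
    counts: dict[int, dict[str, int]] = {}
    for pl in mapping_result.placements:
        for mp in (pl.mate1, pl.mate2):
            seq = mp.seq
            window = ref[mp.start:mp.end]
            res = edlib.align(seq, window, mode="NW", task="path")
            ri = mp.start
            qi = 0
            num = ""
            for ch in res["cigar"]:
                if ch.isdigit():
                    num += ch
                    continue
                n = int(num)
                num = ""
                if ch in ("=", "X", "M"):
                    for _ in range(n):
                        d = counts.setdefault(ri, {})
                        b = seq[qi]
                        d[b] = d.get(b, 0) + 1
                        ri += 1
                        qi += 1
                elif ch == "I":
                    qi += n
                elif ch == "D":
                    ri += n
    return counts
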