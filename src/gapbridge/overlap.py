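"""Bidirectional overlap search: find contigs that dovetail onto a gap flank
and chain them until a common bridging contig joins both sides.

The search works in "walk space": sequences are oriented so that the walk
always proceeds left-to-right across the gap.  An acceptable overlap is a
dovetail — the alignment must reach (within ``slack``) the gap-facing end of
the query edge and come within ``max_trim`` of the leading terminus of the
subject, because multi-copy contigs frequently carry a short foreign terminal
segment from one of their source loci that has to be trimmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import dna
from .align import ScoreScheme, banded_align, _seed_diagonals
from .model import FORWARD, REVERSE, ContigSet, GapRecord


def _flip(orientation: str) -> str:
    return REVERSE if orientation == FORWARD else FORWARD


@dataclass
class SearchParams:
    """Tunables of the overlap search (defaults follow the pipeline's
    standard thresholds: identity > 95%, e-value < 1e-10)."""

    edge_len: int = 1000
    min_identity: float = 0.95
    max_evalue: float = 1e-10
    min_overlap: int = 30
    max_iterations: int = 6
    max_copies_per_path: int = 2
    slack: int = 10          # residual overhang allowed at the query's gap-facing end
    max_trim: int = 150      # foreign terminal segment allowed on the subject terminus
    band: int = 16
    seed_k: int = 11
    span_margin: int = 4000  # path span bound: 2 * gap estimate + span_margin
    default_max_span: int = 8000  # span bound when the gap has no estimate
    max_chains: int = 64     # frontier cap per side (deterministic pruning)


@dataclass
class EdgeSeq:
    """An edge sequence taken from one side of a contig.

    Tag "W" marks the last ``edge_len`` bp of the 3' end (the contig sits
    west of the gap), "E" the first ``edge_len`` bp of the 5' end.
    """

    contig_id: str
    side_tag: str
    seq: str
    edge_len: int = 1000


def extract_edge(contig, side: str, edge_len: int = 1000) -> EdgeSeq:
    """Edge sequence of a contig; ``side`` is "5p" or "3p" (forward strand)."""
    if side not in ("5p", "3p"):
        raise ValueError("side must be '5p' or '3p'")
    if side == "3p":
        return EdgeSeq(contig.id, "W", contig.seq[-edge_len:], edge_len)
    return EdgeSeq(contig.id, "E", contig.seq[:edge_len], edge_len)


@dataclass
class OverlapHit:
    """A dovetail alignment of an edge against an oriented subject contig.

    Intervals are 0-based half-open; the subject interval refers to the
    oriented subject sequence (walk space).
    """

    query: EdgeSeq
    subject_id: str
    subject_orientation: str
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    identity: float
    score: int
    evalue: float
    reaches_edge: bool
    subject_trim: int     # foreign head segment on the subject (<= max_trim)
    query_residual: int   # unaligned residue at the query's gap-facing end (<= slack)
    subject_length: int = 0


@dataclass
class Junction:
    """How two consecutive path members merge."""

    overlap: int      # aligned overlap consumed at the junction (bp)
    identity: float
    trim_left: int    # bases trimmed from the left partner's gap-facing end
    trim_right: int   # foreign bases trimmed from the right partner's head
    score: int = 0


@dataclass
class BridgePath:
    """An ordered oriented contig chain joining the two flanks of a gap."""

    contigs: list[tuple[str, str]]
    junctions: list[Junction]
    consensus: str
    score: int = 0

    @property
    def n_intermediates(self) -> int:
        return len(self.contigs) - 2

    @property
    def intermediate_ids(self) -> list[str]:
        return [cid for cid, _o in self.contigs[1:-1]]

    def key(self):
        return tuple(self.contigs)


def _best_dovetail(q_codes, s_codes, s_len, query_len, scheme, params,
                   min_identity, min_overlap):
    """Best-scoring alignment among seed clusters that satisfies the
    dovetail constraints (several clusters are tried because a repeat can
    produce a higher-scoring internal match that is not a dovetail)."""
    best = None
    for dmin, dmax in _seed_diagonals(q_codes, s_codes, params.seed_k):
        aln = banded_align(q_codes, s_codes, dmin, dmax, scheme, params.band)
        if aln.columns == 0:
            continue
        q_res = query_len - aln.q_end
        if (q_res > params.slack or aln.s_start > params.max_trim
                or aln.s_end - aln.s_start < min_overlap
                or aln.identity < min_identity
                or s_len - aln.s_end < 1):
            continue
        if best is None or aln.score > best.score:
            best = aln
    return best


def find_overlaps(edge: EdgeSeq, contig_db: ContigSet, scheme: ScoreScheme = None,
                  min_identity: float = 0.95, max_evalue: float = 1e-10,
                  min_overlap: int = 30, params: SearchParams = None,
                  exclude=()) -> list[OverlapHit]:
    """Dovetail hits of an edge against both strands of every other contig.

    A hit must reach the gap-facing (3') end of the edge within ``slack`` and
    the leading (5') terminus of the oriented subject within ``max_trim``, and
    the subject must extend beyond the overlap — i.e. the hit is consistent
    with walking rightward across the gap.  Sorted by descending score, then
    descending identity, then contig id.
    """
    params = params or SearchParams()
    scheme = scheme or ScoreScheme()
    exclude = set(exclude) | {edge.contig_id}
    q_fwd = dna.encode(edge.seq)
    q_rev = dna.encode(dna.revcomp(edge.seq))
    index = contig_db.kmer_index()
    db_len = contig_db.total_length

    from .model import _iter_kmers

    candidates: set[tuple[str, str]] = set()
    for codes, orient in ((q_fwd, FORWARD), (q_rev, REVERSE)):
        for key, _pos in _iter_kmers(codes, contig_db.k):
            for ci, _sp in index.get(key, ()):
                cid = contig_db.contig_id_at(ci)
                if cid not in exclude:
                    candidates.add((cid, orient))

    hits = []
    for cid, orient in sorted(candidates):
        contig = contig_db.lookup(cid)
        s_str = contig.oriented(orient)
        s_codes = dna.encode(s_str)
        best = _best_dovetail(q_fwd, s_codes, len(s_str), len(edge.seq),
                              scheme, params, min_identity, min_overlap)
        if best is None:
            continue
        ev = scheme.evalue(best.score, len(edge.seq), db_len)
        if ev > max_evalue:
            continue
        hits.append(OverlapHit(
            query=edge, subject_id=cid, subject_orientation=orient,
            query_interval=(best.q_start, best.q_end),
            subject_interval=(best.s_start, best.s_end),
            identity=best.identity, score=best.score, evalue=ev,
            reaches_edge=True, subject_trim=best.s_start,
            query_residual=len(edge.seq) - best.q_end,
            subject_length=len(s_str)))
    hits.sort(key=lambda h: (-h.score, -h.identity, h.subject_id, h.subject_orientation))
    return hits


def chain_consensus(chain, contig_db: ContigSet, scheme: ScoreScheme = None,
                    params: SearchParams = None, multi_copy_ids=frozenset()):
    """Validate an oriented contig chain junction-by-junction and merge it
    into a consensus sequence.

    Within each junction overlap, bases are taken from the non-multi-copy
    partner when exactly one partner is multi-copy (multi-copy contigs are
    prone to chimeric edges).  Returns a :class:`BridgePath` or None when a
    junction fails the dovetail or identity requirements.
    """
    params = params or SearchParams()
    scheme = scheme or ScoreScheme()
    first_id, first_or = chain[0]
    cons = contig_db.lookup(first_id).oriented(first_or)
    junctions = []
    total_score = 0
    for cid, orient in chain[1:]:
        query = cons[-params.edge_len:]
        s_str = contig_db.lookup(cid).oriented(orient)
        q_codes = dna.encode(query)
        s_codes = dna.encode(s_str)
        best = _best_dovetail(q_codes, s_codes, len(s_str), len(query),
                              scheme, params, params.min_identity,
                              params.min_overlap)
        if best is None:
            return None
        q_res = len(query) - best.q_end
        s_trim = best.s_start
        overlap_s = best.s_end - best.s_start
        left_id = chain[len(junctions)][0]
        left_multi = left_id in multi_copy_ids
        right_multi = cid in multi_copy_ids
        if left_multi and not right_multi:
            # prefer the subject's bases across the overlap
            q_span = best.q_end - best.q_start
            cons = cons[:len(cons) - q_res - q_span] + s_str[best.s_start:]
            overlap = q_span
        else:
            cons = cons[:len(cons) - q_res] + s_str[best.s_end:]
            overlap = overlap_s
        junctions.append(Junction(overlap=overlap, identity=best.identity,
                                  trim_left=q_res, trim_right=s_trim,
                                  score=best.score))
        total_score += best.score
    return BridgePath(contigs=list(chain), junctions=junctions,
                      consensus=cons, score=total_score)


class GapResolver:
    """Caches per-edge overlap hits and resolves gaps against one database."""

    def __init__(self, contig_db: ContigSet, scheme: ScoreScheme = None,
                 params: SearchParams = None, placed: dict[str, str] | None = None):
        self.db = contig_db
        self.scheme = scheme or ScoreScheme()
        self.params = params or SearchParams()
        #: contig id -> scaffold id, for contigs placed in scaffolds; a placed
        #: contig is never used as a bridge inside its own scaffold.
        self.placed = placed or {}
        self._hit_cache: dict[tuple[str, str], list[OverlapHit]] = {}

    def _edge_hits(self, cid: str, orient: str) -> list[OverlapHit]:
        key = (cid, orient)
        if key not in self._hit_cache:
            contig = self.db.lookup(cid)
            seq = contig.oriented(orient)
            edge = EdgeSeq(cid, "W", seq[-self.params.edge_len:], self.params.edge_len)
            self._hit_cache[key] = find_overlaps(
                edge, self.db, self.scheme, self.params.min_identity,
                self.params.max_evalue, self.params.min_overlap, self.params)
        return self._hit_cache[key]

    def resolve_gap(self, gap: GapRecord) -> list[BridgePath]:
        """All orientation-consistent bridge paths for a gap, best first.

        Paths are ordered by (number of contigs, -score, contig ids): the
        most parsimonious chain with the strongest junctions comes first.
        """
        p = self.params
        left = (gap.left_contig_id, gap.left_orientation)
        right = (gap.right_contig_id, gap.right_orientation)
        est = gap.estimated_length
        max_span = (2 * max(est, 0) + p.span_margin) if est is not None \
            else p.default_max_span
        scaffold = gap.scaffold_id

        def blocked(cid):
            # placed contigs of the same scaffold cannot be bridges
            return (scaffold is not None and self.placed.get(cid) == scaffold) \
                or cid in (left[0], right[0])

        left_routes = self._walk(left, right, blocked, max_span)
        right_rc = (right[0], _flip(right[1]))
        left_rc_target = (left[0], _flip(left[1]))
        right_routes = self._walk(right_rc, left_rc_target, blocked, max_span)

        # routes are chains in walk space; meet left chains with right chains
        chains: list[tuple] = []
        seen = set()

        def add_chain(chain):
            if chain[-1] != right or chain[0] != left:
                return
            counts = {}
            for cid, _o in chain:
                counts[cid] = counts.get(cid, 0) + 1
                if counts[cid] > p.max_copies_per_path:
                    return
            if chain not in seen:
                seen.add(chain)
                chains.append(chain)

        right_by_node: dict[tuple[str, str], list[tuple]] = {}
        for rchain in right_routes:
            for k in range(len(rchain)):
                node_fwd = (rchain[k][0], _flip(rchain[k][1]))
                right_by_node.setdefault(node_fwd, []).append(rchain[:k + 1])

        for lchain in left_routes:
            tip = lchain[-1]
            if tip == right:
                add_chain(lchain)
                continue
            for rpart in right_by_node.get(tip, ()):
                # rpart runs right-flank -> ... -> tip in RC space
                tail = [(cid, _flip(o)) for cid, o in reversed(rpart)]
                add_chain(lchain + tuple(tail[1:]))

        multi = getattr(self, "multi_copy_ids", frozenset())
        paths = []
        for chain in chains:
            path = chain_consensus(chain, self.db, self.scheme, p, multi)
            if path is None:
                continue
            flank_len = (self.db.lookup(left[0]).length
                         + self.db.lookup(right[0]).length)
            span = len(path.consensus) - flank_len
            if span > max_span:
                continue
            paths.append(path)
        paths.sort(key=lambda bp: (len(bp.contigs), -bp.score,
                                   tuple(c for c, _o in bp.contigs)))
        # drop duplicate contig chains (can arise from distinct meets)
        out, seen_keys = [], set()
        for bp in paths:
            if bp.key() not in seen_keys:
                seen_keys.add(bp.key())
                out.append(bp)
        return out

    def _walk(self, start, target, blocked, max_span):
        """Iterative frontier search; returns all explored chains."""
        p = self.params
        routes = [(start,)]
        frontier = [(start,)]
        for _it in range(p.max_iterations):
            new_frontier = []
            for chain in frontier:
                tip_id, tip_or = chain[-1]
                if (tip_id, tip_or) == target:
                    continue  # reached the other flank: stop extending
                span = sum(self.db.lookup(c).length for c, _o in chain[1:])
                if span > max_span:
                    continue
                for hit in self._edge_hits(tip_id, tip_or):
                    sid = hit.subject_id
                    node = (sid, hit.subject_orientation)
                    if sid != target[0] and blocked(sid):
                        continue
                    count = sum(1 for c, _o in chain if c == sid)
                    if count >= p.max_copies_per_path:
                        continue
                    new_frontier.append(chain + (node,))
            if not new_frontier:
                break
            new_frontier.sort(key=lambda ch: ch)
            if len(new_frontier) > p.max_chains:
                new_frontier = new_frontier[:p.max_chains]
            routes.extend(new_frontier)
            frontier = new_frontier
        return routes


def resolve_gap(gap: GapRecord, contig_db: ContigSet, params: SearchParams = None,
                scheme: ScoreScheme = None, placed=None) -> list[BridgePath]:
    """Convenience wrapper around :class:`GapResolver` for a single gap."""
    return GapResolver(contig_db, scheme, params, placed).resolve_gap(gap)
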