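"""Turn bridge paths into classified gap solutions.

Gap groups:

* **A** — the two flanking contigs overlap directly (typically a 500-700 bp
  paralogous repeat shared by the flanks broke the assembly);
* **B** — the gap is bridged by a multi-copy contig (transposase, reverse
  transcriptase, rRNA); one solution shared by both strains;
* **C** — subspecies polymorphism: pairs of homologous alternative contigs,
  one per strain, each bridging the gap;
* **D** — an insertion in one strain and not in the other: the insertion
  path and the deletion path coexist.

Classification uses read depth: with two strains at roughly equal abundance,
contigs shared by both strains sit at the modal depth, strain-specific
contigs at half of it, and multi-copy contigs well above it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import ScoreScheme, seed_extend_best
from .model import ContigSet, DepthBands, GapRecord, ScaffoldLayout, enumerate_gaps
from .overlap import BridgePath, GapResolver, SearchParams

log = logging.getLogger("gapbridge")

GROUP_A = "A"
GROUP_B = "B"
GROUP_C = "C"
GROUP_D = "D"
UNRESOLVED = "UNRESOLVED"

REGION_MULTI = "A_multicopy"
REGION_SHARED = "B_shared"
REGION_STRAIN = "C_strain"
REGION_BACKGROUND = "D_background"


@dataclass
class DepthClass:
    contig_id: str
    region: str | None
    note: str | None = None


def classify_depth(contig_set: ContigSet, bands: DepthBands) -> list[DepthClass]:
    """Assign each contig to a depth region given the shared-depth bands."""
    out = []
    sd = bands.shared_depth
    for c in contig_set:
        if c.depth is None:
            log.warning("contig %r has no depth; region unset", c.id)
            out.append(DepthClass(c.id, None))
            continue
        r = c.depth / sd
        if r > bands.multi_copy_min:
            out.append(DepthClass(c.id, REGION_MULTI))
        elif r >= bands.strain_hi:
            out.append(DepthClass(c.id, REGION_SHARED))
        elif r >= bands.strain_lo:
            out.append(DepthClass(c.id, REGION_STRAIN))
        elif r <= bands.background_max:
            out.append(DepthClass(c.id, REGION_BACKGROUND))
        else:
            out.append(DepthClass(c.id, REGION_BACKGROUND, note="ambiguous"))
    return out


def estimate_shared_depth(contig_set: ContigSet) -> float:
    """Length-weighted modal depth of the contigs shared by both strains.

    Iterates a Gaussian KDE with bandwidth 10% of the current mode over the
    depths above the background cutoff; the longest (shared-backbone) contigs
    dominate the weight so the iteration settles on the shared-depth peak.
    """
    from scipy.stats import gaussian_kde

    depths = np.array([c.depth for c in contig_set if c.depth is not None], float)
    lengths = np.array([c.length for c in contig_set if c.depth is not None], float)
    if len(depths) < 10:
        raise ValueError(
            "too few contigs with depth to estimate the shared depth; "
            "pass an explicit shared depth (--shared-depth)")
    mode = float(np.average(depths, weights=lengths))
    if np.ptp(depths) == 0:
        return mode
    for _ in range(8):
        keep = depths > 0.29 * mode
        d, w = depths[keep], lengths[keep]
        if np.ptp(d) == 0:
            return float(d[0])
        bw = max(0.10 * mode, 1.0)
        kde = gaussian_kde(d, bw_method=bw / max(d.std(ddof=0), 1e-9), weights=w)
        grid = np.linspace(d.min(), d.max(), 512)
        mode = float(grid[int(np.argmax(kde(grid)))])
    return mode


@dataclass
class GapSolution:
    """A classified gap with its candidate bridge paths, best path first."""

    gap: GapRecord
    group: str
    paths: list[BridgePath] = field(default_factory=list)
    computed_distance_per_path: list[int] = field(default_factory=list)
    alternative_pairs: list[tuple[str, str]] = field(default_factory=list)
    flags: set = field(default_factory=set)
    notes: list[str] = field(default_factory=list)
    verdicts: list[str] = field(default_factory=list)

    @property
    def consensus_per_path(self) -> list[str]:
        return [p.consensus for p in self.paths]

    @property
    def best_path(self) -> BridgePath | None:
        return self.paths[0] if self.paths else None

    def to_record(self) -> dict:
        return {
            "gap": {
                "name": self.gap.name,
                "left": self.gap.left_contig_id,
                "left_orientation": self.gap.left_orientation,
                "right": self.gap.right_contig_id,
                "right_orientation": self.gap.right_orientation,
                "estimated_length": self.gap.estimated_length,
                "scaffold_id": self.gap.scaffold_id,
            },
            "group": self.group,
            "flags": sorted(self.flags),
            "notes": list(self.notes),
            "verdicts": list(self.verdicts),
            "alternative_pairs": [list(p) for p in self.alternative_pairs],
            "computed_distance_per_path": list(self.computed_distance_per_path),
            "consensus_per_path": self.consensus_per_path,
            "paths": [
                {
                    "contigs": [c for c, _o in p.contigs],
                    "orientations": [o for _c, o in p.contigs],
                    "junctions": [
                        {"overlap": j.overlap, "identity": round(j.identity, 6),
                         "trim_left": j.trim_left, "trim_right": j.trim_right}
                        for j in p.junctions
                    ],
                    "score": p.score,
                }
                for p in self.paths
            ],
        }


def gap_distance(path: BridgePath, contig_db: ContigSet) -> int:
    """Signed gap distance implied by a bridge path: the consensus length
    between the gap-facing ends of the two flanks.  A pure flank overlap
    gives the negative of the overlap length."""
    left_id = path.contigs[0][0]
    right_id = path.contigs[-1][0]
    return (len(path.consensus)
            - contig_db.lookup(left_id).length
            - contig_db.lookup(right_id).length)


def build_consensus(path_chain, contig_set: ContigSet, depth_classes,
                    scheme: ScoreScheme = None, params: SearchParams = None) -> str:
    """Merge an oriented contig chain into a consensus, trimming foreign
    multi-copy edges and preferring non-multi-copy bases within overlaps."""
    from .overlap import chain_consensus

    multi = {d.contig_id for d in depth_classes if d.region == REGION_MULTI}
    path = chain_consensus(path_chain, contig_set, scheme, params, multi)
    if path is None:
        raise ValueError("chain does not merge at the required identity")
    return path.consensus


def _inserted_block(short, long):
    """If ``long`` equals ``short`` with one contiguous block inserted,
    return the block; else None.  Items are (contig_id, orientation)."""
    ns, nl = len(short), len(long)
    if nl <= ns:
        return None
    for i in range(ns + 1):
        if list(long[:i]) == list(short[:i]) and \
                list(long[i + nl - ns:]) == list(short[i:]):
            return list(long[i:i + nl - ns])
    return None


def _homologous(a_id, b_id, contig_db, scheme, min_identity, min_coverage=0.8,
                max_len_ratio=0.2):
    ca, cb = contig_db.lookup(a_id), contig_db.lookup(b_id)
    la, lb = ca.length, cb.length
    if min(la, lb) == 0 or abs(la - lb) > max_len_ratio * min(la, lb):
        return False
    for orient in ("forward", "reverse"):
        aln = seed_extend_best(ca.seq, cb.oriented(orient), scheme)
        if aln is None:
            continue
        cov = min(aln.q_span, aln.s_span) / min(la, lb)
        if cov >= min_coverage and aln.identity >= min_identity:
            return True
    return False


def classify_gap(gap: GapRecord, paths: list[BridgePath], depth_of: dict[str, str],
                 contig_db: ContigSet, scheme: ScoreScheme = None,
                 min_identity: float = 0.95) -> GapSolution:
    """Apply the group decision rules, in order of evidence specificity
    (A > D > C > B)."""
    scheme = scheme or ScoreScheme()
    sol = GapSolution(gap=gap, group=UNRESOLVED, paths=list(paths))
    sol.computed_distance_per_path = [gap_distance(p, contig_db) for p in paths]
    if not paths:
        return sol
    best = paths[0]
    region = lambda cid: depth_of.get(cid)

    flanks_shared = (region(gap.left_contig_id) == REGION_SHARED
                     and region(gap.right_contig_id) == REGION_SHARED)

    # insertion/deletion between the strains: checked before the direct
    # overlap rule because the deletion path of a Group D gap is itself a
    # direct flank overlap — the two-path structure is the stronger evidence
    if len(paths) == 2:
        a, b = paths
        short, long = (a, b) if len(a.contigs) <= len(b.contigs) else (b, a)
        block = _inserted_block(short.contigs, long.contigs)
        if block is not None and flanks_shared and all(
                region(cid) in (REGION_STRAIN, REGION_MULTI) for cid, _o in block):
            sol.group = GROUP_D
            sol.flags.add("insertion_deletion")
            # the insertion path first: it is tested first downstream
            sol.paths = [long, short]
            sol.computed_distance_per_path = [
                gap_distance(long, contig_db), gap_distance(short, contig_db)]
            return sol

    # direct overlap of the flanks
    if best.n_intermediates == 0:
        sol.group = GROUP_A
        return sol

    # pairs of homologous alternative contigs (one per strain)
    if len(paths) >= 2:
        for j in range(1, len(paths)):
            p1, p2 = paths[0], paths[j]
            i1, i2 = p1.intermediate_ids, p2.intermediate_ids
            if not i1 or len(i1) != len(i2):
                continue
            if any(region(c) != REGION_STRAIN for c in i1 + i2):
                continue
            if all(_homologous(x, y, contig_db, scheme, min_identity)
                   for x, y in zip(i1, i2)):
                sol.group = GROUP_C
                sol.alternative_pairs = sorted(
                    {tuple(sorted((x, y))) for x, y in zip(i1, i2)})
                return sol

    # bridged by a multi-copy contig
    if any(region(c) == REGION_MULTI for c in best.intermediate_ids):
        sol.group = GROUP_B
        sol.flags.add("multi_copy_bridge")
        return sol

    # unique non-overlapping bridge
    sol.group = GROUP_A
    sol.notes.append("non-overlap bridge")
    return sol


def compare_distances(solutions, contig_db: ContigSet, insert_sd: float | None = None,
                      tolerance: float | None = None, clamp_min: int = 20) -> None:
    """Flag paths whose computed distance disagrees with the scaffolder
    estimate.

    For insertion/deletion gaps the comparison uses the insertion path and an
    estimate *below* the insertion distance is expected (the scaffolder
    averages over both strains) and not flagged.  A negative computed
    distance with the estimate at the scaffolder's floor is likewise expected
    (scaffolders never emit negative estimates).  A multi-copy gap whose
    estimate exceeds the computed distance by about one copy length is marked
    as a tandem-repeat candidate.
    """
    if tolerance is None:
        tolerance = max(500.0, 3 * insert_sd) if insert_sd else 500.0
    for sol in solutions:
        est = sol.gap.estimated_length
        if est is None or not sol.paths:
            continue
        d = sol.computed_distance_per_path[0]
        disc = d - est
        if sol.group == GROUP_D:
            # insertion path (first); an estimate below it is the expected
            # bias (the scaffolder averages the two strains), never flagged
            if disc < -tolerance:
                sol.flags.add("distance_discrepant")
            continue
        if d < 0 and est <= clamp_min:
            continue
        if abs(disc) > tolerance:
            sol.flags.add("distance_discrepant")
            best = sol.paths[0]
            if "multi_copy_bridge" in sol.flags and est > d:
                copy_len = max(
                    (contig_db.lookup(c).length for c in best.intermediate_ids),
                    default=0)
                if copy_len and abs((est - d) - copy_len) <= tolerance:
                    sol.flags.add("tandem_candidate")


def tandem_core(solution, contig_db: ContigSet) -> str | None:
    """The trimmed sequence of the multi-copy bridge of a tandem-candidate
    gap — the repetitive element whose copy number is in question."""
    if not solution.paths:
        return None
    p = solution.paths[0]
    for (cid, orient), j in zip(p.contigs[1:-1], p.junctions):
        seq = contig_db.lookup(cid).oriented(orient)
        return seq[j.trim_right:]
    return None


def resolve_tandem_candidates(solutions, contig_db: ContigSet, pairs,
                              insert_model, map_params=None,
                              copies: int = 2) -> dict:
    """Confirm tandem-candidate gaps with the poly-N spanning-pair test and
    rewrite the consensus of confirmed gaps with the duplicated element.

    Read mapping alone cannot tell one copy from two adjacent copies; pairs
    spanning a poly-N spacer between two concatenated copies can.  The
    corrected consensus restores the second copy immediately after the
    first, which also brings the computed gap distance back in line with
    the mate-pair estimate.
    """
    from .mapping import tandem_test

    outcomes = {}
    for sol in solutions:
        if "tandem_candidate" not in sol.flags:
            continue
        core = tandem_core(sol, contig_db)
        if core is None:
            continue
        call = tandem_test(core, pairs, insert_model, params=map_params)
        outcomes[sol.gap.name] = call
        if call["call"] != "tandem":
            continue
        p = sol.paths[0]
        cons = p.consensus
        idx = cons.find(core)
        if idx < 0:
            sol.notes.append("tandem confirmed but element not locatable in consensus")
            continue
        end = idx + len(core)
        p.consensus = cons[:end] + core * (copies - 1) + cons[end:]
        sol.computed_distance_per_path[0] += len(core) * (copies - 1)
        sol.flags.add("tandem_resolved")
        sol.notes.append(
            f"tandem copies confirmed by {call['spanning_pairs']} spanning pairs; "
            f"consensus expanded to {copies} copies")
    return outcomes


@dataclass
class MergeProposal:
    """A strain-specific scaffold proposed as the alternative to bridges of
    adjacent gaps in a host scaffold."""

    alt_scaffold_id: str
    host_scaffold_id: str
    substitutions: list[tuple[str, str, str]]  # (alt contig, partner bridge, gap name)


def detect_alternative_scaffolds(scaffolds, solutions, contig_set: ContigSet,
                                 depth_of: dict[str, str]) -> list[MergeProposal]:
    """Propose whole scaffolds that are strain alternatives to gap bridges.

    A scaffold qualifies when every one of its contigs is one member of an
    alternative pair whose partner bridges a gap of a single host scaffold,
    and those gaps are adjacent in the host.
    """
    pair_of: dict[str, list[tuple[str, str]]] = {}
    gap_index: dict[str, tuple[str, int]] = {}
    for sc in scaffolds:
        gaps = [g.name for g in enumerate_gaps([sc])]
        for i, gname in enumerate(gaps):
            gap_index[gname] = (sc.id, i)
    for sol in solutions:
        for a, b in sol.alternative_pairs:
            pair_of.setdefault(a, []).append((b, sol.gap.name))
            pair_of.setdefault(b, []).append((a, sol.gap.name))
    proposals = []
    for sc in scaffolds:
        cids = [pl.contig_id for pl in sc.placements]
        if not cids or any(depth_of.get(c) != REGION_STRAIN for c in cids):
            continue
        subs = []
        hosts = set()
        positions = []
        ok = True
        for cid in cids:
            entries = [e for e in pair_of.get(cid, ())
                       if gap_index.get(e[1], (None,))[0] not in (None, sc.id)]
            if not entries:
                ok = False
                break
            partner, gname = entries[0]
            host, pos = gap_index[gname]
            hosts.add(host)
            positions.append(pos)
            subs.append((cid, partner, gname))
        if not ok or len(hosts) != 1:
            continue
        positions.sort()
        if all(b - a == 1 for a, b in zip(positions, positions[1:])):
            proposals.append(MergeProposal(sc.id, hosts.pop(), subs))
    return proposals


@dataclass
class ScaffoldOrder:
    """Adjacency graph over scaffold termini plus the selected order."""

    edges: list[dict]
    selected: list[dict]
    components: list[dict]
    closed_circle: bool
    ambiguous: list[str]


def order_scaffolds(scaffolds, contig_db: ContigSet, params: SearchParams = None,
                    scheme: ScoreScheme = None, exclude=()) -> ScaffoldOrder:
    """Determine scaffold adjacency by resolving trial gaps between the
    terminal contigs of every scaffold pair.

    Each resolved trial gap becomes a weighted edge between two scaffold
    termini; a maximum-weight matching in which every terminus has at most
    one partner selects the order.  If the matching plus the scaffolds form a
    single cycle covering all (non-alternative) scaffolds, the order is a
    closed circle.
    """
    import networkx as nx

    from .model import FORWARD, REVERSE, make_gap
    from .overlap import GapResolver

    params = params or SearchParams()
    scheme = scheme or ScoreScheme()
    use = [sc for sc in scaffolds if sc.id not in set(exclude) and sc.placements]
    placed = {pl.contig_id: sc.id for sc in use for pl in sc.placements}
    resolver = GapResolver(contig_db, scheme, params, placed)

    def terminus(sc, end):
        """(contig_id, orientation facing outward->rightward) for an end."""
        if end == "R":
            pl = sc.placements[-1]
            return pl.contig_id, pl.orientation
        pl = sc.placements[0]
        return pl.contig_id, REVERSE if pl.orientation == FORWARD else FORWARD

    edges = []
    for i, si in enumerate(use):
        for sj in use[i + 1:]:
            for ei in ("L", "R"):
                for ej in ("L", "R"):
                    lc, lo = terminus(si, ei)
                    # right flank: entering sj at end ej, oriented inward
                    rc, ro_out = terminus(sj, ej)
                    ro = REVERSE if ro_out == FORWARD else FORWARD
                    if lc == rc:
                        continue
                    gap = make_gap(lc, rc, lo, ro)
                    paths = resolver.resolve_gap(gap)
                    if paths:
                        edges.append({
                            "a": (si.id, ei), "b": (sj.id, ej),
                            "weight": paths[0].score,
                            "path": [c for c, _o in paths[0].contigs],
                            "gap": gap.name,
                        })
    g = nx.Graph()
    for e in edges:
        key = (e["a"], e["b"])
        if not g.has_edge(*key) or g.edges[key]["weight"] < e["weight"]:
            g.add_edge(e["a"], e["b"], weight=e["weight"])
    matching = nx.algorithms.matching.max_weight_matching(g)
    selected = []
    matched_nodes = set()
    for a, b in sorted(matching, key=lambda ab: tuple(sorted(ab))):
        w = g.edges[(a, b)]["weight"]
        selected.append({"a": min(a, b), "b": max(a, b), "weight": w})
        matched_nodes.update((a, b))
    ambiguous = []
    for e in edges:
        pair = frozenset((e["a"], e["b"]))
        if pair not in {frozenset((s["a"], s["b"])) for s in selected}:
            for s in selected:
                if e["weight"] == s["weight"] and \
                        (e["a"] in (s["a"], s["b"]) or e["b"] in (s["a"], s["b"])):
                    ambiguous.append(e["gap"])

    # walk components: scaffold-internal edges join (sid, L)-(sid, R)
    link = nx.Graph()
    for sc in use:
        link.add_edge((sc.id, "L"), (sc.id, "R"), kind="scaffold")
    for s in selected:
        link.add_edge(s["a"], s["b"], kind="join")
    components = []
    for comp in nx.connected_components(link):
        sub = link.subgraph(comp)
        sids = sorted({n[0] for n in comp})
        is_cycle = all(d == 2 for _n, d in sub.degree())
        components.append({"type": "circle" if is_cycle else "chain",
                           "scaffolds": sids})
    closed = (len(components) == 1 and components[0]["type"] == "circle"
              and len(components[0]["scaffolds"]) == len(use))
    return ScaffoldOrder(edges, selected, components, closed, sorted(set(ambiguous)))


@dataclass
class PipelineResult:
    solutions: list[GapSolution]
    bands: DepthBands
    depth_of: dict[str, str]
    proposals: list[MergeProposal]


def solve_gaps(contig_set: ContigSet, scaffolds, params: SearchParams = None,
               scheme: ScoreScheme = None, shared_depth: float | None = None,
               bands: DepthBands = None, insert_sd: float | None = None) -> PipelineResult:
    """Run the full within-scaffold gap-resolution stage."""
    params = params or SearchParams()
    scheme = scheme or ScoreScheme()
    if bands is None:
        sd = shared_depth if shared_depth is not None else estimate_shared_depth(contig_set)
        bands = DepthBands(shared_depth=sd)
    dclasses = classify_depth(contig_set, bands)
    depth_of = {d.contig_id: d.region for d in dclasses}
    placed = {pl.contig_id: sc.id for sc in scaffolds for pl in sc.placements}
    resolver = GapResolver(contig_set, scheme, params, placed)
    resolver.multi_copy_ids = frozenset(
        d.contig_id for d in dclasses if d.region == REGION_MULTI)
    solutions = []
    for gap in enumerate_gaps(scaffolds):
        paths = resolver.resolve_gap(gap)
        solutions.append(classify_gap(gap, paths, depth_of, contig_set, scheme,
                                      params.min_identity))
    compare_distances(solutions, contig_set, insert_sd=insert_sd)
    proposals = detect_alternative_scaffolds(scaffolds, solutions, contig_set, depth_of)
    return PipelineResult(solutions, bands, depth_of, proposals)
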