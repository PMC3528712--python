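"""Ground-truthed synthetic two-strain metagenome fixtures.

The generator emulates what a pyrosequencing-era overlap assembler produces
from a community of two closely related strains at similar abundance:

* a shared backbone broken into "shared" contigs at every repeat copy and
  every inter-strain difference;
* one collapsed multi-copy contig per transposon family / rRNA-like operon,
  carrying a short foreign terminal segment from one of its source loci
  (the chimeric-edge effect);
* pairs of homologous strain-specific "alternative" contigs at polymorphic
  blocks, and strain-specific insertion contigs (with target-site
  duplications for transposons);
* scaffold layouts whose gap estimates are the true distances plus noise,
  floored at the scaffolder minimum of 20 bp.

Fragmentation is rule-based rather than a re-run of a real assembler, which
is what guarantees a labelled ground truth for every emitted gap.  Adjacent
contigs retain overhangs into the interleaving feature (as reads crossing a
repeat boundary would provide), so every gap is closable by overlap search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import dna
from .mapping import InsertModel, ReadPair
from .model import (FORWARD, REVERSE, Contig, ContigPlacement, ContigSet,
                    MIN_GAP_ESTIMATE, ScaffoldLayout)


@dataclass
class SimConfig:
    """Study conditions of the default fixture.

    Library parameters mirror a 454-style long-read metagenome (198 bp
    reads, ~8.6 kb mate pairs) plus a short-insert Illumina-style library
    (76 bp reads, ~647 bp inserts); per-strain depth 35x so that shared
    contigs sit near 70x.
    """

    seed: int = 42
    ancestor_len: int = 200_000
    snp_divergence: float = 0.002
    transposon_families: int = 4
    rrna_like_operons: int = 3        # copies of one operon-like unit
    operon_len: int = 5000
    paralog_pairs: int = 4
    tandem_dups: int = 1
    large_insertion_len: int = 5000
    small_indel_contigs: int = 2
    plain_overlaps: int = 3
    background_contigs: int = 5
    dispersed_elements: int = 20      # single-copy tandem-test controls
    dispersed_element_len: int = 1400
    depth_per_strain: float = 35.0
    read_error_rate: float = 0.002
    homopolymer_error_rate: float = 0.15   # long-read model only
    insert_short: tuple = (647.0, 60.0, 76)    # mean, sd, read length
    insert_long: tuple = (8600.0, 900.0, 198)
    # strain-specific material keeps >95% homology between alternatives
    block_snp_cap: float = 0.022
    patch_len: int = 40
    patch_snps: int = 16

    @property
    def short_model(self) -> InsertModel:
        return InsertModel(self.insert_short[0], self.insert_short[1])

    @property
    def long_model(self) -> InsertModel:
        return InsertModel(self.insert_long[0], self.insert_long[1])


@dataclass
class GapTruth:
    """Ground truth for one emitted gap."""

    name: str
    left: str
    right: str
    site_type: str
    group: str
    tandem: bool = False
    bridges: dict = field(default_factory=dict)       # strain -> [contig ids]
    expected_consensus: dict = field(default_factory=dict)  # strain -> str
    expected_distance: dict = field(default_factory=dict)   # strain -> int
    distance_for_estimate: float = 0.0
    estimated_length: int = MIN_GAP_ESTIMATE


@dataclass
class GroundTruth:
    strain1_genome: str = ""
    strain2_genome: str = ""
    gaps: list = field(default_factory=list)
    contig_region: dict = field(default_factory=dict)
    contig_true_depth: dict = field(default_factory=dict)
    tandem_element: str = ""
    tandem_element_id: str = ""
    dispersed_elements: list = field(default_factory=list)
    alt_scaffold_id: str = ""
    alt_scaffold_pairs: list = field(default_factory=list)  # (mini contig, main bridge)
    polymorphic_gaps: list = field(default_factory=list)    # gap names with per-strain options


@dataclass
class Fixture:
    config: SimConfig
    contig_set: ContigSet
    scaffolds: list
    truth: GroundTruth


class _Builder:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.truth = GroundTruth()
        self.contigs: list[Contig] = []
        self.placements: list[tuple[str, str]] = []   # main scaffold
        self.gap_truths: list[GapTruth] = []
        self.g1: list[str] = []
        self.g2: list[str] = []
        self.cur: str = ""           # shared contig under construction
        self._n = 0
        self._d1 = config.depth_per_strain
        self.mini_scaffold: list[tuple[str, str]] = []
        self.mini_gap_est: int | None = None

    # -- helpers -----------------------------------------------------------

    def _name(self) -> str:
        self._n += 1
        return f"contig{self._n:05d}"

    def _jit(self) -> float:
        return float(self.rng.uniform(0.9, 1.1))

    def _emit(self, seq: str, depth: float, region: str, place: str | None,
              allow_flip: bool = True) -> tuple[str, str]:
        """Register a contig; possibly stored reverse-complemented."""
        name = self._name()
        flip = allow_flip and self.rng.random() < 0.25
        stored = dna.revcomp(seq) if flip else seq
        orient = REVERSE if flip else FORWARD
        self.contigs.append(Contig(name, stored, depth))
        self.truth.contig_region[name] = region
        self.truth.contig_true_depth[name] = depth
        if place == "main":
            self.placements.append((name, orient))
        elif place == "mini":
            self.mini_scaffold.append((name, orient))
        return name, orient

    def _close_shared(self) -> str:
        cid, _o = self._emit(self.cur, 2 * self._d1 * self._jit(), "B_shared", "main")
        self.cur = ""
        return cid

    def _both(self, seq: str) -> None:
        self.g1.append(seq)
        self.g2.append(seq)

    def _backbone(self, length: int) -> str:
        seg = dna.random_dna(self.rng, length)
        self.cur += seg
        self._both(seg)
        return seg

    def _overhang(self) -> int:
        return int(self.rng.integers(110, 151))

    def _estimate(self, d_true: float) -> int:
        return max(MIN_GAP_ESTIMATE, int(round(d_true + self.rng.normal(0, 100))))

    def _gap(self, left: str, site_type: str, group: str, **kw) -> GapTruth:
        gt = GapTruth(name="", left=left, right="", site_type=site_type,
                      group=group, **kw)
        self.gap_truths.append(gt)
        return gt

    # -- site emitters -----------------------------------------------------

    def site_plain_overlap(self):
        o = int(self.rng.integers(100, 301))
        ov = dna.random_dna(self.rng, o)
        self._both(ov)
        left = self.cur + ov
        self.cur = left
        lid = self._close_shared()
        gt = self._gap(lid, "plain_overlap", "A",
                       distance_for_estimate=-o)
        gt.expected_distance = {"strain1": -o, "strain2": -o}
        self.cur = ov
        gt._pending = ("direct", ov)
        return gt

    def site_paralog(self, copy_seq: str):
        self._both(copy_seq)
        self.cur += copy_seq
        lid = self._close_shared()
        o = -len(copy_seq)
        gt = self._gap(lid, "paralog", "A", distance_for_estimate=o)
        gt.expected_distance = {"strain1": o, "strain2": o}
        self.cur = copy_seq
        gt._pending = ("direct", copy_seq)
        return gt

    def site_family_shared(self, fam, tandem: bool = False):
        o = self._overhang()
        tsd = dna.random_dna(self.rng, fam["tsd"]) if fam["tsd"] else ""
        unit = fam["seq"] + fam["seq"] if tandem else fam["seq"]
        self._both(tsd + unit + tsd)
        left = self.cur + tsd + fam["seq"][:o]
        self.cur = left
        lid = self._close_shared()
        e = len(fam["seq"])
        d_path = e - 2 * o
        d_true = (2 * e - 2 * o) if tandem else d_path
        gt = self._gap(lid, "tandem" if tandem else f"family_{fam['id']}", "B",
                       tandem=tandem, distance_for_estimate=d_true)
        gt.bridges = {"strain1": [fam["id"]], "strain2": [fam["id"]]}
        gt.expected_distance = {"strain1": d_path, "strain2": d_path}
        self.cur = fam["seq"][-o:] + tsd
        gt._pending = ("bridge", tsd + unit + tsd, o, tsd)
        return gt

    def site_insertion(self, block: str, strain: int, site_type: str,
                       bridge_region="C_strain"):
        """Insertion of ``block`` in one strain only (Group D)."""
        o = self._overhang()
        o_r = 150
        if strain == 1:
            self.g1.append(block)
        else:
            self.g2.append(block)
        left = self.cur
        lid = self._close_shared()
        left_tail = left[-o:]
        gt = self._gap(lid, site_type, "D",
                       distance_for_estimate=(len(block) - o - o) / 2.0)
        gt._pending = ("insertion", left_tail, block, o, o_r, strain, bridge_region)
        self.cur = left_tail  # duplicated flank head of the right contig
        return gt

    def site_variant_block(self, b1: str, b2: str, mini: bool):
        o = self._overhang()
        self.g1.append(b1)
        self.g2.append(b2)
        left = self.cur
        lid = self._close_shared()
        left_tail = left[-o:]
        gt = self._gap(lid, "variant_block", "C",
                       distance_for_estimate=(len(b1) + len(b2)) / 2.0)
        gt._pending = ("variant", left_tail, b1, b2, o, mini)
        self.cur = ""
        return gt

    # -- finishing ---------------------------------------------------------

    def finish_site(self, gt: GapTruth, next_head: str):
        """Called once the backbone after a site is long enough to take the
        right-flank overhang ``next_head`` (the first bases of the following
        shared contig)."""
        kind = gt._pending[0]
        if kind == "direct":
            pass
        elif kind == "bridge":
            pass
        elif kind == "insertion":
            _k, left_tail, block, o, o_r, strain, region = gt._pending
            bid, _orr = self._emit(left_tail + block + next_head[:o_r],
                                   self._d1 * self._jit(), region, None)
            gt.bridges = {f"strain{strain}": [bid],
                          f"strain{3 - strain}": []}
        elif kind == "variant":
            _k, left_tail, b1, b2, o, mini = gt._pending
            v1, _o1 = self._emit(left_tail + b1 + next_head[:o],
                                 self._d1 * self._jit(), "C_strain", None)
            v2, _o2 = self._emit(left_tail + b2 + next_head[:o],
                                 self._d1 * self._jit(),
                                 "C_strain", "mini" if mini else None)
            gt.bridges = {"strain1": [v1], "strain2": [v2]}
            self.truth.polymorphic_gaps.append(gt)
            if mini:
                self.truth.alt_scaffold_pairs.append((v2, v1))
        del gt._pending


def _family_plan(cfg: SimConfig, rng) -> list[dict]:
    fams = []
    for i in range(cfg.transposon_families):
        if i == 0:
            # tandem family: long enough to hold whole short-insert pairs
            # (so single-copy controls are well covered) and to make the
            # tandem distance deficit unmistakable
            length = int(rng.integers(1100, 1601))
        else:
            length = int(rng.integers(600, 2500))
        fams.append({
            "id": f"TE{i}",
            "seq": dna.random_dna(rng, length),
            "tsd": int(rng.integers(4, 13)),
        })
    return fams


def _variant_pair(cfg: SimConfig, rng, length: int) -> tuple[str, str]:
    """Two strain versions of a polymorphic block: dispersed SNPs plus one
    dense hypervariable patch (which is what defeats strain-crossed read
    mapping)."""
    base = dna.random_dna(rng, length)
    n_snp = int(length * cfg.block_snp_cap)
    b1, b2 = list(base), list(base)
    pstart = int(rng.integers(length // 3, 2 * length // 3))
    patch_pos = list(pstart + rng.choice(cfg.patch_len, size=min(cfg.patch_snps, cfg.patch_len), replace=False))
    rest = max(n_snp - len(patch_pos), 8)
    disp_pos = list(rng.choice(length, size=rest, replace=False))
    for p in patch_pos + disp_pos:
        p = int(p) % length
        alt = "ACGT"[(("ACGT".index(base[p])) + int(rng.integers(1, 4))) % 4]
        if rng.random() < 0.5:
            b1[p] = alt
        else:
            b2[p] = alt
    return "".join(b1), "".join(b2)


def generate_strain_pair(config: SimConfig):
    """Build the two strain genomes and the ground-truth skeleton."""
    fx = _build(config)
    return fx.truth.strain1_genome, fx.truth.strain2_genome, fx.truth


def fragment_into_contigs(strain1: str, strain2: str, truth: GroundTruth,
                          config: SimConfig):
    """Rule-based fragmentation of the strain pair into contigs, scaffold
    layouts and per-contig depths.  The fragmentation rules are applied
    during genome construction (that is what makes every gap labelled), so
    this re-derives the fixture for the given truth object."""
    fx = _build(config)
    if fx.truth.strain1_genome != strain1 or fx.truth.strain2_genome != strain2:
        raise ValueError("genomes do not correspond to this configuration")
    return fx.contig_set, fx.scaffolds, fx.truth


def make_fixture(seed: int = 42, **overrides) -> Fixture:
    return _build(SimConfig(seed=seed, **overrides))


def _build(config: SimConfig) -> Fixture:
    cfg = config
    b = _Builder(cfg)
    rng = b.rng
    fams = _family_plan(cfg, rng)

    # site order: interleave deterministically, shuffled by the seed
    sites: list[tuple] = []
    sites += [("plain",) for _ in range(cfg.plain_overlaps)]
    paralogs = []
    for p in range(cfg.paralog_pairs):
        plen = int(rng.integers(500, 701))
        base = dna.random_dna(rng, plen)
        ident = rng.uniform(0.90, 0.98)
        copy2 = dna.mutate(rng, base, 1 - ident)
        paralogs.append((base, copy2))
        sites += [("paralog", p, 0), ("paralog", p, 1)]
    for fam in fams:
        n_shared = 2 if fam["id"] != "TE1" else 3
        sites += [("te_shared", fam["id"]) for _ in range(n_shared)]
    if cfg.tandem_dups:
        sites += [("te_tandem", "TE0")]
    sites += [("te_insert", "TE2", 1), ("te_insert", "TE3", 2)]
    operon = {"id": "OPR", "seq": dna.random_dna(rng, cfg.operon_len), "tsd": 0}
    sites += [("operon",) for _ in range(cfg.rrna_like_operons)]
    sites += [("large_insert",)]
    for i in range(cfg.small_indel_contigs):
        sites += [("small_insert", 1 if i % 2 == 0 else 2)]
    # variant blocks: two standalone + the adjacent pair for the alt scaffold
    sites += [("block", 0, False), ("block", 1, False), ("block_pair",)]
    order = list(rng.permutation(len(sites)))
    # the adjacent pair counts as two sites; keep list as-is, order shuffled
    sites = [sites[i] for i in order]

    feature_len = sum({
        "plain": 200, "paralog": 600, "te_shared": 1800, "te_tandem": 1300,
        "te_insert": 1800, "operon": cfg.operon_len, "large_insert": cfg.large_insertion_len,
        "small_insert": 1000, "block": 1500, "block_pair": 5500,
    }[s[0]] for s in sites)
    n_seg = len(sites) + 2
    seg_len = max(2000, (cfg.ancestor_len - feature_len) // n_seg)

    pending: GapTruth | None = None

    def backbone_and_finish(length):
        nonlocal pending
        seg = dna.random_dna(rng, length)
        b.cur += seg
        b._both(seg)
        if pending is not None:
            b.finish_site(pending, seg)
            pending = None

    backbone_and_finish(int(seg_len * rng.uniform(0.8, 1.2)))
    for site in sites:
        kind = site[0]
        if kind == "plain":
            gt = b.site_plain_overlap()
        elif kind == "paralog":
            gt = b.site_paralog(paralogs[site[1]][site[2]])
        elif kind == "te_shared":
            fam = next(f for f in fams if f["id"] == site[1])
            gt = b.site_family_shared(fam)
        elif kind == "te_tandem":
            fam = next(f for f in fams if f["id"] == site[1])
            gt = b.site_family_shared(fam, tandem=True)
        elif kind == "te_insert":
            fam = next(f for f in fams if f["id"] == site[1])
            tsd = dna.random_dna(rng, fam["tsd"])
            gt = b.site_insertion(fam["seq"] + tsd, site[1 + 1],
                                  f"te_insert_{fam['id']}")
        elif kind == "operon":
            gt = b.site_family_shared(operon)
        elif kind == "large_insert":
            gt = b.site_insertion(dna.random_dna(rng, cfg.large_insertion_len),
                                  1, "large_insert")
        elif kind == "small_insert":
            gt = b.site_insertion(dna.random_dna(rng, 1000), site[1], "small_insert")
        elif kind == "block":
            blen = int(rng.integers(1200, 1800))
            b1_, b2_ = _variant_pair(cfg, rng, blen)
            gt = b.site_variant_block(b1_, b2_, mini=False)
        elif kind == "block_pair":
            l1 = int(rng.integers(1200, 1800))
            b1_, b2_ = _variant_pair(cfg, rng, l1)
            gt = b.site_variant_block(b1_, b2_, mini=True)
            pending = gt
            backbone_and_finish(2500)   # shared mid contig between the pair
            l2 = int(rng.integers(1200, 1800))
            c1_, c2_ = _variant_pair(cfg, rng, l2)
            gt2 = b.site_variant_block(c1_, c2_, mini=True)
            pending = gt2
            gt = gt2
        else:
            raise AssertionError(kind)
        if kind != "block_pair":
            pending = gt
        backbone_and_finish(int(seg_len * rng.uniform(0.8, 1.2)))
    # close the trailing shared contig
    b._close_shared()

    # family and operon consensus contigs with one chimeric foreign edge
    genome1 = "".join(b.g1)
    genome2 = "".join(b.g2)
    for fam in fams + [operon]:
        foreign = dna.random_dna(rng, int(rng.integers(40, 121)))
        copies = genome1.count(fam["seq"]) + genome2.count(fam["seq"])
        depth = copies * b._d1 * b._jit()
        cid, _o = b._emit(foreign + fam["seq"], depth, "A_multicopy", None,
                          allow_flip=False)
        for gt in b.gap_truths:
            for k in gt.bridges:
                gt.bridges[k] = [cid if x == fam["id"] else x for x in gt.bridges[k]]
        if fam["id"] == "TE0":
            b.truth.tandem_element = fam["seq"]
            b.truth.tandem_element_id = cid

    # background organisms
    for i in range(cfg.background_contigs):
        b._emit(dna.random_dna(rng, int(rng.integers(1000, 4000))),
                14.0 * b._jit(), "D_background", None)

    # single-copy control elements for the tandem test, sampled away from
    # every repeat family (a window overlapping the tandem site would be a
    # genuinely tandem element, not a control)
    el = cfg.dispersed_element_len
    k_ctl = 32
    repeat_kmers = set()
    for fam in fams + [operon]:
        for s in (fam["seq"], dna.revcomp(fam["seq"])):
            for i in range(0, len(s) - k_ctl + 1, 8):
                repeat_kmers.add(s[i:i + k_ctl])
    picked = 0
    for _try in range(cfg.dispersed_elements * 40):
        if picked >= cfg.dispersed_elements:
            break
        pos = int(rng.integers(0, len(genome1) - el))
        cand = genome1[pos:pos + el]
        if any(cand[i:i + k_ctl] in repeat_kmers
               for i in range(0, el - k_ctl + 1)):
            continue
        b.truth.dispersed_elements.append(cand)
        picked += 1

    contig_set = ContigSet(b.contigs)
    # main scaffold
    main_placements = [ContigPlacement(cid, orient, i)
                       for i, (cid, orient) in enumerate(b.placements)]
    gap_ests = []
    for i, gt in enumerate(b.gap_truths):
        gt.right = b.placements[i + 1][0]
        gt.name = f"{gt.left}-G-{gt.right}"
        gt.estimated_length = b._estimate(gt.distance_for_estimate)
        gap_ests.append(gt.estimated_length)
    main = ScaffoldLayout("scaffold001", main_placements, gap_ests)
    scaffolds = [main]
    if b.mini_scaffold:
        mini_pl = [ContigPlacement(cid, orient, i)
                   for i, (cid, orient) in enumerate(b.mini_scaffold)]
        mid_est = b._estimate(2500 - 2 * 130)
        mini = ScaffoldLayout("scaffold002", mini_pl, [mid_est] * (len(mini_pl) - 1))
        scaffolds.append(mini)
        b.truth.alt_scaffold_id = "scaffold002"
        for i in range(len(b.mini_scaffold) - 1):
            gt = GapTruth(name="", left=b.mini_scaffold[i][0],
                          right=b.mini_scaffold[i + 1][0],
                          site_type="alt_scaffold_internal", group="A",
                          estimated_length=mid_est)
            gt.name = f"{gt.left}-G-{gt.right}"
            b.gap_truths.append(gt)

    b.truth.strain1_genome = genome1
    b.truth.strain2_genome = genome2
    b.truth.gaps = b.gap_truths
    _fill_expected(b, contig_set)
    return Fixture(cfg, contig_set, scaffolds, b.truth)


def _fill_expected(b: _Builder, contig_set: ContigSet) -> None:
    """Record the expected correct consensus per strain for every gap, as
    the genome substring from the start of the left flank to the end of the
    right flank (in placement orientation)."""
    g1 = b.truth.strain1_genome
    g2 = b.truth.strain2_genome
    orient_of = {cid: o for cid, o in b.placements}
    orient_of.update({cid: o for cid, o in b.mini_scaffold})
    for gt in b.gap_truths:
        lseq = contig_set.lookup(gt.left).oriented(orient_of[gt.left])
        rseq = contig_set.lookup(gt.right).oriented(orient_of[gt.right])
        for strain, g in (("strain1", g1), ("strain2", g2)):
            cons = _expected_span(g, lseq, rseq, gt, strain, contig_set)
            if cons is not None:
                gt.expected_consensus[strain] = cons
        if not gt.expected_distance:
            gt.expected_distance = {
                s: len(c) - len(lseq) - len(rseq)
                for s, c in gt.expected_consensus.items()}


def _expected_span(genome: str, lseq: str, rseq: str, gt: GapTruth,
                   strain: str, contig_set: ContigSet) -> str | None:
    """Genome substring from the start of the left flank to the end of the
    right flank, tolerating a duplicated head on either flank (the head a
    right flank inherits at an insertion site does not occur contiguously in
    the insertion strain, and in the consensus it is trimmed)."""
    max_dup = 200
    ls = lskip = -1
    for skip in range(0, max_dup + 1):
        pos = genome.find(lseq[skip:])
        if pos >= 0:
            ls, lskip = pos, skip
            break
    if ls < 0:
        return None
    for skip in range(0, max_dup + 1):
        rs = genome.find(rseq[skip:], ls + 1)
        if rs >= 0:
            return lseq[:lskip] + genome[ls:rs + len(rseq) - skip]
    return None


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_pairs(genome: str, insert_model: InsertModel, depth: float,
                   read_len: int, seed: int, error_rate: float = 0.0,
                   homopolymer_error_rate: float = 0.0,
                   circular: bool = True, id_prefix: str = "p") -> list[ReadPair]:
    """Innie read pairs at the requested mean coverage.

    Fragment starts are uniform over the (optionally circular) genome;
    insert sizes are normal, truncated at twice the read length.
    Substitution errors occur at ``error_rate``; the long-read model
    additionally perturbs homopolymer run lengths."""
    rng = np.random.default_rng(seed)
    g = len(genome)
    n_pairs = int(round(g * depth / (2 * read_len)))
    ext = genome + genome[:int(insert_model.mean + 6 * insert_model.sd) + read_len] \
        if circular else genome
    pairs = []
    for i in range(n_pairs):
        ins = int(round(rng.normal(insert_model.mean, insert_model.sd)))
        ins = max(ins, 2 * read_len)
        if circular:
            start = int(rng.integers(0, g))
        else:
            if g - ins <= 0:
                continue
            start = int(rng.integers(0, g - ins))
        frag = ext[start:start + ins]
        if len(frag) < ins:
            continue
        m1 = frag[:read_len]
        m2 = dna.revcomp(frag[-read_len:])
        if error_rate:
            m1 = dna.mutate(rng, m1, error_rate)
            m2 = dna.mutate(rng, m2, error_rate)
        if homopolymer_error_rate:
            m1 = _perturb_homopolymers(rng, m1, homopolymer_error_rate)
            m2 = _perturb_homopolymers(rng, m2, homopolymer_error_rate)
        pairs.append(ReadPair(f"{id_prefix}{i}", m1, m2, true_insert=ins))
    return pairs


def _perturb_homopolymers(rng, seq: str, rate: float) -> str:
    out = []
    last = 0
    for s, e, base in dna.homopolymer_runs(seq, min_len=3):
        out.append(seq[last:s])
        run = e - s
        if rng.random() < rate:
            run += 1 if rng.random() < 0.5 else -1
        out.append(base * run)
        last = e
    out.append(seq[last:])
    return "".join(out)


def community_pairs(truth: GroundTruth, insert_model: InsertModel, depth_per_strain: float,
                    read_len: int, seed: int, error_rate: float = 0.0) -> list[ReadPair]:
    """Pairs from both strains at equal abundance."""
    p1 = simulate_pairs(truth.strain1_genome, insert_model, depth_per_strain,
                        read_len, seed, error_rate, id_prefix="s1_")
    p2 = simulate_pairs(truth.strain2_genome, insert_model, depth_per_strain,
                        read_len, seed + 1, error_rate, id_prefix="s2_")
    return p1 + p2


def write_fastq(pairs, path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.mate1_seq}\n+\n{'I' * len(p.mate1_seq)}\n")
            f2.write(f"@{p.id}/2\n{p.mate2_seq}\n+\n{'I' * len(p.mate2_seq)}\n")


def write_fixture(fixture: Fixture, outdir) -> None:
    """Write the fixture in the formats the pipeline reads, plus the truth."""
    import os

    from .model import write_depths, write_fasta, write_scaffolds

    os.makedirs(outdir, exist_ok=True)
    write_fasta([(c.id, c.seq) for c in fixture.contig_set],
                os.path.join(outdir, "contigs.fasta"))
    write_depths(fixture.contig_set, os.path.join(outdir, "depths.tsv"))
    write_scaffolds(fixture.scaffolds, fixture.contig_set,
                    os.path.join(outdir, "scaffolds.agp"))
    write_fasta([("strain1", fixture.truth.strain1_genome),
                 ("strain2", fixture.truth.strain2_genome)],
                os.path.join(outdir, "strain_genomes.fasta"))
    t = fixture.truth
    payload = {
        "gaps": [{k: v for k, v in asdict(g).items()} for g in t.gaps],
        "contig_region": t.contig_region,
        "contig_true_depth": t.contig_true_depth,
        "tandem_element_id": t.tandem_element_id,
        "alt_scaffold_id": t.alt_scaffold_id,
        "alt_scaffold_pairs": [list(p) for p in t.alt_scaffold_pairs],
    }
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Scaffold-ordering fixture: one circular genome cut into scaffolds
# ---------------------------------------------------------------------------

def make_ordering_fixture(seed: int = 0, n_scaffolds: int = 3,
                          contigs_per_scaffold: int = 2,
                          contig_len: int = 6000, overlap: int = 150):
    """A circular genome cut into consecutive overlapping contigs grouped
    into scaffolds; the correct order is the circle."""
    rng = np.random.default_rng(seed)
    n = n_scaffolds * contigs_per_scaffold
    g_len = n * contig_len
    genome = dna.random_dna(rng, g_len)
    ext = genome + genome[:overlap]
    contigs = []
    for i in range(n):
        seq = ext[i * contig_len:(i + 1) * contig_len + overlap]
        contigs.append(Contig(f"oc{i:02d}", seq, 70.0))
    cs = ContigSet(contigs)
    scaffolds = []
    for s in range(n_scaffolds):
        pls = [ContigPlacement(f"oc{s * contigs_per_scaffold + j:02d}", FORWARD, j)
               for j in range(contigs_per_scaffold)]
        scaffolds.append(ScaffoldLayout(
            f"oscaf{s}", pls, [MIN_GAP_ESTIMATE] * (contigs_per_scaffold - 1)))
    return cs, scaffolds, genome
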