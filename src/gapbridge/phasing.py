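"""Separate two strain genomes from a chimeric assembly.

The gap solutions of a two-strain assembly yield a *chimeric* reference: a
shared backbone with, at every polymorphic gap, a set of alternative
sequences (one per strain).  Read pairs from a community containing exactly
one of the strains are mapped against the realized reference; regions of
poor pair-validated coverage mark sites where the wrong alternative was
chosen, and those sites are switched until the mapping is clean.  The other
strain then takes the complementary option at every two-option site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .mapping import (InsertModel, MapParams, low_coverage_regions, map_pairs)
from .solver import GROUP_C, GROUP_D, UNRESOLVED

log = logging.getLogger("gapbridge")


@dataclass
class AlternativeSite:
    """A region of the chimeric reference with per-strain alternatives.

    ``options`` are the alternative sequences including a short shared
    anchor on each side; for insertion/deletion sites the deletion option is
    simply the shorter sequence (the anchors keep it non-empty).
    """

    site_id: str
    gap_name: str
    options: list[str]
    kind: str                      # "substitution_block" | "insertion_deletion"
    current_choice: int = 0

    def __post_init__(self):
        if len(self.options) < 2:
            raise ValueError("an alternative site needs at least two options")
        if len(set(self.options)) != len(self.options):
            raise ValueError("alternative options must be distinct")


@dataclass
class PhasedAssembly:
    """A chimeric reference: backbone parts interleaved with sites."""

    parts: list  # ("seq", str) or ("site", index into sites)
    sites: list[AlternativeSite]

    def realize(self, choices: dict[str, int] | None = None) -> str:
        return self.realize_with_spans(choices)[0]

    def realize_with_spans(self, choices=None):
        """Realized sequence plus each site's (start, end) span in it."""
        out = []
        pos = 0
        spans: dict[str, tuple[int, int]] = {}
        for kind, val in self.parts:
            if kind == "seq":
                out.append(val)
                pos += len(val)
            else:
                site = self.sites[val]
                choice = site.current_choice if choices is None \
                    else choices.get(site.site_id, site.current_choice)
                seq = site.options[choice]
                spans[site.site_id] = (pos, pos + len(seq))
                out.append(seq)
                pos += len(seq)
        return "".join(out), spans

    @property
    def choices(self) -> dict[str, int]:
        return {s.site_id: s.current_choice for s in self.sites}


def build_chimeric_reference(solutions, scaffolds, contig_db,
                             skip_scaffolds=(), anchor: int = 160) -> PhasedAssembly:
    """Splice gap solutions into their scaffolds.

    Single-solution gaps (Groups A and B) are spliced in directly; gaps with
    alternatives (C and D) become :class:`AlternativeSite` records whose
    first option follows the solver's path order — for insertion/deletion
    gaps that is the insertion (insertion-first rule).  Unresolved gaps are
    left as N-runs of the estimated length.
    """
    by_gap = {s.gap.name: s for s in solutions}
    parts: list = []
    sites: list[AlternativeSite] = []
    for sc in scaffolds:
        if sc.id in set(skip_scaffolds):
            continue
        if not sc.placements:
            continue
        pend = contig_db.lookup(sc.placements[0].contig_id).oriented(
            sc.placements[0].orientation)
        consumed = 0  # leading flank bases living inside the previous site
        from .model import enumerate_gaps

        for gap in enumerate_gaps([sc]):
            sol = by_gap.get(gap.name)
            right = contig_db.lookup(gap.right_contig_id).oriented(
                gap.right_orientation)
            if sol is None or sol.group == UNRESOLVED or not sol.paths:
                est = gap.estimated_length or 100
                pend = pend + "N" * est + right
                consumed = 0
                continue
            left_len = contig_db.lookup(gap.left_contig_id).length
            right_len = contig_db.lookup(gap.right_contig_id).length
            if sol.group in (GROUP_C, GROUP_D) and len(sol.paths) >= 2:
                options = []
                for p in sol.paths:
                    mid = p.consensus[left_len - anchor:len(p.consensus) - right_len + anchor]
                    if mid not in options:
                        options.append(mid)
                if len(options) >= 2:
                    site = AlternativeSite(
                        site_id=f"site{len(sites):03d}", gap_name=gap.name,
                        options=options,
                        kind="insertion_deletion" if sol.group == GROUP_D
                        else "substitution_block")
                    if site.kind == "insertion_deletion":
                        # insertion-first: start from the longest option
                        site.current_choice = max(
                            range(len(options)), key=lambda i: len(options[i]))
                    parts.append(("seq", pend[:len(pend) - anchor]))
                    sites.append(site)
                    parts.append(("site", len(sites) - 1))
                    pend = right[anchor:]
                    consumed = anchor
                    continue
            # unique solution: splice the best path's consensus
            cons = sol.paths[0].consensus
            pend = pend[:len(pend) - (left_len - consumed)] + cons[consumed:]
            consumed = 0
        parts.append(("seq", pend))
    return PhasedAssembly(parts, sites)


@dataclass
class SeparationResult:
    genome: str
    choices: dict[str, int]
    rounds: int
    switches: int
    converged: bool
    unresolved_sites: list[str]
    low_coverage: list


def progressive_separation(phased: PhasedAssembly, pairs, insert_model: InsertModel,
                           map_params: MapParams = None, max_rounds: int = 20,
                           min_depth: int = 5, edge_margin: int | None = None,
                           site_pad: int = 20) -> SeparationResult:
    """Iteratively switch alternative choices until single-strain read pairs
    cover every site.

    All sites intersecting a low-coverage interval are switched together
    each round; a visited-configuration memo stops oscillation, in which
    case the configuration with the smallest total low-coverage footprint
    wins.  Intervals within ``edge_margin`` of the reference ends are
    ignored (coverage necessarily ramps down there).
    """
    map_params = map_params or MapParams()
    if edge_margin is None:
        edge_margin = int(insert_model.mean + map_params.sd_mult * insert_model.sd)
    tried: dict[str, set[int]] = {s.site_id: {s.current_choice} for s in phased.sites}
    seen_configs = set()
    best_config = None
    best_footprint = None
    total_switches = 0
    rounds = 0
    converged = False
    lows_last = []
    for rounds in range(1, max_rounds + 1):
        realized, spans = phased.realize_with_spans()
        config = tuple(s.current_choice for s in phased.sites)
        res = map_pairs(pairs, realized, insert_model, map_params)
        # repeat-shadowed regions (covered only by multi-mapped pairs) are
        # not evidence of a wrong choice: count ambiguous coverage here
        lows = low_coverage_regions(res.profile, min_depth, count_ambiguous=True)
        lows = [iv for iv in lows
                if iv.end > edge_margin and iv.start < len(realized) - edge_margin]
        lows_last = lows
        footprint = sum(iv.end - iv.start for iv in lows)
        if best_footprint is None or footprint < best_footprint:
            best_footprint = footprint
            best_config = config
        hit_sites = []
        for site in phased.sites:
            s, e = spans[site.site_id]
            if any(iv.end > s - site_pad and iv.start < e + site_pad for iv in lows):
                hit_sites.append(site)
        if not hit_sites:
            converged = True
            break
        if config in seen_configs:
            log.warning("separation revisited a configuration; keeping the "
                        "one with the smallest low-coverage footprint")
            break
        seen_configs.add(config)
        switched = False
        for site in hit_sites:
            untried = [i for i in range(len(site.options))
                       if i not in tried[site.site_id]]
            if untried:
                site.current_choice = untried[0]
                tried[site.site_id].add(untried[0])
                total_switches += 1
                switched = True
        if not switched:
            break
    if not converged and best_config is not None:
        for site, choice in zip(phased.sites, best_config):
            site.current_choice = choice
    realized, spans = phased.realize_with_spans()
    unresolved = []
    if not converged:
        for site in phased.sites:
            s, e = spans[site.site_id]
            if any(iv.end > s - site_pad and iv.start < e + site_pad
                   for iv in lows_last):
                unresolved.append(site.site_id)
    return SeparationResult(realized, phased.choices, rounds, total_switches,
                            converged, unresolved, lows_last)


def assign_second_strain(phased: PhasedAssembly, strain1_choices: dict[str, int]):
    """The complementary choices: at every two-option site the second strain
    takes the other option; sites with more than two options are flagged for
    user input rather than guessed."""
    choices = {}
    flagged = []
    for site in phased.sites:
        c1 = strain1_choices[site.site_id]
        if len(site.options) == 2:
            choices[site.site_id] = 1 - c1
        else:
            flagged.append(site.site_id)
            choices[site.site_id] = c1
    genome = phased.realize(choices)
    return genome, choices, flagged
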