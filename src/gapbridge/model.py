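"""Core domain types and readers/writers for the assembly formats.

The pipeline consumes three kinds of input produced by an upstream
assembler/scaffolder:

* contigs as FASTA, with per-contig average read depth in a TSV sidecar;
* scaffold layouts as AGP v2.0 (components ``W``, gaps ``N``/``U``);
* paired reads as FASTQ (handled in :mod:`gapbridge.mapping`).

Internal coordinates are 0-based half-open on the forward strand; AGP I/O
converts at the boundary.  Sequences are uppercased on load and characters
outside {A,C,G,T,N} are rejected.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import dna

log = logging.getLogger("gapbridge")

FORWARD = "forward"
REVERSE = "reverse"

#: Scaffolders in this pipeline's input never emit a gap estimate below this.
MIN_GAP_ESTIMATE = 20


class InputError(ValueError):
    """Raised for malformed or inconsistent pipeline input."""


@dataclass
class Contig:
    """A contiguous assembled sequence with optional mean read depth."""

    id: str
    seq: str
    depth: float | None = None

    def __post_init__(self):
        if len(self.seq) == 0:
            raise InputError(f"contig {self.id!r} has empty sequence")
        if self.depth is not None and self.depth < 0:
            raise InputError(f"contig {self.id!r} has negative depth")

    @property
    def length(self) -> int:
        return len(self.seq)

    def oriented(self, orientation: str) -> str:
        return self.seq if orientation == FORWARD else dna.revcomp(self.seq)


class ContigSet:
    """A contig database with a lazily built k-mer index over forward strands.

    The index maps each 2-bit packed k-mer to the (contig index, offset)
    pairs where it occurs; reverse-strand matches are found by searching the
    reverse complement of the query.  K-mers containing N are skipped.
    """

    def __init__(self, contigs=(), k: int = 11):
        self.k = k
        self._ids: list[str] = []
        self._by_id: dict[str, Contig] = {}
        self._index: dict[int, list[tuple[int, int]]] | None = None
        self._encoded: dict[str, np.ndarray] = {}
        for c in contigs:
            self.add(c)

    def add(self, contig: Contig) -> None:
        if contig.id in self._by_id:
            raise InputError(f"duplicate contig id {contig.id!r}")
        self._by_id[contig.id] = contig
        self._ids.append(contig.id)
        self._index = None

    def __len__(self):
        return len(self._ids)

    def __contains__(self, cid):
        return cid in self._by_id

    def __iter__(self):
        return (self._by_id[i] for i in self._ids)

    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    def lookup(self, cid: str) -> Contig:
        try:
            return self._by_id[cid]
        except KeyError:
            raise KeyError(f"unknown contig id {cid!r}") from None

    def encoded(self, cid: str) -> np.ndarray:
        arr = self._encoded.get(cid)
        if arr is None:
            arr = dna.encode(self._by_id[cid].seq)
            self._encoded[cid] = arr
        return arr

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self)

    def kmer_index(self) -> dict[int, list[tuple[int, int]]]:
        if self._index is None:
            idx: dict[int, list[tuple[int, int]]] = {}
            k = self.k
            for ci, cid in enumerate(self._ids):
                codes = self.encoded(cid)
                for key, pos in _iter_kmers(codes, k):
                    idx.setdefault(key, []).append((ci, pos))
            self._index = idx
        return self._index

    def contig_id_at(self, index: int) -> str:
        return self._ids[index]


def _iter_kmers(codes: np.ndarray, k: int):
    """Yield (packed kmer, position); skips windows containing N."""
    n = len(codes)
    if n < k:
        return
    mask = (1 << (2 * k)) - 1
    key = 0
    valid = 0  # number of consecutive non-N bases ending here
    for i in range(n):
        c = codes[i]
        if c >= 4:
            valid = 0
            key = 0
            continue
        key = ((key << 2) | int(c)) & mask
        valid += 1
        if valid >= k:
            yield key, i - k + 1


@dataclass
class ContigPlacement:
    """An oriented contig at a position of a scaffold layout."""

    contig_id: str
    orientation: str
    order_index: int


@dataclass
class ScaffoldLayout:
    """Ordered oriented contigs separated by gaps of estimated length."""

    id: str
    placements: list[ContigPlacement]
    gap_estimates: list[int]

    def __post_init__(self):
        if len(self.gap_estimates) != max(len(self.placements) - 1, 0):
            raise InputError(
                f"scaffold {self.id!r}: expected {len(self.placements) - 1} "
                f"gap estimates, got {len(self.gap_estimates)}"
            )


@dataclass
class GapRecord:
    """A gap between two adjacent oriented contigs, named '<left>-G-<right>'.

    ``left_side``/``right_side`` give the contig edge (on the forward strand
    of the contig itself) that faces the gap: the 3' edge of the left flank
    faces the 5' edge of the right flank in scaffold coordinates.
    """

    name: str
    left_contig_id: str
    left_orientation: str
    right_contig_id: str
    right_orientation: str
    estimated_length: int | None = None
    scaffold_id: str | None = None

    def __post_init__(self):
        expect = f"{self.left_contig_id}-G-{self.right_contig_id}"
        if self.name != expect:
            raise InputError(f"gap name {self.name!r} does not match flanks {expect!r}")

    @property
    def left_side(self) -> str:
        # forward left flank: the gap faces its 3' end
        return "3p" if self.left_orientation == FORWARD else "5p"

    @property
    def right_side(self) -> str:
        return "5p" if self.right_orientation == FORWARD else "3p"


def make_gap(left_id, right_id, left_orientation=FORWARD, right_orientation=FORWARD,
             estimated_length=None, scaffold_id=None) -> GapRecord:
    return GapRecord(
        name=f"{left_id}-G-{right_id}",
        left_contig_id=left_id,
        left_orientation=left_orientation,
        right_contig_id=right_id,
        right_orientation=right_orientation,
        estimated_length=estimated_length,
        scaffold_id=scaffold_id,
    )


@dataclass
class DepthBands:
    """Read-depth region boundaries, expressed as ratios of the modal depth
    of contigs shared by the two strains.

    With a shared depth near 70x the defaults reproduce absolute cutoffs of
    >91x for multi-copy contigs, ~24.5-52.5x for strain-specific contigs and
    <20x for background organisms.
    """

    shared_depth: float
    multi_copy_min: float = 1.3
    strain_lo: float = 0.35
    strain_hi: float = 0.75
    background_max: float = 0.29

    def __post_init__(self):
        if not (self.background_max < self.strain_lo < self.strain_hi < 1 < self.multi_copy_min):
            raise InputError("depth band ratios must satisfy "
                             "background_max < strain_lo < strain_hi < 1 < multi_copy_min")
        if self.shared_depth <= 0:
            raise InputError("shared_depth must be positive")


# ---------------------------------------------------------------------------
# FASTA / TSV / AGP I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, str(rec.seq)))
    return out


def write_fasta(records, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_contigs(fasta_path, depth_tsv_path=None, k: int = 11) -> ContigSet:
    """Load contigs, uppercasing sequences and joining depths by contig id.

    Depth rows for unknown ids are ignored with a warning; contigs without a
    depth row get ``depth=None`` with a warning.
    """
    cs = ContigSet(k=k)
    for name, seq in read_fasta(fasta_path):
        cs.add(Contig(id=name, seq=dna.clean(seq)))
    if len(cs) == 0:
        raise InputError(f"no contigs in {fasta_path}")
    if depth_tsv_path is not None:
        import pandas as pd

        df = pd.read_csv(depth_tsv_path, sep="\t")
        if not {"contig_id", "depth"} <= set(df.columns):
            raise InputError("depth TSV must have columns 'contig_id' and 'depth'")
        seen = set()
        for row in df.itertuples(index=False):
            cid = str(row.contig_id)
            if cid not in cs:
                log.warning("depth row for unknown contig %r ignored", cid)
                continue
            cs.lookup(cid).depth = float(row.depth)
            seen.add(cid)
        for cid in cs.ids:
            if cid not in seen:
                log.warning("contig %r has no depth entry", cid)
    return cs


def write_depths(contig_set: ContigSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tdepth\n")
        for c in contig_set:
            if c.depth is not None:
                fh.write(f"{c.id}\t{c.depth:.2f}\n")


def read_scaffolds(agp_path, contig_set: ContigSet) -> list[ScaffoldLayout]:
    """Parse an AGP v2.0 file into scaffold layouts.

    W lines become placements (AGP 1-based inclusive coordinates are
    converted internally); N/U lines become gap-length estimates.  Estimates
    below 20 are clamped to 20 with a warning.
    """
    scaffolds: dict[str, dict] = {}
    order: list[str] = []
    with open(agp_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise InputError(f"{agp_path}:{lineno}: short AGP line")
            obj, beg, end, _part, ctype = f[0], int(f[1]), int(f[2]), f[3], f[4]
            if obj not in scaffolds:
                scaffolds[obj] = {"placements": [], "gaps": [], "cursor": 0, "last": "gap"}
                order.append(obj)
            st = scaffolds[obj]
            if beg != st["cursor"] + 1 or end < beg:
                raise InputError(
                    f"{agp_path}:{lineno}: non-monotone object coordinates in {obj!r}")
            st["cursor"] = end
            if ctype == "W":
                cid = f[5]
                if cid not in contig_set:
                    raise InputError(f"{agp_path}:{lineno}: unknown component id {cid!r}")
                orient = REVERSE if f[8].strip() in ("-", "minus") else FORWARD
                st["placements"].append(
                    ContigPlacement(cid, orient, len(st["placements"])))
                st["last"] = "W"
            elif ctype in ("N", "U"):
                gap_len = int(f[5])
                if gap_len < MIN_GAP_ESTIMATE:
                    log.warning("%s:%d: gap estimate %d clamped to %d",
                                agp_path, lineno, gap_len, MIN_GAP_ESTIMATE)
                    gap_len = MIN_GAP_ESTIMATE
                st["gaps"].append(gap_len)
                st["last"] = "gap"
            else:
                raise InputError(f"{agp_path}:{lineno}: unsupported component type {ctype!r}")
    out = []
    for obj in order:
        st = scaffolds[obj]
        out.append(ScaffoldLayout(obj, st["placements"], st["gaps"]))
    return out


def write_scaffolds(scaffolds, contig_set: ContigSet, path) -> None:
    """Write layouts as AGP v2.0 (inverse of :func:`read_scaffolds`)."""
    with open(path, "w") as fh:
        fh.write("##agp-version 2.0\n")
        for sc in scaffolds:
            cursor = 0
            part = 0
            for i, pl in enumerate(sc.placements):
                if i > 0:
                    gap = sc.gap_estimates[i - 1]
                    part += 1
                    fh.write(f"{sc.id}\t{cursor + 1}\t{cursor + gap}\t{part}\tN\t"
                             f"{gap}\tscaffold\tyes\tpaired-ends\n")
                    cursor += gap
                length = contig_set.lookup(pl.contig_id).length
                part += 1
                o = "+" if pl.orientation == FORWARD else "-"
                fh.write(f"{sc.id}\t{cursor + 1}\t{cursor + length}\t{part}\tW\t"
                         f"{pl.contig_id}\t1\t{length}\t{o}\n")
                cursor += length


def enumerate_gaps(scaffolds) -> list[GapRecord]:
    """One GapRecord per adjacent placement pair, in scaffold order."""
    gaps = []
    for sc in scaffolds:
        for i in range(len(sc.placements) - 1):
            a, b = sc.placements[i], sc.placements[i + 1]
            gaps.append(make_gap(
                a.contig_id, b.contig_id, a.orientation, b.orientation,
                estimated_length=sc.gap_estimates[i], scaffold_id=sc.id))
    return gaps


# ---------------------------------------------------------------------------
# Gap report
# ---------------------------------------------------------------------------

def write_report(gap_solutions, path) -> None:
    """Write the structured JSON gap report plus consensus and alignment FASTA.

    ``path`` is the JSON file; a multi-FASTA of best-path consensus sequences
    is written next to it with suffix ``.consensus.fasta`` and per-gap
    alignment FASTA files under ``<path>.alignments/``.
    """
    records = []
    consensus_records = []
    aln_dir = str(path) + ".alignments"
    os.makedirs(aln_dir, exist_ok=True)
    for sol in gap_solutions:
        rec = sol.to_record() if hasattr(sol, "to_record") else dict(sol)
        records.append(rec)
        name = rec["gap"]["name"]
        cons = rec.get("consensus_per_path") or []
        if cons:
            consensus_records.append((name, cons[0]))
        if len(cons) >= 1:
            _write_gap_alignment(name, cons, os.path.join(aln_dir, f"{name}.fasta"))
    payload = {"n_gaps": len(records), "gaps": records}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    write_fasta(consensus_records, str(path) + ".consensus.fasta")


def _write_gap_alignment(name, seqs, path) -> None:
    """Aligned multi-FASTA of the alternative consensus sequences of a gap.

    Sequences are padded against the first consensus using an edit-distance
    alignment; this is an inspection aid, not a polished MSA.
    """
    import edlib

    if len(seqs) == 1:
        write_fasta([(f"{name}.path0", seqs[0])], path)
        return
    ref = seqs[0]
    rows = [list(ref)]
    names = [f"{name}.path0"]
    for i, s in enumerate(seqs[1:], 1):
        res = edlib.align(s, ref, task="path", mode="NW")
        q, t = _expand_cigar(s, ref, res["cigar"])
        # merge target gaps into every existing row
        merged_rows = []
        ti = 0
        ins_at: dict[int, int] = {}
        for ch in t:
            if ch == "-":
                ins_at[ti] = ins_at.get(ti, 0) + 1
            else:
                ti += 1
        for row in rows:
            out = []
            for j, ch in enumerate(row):
                out.extend("-" * ins_at.get(j, 0))
                out.append(ch)
            out.extend("-" * ins_at.get(len(row), 0))
            merged_rows.append(out)
        rows = merged_rows
        rows.append(list(q))
        names.append(f"{name}.path{i}")
        ref = "".join(c for c in rows[0])
    width = max(len(r) for r in rows)
    rows = [r + ["-"] * (width - len(r)) for r in rows]
    write_fasta([(n, "".join(r)) for n, r in zip(names, rows)], path)


def _expand_cigar(query, target, cigar):
    q, t = [], []
    qi = ti = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in ("=", "X", "M"):
            q.append(query[qi:qi + n]); t.append(target[ti:ti + n])
            qi += n; ti += n
        elif ch == "I":
            q.append(query[qi:qi + n]); t.append("-" * n)
            qi += n
        elif ch == "D":
            q.append("-" * n); t.append(target[ti:ti + n])
            ti += n
    return "".join(q), "".join(t)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
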