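"""Local alignment: scoring scheme, Karlin-Altschul statistics, and a
Smith-Waterman kernel used both in full (all diagonals) and banded form.

The default scheme (match +1, mismatch -2, gap open -2, gap extend -1) is the
conventional choice for nucleotide overlaps expected to be ~95% identical.
E-values use ungapped Karlin-Altschul parameters applied to the gapped score,
which is adequate for threshold gating at e <= 1e-10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import dna

NEG = -(10 ** 9)


def _ka_lambda(match: int, mismatch: int, tol: float = 1e-12) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for uniform base composition.

    With p_i = 1/4 the match probability is 1/4 and mismatch 3/4.  Bisection;
    requires a negative expected score and a positive match score.
    """
    if match <= 0:
        raise ValueError("match score must be positive")
    expected = 0.25 * match + 0.75 * mismatch
    if expected >= 0:
        raise ValueError("expected score per pair must be negative")

    def f(lam):
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    lo, hi = 1e-9, 1.0
    while f(hi) < 0:
        hi *= 2
        if hi > 1e4:
            raise ValueError("failed to bracket lambda")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _ka_k(match: int, mismatch: int, lam: float) -> float:
    """Coarse ungapped approximation of the Karlin-Altschul K parameter.

    Uses K ~ (1 - exp(-lambda))^2 / H with H the relative entropy of the
    aligned-pair distribution.  Accurate to within a small factor, which is
    sufficient for e-value threshold gating.
    """
    h = lam * (0.25 * match * math.exp(lam * match)
               + 0.75 * mismatch * math.exp(lam * mismatch))
    return (1.0 - math.exp(-lam)) ** 2 / h


@dataclass(frozen=True)
class ScoreScheme:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -2
    gap_extend: int = -1
    lambda_ka: float = field(default=None)
    k_ka: float = field(default=None)

    def __post_init__(self):
        if self.lambda_ka is None:
            lam, k = karlin_altschul_params(self)
            object.__setattr__(self, "lambda_ka", lam)
            object.__setattr__(self, "k_ka", k)

    def evalue(self, score: int, m: int, n: int) -> float:
        return self.k_ka * m * n * math.exp(-self.lambda_ka * score)


def karlin_altschul_params(scheme) -> tuple[float, float]:
    """(lambda, K) for the scheme's match/mismatch scores under p_i = 1/4."""
    lam = _ka_lambda(scheme.match, scheme.mismatch)
    return lam, _ka_k(scheme.match, scheme.mismatch, lam)


@dataclass
class LocalAlignment:
    """A local alignment of query against subject, 0-based half-open."""

    score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def s_span(self) -> int:
        return self.s_end - self.s_start


@njit(cache=True)
def _sw_kernel(q, s, dmin, dmax, match, mismatch, gopen, gext):  # pragma: no cover
    """Affine-gap Smith-Waterman restricted to diagonals d = j - i in
    [dmin, dmax] (1-based matrix convention internally).

    Gap of length g costs -(gopen + g*gext).  Returns
    (score, q_start, q_end, s_start, s_end, matches, columns).
    """
    n = len(q)
    m = len(s)
    open_cost = -(gopen + gext)
    ext_cost = -gext
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    hprev = np.full(m + 1, NEG, dtype=np.int64)
    hcur = np.full(m + 1, NEG, dtype=np.int64)
    fprev = np.full(m + 1, NEG, dtype=np.int64)
    fcur = np.full(m + 1, NEG, dtype=np.int64)
    for j in range(m + 1):
        hprev[j] = 0
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        lo = i + dmin
        hi = i + dmax
        if lo < 1:
            lo = 1
        if hi > m:
            hi = m
        for j in range(m + 1):
            hcur[j] = NEG
            fcur[j] = NEG
        if lo <= 1:
            hcur[0] = 0
        e = NEG
        qc = q[i - 1]
        for j in range(lo, hi + 1):
            # E: gap consuming subject chars (moves j)
            e_open = hcur[j - 1] - open_cost
            e_ext = e - ext_cost
            eext = 0
            if e_ext > e_open:
                e = e_ext
                eext = 1
            else:
                e = e_open
            # F: gap consuming query chars (moves i)
            f_open = hprev[j] - open_cost
            f_ext = fprev[j] - ext_cost
            fext = 0
            if f_ext > f_open:
                fcur[j] = f_ext
                fext = 1
            else:
                fcur[j] = f_open
            sc = s[j - 1]
            sub = match if (qc == sc and qc < 4) else mismatch
            diag = hprev[j - 1] + sub
            h = 0
            hp = 0
            if diag > h:
                h = diag
                hp = 1
            if e > h:
                h = e
                hp = 2
            if fcur[j] > h:
                h = fcur[j]
                hp = 3
            hcur[j] = h
            ptr[i, j] = hp | (eext << 2) | (fext << 3)
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = hprev
        hprev = hcur
        hcur = tmp
        tmp = fprev
        fprev = fcur
        fcur = tmp
    # traceback
    i = bi
    j = bj
    matches = 0
    columns = 0
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 and j > 0:
        p = ptr[i, j]
        if state == 0:
            hp = p & 3
            if hp == 0:
                break
            if hp == 1:
                columns += 1
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif hp == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            ext = (p >> 2) & 1
            j -= 1
            if ext == 0:
                state = 0
        else:
            columns += 1
            ext = (p >> 3) & 1
            i -= 1
            if ext == 0:
                state = 0
    return best, i, bi, j, bj, matches, columns


def smith_waterman(query: str, subject: str, scheme: ScoreScheme = None) -> LocalAlignment:
    """Full Smith-Waterman over all diagonals (the exhaustive route)."""
    scheme = scheme or ScoreScheme()
    q = dna.encode(query)
    s = dna.encode(subject)
    res = _sw_kernel(q, s, -len(q), len(s), scheme.match, scheme.mismatch,
                     scheme.gap_open, scheme.gap_extend)
    return LocalAlignment(int(res[0]), int(res[1]), int(res[2]),
                          int(res[3]), int(res[4]), int(res[5]), int(res[6]))


def banded_align(q_codes: np.ndarray, s_codes: np.ndarray, dmin: int, dmax: int,
                 scheme: ScoreScheme, band: int = 16) -> LocalAlignment:
    """Smith-Waterman restricted to diagonals [dmin - band, dmax + band]."""
    res = _sw_kernel(q_codes, s_codes, dmin - band, dmax + band,
                     scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend)
    return LocalAlignment(int(res[0]), int(res[1]), int(res[2]),
                          int(res[3]), int(res[4]), int(res[5]), int(res[6]))


def _seed_diagonals(q_codes: np.ndarray, s_codes: np.ndarray, k: int = 11):
    """Diagonal clusters (dmin, dmax) of exact k-mer matches between q and s."""
    index: dict[int, list[int]] = {}
    from .model import _iter_kmers

    for key, pos in _iter_kmers(s_codes, k):
        index.setdefault(key, []).append(pos)
    diags = []
    for key, qpos in _iter_kmers(q_codes, k):
        for spos in index.get(key, ()):
            diags.append(spos - qpos)
    if not diags:
        return []
    diags.sort()
    clusters = []
    start = prev = diags[0]
    for d in diags[1:]:
        if d - prev > 32:
            clusters.append((start, prev))
            start = d
        prev = d
    clusters.append((start, prev))
    return clusters


def seed_extend_best(query: str, subject: str, scheme: ScoreScheme = None,
                     k: int = 11, band: int = 16) -> LocalAlignment | None:
    """Best local alignment found by exact k-mer seeding plus banded extension.

    Returns None when no seed exists (no exact k-mer is shared).
    """
    scheme = scheme or ScoreScheme()
    q = dna.encode(query)
    s = dna.encode(subject)
    best = None
    for dmin, dmax in _seed_diagonals(q, s, k):
        aln = banded_align(q, s, dmin, dmax, scheme, band)
        if best is None or aln.score > best.score:
            best = aln
    return best
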