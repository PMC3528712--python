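"""Low-level DNA sequence helpers.

Sequences are plain Python strings over the alphabet {A, C, G, T, N},
uppercase.  For alignment kernels they are encoded as ``uint8`` arrays with
A=0, C=1, G=2, T=3, N=4; N never matches anything, including another N.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGTN"

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i

_COMP = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for malformed DNA input."""


def clean(seq: str) -> str:
    """Uppercase ``seq`` and reject characters outside A/C/G/T/N."""
    s = seq.upper()
    arr = np.frombuffer(s.encode("ascii", errors="replace"), dtype=np.uint8)
    if np.any(_CODE[arr] == 255):
        bad = sorted({chr(b) for b in arr[_CODE[arr] == 255]})
        raise SequenceError(f"sequence contains invalid characters: {bad}")
    return s


def encode(seq: str) -> np.ndarray:
    """Encode a clean sequence as uint8 codes."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random sequence over A/C/G/T."""
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply substitutions at the given per-base rate (never to the same base)."""
    if rate <= 0:
        return seq
    arr = encode(seq)
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        if arr[i] < 4:
            arr[i] = (arr[i] + rng.integers(1, 4)) % 4
    return decode(arr)


def homopolymer_runs(seq: str, min_len: int = 3):
    """Yield (start, end, base) for maximal homopolymer runs of length >= min_len."""
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len and seq[i] != "N":
            yield i, j, seq[i]
        i = j
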