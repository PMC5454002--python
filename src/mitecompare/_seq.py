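"""Low-level sequence utilities: numeric encoding, k-mer codes, identity.

Encoding: A=0, C=1, G=2, T=3, N=4.  The complement of code b (b<4) is 3-b,
so a base pair (x, y) is Watson-Crick complementary iff x + y == 3.
"""

from __future__ import annotations

import numpy as np

_ENC = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i
    _ENC[ord(b.lower())] = i

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Numeric encoding (int8): A,C,G,T -> 0..3, anything else -> 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-mer (length n-k+1); -1 where a window has an N."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64)
    c = codes.astype(np.int64)
    out = np.zeros(n - k + 1, dtype=np.int64)
    bad = np.zeros(n - k + 1, dtype=bool)
    for i in range(k):
        w = c[i : n - k + 1 + i]
        out = out * 4 + np.where(w == 4, 0, w)
        bad |= w == 4
    out[bad] = -1
    return out


def hamming_identity(a: str, b: str) -> float:
    """Fraction of matching positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming_identity requires equal lengths")
    if not a:
        return 0.0
    xa = encode(a)
    xb = encode(b)
    return float(np.mean((xa == xb) & (xa != 4)))


def best_diagonal_segment(
    match: np.ndarray, mismatch_penalty: float
) -> tuple[int, int, int] | None:
    """Best-scoring contiguous segment of a boolean match array.

    Scores +1 per match and -mismatch_penalty per mismatch (Kadane's
    algorithm), then trims flanking mismatches.  Returns (start, stop,
    n_matches) with stop exclusive, or None if all positions mismatch.
    """
    if len(match) == 0 or not match.any():
        return None
    score = np.where(match, 1.0, -mismatch_penalty)
    best = -np.inf
    best_range = (0, 0)
    cur = 0.0
    cur_start = 0
    for i, s in enumerate(score):
        if cur <= 0:
            cur = s
            cur_start = i
        else:
            cur += s
        if cur > best:
            best = cur
            best_range = (cur_start, i + 1)
    a, b = best_range
    while a < b and not match[a]:
        a += 1
    while b > a and not match[b - 1]:
        b -= 1
    if a >= b:
        return None
    return a, b, int(match[a:b].sum())
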