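"""Vectorised k-mer hashing shared by overlap detection, anchoring and
the unique-k-mer (effective genome size) computation.

Hashes are rolling polynomial hashes over odd 64-bit multipliers with
wrap-around arithmetic; two independent multipliers give an effectively
128-bit key, so collisions are negligible even genome-wide.  Positions
containing N are masked out.
"""
from __future__ import annotations

import numpy as np

_M1 = np.uint64(0x9E3779B97F4A7C15)
_M2 = np.uint64(0xC2B2AE3D27D4EB4F)

_ENC = np.full(256, 4, dtype=np.uint8)
for i, c in enumerate("ACGT"):
    _ENC[ord(c)] = i


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes A=0 C=1 G=2 T=3, N/other=4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def _pow_mod(base: np.uint64, exp: int) -> np.uint64:
    out = np.uint64(1)
    b = np.uint64(base)
    with np.errstate(over="ignore"):
        while exp:
            if exp & 1:
                out = out * b
            b = b * b
            exp >>= 1
    return out


def _inv_mod64(a: np.uint64) -> np.uint64:
    # Newton iteration for the inverse of an odd number mod 2^64.
    x = np.uint64(a)
    with np.errstate(over="ignore"):
        for _ in range(6):
            x = x * (np.uint64(2) - np.uint64(a) * x)
    return x


def _rolling(codes: np.ndarray, k: int, mult: np.uint64) -> np.ndarray:
    """Hash of every k-window: h(i) = sum_j codes[i+j]*mult^(k-1-j) mod 2^64."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    inv = _inv_mod64(mult)
    with np.errstate(over="ignore"):
        # inv^t for t = 0..n-1
        inv_pows = np.concatenate(
            [[np.uint64(1)], np.full(n - 1, inv, dtype=np.uint64)]).cumprod(dtype=np.uint64)
        terms = (codes.astype(np.uint64) + np.uint64(1)) * inv_pows
        prefix = np.concatenate([[np.uint64(0)], terms.cumsum(dtype=np.uint64)])
        diff = prefix[k:] - prefix[:-k]
        mult_pows = np.concatenate(
            [[_pow_mod(mult, k - 1)], np.full(n - k, mult, dtype=np.uint64)]
        ).cumprod(dtype=np.uint64)
        return diff * mult_pows


def window_has_n(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean per window: does the k-window contain an N?"""
    isn = (codes == 4).astype(np.int32)
    cs = np.concatenate([[0], isn.cumsum()])
    return (cs[k:] - cs[:-k]) > 0


def kmer_keys(seq: str, k: int, canonical: bool = False):
    """Per-position 128-bit k-mer keys as two uint64 arrays plus a validity mask.

    With ``canonical=True`` each k-mer is folded with its reverse complement
    (key = elementwise min of the two hash pairs), so strand is ignored.
    """
    codes = encode(seq)
    h1 = _rolling(codes, k, _M1)
    h2 = _rolling(codes, k, _M2)
    valid = ~window_has_n(codes, k)
    if canonical:
        rc = (np.uint8(3) - codes[::-1]) % np.uint8(7)  # 4 -> 4 stays N-ish
        rc[codes[::-1] == 4] = 4
        r1 = _rolling(rc, k, _M1)[::-1]
        r2 = _rolling(rc, k, _M2)[::-1]
        swap = (r1 < h1) | ((r1 == h1) & (r2 < h2))
        h1 = np.where(swap, r1, h1)
        h2 = np.where(swap, r2, h2)
    return h1, h2, valid


def unique_kmer_fraction(seqs: list[str], k: int) -> float:
    """Fraction of valid k-mer positions whose canonical k-mer occurs exactly
    once across all sequences."""
    parts1, parts2 = [], []
    for s in seqs:
        if len(s) < k:
            continue
        h1, h2, valid = kmer_keys(s, k, canonical=True)
        parts1.append(h1[valid])
        parts2.append(h2[valid])
    if not parts1:
        raise ValueError(f"no sequence of length >= k={k}")
    a = np.concatenate(parts1)
    b = np.concatenate(parts2)
    n = a.size
    if n == 0:
        raise ValueError("no valid (N-free) k-mers")
    order = np.lexsort((b, a))
    a, b = a[order], b[order]
    new = np.empty(n, dtype=bool)
    new[0] = True
    new[1:] = (a[1:] != a[:-1]) | (b[1:] != b[:-1])
    group_ids = np.cumsum(new) - 1
    counts = np.bincount(group_ids)
    singleton = counts[group_ids] == 1
    return float(singleton.sum()) / float(n)


def sampled_positions(length: int, k: int, window: int) -> np.ndarray:
    """Start positions sampled every ``window`` bp (always includes the last
    full window)."""
    last = length - k
    if last < 0:
        return np.empty(0, dtype=np.int64)
    pos = np.arange(0, last + 1, window, dtype=np.int64)
    if pos[-1] != last:
        pos = np.append(pos, last)
    return pos
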