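"""Vectorized k-mer machinery shared by the comparison and element-matching
stages.  Bases are encoded A,C,G,T -> 0..3; anything else (N) encodes to 255
and poisons every word that covers it."""

from __future__ import annotations

import numpy as np

__all__ = ["encode", "revcomp", "kmer_values", "unique_kmer_positions"]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i

_COMP = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (255 for N/invalid)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed k-mer integer values at every start position, plus a validity
    mask (False where the word covers an N).  Requires k <= 31."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    v = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        valid &= c != 255
        v = (v << np.uint64(2)) | (c.astype(np.uint64) & np.uint64(3))
    return v, valid


def unique_kmer_positions(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Values and start positions of the k-mers occurring exactly once.

    Words containing N are excluded.  Returned arrays are sorted by value.
    """
    v, valid = kmer_values(codes, k)
    pos = np.flatnonzero(valid)
    vv = v[pos]
    order = np.argsort(vv, kind="stable")
    sv = vv[order]
    spos = pos[order]
    if len(sv) == 0:
        return sv, spos
    # boundaries of equal-value groups
    new = np.empty(len(sv), dtype=bool)
    new[0] = True
    np.not_equal(sv[1:], sv[:-1], out=new[1:])
    starts = np.flatnonzero(new)
    counts = np.diff(np.append(starts, len(sv)))
    singles = starts[counts == 1]
    return sv[singles], spos[singles]
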