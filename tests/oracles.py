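"""Independent test oracles: a brute-force unit-cost Needleman-Wunsch
aligner with traceback (used to check connector coverage and difference
counts), and an exhaustive k-mer counter."""

from __future__ import annotations

import numpy as np


def nw_align(a: str, b: str) -> tuple[int, list[tuple]]:
    """Unit-cost optimal global alignment by full dynamic programming.

    Among all unit-cost-optimal alignments, one with the fewest gap
    openings is returned (lexicographic cost unit*K + openings with K
    larger than any possible opening count), so gaps come out contiguous
    instead of scattered over chance single-base matches.  Returns
    (distance, columns) where each column is (i, j, is_match) with i/j the
    0-based positions consumed in a/b (None for a gap).
    """
    n, m = len(a), len(b)
    K = n + m + 2  # scale separating the unit cost from the opening count
    INF = np.int32(2**30)
    ac = np.frombuffer(a.encode(), dtype=np.uint8)
    bc = np.frombuffer(b.encode(), dtype=np.uint8)
    js = np.arange(m + 1, dtype=np.int64)
    M = np.full((n + 1, m + 1), INF, dtype=np.int64)
    Ix = np.full((n + 1, m + 1), INF, dtype=np.int64)  # gap consuming a
    Iy = np.full((n + 1, m + 1), INF, dtype=np.int64)  # gap consuming b
    M[0, 0] = 0
    Iy[0, 1:] = K * js[1:] + 1
    for i in range(1, n + 1):
        sub = K * (ac[i - 1] != bc).astype(np.int64)
        prev = np.minimum(np.minimum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = prev[:-1] + sub
        Ix[i] = np.minimum(np.minimum(M[i - 1], Iy[i - 1]) + K + 1, Ix[i - 1] + K)
        base = np.minimum(M[i], Ix[i])
        t = np.minimum.accumulate(base - K * js)
        Iy[i, 1:] = t[:-1] + K * (js[1:] - 1) + K + 1
        Iy[i, 0] = INF
    finals = {"M": M[n, m], "Ix": Ix[n, m], "Iy": Iy[n, m]}
    state = min(finals, key=finals.get)
    total = int(finals[state])
    cols: list[tuple] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            cols.append((i - 1, j - 1, a[i - 1] == b[j - 1]))
            target = M[i, j] - K * (a[i - 1] != b[j - 1])
            i, j = i - 1, j - 1
            for s, mat in (("M", M), ("Ix", Ix), ("Iy", Iy)):
                if mat[i, j] == target:
                    state = s
                    break
        elif state == "Ix":
            cols.append((i - 1, None, False))
            if i >= 1 and Ix[i, j] == Ix[i - 1, j] + K:
                state = "Ix"
            elif M[i - 1, j] <= Iy[i - 1, j]:
                state = "M"
            else:
                state = "Iy"
            i -= 1
        else:  # Iy
            cols.append((None, j - 1, False))
            if j >= 1 and Iy[i, j] == Iy[i, j - 1] + K:
                state = "Iy"
            elif M[i, j - 1] <= Ix[i, j - 1]:
                state = "M"
            else:
                state = "Ix"
            j -= 1
    cols.reverse()
    return total // K, cols


def kmer_counts(seq: str, k: int) -> dict[str, list[int]]:
    """Exhaustive k-mer occurrence positions (words with N excluded)."""
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" not in w:
            out.setdefault(w, []).append(i)
    return out


def mutate_pair(rng: np.random.Generator, seq: str, sub_rate: float = 0.014,
                n_indels: int = 0, indel_max: int = 30) -> tuple[str, str]:
    """Derive two sequences from a common template by random substitutions
    (assigned to either side) and optional small indels; a minimal local
    generator for alignment-oracle tests."""
    a = list(seq)
    b = list(seq)
    bases = "ACGT"
    for i in range(len(seq)):
        if rng.random() < sub_rate:
            alt = bases[(bases.index(seq[i]) + 1 + int(rng.integers(0, 3))) % 4]
            if rng.random() < 0.5:
                a[i] = alt
            else:
                b[i] = alt
    sa, sb = "".join(a), "".join(b)
    for _ in range(n_indels):
        pos = int(rng.integers(10, max(11, len(sb) - 40)))
        ln = int(rng.integers(1, indel_max + 1))
        if rng.random() < 0.5:
            ins = "".join(bases[int(x)] for x in rng.integers(0, 4, size=ln))
            sb = sb[:pos] + ins + sb[pos:]
        else:
            sb = sb[:pos] + sb[pos + ln :]
    return sa, sb
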