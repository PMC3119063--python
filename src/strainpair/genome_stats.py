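"""Composition statistics of a replicon: windowed %G+C deviation,
cumulative base-skew series, tetranucleotide under-representation, and a
windowed tetramer-deviation profile (a foreign-DNA signal).

The tetramer expectation uses a maximal-order Markov model
(E(w1w2w3w4) = N(w1w2w3) * N(w2w3w4) / N(w2w3)), counted on both strands,
the standard construction for word-avoidance statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
import numpy as np
import pandas as pd

from . import _kmers
from .seq_io import Genome

__all__ = [
    "WindowStat",
    "SkewSeries",
    "gc_deviation_windows",
    "cumulative_skew",
    "tetramer_avoidance",
    "tetramer_deviation_profile",
]

_BASES = "ACGT"
_TETRAMERS = ["".join(p) for p in product(_BASES, repeat=4)]


@dataclass(frozen=True)
class WindowStat:
    start: int  # 0-based
    width: int
    gc: float
    z: float
    flagged: bool


@dataclass
class SkewSeries:
    base_pair: str  # e.g. "GC", "CT"
    window: int
    values: np.ndarray  # cumulative per-window (X - Y) / (X + Y)


def _counts_per_window(codes: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-window counts of each base code 0..3 and of non-N bases.

    Trailing bases that do not fill a window are dropped.
    """
    nwin = len(codes) // width
    trimmed = codes[: nwin * width].reshape(nwin, width)
    per_base = np.stack([(trimmed == b).sum(axis=1) for b in range(4)], axis=1)
    return per_base, per_base.sum(axis=1)


def gc_deviation_windows(
    genome: Genome, width: int = 1000, sd_cut: float = 2.5
) -> list[WindowStat]:
    """%G+C of non-overlapping windows, flagged when deviating more than
    ``sd_cut`` standard deviations from the replicon window mean.

    N bases are excluded from numerator and denominator; all-N windows are
    excluded from the statistics and never flagged.
    """
    if len(genome) < width:
        raise ValueError(f"genome shorter than one window ({len(genome)} < {width})")
    codes = _kmers.encode(genome.sequence)
    per_base, valid = _counts_per_window(codes, width)
    gc_counts = per_base[:, 1] + per_base[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(valid > 0, gc_counts / np.maximum(valid, 1), np.nan)
    usable = valid > 0
    mean = float(np.mean(gc[usable]))
    sd = float(np.std(gc[usable]))
    out: list[WindowStat] = []
    for i in range(len(gc)):
        if not usable[i]:
            out.append(WindowStat(i * width, width, float("nan"), 0.0, False))
            continue
        z = (gc[i] - mean) / sd if sd > 0 else 0.0
        out.append(WindowStat(i * width, width, float(gc[i]), float(z), abs(z) > sd_cut))
    return out


def cumulative_skew(
    genome: Genome, X: str = "G", Y: str = "C", window: int = 1000
) -> SkewSeries:
    """Cumulative per-window skew: value_i = sum_{j<=i} (X_j - Y_j)/(X_j + Y_j),
    with zero contribution where a window contains neither base."""
    if X == Y:
        raise ValueError("skew bases must differ")
    codes = _kmers.encode(genome.sequence)
    per_base, _ = _counts_per_window(codes, window)
    ix, iy = _BASES.index(X), _BASES.index(Y)
    nx = per_base[:, ix].astype(float)
    ny = per_base[:, iy].astype(float)
    denom = nx + ny
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(denom > 0, (nx - ny) / np.maximum(denom, 1), 0.0)
    return SkewSeries(base_pair=X + Y, window=window, values=np.cumsum(skew))


def _strand_symmetric_counts(codes: np.ndarray, k: int) -> np.ndarray:
    """k-mer counts summed over both strands."""
    v, valid = _kmers.kmer_values(codes, k)
    counts = np.bincount(v[valid].astype(np.int64), minlength=4**k)
    # reverse complement on packed values
    rc = np.zeros(4**k, dtype=np.int64)
    idx = np.arange(4**k)
    out = np.zeros_like(idx)
    tmp = idx.copy()
    for _ in range(k):
        out = (out << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return counts + counts[out]


def tetramer_avoidance(genome: Genome) -> pd.DataFrame:
    """Observed/expected ratios for all 256 tetramers under the order-2
    Markov expectation, counted on both strands, ranked ascending by O/E
    (the strongly avoided words come first).

    Tetramers whose expectation is undefined (zero-count middle
    dinucleotide) get O/E = NaN and sort last.
    """
    if len(genome) < 10_000:
        raise ValueError("genome too short for tetramer statistics (< 10 kb)")
    codes = _kmers.encode(genome.sequence)
    c4 = _strand_symmetric_counts(codes, 4).astype(float)
    c3 = _strand_symmetric_counts(codes, 3).astype(float)
    c2 = _strand_symmetric_counts(codes, 2).astype(float)
    idx = np.arange(256)
    left3 = idx >> 2  # w1w2w3
    right3 = idx & 0x3F  # w2w3w4
    mid2 = (idx >> 2) & 0xF  # w2w3
    denom = c2[mid2]
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = np.where(denom > 0, c3[left3] * c3[right3] / np.maximum(denom, 1), np.nan)
        oe = np.where(expected > 0, c4 / np.maximum(expected, 1e-300), np.nan)
    df = pd.DataFrame(
        {"tetramer": _TETRAMERS, "observed": c4, "expected": expected, "oe_ratio": oe}
    )
    return df.sort_values("oe_ratio", na_position="last").reset_index(drop=True)


def tetramer_deviation_profile(
    genome: Genome, window: int = 5000, step: int = 1000
) -> pd.DataFrame:
    """Per-window tetramer deviation score: the RMS over all 256 tetramers
    of the binomial z-score of the window count against the whole-replicon
    tetramer frequencies (both strands).  High scores mark segments of
    foreign composition."""
    if len(genome) < window:
        raise ValueError("genome shorter than one window")
    codes = _kmers.encode(genome.sequence)
    total = _strand_symmetric_counts(codes, 4).astype(float)
    p = total / max(1.0, total.sum())
    starts = np.arange(0, len(genome) - window + 1, step)
    scores = np.empty(len(starts))
    for i, s in enumerate(starts):
        c = _strand_symmetric_counts(codes[s : s + window], 4).astype(float)
        n = c.sum()
        if n == 0:
            scores[i] = 0.0
            continue
        var = n * p * (1 - p)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(var > 0, (c - n * p) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
        scores[i] = float(np.sqrt(np.mean(z**2)))
    return pd.DataFrame({"start": starts, "score": scores})
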