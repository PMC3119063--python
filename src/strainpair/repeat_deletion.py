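"""Direct repeats at indel junctions: detection of the repeat-mediated
deletion signature, the deletion length law, and the chance-expectation
statistic.

A repeat-mediated deletion leaves a characteristic junction: the strain
that retains the sequence reads ...R core R..., while the other strain
reads ...R... -- the core plus exactly one copy of the short direct repeat
R have been deleted.  Because the indel's placement against the junction is
ambiguous by cyclic shift, the repeat can surface either as a shared prefix
of the indel with its right flank or as a shared suffix with its left
flank; detection checks both phases and the repeat length is invariant
under the shift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .run_connector import ComparisonMap, Connector

__all__ = [
    "RepeatFlank",
    "flanking_direct_repeat",
    "apply_repeat_mediated_deletion",
    "expected_chance_repeats",
    "repeat_length_census",
    "CENSUS_BINS",
]


@dataclass(frozen=True)
class RepeatFlank:
    """A direct repeat flanking a deleted (or inserted) core."""

    repeat_seq: str
    repeat_len: int
    exact: bool
    mismatches: int
    core_len: int
    deleted_total: int  # core plus one repeat copy

    def __post_init__(self) -> None:
        assert self.deleted_total == self.core_len + self.repeat_len
        assert not self.exact or self.mismatches == 0


def _prefix_match(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i] and a[i] != "N":
        i += 1
    return i


def _tolerant_prefix_match(a: str, b: str, per10: int = 1) -> tuple[int, int]:
    """Longest r with at most per10 mismatches per 10 bp between a[:r] and
    b[:r]; returns (r, mismatches)."""
    n = min(len(a), len(b))
    best = (0, 0)
    mism = 0
    for i in range(n):
        if a[i] != b[i] or a[i] == "N":
            mism += 1
        if mism <= (i + 1) // 10 * per10:
            best = (i + 1, mism)
    return best


def flanking_direct_repeat(
    cmap_or_seqs,
    region: Connector,
    min_len: int = 4,
    max_scan: int = 1000,
    allow_inexact: bool = True,
) -> Optional[RepeatFlank]:
    """Detect a direct repeat at the junction of an indel-like region.

    ``cmap_or_seqs`` is either a :class:`ComparisonMap` or a pair
    ``(seqA, seqB)`` of genome sequences.  The longer connector side is the
    retained sequence; the repeat is the maximal exact match between the
    retained segment's start and the right flank, or between its end and
    the left flank (the two shift phases of the same junction).  Returns
    None when the maximal match is shorter than ``min_len``.

    A variant (inexact) repeat with at most one mismatch per 10 bp is
    reported flagged ``exact=False`` when it is longer than the exact one.
    """
    if isinstance(cmap_or_seqs, ComparisonMap):
        sa, sb = cmap_or_seqs.genomeA.sequence, cmap_or_seqs.genomeB.sequence
    else:
        sa, sb = cmap_or_seqs
    if region.lenA >= region.lenB:
        seq, start, end = sa, region.startA, region.endA
    else:
        seq, start, end = sb, region.startB, region.endB
    ins = seq[start:end]
    if not ins:
        return None
    left = seq[max(0, start - max_scan) : start]
    right = seq[end : end + max_scan]
    r_prefix = _prefix_match(ins, right)
    r_suffix = _prefix_match(ins[::-1], left[::-1])
    if r_prefix >= r_suffix:
        r, phase = r_prefix, "prefix"
    else:
        r, phase = r_suffix, "suffix"
    mism = 0
    exact = True
    if r < min_len and allow_inexact:
        # no exact repeat; look for a variant repeat (<= 1 mismatch / 10 bp),
        # assumed mutated towards identity in the other strain before deletion
        v1, m1 = _tolerant_prefix_match(ins, right)
        v2, m2 = _tolerant_prefix_match(ins[::-1], left[::-1])
        if (v1, -m1) >= (v2, -m2):
            v, m, ph = v1, m1, "prefix"
        else:
            v, m, ph = v2, m2, "suffix"
        if v > r and m > 0:
            r, mism, exact, phase = v, m, False, ph
    if r < min_len:
        return None
    repeat_seq = ins[:r] if phase == "prefix" else ins[-r:]
    return RepeatFlank(
        repeat_seq=repeat_seq,
        repeat_len=r,
        exact=exact,
        mismatches=mism,
        core_len=len(ins) - r,
        deleted_total=len(ins),
    )


def apply_repeat_mediated_deletion(
    seq: str, repeat1_pos: int, repeat2_pos: int, repeat_len: int
) -> str:
    """Delete the core between two identical direct repeats plus one repeat
    copy: ...R core R... becomes ...R... .

    The output is shorter by ``core_len + repeat_len`` =
    ``repeat2_pos - repeat1_pos`` bases.
    """
    if repeat1_pos > repeat2_pos:
        repeat1_pos, repeat2_pos = repeat2_pos, repeat1_pos
    r1 = seq[repeat1_pos : repeat1_pos + repeat_len]
    r2 = seq[repeat2_pos : repeat2_pos + repeat_len]
    if len(r1) < repeat_len or len(r2) < repeat_len:
        raise ValueError("repeat positions fall outside the sequence")
    if r1 != r2:
        raise ValueError(f"sequences at the two repeat positions differ: {r1!r} != {r2!r}")
    return seq[: repeat1_pos + repeat_len] + seq[repeat2_pos + repeat_len :]


def expected_chance_repeats(
    n_indels: int, k: int, base_freqs: Optional[Mapping[str, float] | Sequence[float]] = None
) -> float:
    """Expected number of indels whose junction carries a chance direct
    repeat of length k: E = n * p**k with p = sum of squared base
    frequencies (the per-position probability that two independent junction
    bases match).  Uniform composition gives p = 1/4.
    """
    if n_indels < 0 or k < 1:
        raise ValueError("n_indels must be >= 0 and k >= 1")
    if base_freqs is None:
        p = 0.25
    else:
        freqs = (
            [base_freqs[b] for b in "ACGT"]
            if isinstance(base_freqs, Mapping)
            else list(base_freqs)
        )
        if len(freqs) != 4 or any(f < 0 for f in freqs) or abs(sum(freqs) - 1.0) > 1e-6:
            raise ValueError("base_freqs must be four non-negative values summing to 1")
        p = sum(f * f for f in freqs)
    return n_indels * p**k


CENSUS_BINS = ["4", "5", "6", "7-9", "10-19", ">=20"]


def _bin_of(r: int) -> Optional[str]:
    if r < 4:
        return None
    if r <= 6:
        return str(r)
    if r <= 9:
        return "7-9"
    if r <= 19:
        return "10-19"
    return ">=20"


def repeat_length_census(
    flanks: Iterable[Optional[RepeatFlank]],
    n_indels: Optional[int] = None,
    base_freqs=None,
) -> pd.DataFrame:
    """Count exact junction repeats by length class and compare with the
    chance expectation.

    Bins: 4, 5, 6, 7-9, 10-19, >=20.  Inexact (variant) repeats are
    excluded from the census.  ``n_indels`` (defaults to the number of
    inputs) scales the expectation E = n * p**k, summed over each bin's
    lengths.
    """
    flanks = list(flanks)
    if n_indels is None:
        n_indels = len(flanks)
    counts = {b: 0 for b in CENSUS_BINS}
    for f in flanks:
        if f is None or not f.exact:
            continue
        b = _bin_of(f.repeat_len)
        if b is not None:
            counts[b] += 1
    expected = {}
    for b in CENSUS_BINS:
        if b in ("4", "5", "6"):
            ks = [int(b)]
        elif b == "7-9":
            ks = list(range(7, 10))
        elif b == "10-19":
            ks = list(range(10, 20))
        else:
            ks = list(range(20, 41))
        expected[b] = sum(expected_chance_repeats(n_indels, k, base_freqs) for k in ks)
    return pd.DataFrame(
        {
            "repeat_length": CENSUS_BINS,
            "observed": [counts[b] for b in CENSUS_BINS],
            "expected_by_chance": [expected[b] for b in CENSUS_BINS],
        }
    )
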