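"""Thin wrapper over edlib for unit-cost global alignment statistics.

Run/connector decomposition never uses these alignments to find runs; they
only annotate connectors (difference counts, identity) and drive the
divergence filter, where the unit-cost optimal alignment is the stated
convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

__all__ = ["AlignmentStats", "global_alignment", "identity"]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class AlignmentStats:
    distance: int  # unit-cost optimal edit distance (mismatches + gap columns)
    columns: int  # total alignment columns
    matches: int  # matching columns
    longest_gap_run: int  # longest run of consecutive I or D columns
    cigar: tuple[tuple[int, str], ...]

    @property
    def identity(self) -> float:
        """Matching columns / total columns (gaps count in the denominator)."""
        if self.columns == 0:
            return 1.0
        return self.matches / self.columns


def _parse_cigar(cigar: str) -> tuple[tuple[int, str], ...]:
    return tuple((int(n), op) for n, op in _CIGAR_RE.findall(cigar))


def global_alignment(a: str, b: str) -> AlignmentStats:
    """Unit-cost optimal global (NW) alignment of two sequences."""
    if not a and not b:
        return AlignmentStats(0, 0, 0, 0, ())
    if not a or not b:
        n = max(len(a), len(b))
        op = "D" if not a else "I"
        return AlignmentStats(n, n, 0, n, ((n, op),))
    res = edlib.align(a, b, mode="NW", task="path")
    ops = _parse_cigar(res["cigar"])
    columns = sum(n for n, _ in ops)
    distance = res["editDistance"]
    gap_run = 0
    cur = 0
    for n, op in ops:
        if op in "ID":
            cur += n
            gap_run = max(gap_run, cur)
        else:
            cur = 0
    return AlignmentStats(distance, columns, columns - distance, gap_run, ops)


def identity(a: str, b: str) -> float:
    return global_alignment(a, b).identity
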