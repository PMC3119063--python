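"""Decomposition of two co-linear chromosomes into identical "runs" and
divergent "connectors".

The two genomes are tiled by an alternating series of runs (maximal,
character-identical segments at aligned positions) and connectors (the
divergent sequence pairs between consecutive runs; a point mutation is a
connector of length one on each side, a pure indel has length zero on one
side).  Runs are seeded exclusively from words that are unique within each
genome, which makes the procedure robust against dispersed duplications: a
repeated word can never anchor, so only the co-linear copy of a duplicated
region is matched, via the unique words of its context.

The comparison has two phases.  A scaffolding phase anchors long unique
words (15-mers by default), extends them to maximal runs, selects the
heaviest strictly co-ordered subset, and accepts the longest runs until
they cover a configurable fraction of the shorter genome.  A refinement
phase then recursively processes every gap between accepted runs: the
longest unique-word run inside the gap is intercalated and the two flanking
sub-gaps are refined in turn; a gap in which no acceptable run can be found
becomes a single connector.

Chance guard.  Two unrelated sequences of lengths m and n share spurious
identical substrings of length up to about log4(m*n).  Refinement therefore
only intercalates runs longer than that expectation plus a fixed margin;
shorter matches inside a divergent gap are treated as noise and left inside
the connector.  This keeps genuinely unrelated replacement regions (e.g.
deletion-coupled insertions) intact as single connectors instead of
splitting them on coincidental word matches.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from . import _kmers
from .alignment import AlignmentStats, global_alignment
from .seq_io import Genome

__all__ = [
    "Run",
    "Connector",
    "ComparisonMap",
    "CompareConfig",
    "unique_word_matches",
    "build_scaffold",
    "refine",
    "compare_chromosomes",
    "shared_identity",
]


@dataclass
class CompareConfig:
    """Numeric knobs of the comparison.

    ``k_scaffold``/``scaffold_coverage`` control the first phase (long
    unique words; longest runs accepted until they sum to the given
    fraction of the shorter genome).  ``k_refine`` is the minimum word
    length of the refinement phase; shorter words cannot exist, so a run is
    never shorter than 3 bases.  ``chance_margin`` is added to the
    log4-scale expected longest chance match when deciding whether a run
    found inside a gap is real.  ``ndiff_cap`` bounds the connector size
    (per side) for which difference counts are computed eagerly.
    """

    k_scaffold: int = 15
    scaffold_coverage: float = 0.30
    k_refine: int = 3
    chance_margin: int = 3
    ndiff_cap: int = 10_000


@dataclass
class Run:
    """A maximal identical segment: A[startA:startA+length) == B[startB:startB+length)."""

    startA: int
    startB: int
    length: int

    @property
    def endA(self) -> int:
        return self.startA + self.length

    @property
    def endB(self) -> int:
        return self.startB + self.length


@dataclass
class Connector:
    """The divergent pair between two runs; either side may have length 0."""

    startA: int
    lenA: int
    startB: int
    lenB: int
    _stats: Optional[AlignmentStats] = field(default=None, repr=False, compare=False)

    @property
    def endA(self) -> int:
        return self.startA + self.lenA

    @property
    def endB(self) -> int:
        return self.startB + self.lenB

    def stats(self, seqA: str, seqB: str, cap: int = 10_000) -> Optional[AlignmentStats]:
        """Unit-cost global alignment statistics of the two sides, cached.
        Returns None when either side exceeds ``cap`` (difference counts on
        huge connectors are never needed: the length-difference criterion
        already classifies them)."""
        if self._stats is None:
            if self.lenA > cap or self.lenB > cap:
                return None
            a = seqA[self.startA : self.endA]
            b = seqB[self.startB : self.endB]
            self._stats = global_alignment(a, b)
        return self._stats

    def n_diffs(self, seqA: str, seqB: str, cap: int = 10_000) -> Optional[int]:
        st = self.stats(seqA, seqB, cap)
        return None if st is None else st.distance

    def identity(self, seqA: str, seqB: str, cap: int = 10_000) -> Optional[float]:
        st = self.stats(seqA, seqB, cap)
        return None if st is None else st.identity


Element = Union[Run, Connector]


@dataclass
class ComparisonMap:
    """Ordered alternating series of runs and connectors tiling both genomes."""

    genomeA: Genome
    genomeB: Genome
    elements: list[Element]

    def runs(self) -> list[Run]:
        return [e for e in self.elements if isinstance(e, Run)]

    def connectors(self) -> list[Connector]:
        return [e for e in self.elements if isinstance(e, Connector)]

    def tiles_exactly(self) -> bool:
        """Check the tiling property: concatenated A-sides reproduce genome A
        byte-exactly, and likewise for B."""
        a_parts: list[str] = []
        b_parts: list[str] = []
        sa, sb = self.genomeA.sequence, self.genomeB.sequence
        for e in self.elements:
            if isinstance(e, Run):
                a_parts.append(sa[e.startA : e.endA])
                b_parts.append(sb[e.startB : e.endB])
            else:
                a_parts.append(sa[e.startA : e.endA])
                b_parts.append(sb[e.startB : e.endB])
        return "".join(a_parts) == sa and "".join(b_parts) == sb

    def project_a_to_b(self, posA: int) -> int:
        """Map a position in A to the corresponding position in B through the
        nearest run (exact inside runs, clamped inside connectors)."""
        runs = self.runs()
        if not runs:
            return min(posA, len(self.genomeB.sequence))
        starts = [r.startA for r in runs]
        i = bisect_right(starts, posA) - 1
        if i < 0:
            return max(0, runs[0].startB - (runs[0].startA - posA))
        r = runs[i]
        if posA < r.endA:
            return r.startB + (posA - r.startA)
        if i + 1 < len(runs):
            return min(r.endB + (posA - r.endA), runs[i + 1].startB)
        return min(r.endB + (posA - r.endA), len(self.genomeB.sequence))

    def connector_shift_range(self, c: Connector, cap: int = 64) -> tuple[int, int]:
        """How far the connector's junction can slide left/right while the
        tiling stays valid (direct-repeat placement ambiguity).  Returns
        (left_slack, right_slack), each capped.

        Sliding one step left moves the last base of the left run into the
        connector and pops the connector's last base(s) into the right run;
        this is valid when the popped base on every non-empty side equals
        the run base entering.
        """
        sa, sb = self.genomeA.sequence, self.genomeB.sequence
        na, nb = len(sa), len(sb)

        def ok_left(i: int) -> bool:
            ia, ib = c.startA - i - 1, c.startB - i - 1
            if ia < 0 or ib < 0 or sa[ia] != sb[ib]:
                return False
            if c.lenA > 0 and sa[c.endA - i - 1] != sa[ia]:
                return False
            if c.lenB > 0 and sb[c.endB - i - 1] != sb[ib]:
                return False
            return True

        def ok_right(i: int) -> bool:
            ia, ib = c.endA + i, c.endB + i
            if ia >= na or ib >= nb or sa[ia] != sb[ib]:
                return False
            if c.lenA > 0 and sa[c.startA + i] != sa[ia]:
                return False
            if c.lenB > 0 and sb[c.startB + i] != sb[ib]:
                return False
            return True

        left = 0
        while left < cap and ok_left(left):
            left += 1
        right = 0
        while right < cap and ok_right(right):
            right += 1
        return left, right


# ---------------------------------------------------------------------------
# word matching


def unique_word_matches(segA: str, segB: str, k: int) -> set[tuple[int, int]]:
    """Anchors (posA, posB) of words occurring exactly once in segA AND
    exactly once in segB (and identical).  Words containing N are excluded."""
    if k < 3:
        raise ValueError("word length must be >= 3")
    return {
        (int(a), int(b))
        for a, b in zip(*_unique_matches(_kmers.encode(segA), _kmers.encode(segB), k))
    }


def _unique_matches(
    codesA: np.ndarray, codesB: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    va, pa = _kmers.unique_kmer_positions(codesA, k)
    vb, pb = _kmers.unique_kmer_positions(codesB, k)
    if len(va) == 0 or len(vb) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    common, ia, ib = np.intersect1d(va, vb, assume_unique=True, return_indices=True)
    return pa[ia].astype(np.int64), pb[ib].astype(np.int64)


# ---------------------------------------------------------------------------
# extension to maximal runs


def _diagonal_runs(
    codesA: np.ndarray,
    codesB: np.ndarray,
    posA: np.ndarray,
    posB: np.ndarray,
    k: int,
    aLo: int = 0,
    aHi: Optional[int] = None,
    bLo: int = 0,
    bHi: Optional[int] = None,
) -> list[Run]:
    """Extend anchors to maximal identical runs, deduplicated per diagonal.

    For every diagonal that carries at least one anchor, the equality
    profile along the diagonal (within the interval bounds) is computed
    vectorized and run-length encoded; runs containing an anchor word are
    returned.  N never matches N.
    """
    if aHi is None:
        aHi = len(codesA)
    if bHi is None:
        bHi = len(codesB)
    if len(posA) == 0:
        return []
    diags = posA - posB
    runs: list[Run] = []
    for d in np.unique(diags):
        sel = diags == d
        apos = np.sort(posA[sel])
        lo = max(aLo, bLo + d)
        hi = min(aHi, bHi + d)
        if hi <= lo:
            continue
        a_slice = codesA[lo:hi]
        b_slice = codesB[lo - d : hi - d]
        eq = (a_slice == b_slice) & (a_slice != 255)
        if not eq.any():
            continue
        # run-length encode eq
        idx = np.flatnonzero(np.diff(eq.astype(np.int8)))
        starts = np.concatenate(([0], idx + 1))
        ends = np.concatenate((idx + 1, [len(eq)]))
        run_start = starts[eq[starts]] + lo
        run_end = ends[eq[starts]] + lo
        # keep runs containing at least one anchor word start
        j = np.searchsorted(run_start, apos, side="right") - 1
        j = np.unique(j[j >= 0])
        for ji in j:
            s, e = int(run_start[ji]), int(run_end[ji])
            # anchor word must fit in the run
            hits = apos[(apos >= s) & (apos + k <= e)]
            if len(hits):
                runs.append(Run(s, s - int(d), e - s))
    return runs


# ---------------------------------------------------------------------------
# scaffolding


def _max_collinear_chain(runs: list[Run]) -> list[Run]:
    """Maximum-total-length subset of runs strictly increasing in both
    genomes (weighted longest-increasing-subsequence on startB, ordered by
    startA), via a Fenwick tree of prefix maxima."""
    if not runs:
        return []
    runs = sorted(runs, key=lambda r: (r.startA, r.startB))
    bstarts = sorted({r.startB for r in runs})
    rank = {b: i + 1 for i, b in enumerate(bstarts)}
    size = len(bstarts) + 1
    best_val = [0] * size  # Fenwick of (total length)
    best_idx = [-1] * size
    dp = [0] * len(runs)
    parent = [-1] * len(runs)

    def query(r: int) -> tuple[int, int]:
        v, idx = 0, -1
        while r > 0:
            if best_val[r] > v:
                v, idx = best_val[r], best_idx[r]
            r -= r & (-r)
        return v, idx

    def update(r: int, v: int, idx: int) -> None:
        while r < size:
            if v > best_val[r]:
                best_val[r], best_idx[r] = v, idx
            r += r & (-r)

    for i, run in enumerate(runs):
        v, idx = query(rank[run.startB] - 1)
        dp[i] = v + run.length
        parent[i] = idx
        update(rank[run.startB], dp[i], i)

    i = max(range(len(runs)), key=lambda j: dp[j])
    chain: list[Run] = []
    while i >= 0:
        chain.append(runs[i])
        i = parent[i]
    chain.reverse()
    return chain


def build_scaffold(
    A: Genome, B: Genome, k15: int = 15, coverage: float = 0.30
) -> list[Run]:
    """Scaffolding phase: unique long-word anchors, maximal extension, a
    strictly co-ordered chain, and acceptance of the longest runs until
    their cumulative length first reaches ``coverage`` of the shorter
    genome (the run crossing the threshold is included).
    """
    codesA = _kmers.encode(A.sequence)
    codesB = _kmers.encode(B.sequence)
    pa, pb = _unique_matches(codesA, codesB, k15)
    candidates = _diagonal_runs(codesA, codesB, pa, pb, k15)
    chain = _max_collinear_chain(candidates)
    target = coverage * min(len(A), len(B))
    accepted: list[Run] = []
    total = 0
    for run in sorted(chain, key=lambda r: (-r.length, r.startA)):
        if total >= target:
            break
        clash = any(
            not (run.endA <= a.startA or run.startA >= a.endA)
            or not (run.endB <= a.startB or run.startB >= a.endB)
            for a in accepted
        )
        if clash:
            continue
        accepted.append(run)
        total += run.length
    accepted.sort(key=lambda r: r.startA)
    # enforce strict co-ordering (defensive; the chain already is)
    ordered: list[Run] = []
    for run in accepted:
        if ordered and (run.startA < ordered[-1].endA or run.startB < ordered[-1].endB):
            continue
        ordered.append(run)
    return ordered


# ---------------------------------------------------------------------------
# refinement


def _chance_floor(lenA: int, lenB: int, margin: int) -> int:
    """Minimum believable run length inside a gap pair: the log4-scale
    expected longest chance match between unrelated sequences plus a
    margin, never below 3."""
    prod = max(1, lenA) * max(1, lenB)
    return max(3, math.ceil(math.log(prod, 4)) + margin)


def _best_gap_run(
    codesA: np.ndarray,
    codesB: np.ndarray,
    aLo: int,
    aHi: int,
    bLo: int,
    bHi: int,
    cfg: CompareConfig,
) -> Optional[Run]:
    la, lb = aHi - aLo, bHi - bLo
    if la == 0 or lb == 0:
        return None
    floor = _chance_floor(la, lb, cfg.chance_margin)
    if min(la, lb) < floor:
        return None
    min_side = min(la, lb)
    # word length where uniqueness is plausible for the gap size
    k = max(cfg.k_refine, min(15, int(math.log(min_side, 4))))
    ks: list[int] = []
    while k <= min_side:
        ks.append(k)
        k *= 2
    if not ks or ks[-1] != min_side:
        ks.append(min_side)
    segA = codesA[aLo:aHi]
    segB = codesB[bLo:bHi]
    for k in ks:
        pa, pb = _unique_matches(segA, segB, k)
        if len(pa) == 0:
            continue
        runs = _diagonal_runs(segA, segB, pa, pb, k)
        best: Optional[Run] = None
        for r in runs:
            if r.length < floor:
                continue
            key = (-r.length, r.startA, r.startB)
            if best is None or key < (-best.length, best.startA, best.startB):
                best = r
        if best is not None:
            return Run(best.startA + aLo, best.startB + bLo, best.length)
    return None


def refine(
    genomeA: Genome,
    genomeB: Genome,
    gapA: tuple[int, int],
    gapB: tuple[int, int],
    k3: int = 3,
    config: Optional[CompareConfig] = None,
) -> list[Element]:
    """Refine the gap pair between two accepted runs (or sequence ends)
    into an ordered list of runs and connectors.

    The longest acceptable unique-word run is intercalated and both flanks
    are refined recursively (implemented with an explicit stack).  A gap
    pair with no acceptable run becomes a single connector; zero-length gap
    sides yield pure-indel connectors.
    """
    cfg = config or CompareConfig(k_refine=k3)
    codesA = _kmers.encode(genomeA.sequence)
    codesB = _kmers.encode(genomeB.sequence)
    return _refine_codes(codesA, codesB, gapA, gapB, cfg)


def _refine_codes(
    codesA: np.ndarray,
    codesB: np.ndarray,
    gapA: tuple[int, int],
    gapB: tuple[int, int],
    cfg: CompareConfig,
) -> list[Element]:
    out: list[Element] = []
    stack: list[tuple] = [("gap", gapA[0], gapA[1], gapB[0], gapB[1])]
    while stack:
        item = stack.pop()
        if item[0] == "emit":
            out.append(item[1])
            continue
        _, aLo, aHi, bLo, bHi = item
        if aHi - aLo == 0 and bHi - bLo == 0:
            continue
        best = _best_gap_run(codesA, codesB, aLo, aHi, bLo, bHi, cfg)
        if best is None:
            out.append(Connector(aLo, aHi - aLo, bLo, bHi - bLo))
            continue
        # depth-first, left first: push right gap, then the run, then left gap
        stack.append(("gap", best.endA, aHi, best.endB, bHi))
        stack.append(("emit", best))
        stack.append(("gap", aLo, best.startA, bLo, best.startB))
    return out


# ---------------------------------------------------------------------------
# full comparison


def _merge_elements(elements: list[Element]) -> list[Element]:
    """Merge adjacent runs that are contiguous in both genomes and drop
    empty connectors."""
    merged: list[Element] = []
    for e in elements:
        if isinstance(e, Connector) and e.lenA == 0 and e.lenB == 0:
            continue
        if (
            merged
            and isinstance(e, Run)
            and isinstance(merged[-1], Run)
            and merged[-1].endA == e.startA
            and merged[-1].endB == e.startB
        ):
            merged[-1].length += e.length
            continue
        merged.append(e)
    return merged


def compare_chromosomes(
    A: Genome, B: Genome, config: Optional[CompareConfig] = None
) -> ComparisonMap:
    """Base-by-base comparison of two co-linear genomes.

    The returned map tiles both genomes exactly: concatenating the A-sides
    of all elements in order reproduces genome A, and likewise for B.
    Degenerate inputs (an empty genome) yield a single connector.
    """
    cfg = config or CompareConfig()
    na, nb = len(A), len(B)
    if na == 0 or nb == 0:
        elements: list[Element] = []
        if na or nb:
            elements = [Connector(0, na, 0, nb)]
        return ComparisonMap(A, B, elements)
    codesA = _kmers.encode(A.sequence)
    codesB = _kmers.encode(B.sequence)
    scaffold = build_scaffold(A, B, cfg.k_scaffold, cfg.scaffold_coverage)
    elements = []
    prevA, prevB = 0, 0
    for run in scaffold + [Run(na, nb, 0)]:
        if run.startA > prevA or run.startB > prevB:
            elements.extend(
                _refine_codes(codesA, codesB, (prevA, run.startA), (prevB, run.startB), cfg)
            )
        if run.length:
            elements.append(run)
        prevA, prevB = run.endA, run.endB
    return ComparisonMap(A, B, _merge_elements(elements))


# ---------------------------------------------------------------------------
# shared-sequence statistics


def shared_identity(
    cmap: ComparisonMap,
    strain_specific: Optional[list[Connector]] = None,
    cap: int = 10_000,
) -> float:
    """Nucleotide identity over the shared sequence: all runs plus trivial
    connectors (matches / total aligned columns, gap columns counted as
    non-matches), excluding the given strain-specific regions.

    Raises ValueError when the shared sequence is empty.
    """
    excluded = {id(c) for c in (strain_specific or [])}
    sa, sb = cmap.genomeA.sequence, cmap.genomeB.sequence
    matches = 0
    columns = 0
    for e in cmap.elements:
        if isinstance(e, Run):
            matches += e.length
            columns += e.length
        else:
            if id(e) in excluded:
                continue
            st = e.stats(sa, sb, cap)
            if st is None:  # huge connector outside the strain-specific set
                columns += max(e.lenA, e.lenB)
            else:
                matches += st.matches
                columns += st.columns
    if columns == 0:
        raise ValueError("shared sequence is empty; identity undefined")
    return matches / columns


def shared_fraction(
    cmap: ComparisonMap, strain_specific: Optional[list[Connector]] = None
) -> tuple[float, float]:
    """Fraction of each genome inside the shared sequence (everything
    outside the strain-specific regions)."""
    regions = strain_specific or []
    na, nb = len(cmap.genomeA), len(cmap.genomeB)
    specA = sum(c.lenA for c in regions)
    specB = sum(c.lenB for c in regions)
    return ((na - specA) / na if na else 1.0, (nb - specB) / nb if nb else 1.0)
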