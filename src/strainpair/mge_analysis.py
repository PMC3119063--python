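"""Mobile genetic element (MGE) analysis against a family catalog.

Six element categories are modelled, following the standard taxonomy of
haloarchaeal mobile elements: IS605-type transposons (TP-A: no inverted
terminal repeats, near-terminal palindromes, no target duplications),
canonical transposons (TP-B: ITRs, often target duplications), MITEs
(miniature inverted-repeat transposable elements: ITRs related to a parent
transposon, target duplications, too short to encode a transposase), PATEs
(palindrome-associated transposable elements: near-terminal palindromes,
no ITRs, no TDs), and small mobile repeats of types A and B (ITRs
unrelated to transposons, no TDs).

Family discovery itself is expert/iterative work and is out of scope here;
the module matches genomes against a supplied catalog of family consensus
sequences (seed-and-extend with unit-cost alignment verification), classes
each hit as complete / partial / terminal-only, decides strain-specific
element insertion (SSEI) status against a comparison map, measures target
duplications, and aggregates the element-in-element targeting matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from . import _kmers
from .alignment import global_alignment
from .repeat_deletion import RepeatFlank, _tolerant_prefix_match, flanking_direct_repeat
from .run_connector import ComparisonMap, Connector
from .seq_io import Genome

__all__ = [
    "CATEGORIES",
    "ElementFamily",
    "ElementHit",
    "TargetingMatrix",
    "load_catalog",
    "write_catalog",
    "locate_elements",
    "call_ssei",
    "detect_target_duplication",
    "targeting_matrix",
    "detect_core_deletion",
]

# category order used in all tables
CATEGORIES = ["PATE", "TP_A", "TP_B", "MITE", "SMR_A", "SMR_B"]
_TD_CATEGORIES = {"TP_B", "MITE"}  # the only categories causing target duplications


@dataclass
class ElementFamily:
    """One mobile-element family: consensus sequence plus its category
    characteristics (ITR, target-duplication length range, length range)."""

    code: str
    category: str
    consensus: str
    itr: Optional[str] = None
    td_range: Optional[tuple[int, int]] = None
    length_range: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown MGE category {self.category!r}")
        if self.category not in _TD_CATEGORIES and self.td_range is not None:
            raise ValueError(f"{self.category} elements do not cause target duplications")
        if self.length_range is None:
            self.length_range = (len(self.consensus), len(self.consensus))

    @property
    def max_td(self) -> int:
        return self.td_range[1] if self.td_range else 0


@dataclass
class ElementHit:
    """A located element instance in one genome."""

    family: ElementFamily
    genome: str  # 'A' or 'B'
    start: int  # 0-based half-open
    end: int
    strand: str = "+"
    completeness: str = "complete"  # complete | partial | terminal_only
    identity: float = 1.0
    status: Optional[str] = None  # common | SSEI | within_indel | unresolved
    td_len: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# catalog I/O


def load_catalog(fasta_path: str | Path, tsv_path: str | Path) -> list[ElementFamily]:
    """Catalog = consensus FASTA plus a TSV with columns code, category,
    itr, td_min, td_max, len_min, len_max ('.' for not applicable)."""
    from .seq_io import read_fasta

    seqs = {g.name: g.sequence for g in read_fasta(fasta_path)}
    fams: list[ElementFamily] = []
    with open(tsv_path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            td = (
                None
                if row["td_min"] == "."
                else (int(row["td_min"]), int(row["td_max"]))
            )
            lr = (
                None
                if row["len_min"] == "."
                else (int(row["len_min"]), int(row["len_max"]))
            )
            fams.append(
                ElementFamily(
                    code=row["code"],
                    category=row["category"],
                    consensus=seqs[row["code"]],
                    itr=None if row["itr"] == "." else row["itr"],
                    td_range=td,
                    length_range=lr,
                )
            )
    return fams


def write_catalog(
    families: Sequence[ElementFamily], fasta_path: str | Path, tsv_path: str | Path
) -> None:
    from .seq_io import Genome, write_fasta

    write_fasta([Genome(f.code, f.consensus, "linear") for f in families], fasta_path)
    with open(tsv_path, "w") as fh:
        fh.write("#code\tcategory\titr\ttd_min\ttd_max\tlen_min\tlen_max\n")
        for f in families:
            td = f.td_range or (".", ".")
            lr = f.length_range or (".", ".")
            fh.write(
                f"{f.code}\t{f.category}\t{f.itr or '.'}\t{td[0]}\t{td[1]}\t{lr[0]}\t{lr[1]}\n"
            )


# ---------------------------------------------------------------------------
# element location


def _classify_hit(hit_seq: str, consensus: str, family: ElementFamily, min_identity: float,
                  min_coverage: float) -> Optional[tuple[str, float]]:
    """Classify an aligned candidate against the family consensus.

    Returns (completeness, identity) or None when the candidate does not
    match the family at all.  terminal_only = the candidate is shorter than
    the family minimum but matches the consensus with one large internal
    deletion and well-matched ends (fused terminal sequences).
    """
    if not hit_seq:
        return None
    st = global_alignment(hit_seq, consensus)
    if st.columns == 0:
        return None
    coverage = st.matches / max(1, len(consensus))
    # a complete element may itself be interrupted by a nested insertion;
    # judge identity with candidate-side insertions excluded (the coverage
    # requirement already bounds how much consensus may be missing)
    total_insert = sum(n for n, op in st.cigar if op == "I")
    core_cols = max(1, st.columns - total_insert)
    if coverage >= min_coverage and st.matches / core_cols >= min_identity:
        return "complete", st.matches / core_cols
    min_len = family.length_range[0] if family.length_range else len(consensus)
    if len(hit_seq) < min_len:
        # fused terminal remnant: the candidate is explained by the
        # consensus prefix plus suffix (core deleted), both ends matching
        p, _ = _tolerant_prefix_match(hit_seq, consensus)
        s, _ = _tolerant_prefix_match(hit_seq[::-1], consensus[::-1])
        if p >= 8 and s >= 8 and p + s >= 0.8 * len(hit_seq):
            return "terminal_only", min(1.0, (p + s) / max(1, len(hit_seq)))
    if len(hit_seq) >= 0.3 * len(consensus):
        # a genuine fragment matches a contiguous stretch of the consensus
        infix = edlib.align(hit_seq, consensus, mode="HW")
        ident = 1.0 - infix["editDistance"] / max(1, len(hit_seq))
        if ident >= min_identity:
            return "partial", ident
    return None


def _scan_one_strand(
    seq: str,
    codes: np.ndarray,
    sorted_kmers: np.ndarray,
    kmer_pos: np.ndarray,
    family: ElementFamily,
    consensus: str,
    strand: str,
    genome_label: str,
    min_identity: float,
    min_coverage: float,
    seed_k: int,
) -> list[ElementHit]:
    cons_codes = _kmers.encode(consensus)
    cv, cvalid = _kmers.kmer_values(cons_codes, seed_k)
    cpos = np.flatnonzero(cvalid)
    if len(cpos) == 0:
        return []
    cvv = cv[cpos]
    lo = np.searchsorted(sorted_kmers, cvv, side="left")
    hi = np.searchsorted(sorted_kmers, cvv, side="right")
    g_list, c_list = [], []
    for i in range(len(cvv)):
        if hi[i] > lo[i]:
            g = kmer_pos[lo[i] : hi[i]]
            g_list.append(g)
            c_list.append(np.full(len(g), cpos[i]))
    if not g_list:
        return []
    gpos = np.concatenate(g_list)
    cpos_m = np.concatenate(c_list)
    order = np.argsort(gpos, kind="stable")
    gpos, cpos_m = gpos[order], cpos_m[order]
    L = len(consensus)
    hits: list[ElementHit] = []
    i = 0
    n = len(gpos)
    while i < n:
        j = i + 1
        while j < n and gpos[j] - gpos[j - 1] <= L:
            j += 1
        # candidate boundaries: an infix alignment of the consensus into the
        # seed window (best for complete copies), and the raw seed span
        # (best for terminal-only remnants, where the infix alignment would
        # stretch the absent core over unrelated sequence)
        win_lo = max(0, int(gpos[i:j].min() - cpos_m[i:j].max()) - 30)
        win_hi = min(len(seq), int((gpos[i:j] - cpos_m[i:j]).max()) + L + 30)
        window = seq[win_lo:win_hi]
        candidates: list[tuple[int, int]] = []
        res = edlib.align(consensus, window, mode="HW", task="locations")
        if res["locations"]:
            t0, t1 = res["locations"][0]
            candidates.append((win_lo + t0, win_lo + t1 + 1))
        candidates.append((int(gpos[i:j].min()), int(gpos[j - 1]) + seed_k))
        rank = {"complete": 2, "terminal_only": 1, "partial": 0}
        best_hit: Optional[ElementHit] = None
        for start, end in dict.fromkeys(candidates):
            cls = _classify_hit(seq[start:end], consensus, family, min_identity, min_coverage)
            if cls is None:
                continue
            completeness, ident = cls
            cand = ElementHit(
                family=family,
                genome=genome_label,
                start=start,
                end=end,
                strand=strand,
                completeness=completeness,
                identity=ident,
            )
            if best_hit is None or (rank[cand.completeness], cand.identity) > (
                rank[best_hit.completeness],
                best_hit.identity,
            ):
                best_hit = cand
        if best_hit is not None:
            hits.append(best_hit)
        i = j
    return hits


def locate_elements(
    genome: Genome,
    catalog: Sequence[ElementFamily],
    min_identity: float = 0.80,
    min_coverage: float = 0.90,
    genome_label: str = "A",
    seed_k: int = 12,
    both_strands: bool = True,
) -> list[ElementHit]:
    """Seed-and-extend matching of catalog family consensi against one
    genome.  Overlapping hits of the same family are merged (best kept);
    completeness is complete / partial / terminal_only."""
    if not catalog:
        return []
    codes = _kmers.encode(genome.sequence)
    v, valid = _kmers.kmer_values(codes, seed_k)
    pos = np.flatnonzero(valid)
    vv = v[pos]
    order = np.argsort(vv, kind="stable")
    sorted_kmers, kmer_pos = vv[order], pos[order]
    hits: list[ElementHit] = []
    for fam in catalog:
        fam_hits: list[ElementHit] = []
        strands = [("+", fam.consensus)]
        if both_strands:
            strands.append(("-", _kmers.revcomp(fam.consensus)))
        for strand, consensus in strands:
            fam_hits.extend(
                _scan_one_strand(
                    genome.sequence,
                    codes,
                    sorted_kmers,
                    kmer_pos,
                    fam,
                    consensus,
                    strand,
                    genome_label,
                    min_identity,
                    min_coverage,
                    seed_k,
                )
            )
        # merge overlaps within the family, keeping the better hit
        fam_hits.sort(key=lambda h: (h.start, -(h.end - h.start)))
        merged: list[ElementHit] = []
        for h in fam_hits:
            if merged and h.start < merged[-1].end:
                prev = merged[-1]
                rank = {"complete": 2, "terminal_only": 1, "partial": 0}
                if (rank[h.completeness], h.identity, h.length) > (
                    rank[prev.completeness],
                    prev.identity,
                    prev.length,
                ):
                    merged[-1] = h
                continue
            merged.append(h)
        hits.extend(merged)
    hits.sort(key=lambda h: h.start)
    return hits


# ---------------------------------------------------------------------------
# SSEI calling


def _reciprocal_overlap(a0: int, a1: int, b0: int, b1: int) -> float:
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return inter / max(a1 - a0, b1 - b0)


def call_ssei(
    cmap: ComparisonMap,
    hitsA: Sequence[ElementHit],
    hitsB: Sequence[ElementHit],
    regions: Sequence[Connector],
    min_reciprocal: float = 0.90,
    td_slack: int = 5,
) -> None:
    """Assign each hit a status in place: SSEI (the element interrupts a
    sequence that is contiguous in the other strain), common (an equivalent
    hit occupies the aligned position in the other genome), or within_indel
    (nested inside a larger strain-specific region).

    An SSEI's region must coincide with the hit (>= ``min_reciprocal``
    reciprocal overlap, boundaries modulo junction-repeat shift, absorbed
    here by a small pad) and the other side of the region must not exceed
    the family's maximum target duplication plus ``td_slack``.
    """
    regs = list(regions)

    def classify(hits_self, hits_other, side: str, project) -> None:
        other_sorted = sorted(hits_other, key=lambda h: h.start)
        other_starts = [h.start for h in other_sorted]
        for h in hits_self:
            h.status = None
            # SSEI: region coinciding with the hit
            for r in regs:
                if side == "A":
                    r0, r1, other_len = r.startA, r.endA, r.lenB
                else:
                    r0, r1, other_len = r.startB, r.endB, r.lenA
                pad = h.family.max_td + td_slack
                ov = _reciprocal_overlap(h.start, h.end, r0, r1)
                if ov >= min_reciprocal and other_len <= h.family.max_td + td_slack:
                    h.status = "SSEI"
                    break
                # nested strictly inside a larger region
                if r0 < h.start and h.end < r1 and (r1 - r0) > (h.end - h.start) + pad:
                    h.status = "within_indel"
                    break
            if h.status is not None:
                continue
            # common: same-family hit at the aligned position in the other genome
            p0, p1 = project(h.start), project(h.end)
            import bisect

            i = bisect.bisect_left(other_starts, p0 - 2 * h.length) if other_starts else 0
            found = False
            for oh in other_sorted[i:]:
                if oh.start > p1 + h.length:
                    break
                if oh.family.code == h.family.code and _reciprocal_overlap(
                    p0, p1, oh.start, oh.end
                ) >= 0.5:
                    found = True
                    break
            h.status = "common" if found else "unresolved"

    def a_to_b(p: int) -> int:
        return cmap.project_a_to_b(p)

    # projection B->A via a swapped view of the runs
    runsB = sorted(cmap.runs(), key=lambda r: r.startB)
    startsB = [r.startB for r in runsB]

    def b_to_a(p: int) -> int:
        import bisect

        if not runsB:
            return min(p, len(cmap.genomeA.sequence))
        i = bisect.bisect_right(startsB, p) - 1
        if i < 0:
            return max(0, runsB[0].startA - (runsB[0].startB - p))
        r = runsB[i]
        if p < r.endB:
            return r.startA + (p - r.startB)
        if i + 1 < len(runsB):
            return min(r.endA + (p - r.endB), runsB[i + 1].startA)
        return min(r.endA + (p - r.endB), len(cmap.genomeA.sequence))

    classify(hitsA, hitsB, "A", a_to_b)
    classify(hitsB, hitsA, "B", b_to_a)


def detect_target_duplication(
    cmap: ComparisonMap, ssei_hit: ElementHit, region: Connector
) -> int:
    """Length of the target duplication flanking an SSEI (0 when none):
    the maximal exact direct repeat at the insertion junction that exists
    as a single copy at the aligned site in the other strain."""
    fl = flanking_direct_repeat(cmap, region, min_len=1)
    if fl is None or not fl.exact:
        return 0
    td = fl.repeat_len
    ssei_hit.td_len = td
    return td


# ---------------------------------------------------------------------------
# targeting matrix


@dataclass
class TargetingMatrix:
    """6x6 count table of element-in-element insertions: rows = category of
    the inserted (inner) element, columns = category of the host."""

    counts: pd.DataFrame

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "TargetingMatrix":
        counts = counts.reindex(index=CATEGORIES, columns=CATEGORIES, fill_value=0)
        return cls(counts.astype(int))

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.values.sum())

    def with_margins(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["Total"] = self.row_totals
        out.loc["Total"] = out.sum(axis=0)
        return out


def targeting_matrix(
    hitsA: Sequence[ElementHit], hitsB: Sequence[ElementHit]
) -> TargetingMatrix:
    """Count every hit strictly nested inside another hit (>= 1 bp of host
    on both sides), summed over both genomes; the smallest containing host
    is credited."""
    counts = pd.DataFrame(0, index=CATEGORIES, columns=CATEGORIES, dtype=int)
    for hits in (hitsA, hitsB):
        hs = sorted(hits, key=lambda h: (h.start, -(h.end - h.start)))
        for inner in hs:
            host = None
            for h in hs:
                if h is inner:
                    continue
                if h.start < inner.start and inner.end < h.end:
                    if host is None or (h.end - h.start) < (host.end - host.start):
                        host = h
            if host is not None:
                counts.loc[inner.family.category, host.family.category] += 1
    return TargetingMatrix.from_counts(counts)


# ---------------------------------------------------------------------------
# element core deletions


def detect_core_deletion(
    hit_pair: tuple[ElementHit, ElementHit],
    cmap: Optional[ComparisonMap] = None,
    region: Optional[Connector] = None,
) -> tuple[bool, Optional[RepeatFlank]]:
    """True when one hit of an aligned same-family pair is complete and the
    other is terminal-only, with a junction direct repeat consistent with a
    repeat-mediated core deletion (the core and one copy of the terminal
    repeat have been removed, fusing the termini)."""
    h1, h2 = hit_pair
    if h1.family.code != h2.family.code:
        return False, None
    comps = {h1.completeness, h2.completeness}
    if comps != {"complete", "terminal_only"}:
        return False, None
    fl = None
    if cmap is not None and region is not None:
        fl = flanking_direct_repeat(cmap, region, min_len=4)
        if fl is None:
            return False, None
    return True, fl
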