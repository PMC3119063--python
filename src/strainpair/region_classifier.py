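"""Classification of strain-specific regions into the category taxonomy:
mobile-element insertions, element core deletions, repeat switches, tandem
("polyrepeat") copy-number changes, deletion-coupled insertions (DCIs:
unrelated sequences, each at least 20 bp, at exactly the same aligned
position), and plain indels; with size classes short (< 150 bp), medium
(150 bp - 1.5 kb) and long (> 1.5 kb).

Precedence.  The most specific signatures are tested first: an element
core deletion (complete element in one strain, fused-terminal remnant in
the other) would also satisfy the plain element-insertion test, since the
region is mostly covered by the element hit, so it must be recognised
before the generic MGE rule; the generic ordering then follows with MGE,
switch_repeat, polyrepeat, DCI, and indel as the fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .mge_analysis import ElementHit, detect_core_deletion
from .repeat_deletion import flanking_direct_repeat
from .run_connector import ComparisonMap, Connector
from .seq_io import RegionRecord

__all__ = [
    "ClassifierConfig",
    "categorize",
    "detect_polyrepeat",
    "polarize",
    "build_region_records",
]

SIZE_SHORT = 150
SIZE_LONG = 1500
DCI_MIN_SIDE = 20  # the published minimal cut-off for independent indel sides


@dataclass
class ClassifierConfig:
    dci_min_side: int = DCI_MIN_SIDE
    size_short: int = SIZE_SHORT
    size_long: int = SIZE_LONG
    mge_min_coverage: float = 0.80
    td_slack: int = 5
    poly_max_period: int = 50
    poly_min_coverage: float = 0.90
    poly_min_copy_identity: float = 0.80
    tetramer_z_cut: float = 3.0


def _size_class(n: int, cfg: ClassifierConfig) -> str:
    if n < cfg.size_short:
        return "short"
    if n <= cfg.size_long:
        return "medium"
    return "long"


# ---------------------------------------------------------------------------
# polyrepeat detection


@dataclass(frozen=True)
class Polyrepeat:
    unit: str
    period: int
    copiesA: float
    copiesB: float


def _tandem_period(seq: str, max_period: int, min_coverage: float, min_copy_identity: float
                   ) -> Optional[tuple[str, int]]:
    """Smallest period whose tandem repetition explains the sequence:
    at least two full copies, covering >= min_coverage of the sequence,
    each copy >= min_copy_identity identical to the consensus unit."""
    n = len(seq)
    for p in range(1, min(max_period, n // 2) + 1):
        ncopies = n // p
        if ncopies < 2 or ncopies * p < min_coverage * n:
            continue
        copies = [seq[i * p : (i + 1) * p] for i in range(ncopies)]
        unit = "".join(
            max("ACGTN", key=lambda b: sum(c[j] == b for c in copies)) for j in range(p)
        )
        ok = all(
            sum(a == b for a, b in zip(c, unit)) >= min_copy_identity * p for c in copies
        )
        if ok:
            return unit, p
    return None


def _count_flank_copies(flank: str, unit: str, from_end: bool) -> int:
    """Number of additional unit copies continuing into a flank."""
    p = len(unit)
    count = 0
    while count <= 10_000:
        if from_end:
            e = len(flank) - count * p
            s = e - p
            if s < 0:
                break
            seg = flank[s:e]
        else:
            seg = flank[count * p : (count + 1) * p]
        if len(seg) < p or sum(a == b for a, b in zip(seg, unit)) < 0.8 * p:
            break
        count += 1
    return count


def detect_polyrepeat(
    sideA: str,
    sideB: str,
    flanks: tuple[str, str] = ("", ""),
    cfg: Optional[ClassifierConfig] = None,
) -> Optional[Polyrepeat]:
    """Detect a tandem copy-number difference between the two sides.

    Both sides must be explained by the same short unit (period 1-50,
    >= 90% coverage, copies >= 80% identical to the consensus); when one
    side is empty, the flanking sequence must itself continue the array
    (otherwise there is no repeat context and the region is a plain indel).
    An exact insertion/deletion point within a tandem array is undefined;
    only the unit and the copy numbers are meaningful.
    """
    cfg = cfg or ClassifierConfig()
    left_flank, right_flank = flanks
    if not sideA and not sideB:
        return None
    primary = sideA if len(sideA) >= len(sideB) else sideB
    res = _tandem_period(
        primary, cfg.poly_max_period, cfg.poly_min_coverage, cfg.poly_min_copy_identity
    )
    if res is None:
        return None
    unit, p = res
    other = sideB if primary is sideA else sideA
    if other:
        res2 = _tandem_period(
            other, cfg.poly_max_period, cfg.poly_min_coverage, cfg.poly_min_copy_identity
        )
        if res2 is None or res2[1] != p:
            return None
        # units must match up to rotation
        if res2[0] not in unit + unit:
            return None
    else:
        # one side empty: the array must continue into a flank
        if _count_flank_copies(left_flank, unit, from_end=True) < 1 and _count_flank_copies(
            right_flank, unit, from_end=False
        ) < 1:
            return None
    flank_copies = _count_flank_copies(left_flank, unit, from_end=True) + _count_flank_copies(
        right_flank, unit, from_end=False
    )
    copiesA = len(sideA) / p + flank_copies
    copiesB = len(sideB) / p + flank_copies
    return Polyrepeat(unit=unit, period=p, copiesA=copiesA, copiesB=copiesB)


# ---------------------------------------------------------------------------
# categorization


def _covering_hits(
    start: int, end: int, hits: Sequence[ElementHit], min_coverage: float
) -> list[ElementHit]:
    """Hits overlapping [start, end); returned when their union covers at
    least min_coverage of the interval."""
    if end <= start:
        return []
    sel = [h for h in hits if h.start < end and h.end > start]
    if not sel:
        return []
    covered = 0
    prev_end = start
    for h in sorted(sel, key=lambda h: h.start):
        lo = max(prev_end, h.start)
        hi = min(end, h.end)
        if hi > lo:
            covered += hi - lo
            prev_end = hi
    if covered >= min_coverage * (end - start):
        rank = {"complete": 2, "terminal_only": 1, "partial": 0}
        return sorted(
            sel,
            key=lambda h: (
                -(min(end, h.end) - max(start, h.start)),
                -rank[h.completeness],
                -h.identity,
            ),
        )
    return []


def _mge_category(hit: ElementHit) -> str:
    if hit.family.category in ("TP_A", "TP_B"):
        return "MGE_transposon"
    return "MGE_repeat"


def categorize(
    region: Connector,
    cmap: ComparisonMap,
    hitsA: Sequence[ElementHit],
    hitsB: Sequence[ElementHit],
    cfg: Optional[ClassifierConfig] = None,
) -> tuple[str, dict]:
    """Assign the region a category; returns (category, details).

    The category is a size-classed name (e.g. ``DCI_long``,
    ``indel_short``) or one of ``MGE_transposon``, ``MGE_repeat``,
    ``switch_repeat``, ``delete_repeatcore``, ``indel_polyrepeat``,
    ``misc``.  ``details`` carries the supporting evidence (element codes,
    polyrepeat unit, junction repeat).
    """
    cfg = cfg or ClassifierConfig()
    sa, sb = cmap.genomeA.sequence, cmap.genomeB.sequence
    size = _size_class(max(region.lenA, region.lenB), cfg)
    covA = _covering_hits(region.startA, region.endA, hitsA, cfg.mge_min_coverage)
    covB = _covering_hits(region.startB, region.endB, hitsB, cfg.mge_min_coverage)

    # (1) element core deletion: complete element spanning one side,
    # terminal-only remnant of the same family at the aligned site
    long_cov, short_hits, long_len, short_len = (
        (covA, hitsB, region.lenA, region.lenB)
        if region.lenA >= region.lenB
        else (covB, hitsA, region.lenB, region.lenA)
    )
    if long_cov:
        main = long_cov[0]
        if main.completeness == "complete":
            # the fused-terminal remnant in the other strain spans the
            # region's junction on the short side
            if region.lenA >= region.lenB:
                jstart, jend = region.startB, region.endB
            else:
                jstart, jend = region.startA, region.endA
            for oh in short_hits:
                if oh.family.code != main.family.code or oh.completeness != "terminal_only":
                    continue
                if oh.start - 5 <= jend and oh.end + 5 >= jstart:
                    ok, fl = detect_core_deletion((main, oh), cmap, region)
                    if ok:
                        return "delete_repeatcore", {"element": main.family.code, "repeat": fl}

    # (2) mobile element insertion: one side covered by element(s), the
    # other side at most a target duplication
    if covA and region.lenB <= max(h.family.max_td for h in covA) + cfg.td_slack:
        return _mge_category(covA[0]), {"element": covA[0].family.code, "side": "A"}
    if covB and region.lenA <= max(h.family.max_td for h in covB) + cfg.td_slack:
        return _mge_category(covB[0]), {"element": covB[0].family.code, "side": "B"}

    # (3) switch_repeat: both sides are catalog elements
    if covA and covB:
        a0, b0 = covA[0], covB[0]
        if a0.family.code != b0.family.code or a0.strand != b0.strand:
            return "switch_repeat", {"elementA": a0.family.code, "elementB": b0.family.code}

    # (4) polyrepeat
    flank = 200
    left = (
        sa[max(0, region.startA - flank) : region.startA]
        if region.lenA >= region.lenB
        else sb[max(0, region.startB - flank) : region.startB]
    )
    right = (
        sa[region.endA : region.endA + flank]
        if region.lenA >= region.lenB
        else sb[region.endB : region.endB + flank]
    )
    poly = detect_polyrepeat(
        sa[region.startA : region.endA],
        sb[region.startB : region.endB],
        (left, right),
        cfg,
    )
    if poly is not None:
        return "indel_polyrepeat", {"polyrepeat": poly}

    # (5) DCI: both sides at least the minimal indel cut-off
    if min(region.lenA, region.lenB) >= cfg.dci_min_side:
        return f"DCI_{size}", {}

    # (6) plain indel
    return f"indel_{size}", {}


# ---------------------------------------------------------------------------
# polarity (insertion vs deletion)


def polarize(
    region: Connector,
    cmap: ComparisonMap,
    category: str,
    details: dict,
    tetramer_z: Optional[float] = None,
    z_cut: float = 3.0,
) -> str:
    """Decide insertion vs deletion for a region, in rule order: a junction
    direct repeat marks a deletion in the strain carrying the single copy;
    a catalog element marks an insertion in the carrier; a strongly
    deviant composition marks an insertion of foreign DNA; otherwise
    unknown."""
    if category.startswith("MGE"):
        side = details.get("side", "A" if region.lenA >= region.lenB else "B")
        return f"insertion_in_{side}"
    fl = details.get("repeat")
    if fl is None:
        fl = flanking_direct_repeat(cmap, region, min_len=4)
    if fl is not None and fl.exact and min(region.lenA, region.lenB) == 0:
        # the strain with the short side kept only one repeat copy
        lost = "B" if region.lenA >= region.lenB else "A"
        return f"deletion_in_{lost}"
    if tetramer_z is not None and tetramer_z > z_cut:
        carrier = "A" if region.lenA >= region.lenB else "B"
        return f"insertion_in_{carrier}"
    return "unknown"


# ---------------------------------------------------------------------------
# report assembly


def build_region_records(
    cmap: ComparisonMap,
    regions: Sequence[Connector],
    hitsA: Sequence[ElementHit] = (),
    hitsB: Sequence[ElementHit] = (),
    cfg: Optional[ClassifierConfig] = None,
) -> list[RegionRecord]:
    """Classify every strain-specific region and build report rows
    (1-based inclusive coordinates, junction-repeat overlap and deleted
    total where applicable)."""
    cfg = cfg or ClassifierConfig()
    records: list[RegionRecord] = []
    for i, region in enumerate(sorted(regions, key=lambda c: c.startA), start=1):
        category, details = categorize(region, cmap, hitsA, hitsB, cfg)
        fl = details.get("repeat")
        if fl is None:
            fl = flanking_direct_repeat(cmap, region, min_len=4)
        overlap = fl.repeat_len if fl is not None and fl.exact else 0
        total = max(region.lenA, region.lenB) if overlap else 0
        polarity = polarize(region, cmap, category, details)
        location = "in_element" if "element" in details or "elementA" in details else "unknown"
        desc_bits = []
        if "element" in details:
            desc_bits.append(details["element"])
        if "polyrepeat" in details:
            p = details["polyrepeat"]
            desc_bits.append(
                f"unit={p.unit} copiesA={p.copiesA:.1f} copiesB={p.copiesB:.1f}"
            )
        if fl is not None and fl.exact:
            desc_bits.append(f"junction_repeat={fl.repeat_seq}")
        records.append(
            RegionRecord(
                region_number=i,
                category=category,
                posA=region.startA + 1,
                lenA=region.lenA,
                posB=region.startB + 1,
                lenB=region.lenB,
                overlap=overlap,
                sum=total,
                location=location,
                polarity=polarity,
                description="; ".join(desc_bits),
            )
        )
    return records
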