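"""Synthetic strain pairs with planted, logged events.

The generator emulates the situation the pipeline is built for: two
descendants of a recent common ancestor that differ by scattered single-
base substitutions (default divergence 1.4%, i.e. shared-sequence identity
98.6%) and a configurable set of discrete events -- strain-specific
indels, deletion-coupled insertions (unrelated sequences at exactly the
same position, each side at least 20 bp), repeat-mediated deletions
(direct repeat of 4-22 bp flanking a deleted core), tandem copy-number
("polyrepeat") changes, mobile-element insertions with category-appropriate
target duplications, element core deletions, and common / nested elements
for targeting statistics.  Every event is logged with its exact final
coordinates in both strains, so pipeline output can be scored against
ground truth and the simulator can be replayed as its own oracle.

Planted junctions are made unambiguous: the bases at each payload boundary
are constrained to differ from their neighbours (otherwise the planted
repeat length or breakpoint would genuinely be a different one -- a
shifted, equally valid description of the same pair of sequences), and
substitutions keep a safety margin away from event junctions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kmers
from .mge_analysis import ElementFamily
from .seq_io import Genome, RegionRecord

__all__ = [
    "SimConfig",
    "EventTruth",
    "RecoveryMetrics",
    "default_catalog",
    "random_sequence",
    "generate_ancestor",
    "derive_strain_pair",
    "score_recovery",
    "deplete_tetramer",
]

_BASES = "ACGT"

DEFAULT_EVENT_COUNTS = {
    "indel_short": 8,
    "indel_medium": 6,
    "indel_long": 3,
    "dci_short": 4,
    "dci_medium": 4,
    "dci_long": 2,
    "repeat_deletion": 8,
    "polyrepeat": 5,
    "mge_ssei": 8,
    "element_core_deletion": 2,
}

DEFAULT_SIZE_CLASSES = {
    "short": (20, 149),
    "medium": (150, 1500),
    "long": (1501, 8000),
}


@dataclass
class SimConfig:
    """Study conditions of the simulation.

    ``substitution_rate`` is the per-base probability of a single-base
    difference between the strains (each difference is assigned to one
    strain at random).  ``event_counts`` gives the number of planted events
    per category; ``indel_size_classes`` the size ranges (short/medium/
    long); ``repeat_len_range`` the direct-repeat lengths of planted
    repeat-mediated deletions.  ``common_elements``/``nested_elements``
    plant identical (optionally element-in-element) copies in both strains;
    they produce no strain-specific region but feed the targeting matrix.
    """

    ancestor_length: int = 300_000
    gc: float = 0.478
    substitution_rate: float = 0.014
    event_counts: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_COUNTS))
    indel_size_classes: dict = field(default_factory=lambda: dict(DEFAULT_SIZE_CLASSES))
    repeat_len_range: tuple[int, int] = (4, 22)
    core_len_range: tuple[int, int] = (30, 500)
    poly_period_range: tuple[int, int] = (3, 8)
    min_spacing: int = 100
    sub_margin: int = 30
    common_elements: int = 0
    nested_elements: int = 0
    catalog: Optional[list[ElementFamily]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate <= 1 or not 0 <= self.gc <= 1:
            raise ValueError("rates must be in [0,1]")


@dataclass
class EventTruth:
    """Ground truth for one planted event.

    ``posA``/``lenA``/``posB``/``lenB`` are the expected strain-specific
    region in final (0-based) coordinates; ``shift_slack`` is the junction
    ambiguity (direct-repeat / tandem-phase) within which a reported
    boundary is still exact.  ``payload_a``/``payload_b``/``consumed``
    allow byte-exact replay of the event on the ancestor.
    """

    event_id: int
    kind: str
    category: str  # expected region category ('' when expects_region is False)
    strain_affected: str  # 'A', 'B' or 'AB'
    ancestor_pos: int
    posA: int
    lenA: int
    posB: int
    lenB: int
    repeat_len: int = 0
    element_code: Optional[str] = None
    td_len: int = 0
    expects_region: bool = True
    shift_slack: int = 0
    payload_a: str = ""
    payload_b: str = ""
    consumed: int = 0
    region_offset: int = 0  # region start relative to payload start


# ---------------------------------------------------------------------------
# raw sequence helpers


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.478) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(_BASES), size=length, p=p))


def generate_ancestor(cfg: SimConfig) -> Genome:
    """I.i.d. ancestral genome at the target G+C, deterministic under the
    config seed."""
    if cfg.ancestor_length < 10_000:
        raise ValueError("ancestor must be at least 10 kb")
    rng = np.random.default_rng(cfg.seed)
    return Genome("ancestor", random_sequence(rng, cfg.ancestor_length, cfg.gc), "circular")


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[rng.integers(0, 3)]


def _force_boundary(rng: np.random.Generator, payload: str, first_not: str, last_not: str) -> str:
    """Resample the payload's first/last base so they differ from the given
    neighbour bases (keeps the planted junction unambiguous)."""
    p = list(payload)
    if p and p[0] == first_not:
        p[0] = _other_base(rng, first_not)
    if p and p[-1] == last_not:
        p[-1] = _other_base(rng, last_not)
    return "".join(p)


# ---------------------------------------------------------------------------
# default element catalog (synthetic families, one per category trait set)


def _palindrome(rng: np.random.Generator, half: int, gc: float) -> str:
    h = random_sequence(rng, half, gc)
    return h + _kmers.revcomp(h)


def default_catalog(seed: int = 197) -> list[ElementFamily]:
    """A synthetic element catalog covering the six MGE categories with
    their characteristic features: a canonical transposon (TP-B, ITRs,
    target duplications of 5-8 bp), a MITE sharing the transposon's ITR
    (TDs of 4-6 bp), an IS605-type transposon (TP-A, near-terminal
    palindromes, no TDs), a PATE whose near-terminal palindromes form an
    exact 22 bp direct repeat (so that repeat-mediated core deletion
    shortens the 390 bp element to a 52 bp fused-terminal remnant), and
    small mobile repeats of types A and B (ITRs, no TDs).

    The catalog is deterministic under its own seed, independent of the
    simulation seed.
    """
    rng = np.random.default_rng(seed)
    gc = 0.478
    fams: list[ElementFamily] = []

    itr = random_sequence(rng, 20, gc)
    fams.append(
        ElementFamily(
            "TPB1", "TP_B", itr + random_sequence(rng, 910, gc) + _kmers.revcomp(itr),
            itr=itr, td_range=(5, 8),
        )
    )
    fams.append(
        ElementFamily(
            "MITE1", "MITE", itr + random_sequence(rng, 240, gc) + _kmers.revcomp(itr),
            itr=itr, td_range=(4, 6),
        )
    )
    pal5 = _palindrome(rng, 8, gc)
    pal3 = _palindrome(rng, 8, gc)
    fams.append(
        ElementFamily(
            "TPA1", "TP_A",
            random_sequence(rng, 6, gc) + pal5 + random_sequence(rng, 1148, gc)
            + pal3 + random_sequence(rng, 6, gc),
        )
    )
    # PATE: a(15) + R(22) + core(316) + R(22) + b(15) = 390; core deletion
    # removes core plus one R copy -> 52 bp remnant a+R+b
    rep = _palindrome(rng, 11, gc)
    a = random_sequence(rng, 15, gc)
    b = random_sequence(rng, 15, gc)
    core = random_sequence(rng, 316, gc)
    core = _force_boundary(rng, core, first_not=b[0], last_not=a[-1])
    fams.append(ElementFamily("PATE1", "PATE", a + rep + core + rep + b))
    for code in ("SMRA1", "SMRA2"):
        itr_s = random_sequence(rng, 14, gc)
        fams.append(
            ElementFamily(
                code, "SMR_A", itr_s + random_sequence(rng, 82, gc) + _kmers.revcomp(itr_s),
                itr=itr_s,
            )
        )
    itr_b = random_sequence(rng, 12, gc)
    fams.append(
        ElementFamily(
            "SMRB1", "SMR_B", itr_b + random_sequence(rng, 56, gc) + _kmers.revcomp(itr_b),
            itr=itr_b,
        )
    )
    return fams


def pate_remnant(fam: ElementFamily) -> tuple[str, int, int]:
    """Fused-terminal remnant of the PATE-style family after repeat-mediated
    core deletion, plus (repeat_len, lead_len)."""
    if fam.code != "PATE1":
        raise ValueError("core-deletion remnants are defined for the PATE1 family")
    a_len, r_len, b_len = 15, 22, 15
    cons = fam.consensus
    remnant = cons[: a_len + r_len] + cons[-b_len:]
    return remnant, r_len, a_len


# ---------------------------------------------------------------------------
# event construction


def _size_class_of(n: int) -> str:
    if n < 150:
        return "short"
    if n <= 1500:
        return "medium"
    return "long"


def _build_events(cfg: SimConfig, rng: np.random.Generator, anc: str) -> list[EventTruth]:
    """Draw payloads and geometry for every configured event (positions
    assigned later)."""
    catalog = cfg.catalog if cfg.catalog is not None else default_catalog()
    by_cat: dict[str, list[ElementFamily]] = {}
    for f in catalog:
        by_cat.setdefault(f.category, []).append(f)
    events: list[EventTruth] = []
    eid = 0

    def new(**kw) -> EventTruth:
        nonlocal eid
        eid += 1
        return EventTruth(event_id=eid, ancestor_pos=-1, posA=-1, posB=-1, lenA=0, lenB=0, **kw)

    for kind, count in cfg.event_counts.items():
        for _ in range(count):
            strain = "A" if rng.random() < 0.5 else "B"
            if kind.startswith("indel_"):
                size_cls = kind.split("_", 1)[1]
                lo, hi = cfg.indel_size_classes[size_cls]
                n = int(rng.integers(lo, hi + 1))
                is_insert = rng.random() < 0.5
                if is_insert:
                    ev = new(
                        kind="indel_insertion",
                        category=f"indel_{_size_class_of(n)}",
                        strain_affected=strain,
                        payload_a=random_sequence(rng, n, cfg.gc) if strain == "A" else "",
                        payload_b=random_sequence(rng, n, cfg.gc) if strain == "B" else "",
                    )
                else:
                    ev = new(
                        kind="indel_deletion",
                        category=f"indel_{_size_class_of(n)}",
                        strain_affected=strain,
                        consumed=n,
                    )
                events.append(ev)
            elif kind.startswith("dci_"):
                size_cls = kind.split("_", 1)[1]
                lo, hi = cfg.indel_size_classes[size_cls]
                la = int(rng.integers(max(lo, 20), hi + 1))
                lb = int(rng.integers(max(lo, 20), hi + 1))
                ev = new(
                    kind="dci",
                    category=f"DCI_{_size_class_of(max(la, lb))}",
                    strain_affected="AB",
                    payload_a=random_sequence(rng, la, cfg.gc),
                    payload_b=random_sequence(rng, lb, cfg.gc),
                )
                events.append(ev)
            elif kind == "repeat_deletion":
                r = int(rng.integers(cfg.repeat_len_range[0], cfg.repeat_len_range[1] + 1))
                c = int(rng.integers(cfg.core_len_range[0], cfg.core_len_range[1] + 1))
                rep = random_sequence(rng, r, cfg.gc)
                core = random_sequence(rng, c, cfg.gc)
                retained = rep + core + rep
                ev = new(
                    kind="repeat_deletion",
                    category=f"indel_{_size_class_of(c + r)}",
                    strain_affected="B" if strain == "A" else "A",  # deletion in the other strain
                    payload_a=retained if strain == "A" else rep,
                    payload_b=retained if strain == "B" else rep,
                    repeat_len=r,
                    shift_slack=r,
                    region_offset=r,
                )
                events.append(ev)
            elif kind == "polyrepeat":
                p = int(rng.integers(cfg.poly_period_range[0], cfg.poly_period_range[1] + 1))
                delta = max(2, math.ceil(24 / p))
                n_min = int(rng.integers(2, 5))
                unit = random_sequence(rng, p, cfg.gc)
                big, small = unit * (n_min + delta), unit * n_min
                ev = new(
                    kind="polyrepeat",
                    category="indel_polyrepeat",
                    strain_affected=strain,
                    payload_a=big if strain == "A" else small,
                    payload_b=big if strain == "B" else small,
                    shift_slack=(n_min + 1) * p,
                    region_offset=n_min * p,
                )
                events.append(ev)
            elif kind == "mge_ssei":
                fam = catalog[int(rng.integers(0, len(catalog)))]
                td = (
                    int(rng.integers(fam.td_range[0], fam.td_range[1] + 1))
                    if fam.td_range
                    else 0
                )
                ev = new(
                    kind="mge_ssei",
                    category="MGE_transposon" if fam.category in ("TP_A", "TP_B") else "MGE_repeat",
                    strain_affected=strain,
                    element_code=fam.code,
                    td_len=td,
                    shift_slack=td,
                )
                # payloads completed at placement time (TD copies ancestor bases)
                events.append(ev)
            elif kind == "element_core_deletion":
                fam = next(f for f in catalog if f.code == "PATE1")
                remnant, r, lead = pate_remnant(fam)
                ev = new(
                    kind="element_core_deletion",
                    category="delete_repeatcore",
                    strain_affected="B" if strain == "A" else "A",
                    payload_a=fam.consensus if strain == "A" else remnant,
                    payload_b=fam.consensus if strain == "B" else remnant,
                    element_code=fam.code,
                    repeat_len=r,
                    shift_slack=r,
                    region_offset=lead + r,
                )
                events.append(ev)
            else:
                raise ValueError(f"unknown event kind {kind!r}")

    for _ in range(cfg.common_elements):
        fam = catalog[int(rng.integers(0, len(catalog)))]
        events.append(
            new(
                kind="common_element",
                category="",
                strain_affected="AB",
                element_code=fam.code,
                payload_a=fam.consensus,
                payload_b=fam.consensus,
                expects_region=False,
            )
        )
    hosts = [f for f in catalog if f.category in ("PATE", "TP_A", "TP_B")]
    inners = [f for f in catalog if f.category in ("SMR_A", "SMR_B", "MITE")]
    for _ in range(cfg.nested_elements):
        host = hosts[int(rng.integers(0, len(hosts)))]
        inner = inners[int(rng.integers(0, len(inners)))]
        mid = len(host.consensus) // 2 + int(rng.integers(-20, 21))
        payload = host.consensus[:mid] + inner.consensus + host.consensus[mid:]
        events.append(
            new(
                kind="nested_element",
                category="",
                strain_affected="AB",
                element_code=f"{inner.code}>{host.code}",
                payload_a=payload,
                payload_b=payload,
                expects_region=False,
            )
        )
    return events


def _place_events(
    cfg: SimConfig, rng: np.random.Generator, anc: str, events: list[EventTruth]
) -> None:
    """Assign ancestral positions: uniform draws stretched so that event
    footprints stay at least ``min_spacing`` apart."""
    if not events:
        return
    rng.shuffle(events)  # placement order independent of construction order
    pad = cfg.min_spacing
    total_footprint = sum(e.consumed for e in events)
    overhead = 2 * pad + total_footprint + (len(events) - 1) * cfg.min_spacing
    free = len(anc) - overhead
    if free <= 0:
        biggest = max(events, key=lambda e: e.consumed + max(len(e.payload_a), len(e.payload_b)))
        raise ValueError(
            f"planted events do not fit into the ancestor "
            f"(category {biggest.kind} is the largest contributor)"
        )
    cuts = np.sort(rng.integers(0, free + 1, size=len(events)))
    offset = pad
    for ev, cut in zip(events, cuts):
        ev.ancestor_pos = int(offset + cut)
        offset += ev.consumed + cfg.min_spacing
    events.sort(key=lambda e: e.ancestor_pos)


def _finalize_payloads(cfg: SimConfig, rng: np.random.Generator, anc: str, events: list[EventTruth]) -> None:
    """Complete position-dependent payloads and enforce junction
    unambiguity at every payload boundary."""
    catalog = cfg.catalog if cfg.catalog is not None else default_catalog()
    by_code = {f.code: f for f in catalog}
    for ev in events:
        pos = ev.ancestor_pos
        left = anc[pos - 1]
        right = anc[pos + ev.consumed] if pos + ev.consumed < len(anc) else ""

        def nudge_until(cond) -> None:
            # shift the site a few bases right until the fixed payload fits
            nonlocal pos, left, right
            tries = 0
            while not cond() and tries < 12:
                pos += 1
                left = anc[pos - 1]
                right = anc[pos + ev.consumed] if pos + ev.consumed < len(anc) else ""
                tries += 1
            ev.ancestor_pos = pos

        if ev.kind == "indel_insertion":
            pay = ev.payload_a or ev.payload_b
            pay = _force_boundary(rng, pay, first_not=right, last_not=left)
            if ev.payload_a:
                ev.payload_a = pay
            else:
                ev.payload_b = pay
        elif ev.kind == "indel_deletion":
            nudge_until(lambda: anc[pos] != anc[pos + ev.consumed]
                        and anc[pos - 1] != anc[pos + ev.consumed - 1])
            keep = anc[pos : pos + ev.consumed]
            if ev.strain_affected == "A":  # deletion in A: B keeps the segment
                ev.payload_b = keep
            else:
                ev.payload_a = keep
        elif ev.kind == "dci":
            # both inserts must differ from the flanks and from each other
            # at their first and last base (the breakpoint is exact)
            la = list(_force_boundary(rng, ev.payload_a, first_not=right, last_not=left))
            lb = list(_force_boundary(rng, ev.payload_b, first_not=right, last_not=left))
            while lb[0] == la[0] or lb[0] == right:
                lb[0] = _BASES[int(rng.integers(0, 4))]
            while lb[-1] == la[-1] or lb[-1] == left:
                lb[-1] = _BASES[int(rng.integers(0, 4))]
            ev.payload_a, ev.payload_b = "".join(la), "".join(lb)
        elif ev.kind == "repeat_deletion":
            # ...R core R... vs ...R...: the core must not extend the
            # repeat match into either flank
            big = ev.payload_a if len(ev.payload_a) >= len(ev.payload_b) else ev.payload_b
            r = ev.repeat_len
            core = list(big[r : len(big) - r])
            if core and core[0] == anc[pos]:
                core[0] = _other_base(rng, anc[pos])
            if core and core[-1] == anc[pos - 1]:
                core[-1] = _other_base(rng, anc[pos - 1])
            rebuilt = big[:r] + "".join(core) + big[:r]
            if len(ev.payload_a) >= len(ev.payload_b):
                ev.payload_a = rebuilt
            else:
                ev.payload_b = rebuilt
        elif ev.kind == "polyrepeat":
            big = ev.payload_a if len(ev.payload_a) >= len(ev.payload_b) else ev.payload_b
            nudge_until(lambda: anc[pos] != big[0] and anc[pos - 1] != big[-1])
        elif ev.kind == "mge_ssei":
            fam = by_code[ev.element_code]
            elem = fam.consensus
            td = ev.td_len
            nudge_until(
                lambda: elem[0] != anc[pos]
                and elem[-1] != anc[pos - td - 1]
                and (td == 0 or elem[-1] != anc[pos - 1])
            )
            payload = elem + (anc[pos - td : pos] if td else "")
            if ev.strain_affected == "A":
                ev.payload_a = payload
            else:
                ev.payload_b = payload
            ev.lenA = len(payload) if ev.strain_affected == "A" else 0
            ev.lenB = len(payload) if ev.strain_affected == "B" else 0
        elif ev.kind in ("common_element", "nested_element"):
            pay = ev.payload_a
            nudge_until(lambda: pay[0] != anc[pos] and pay[-1] != anc[pos - 1])
        elif ev.kind == "element_core_deletion":
            big = ev.payload_a if len(ev.payload_a) > len(ev.payload_b) else ev.payload_b
            nudge_until(lambda: big[0] != anc[pos] and big[-1] != anc[pos - 1])


def _draw_substitutions(
    cfg: SimConfig, rng: np.random.Generator, anc: str, events: list[EventTruth]
) -> list[EventTruth]:
    """Scatter single-base differences outside event exclusion zones."""
    n = len(anc)
    blocked = np.zeros(n, dtype=bool)
    for ev in events:
        lo = max(0, ev.ancestor_pos - cfg.sub_margin)
        hi = min(n, ev.ancestor_pos + ev.consumed + cfg.sub_margin)
        blocked[lo:hi] = True
    eligible = np.flatnonzero(~blocked)
    hit = eligible[rng.random(len(eligible)) < cfg.substitution_rate]
    subs: list[EventTruth] = []
    for i, pos in enumerate(hit):
        ref = anc[pos]
        alt = _other_base(rng, ref)
        strain = "A" if rng.random() < 0.5 else "B"
        subs.append(
            EventTruth(
                event_id=-1,
                kind="substitution",
                category="",
                strain_affected=strain,
                ancestor_pos=int(pos),
                posA=-1,
                lenA=0,
                posB=-1,
                lenB=0,
                expects_region=False,
                payload_a=alt if strain == "A" else ref,
                payload_b=alt if strain == "B" else ref,
                consumed=1,
            )
        )
    return subs


def derive_strain_pair(
    ancestor: Genome, cfg: SimConfig
) -> tuple[Genome, Genome, list[EventTruth]]:
    """Derive two strains from the ancestor with planted, logged events.

    Returns (GenomeA, GenomeB, truth).  The truth list contains every
    planted event, including individual substitutions; events with
    ``expects_region`` carry the expected strain-specific region in final
    coordinates of both strains.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    anc = ancestor.sequence
    events = _build_events(cfg, rng, anc)
    _place_events(cfg, rng, anc, events)
    _finalize_payloads(cfg, rng, anc, events)
    subs = _draw_substitutions(cfg, rng, anc, events)
    stream = sorted(events + subs, key=lambda e: e.ancestor_pos)

    partsA: list[str] = []
    partsB: list[str] = []
    curA = curB = 0
    prev = 0
    for ev in stream:
        seg = anc[prev : ev.ancestor_pos]
        partsA.append(seg)
        partsB.append(seg)
        curA += len(seg)
        curB += len(seg)
        # region coordinates in final frames
        if ev.expects_region:
            off = ev.region_offset
            la = len(ev.payload_a)
            lb = len(ev.payload_b)
            if ev.kind in ("repeat_deletion", "element_core_deletion", "polyrepeat"):
                long_len, short_len = max(la, lb), min(la, lb)
                ev.posA = curA + off
                ev.posB = curB + off
                if la >= lb:
                    ev.lenA, ev.lenB = long_len - short_len, 0
                else:
                    ev.lenA, ev.lenB = 0, long_len - short_len
            elif ev.kind == "indel_deletion":
                ev.posA, ev.posB = curA, curB
                ev.lenA = ev.consumed if ev.strain_affected == "B" else 0
                ev.lenB = ev.consumed if ev.strain_affected == "A" else 0
            else:
                ev.posA, ev.posB = curA, curB
                ev.lenA, ev.lenB = la, lb
        else:
            ev.posA, ev.posB = curA, curB
            if ev.kind != "substitution":
                ev.lenA, ev.lenB = len(ev.payload_a), len(ev.payload_b)
        if ev.kind == "substitution":
            partsA.append(ev.payload_a)
            partsB.append(ev.payload_b)
            curA += 1
            curB += 1
        elif ev.kind == "indel_deletion":
            partsA.append(ev.payload_a)
            partsB.append(ev.payload_b)
            curA += len(ev.payload_a)
            curB += len(ev.payload_b)
        else:
            partsA.append(ev.payload_a)
            partsB.append(ev.payload_b)
            curA += len(ev.payload_a)
            curB += len(ev.payload_b)
        prev = ev.ancestor_pos + ev.consumed
    tail = anc[prev:]
    partsA.append(tail)
    partsB.append(tail)
    A = Genome("strainA", "".join(partsA), ancestor.topology)
    B = Genome("strainB", "".join(partsB), ancestor.topology)
    return A, B, stream


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class RecoveryMetrics:
    sensitivity: float
    precision: float
    boundary_exact_fraction: float
    category_match_fraction: float
    fully_correct_fraction: float  # matched AND category AND boundary-exact, over all truth
    confusion: pd.DataFrame
    matched: int
    n_truth: int
    n_regions: int
    repeat_len_exact: Optional[float] = None  # among repeat-mediated deletions


def _reciprocal(a0: int, a1: int, b0: int, b1: int) -> float:
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return inter / max(a1 - a0, b1 - b0)


def score_recovery(
    records: Sequence[RegionRecord],
    truth: Sequence[EventTruth],
    min_reciprocal: float = 0.90,
) -> RecoveryMetrics:
    """Score pipeline regions against the planted truth.

    A truth event matches a reported region when the two intervals show at
    least ``min_reciprocal`` reciprocal overlap in the frame of the strain
    that carries the sequence.  A match is boundary-exact when all four
    coordinates agree after a common shift no larger than the event's
    junction ambiguity (repeat/tandem phase).
    """
    expected = [t for t in truth if t.expects_region]
    pairs: list[tuple[EventTruth, Optional[RegionRecord]]] = []
    used: set[int] = set()
    for t in expected:
        best = None
        best_ov = 0.0
        slack = max(t.shift_slack, 0)
        for j, r in enumerate(records):
            if j in used:
                continue
            r_posA, r_posB = r.posA - 1, r.posB - 1
            # boundaries are compared modulo the junction shift class: slide
            # the reported region by up to the event's ambiguity first
            if t.lenA >= t.lenB and t.lenA > 0:
                s = min(max(t.posA - r_posA, -slack), slack)
                ov = _reciprocal(t.posA, t.posA + t.lenA, r_posA + s, r_posA + s + r.lenA)
            elif t.lenB > 0:
                s = min(max(t.posB - r_posB, -slack), slack)
                ov = _reciprocal(t.posB, t.posB + t.lenB, r_posB + s, r_posB + s + r.lenB)
            else:
                ov = 0.0
            if ov > best_ov:
                best, best_ov = (j, r), ov
        if best is not None and best_ov >= min_reciprocal:
            used.add(best[0])
            pairs.append((t, best[1]))
        else:
            pairs.append((t, None))

    matched = sum(1 for _, r in pairs if r is not None)
    exact = 0
    cat_ok = 0
    fully = 0
    rep_total = rep_exact = 0
    rows = []
    for t, r in pairs:
        if r is None:
            rows.append((t.category, "missed"))
            continue
        rows.append((t.category, r.category))
        if r.category == t.category:
            cat_ok += 1
        slack = max(t.shift_slack, 0)
        r_posA, r_posB = r.posA - 1, r.posB - 1
        is_exact = False
        if r.lenA == t.lenA and r.lenB == t.lenB:
            s = r_posA - t.posA
            if abs(s) <= slack and (r_posB - t.posB) == s:
                exact += 1
                is_exact = True
        if is_exact and r.category == t.category:
            fully += 1
        if t.kind in ("repeat_deletion", "element_core_deletion"):
            rep_total += 1
            if r.overlap == t.repeat_len:
                rep_exact += 1
    confusion = (
        pd.DataFrame(rows, columns=["truth", "reported"])
        .value_counts()
        .unstack(fill_value=0)
        if rows
        else pd.DataFrame()
    )
    return RecoveryMetrics(
        sensitivity=matched / len(expected) if expected else 1.0,
        precision=matched / len(records) if records else (1.0 if not expected else 0.0),
        boundary_exact_fraction=exact / matched if matched else 0.0,
        category_match_fraction=cat_ok / matched if matched else 0.0,
        fully_correct_fraction=fully / len(expected) if expected else 1.0,
        confusion=confusion,
        matched=matched,
        n_truth=len(expected),
        n_regions=len(records),
        repeat_len_exact=(rep_exact / rep_total) if rep_total else None,
    )


# ---------------------------------------------------------------------------
# composition helpers for statistics tests


def deplete_tetramer(
    seq: str, motif: str, factor: float, rng: np.random.Generator, max_rounds: int = 20
) -> str:
    """Mutate occurrences of ``motif`` until its count drops by ``factor``
    (an approximation of a genome under strong word avoidance)."""
    target = seq.count(motif) / factor
    s = list(seq)
    for _ in range(max_rounds):
        text = "".join(s)
        positions = []
        i = text.find(motif)
        while i != -1:
            positions.append(i)
            i = text.find(motif, i + 1)
        if len(positions) <= target:
            break
        for p in positions:
            if rng.random() < 0.9:
                j = p + int(rng.integers(0, len(motif)))
                s[j] = _other_base(rng, s[j])
    return "".join(s)
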