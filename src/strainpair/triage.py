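"""Triage of connectors into trivial and non-trivial differences, and the
divergence filter that removes regions of merely enhanced sequence
variability from the non-trivial set.

A connector is non-trivial when any of three criteria fires, tested in
order: (a) the two sides differ in length by at least 20 bp; (b) the
connector contains more than 10 single-base differences (non-match columns
of a unit-cost optimal global alignment of its two sides); (c) the sequence
identity of the two sides is below 50%, evaluated only when both sides are
at least 7 bp long.

The divergence filter emulates a manual inspection step: each non-trivial
connector is re-aligned together with flanking context and dropped when the
alignment looks like a contiguous, moderately divergent stretch of the
shared backbone rather than a genuine replacement -- no long gap run, no
large length difference, decent identity over the flanked window, and the
two sides themselves still recognisably related.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .alignment import global_alignment
from .run_connector import ComparisonMap, Connector

__all__ = [
    "TriageConfig",
    "TriageResult",
    "classify_connector",
    "divergence_filter",
    "select_regions",
]


@dataclass
class TriageConfig:
    """Thresholds of the triage criteria and of the divergence filter.

    min_len_diff, max_diffs, min_identity and identity_min_len are the
    non-triviality criteria (a)-(c).  flank is the context added on each
    side before the filter alignment; a connector is dropped when the
    flanked alignment has no gap run >= drop_gap, a length difference
    < drop_gap, flanked identity >= drop_identity and region-only identity
    >= drop_region_identity.
    """

    min_len_diff: int = 20
    max_diffs: int = 10
    min_identity: float = 0.50
    identity_min_len: int = 7
    flank: int = 150
    drop_gap: int = 20
    drop_identity: float = 0.60
    drop_region_identity: float = 0.70
    ndiff_cap: int = 10_000

    def __post_init__(self) -> None:
        if min(self.min_len_diff, self.max_diffs, self.identity_min_len, self.flank, self.drop_gap) <= 0:
            raise ValueError("all triage thresholds must be positive")
        if not 0 < self.min_identity < 1:
            raise ValueError("min_identity must be in (0,1)")


@dataclass(frozen=True)
class TriageResult:
    non_trivial: bool
    criterion: Optional[str]  # 'a', 'b' or 'c'; None when trivial


def classify_connector(
    c: Connector, cfg: TriageConfig, seqA: str = "", seqB: str = ""
) -> TriageResult:
    """Apply criteria (a)-(c) in order; report the first that fires.

    Criteria (b) and (c) need the connector's alignment statistics, which
    are computed on demand from the genome sequences (huge connectors never
    get here without criterion (a) having fired first).
    """
    if abs(c.lenA - c.lenB) >= cfg.min_len_diff:
        return TriageResult(True, "a")
    st = c.stats(seqA, seqB, cfg.ndiff_cap)
    if st is None:
        # both sides > cap yet length-balanced: align anyway (rare)
        st = c.stats(seqA, seqB, max(c.lenA, c.lenB))
    if st.distance > cfg.max_diffs:
        return TriageResult(True, "b")
    if min(c.lenA, c.lenB) >= cfg.identity_min_len and st.identity < cfg.min_identity:
        return TriageResult(True, "c")
    return TriageResult(False, None)


def divergence_filter(
    c: Connector, seqA: str, seqB: str, cfg: TriageConfig
) -> str:
    """Return 'keep' or 'drop' for a non-trivial connector.

    The connector plus ``cfg.flank`` bases of context on each side (both
    genomes) is globally aligned.  The connector is dropped -- judged to be
    enhanced variability of the shared backbone -- only when all hold:
    the flanked alignment contains no gap run >= drop_gap, the two sides
    differ in length by < drop_gap, flanked identity >= drop_identity, and
    the identity of the region itself (without flanks) >= drop_region_identity.
    A genuine replacement fails at least one of these.  Flanks are
    truncated at sequence ends.
    """
    if abs(c.lenA - c.lenB) >= cfg.drop_gap:
        return "keep"
    a = seqA[max(0, c.startA - cfg.flank) : min(len(seqA), c.endA + cfg.flank)]
    b = seqB[max(0, c.startB - cfg.flank) : min(len(seqB), c.endB + cfg.flank)]
    st = global_alignment(a, b)
    if st.longest_gap_run >= cfg.drop_gap:
        return "keep"
    if st.identity < cfg.drop_identity:
        return "keep"
    region = global_alignment(
        seqA[c.startA : c.endA], seqB[c.startB : c.endB]
    )
    if region.columns and region.identity < cfg.drop_region_identity:
        return "keep"
    return "drop"


def select_regions(
    cmap: ComparisonMap, cfg: Optional[TriageConfig] = None
) -> list[Connector]:
    """Full triage: non-trivial connectors that survive the divergence
    filter, in genome order.  These are the strain-specific regions."""
    cfg = cfg or TriageConfig()
    sa, sb = cmap.genomeA.sequence, cmap.genomeB.sequence
    kept: list[Connector] = []
    for c in cmap.connectors():
        res = classify_connector(c, cfg, sa, sb)
        if not res.non_trivial:
            continue
        if divergence_filter(c, sa, sb, cfg) == "keep":
            kept.append(c)
    return kept
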