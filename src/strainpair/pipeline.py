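"""End-to-end orchestration: compare, triage, classify, repeat census,
element analysis and summary reporting for a pair of co-linear genomes."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .mge_analysis import (
    ElementFamily,
    ElementHit,
    TargetingMatrix,
    call_ssei,
    detect_target_duplication,
    locate_elements,
    targeting_matrix,
)
from .region_classifier import ClassifierConfig, build_region_records
from .repeat_deletion import flanking_direct_repeat, repeat_length_census
from .run_connector import (
    CompareConfig,
    ComparisonMap,
    Connector,
    Run,
    compare_chromosomes,
    shared_fraction,
    shared_identity,
)
from .seq_io import Genome, RegionRecord
from .triage import TriageConfig, classify_connector, select_regions

logger = logging.getLogger("strainpair")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "write_map_tsv", "read_map_tsv"]


@dataclass
class PipelineConfig:
    """All numeric constants of the pipeline, stage by stage."""

    compare: CompareConfig = field(default_factory=CompareConfig)
    triage: TriageConfig = field(default_factory=TriageConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    mge_min_identity: float = 0.80
    mge_min_coverage: float = 0.90
    repeat_floor: int = 4
    stats_window: int = 1000
    stats_sd_cut: float = 2.5
    seed: int = 0

    def log_thresholds(self) -> None:
        for stage in ("compare", "triage", "classifier"):
            logger.info("%s config: %s", stage, getattr(self, stage))


@dataclass
class PipelineResult:
    cmap: ComparisonMap
    regions: list[Connector]
    records: list[RegionRecord]
    hitsA: list[ElementHit]
    hitsB: list[ElementHit]
    census: pd.DataFrame
    targeting: TargetingMatrix
    summary: dict


def run_pipeline(
    genomeA: Genome,
    genomeB: Genome,
    catalog: Optional[Sequence[ElementFamily]] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Compare two genomes and classify every strain-specific difference.

    Stages: run/connector comparison, triage plus divergence filter,
    element location (when a catalog is supplied), region classification,
    junction-repeat census, SSEI calling, target duplications, and the
    element-in-element targeting matrix.  The summary is recomputed from
    the emitted tables, never kept as separate state.
    """
    cfg = config or PipelineConfig()
    cfg.log_thresholds()
    t0 = time.time()
    cmap = compare_chromosomes(genomeA, genomeB, cfg.compare)
    logger.info("compare: %d elements in %.1fs", len(cmap.elements), time.time() - t0)

    sa, sb = genomeA.sequence, genomeB.sequence
    connectors = cmap.connectors()
    non_trivial = [
        c for c in connectors if classify_connector(c, cfg.triage, sa, sb).non_trivial
    ]
    regions = select_regions(cmap, cfg.triage)
    logger.info(
        "triage: %d connectors, %d non-trivial, %d strain-specific",
        len(connectors),
        len(non_trivial),
        len(regions),
    )

    hitsA: list[ElementHit] = []
    hitsB: list[ElementHit] = []
    if catalog:
        hitsA = locate_elements(
            genomeA, catalog, cfg.mge_min_identity, cfg.mge_min_coverage, genome_label="A"
        )
        hitsB = locate_elements(
            genomeB, catalog, cfg.mge_min_identity, cfg.mge_min_coverage, genome_label="B"
        )
        call_ssei(cmap, hitsA, hitsB, regions)

    records = build_region_records(cmap, regions, hitsA, hitsB, cfg.classifier)

    indel_flanks = [
        flanking_direct_repeat(cmap, c, min_len=cfg.repeat_floor)
        for c in regions
        if min(c.lenA, c.lenB) < cfg.classifier.dci_min_side
    ]
    n_indels = sum(1 for c in regions if min(c.lenA, c.lenB) < cfg.classifier.dci_min_side)
    census = repeat_length_census(indel_flanks, n_indels=n_indels)

    tmat = targeting_matrix(hitsA, hitsB)
    for h in hitsA + hitsB:
        if h.status == "SSEI":
            for r in regions:
                r0 = r.startA if h.genome == "A" else r.startB
                r1 = r.endA if h.genome == "A" else r.endB
                if r0 <= h.start and h.end <= r1 + h.family.max_td + 5:
                    detect_target_duplication(cmap, h, r)
                    break

    trivial_connectors = [c for c in connectors if c not in non_trivial]
    ident = shared_identity(cmap, strain_specific=regions)
    fracA, fracB = shared_fraction(cmap, regions)
    cat_counts: dict[str, int] = {}
    for r in records:
        cat_counts[r.category] = cat_counts.get(r.category, 0) + 1
    ssei_by_family: dict[str, int] = {}
    for h in hitsA + hitsB:
        if h.status == "SSEI":
            ssei_by_family[h.family.code] = ssei_by_family.get(h.family.code, 0) + 1

    summary = {
        "n_runs": len(cmap.runs()),
        "n_connectors": len(connectors),
        "n_trivial": len(trivial_connectors),
        "n_non_trivial": len(non_trivial),
        "n_strain_specific": len(regions),
        "category_counts": cat_counts,
        "shared_identity": ident,
        "shared_fraction_A": fracA,
        "shared_fraction_B": fracB,
        "ssei_per_family": ssei_by_family,
        "targeting_total": tmat.grand_total,
    }
    return PipelineResult(cmap, regions, records, hitsA, hitsB, census, tmat, summary)


# ---------------------------------------------------------------------------
# map serialization


def write_map_tsv(cmap: ComparisonMap, path: str | Path) -> None:
    """Serialize the comparison map as alternating records
    (type, startA, lenA, startB, lenB), 0-based half-open."""
    with open(path, "w") as fh:
        fh.write("#type\tstartA\tlenA\tstartB\tlenB\n")
        for e in cmap.elements:
            if isinstance(e, Run):
                fh.write(f"run\t{e.startA}\t{e.length}\t{e.startB}\t{e.length}\n")
            else:
                fh.write(f"connector\t{e.startA}\t{e.lenA}\t{e.startB}\t{e.lenB}\n")


def read_map_tsv(path: str | Path, genomeA: Genome, genomeB: Genome) -> ComparisonMap:
    elements = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            typ, sa, la, sb, lb = line.rstrip("\n").split("\t")
            if typ == "run":
                elements.append(Run(int(sa), int(sb), int(la)))
            else:
                elements.append(Connector(int(sa), int(la), int(sb), int(lb)))
    return ComparisonMap(genomeA, genomeB, elements)
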