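"""Small reference datasets.

HALOQUADRATUM_TARGETING_COUNTS is the published element-in-element
insertion count table for the Haloquadratum walsbyi C23(T)/HBSQ001
chromosome pair: rows are the category of the inserted (inner) element,
columns the category of the host.  It serves as a worked example and
cross-check for :class:`strainpair.mge_analysis.TargetingMatrix`
aggregation (row/column/grand totals recompute from the cells).
"""

from __future__ import annotations

import pandas as pd

from .mge_analysis import CATEGORIES, TargetingMatrix

__all__ = ["HALOQUADRATUM_TARGETING_COUNTS", "haloquadratum_targeting_matrix"]

# rows: inserted element category; columns: host category
_CELLS = {
    "PATE": {"PATE": 6, "TP_A": 12},
    "TP_A": {"TP_A": 5},
    "TP_B": {"PATE": 7, "TP_A": 3, "TP_B": 5},
    "MITE": {"PATE": 13, "TP_A": 17, "SMR_A": 1},
    "SMR_A": {"PATE": 79, "TP_A": 25, "TP_B": 9, "SMR_A": 1},
    "SMR_B": {"PATE": 1, "TP_A": 2, "TP_B": 5, "SMR_A": 1},
}

HALOQUADRATUM_TARGETING_COUNTS = (
    pd.DataFrame(_CELLS).T.reindex(index=CATEGORIES, columns=CATEGORIES).fillna(0).astype(int)
)


def haloquadratum_targeting_matrix() -> TargetingMatrix:
    return TargetingMatrix.from_counts(HALOQUADRATUM_TARGETING_COUNTS)
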