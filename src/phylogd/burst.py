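"""Calling clustered gene-duplication bursts (candidate WGD signals).

A species-tree node is called a CGD (cluster of gene duplications) when its
pooled duplication statistics clear a two-part rule: (1) at least
``min_gd`` retained duplications and a duplication ratio of at least
``min_ratio`` of the relevant gene trees; (2) an ABAB fraction of at least
``min_abab``.  The stock thresholds (600 duplications, 6%, 30%) are
calibrated to a survey of ~45k gene trees; :func:`scale_thresholds`
rescales the count threshold proportionally for smaller gene-tree sets so
the rule stays exercisable at any scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

DEFAULT_MIN_GD = 600
DEFAULT_MIN_RATIO = 0.06
DEFAULT_MIN_ABAB = 0.30
REFERENCE_N_TREES = 45722


@dataclass(frozen=True)
class CGDCall:
    """Burst decision for one species-tree node."""

    species_node_id: int
    gd_count: int
    gd_ratio: float
    abab_fraction: float
    passed: bool
    min_gd: int
    min_ratio: float
    min_abab: float
    reason: str = ""  # set when passed is False


def scale_thresholds(min_gd: int, n_trees_actual: int,
                     n_trees_reference: int = REFERENCE_N_TREES) -> int:
    """Rescale a duplication-count threshold to a smaller gene-tree set.

    Proportional scaling with round-half-up and a floor of 1:
    ``max(1, round(min_gd * n_trees_actual / n_trees_reference))``.
    """
    if min_gd <= 0 or n_trees_actual <= 0 or n_trees_reference <= 0:
        raise ValueError("counts must be positive")
    scaled = math.floor(min_gd * n_trees_actual / n_trees_reference + 0.5)
    return max(1, scaled)


def detect_cgd(stats: pd.DataFrame, min_gd: int = DEFAULT_MIN_GD,
               min_ratio: float = DEFAULT_MIN_RATIO,
               min_abab: float = DEFAULT_MIN_ABAB) -> list[CGDCall]:
    """Apply the two-part burst rule to a per-node statistics table.

    ``stats`` is the output of ``reconciliation.summarize_by_node``.  All
    comparisons are inclusive (>=).  A node whose gd_ratio is undefined
    (no relevant trees) or whose abab_fraction is undefined (no
    duplications) cannot pass and carries a reason code.  Calls are sorted
    by gd_count descending (species node id ascending on ties).
    """
    calls = []
    for node_id, row in stats.iterrows():
        gd_count = int(row["gd_count"])
        gd_ratio = float(row["gd_ratio"])
        abab_fraction = float(row["abab_fraction"])
        reason = ""
        if pd.isna(row["gd_ratio"]):
            passed, reason = False, "no_relevant_trees"
        elif pd.isna(row["abab_fraction"]):
            passed, reason = False, "no_duplications"
        else:
            passed = (gd_count >= min_gd and gd_ratio >= min_ratio
                      and abab_fraction >= min_abab)
            if not passed:
                fails = []
                if gd_count < min_gd:
                    fails.append("count")
                if gd_ratio < min_ratio:
                    fails.append("ratio")
                if abab_fraction < min_abab:
                    fails.append("abab")
                reason = "below_" + "+".join(fails)
        calls.append(CGDCall(
            species_node_id=int(node_id), gd_count=gd_count,
            gd_ratio=gd_ratio, abab_fraction=abab_fraction, passed=passed,
            min_gd=min_gd, min_ratio=min_ratio, min_abab=min_abab,
            reason=reason,
        ))
    calls.sort(key=lambda c: (-c.gd_count, c.species_node_id))
    return calls


def calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.species_node_id, c.gd_count, c.gd_ratio, c.abab_fraction,
          c.passed, c.reason) for c in calls],
        columns=["species_node_id", "gd_count", "gd_ratio", "abab_fraction",
                 "passed", "reason"],
    )
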