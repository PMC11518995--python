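"""Per-variant sequencing-quality filter cascade.

SNVs must satisfy four caller-level annotations simultaneously:
no clipped supporting reads (CLPM <= 0), median alignment score
ASMD >= 140, mapping quality >= 30 and base quality >= 25 (all
boundaries inclusive).  Non-SNV classes are not subject to this
cascade — indel-class calls are assumed to have passed their own
caller's filters upstream — and pass through flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable


@dataclass(frozen=True)
class QualityThresholds:
    clpm_max: float = 0.0
    asmd_min: float = 140.0
    mapq_min: float = 30.0
    baseq_min: float = 25.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not np.isfinite(v):
                raise ValueError(f"threshold {name} must be finite, got {v}")


#: flag for non-SNV records that bypass the SNV-specific cascade
NOT_QUALITY_FILTERED = "not_quality_filtered"
UNANNOTATED = "unannotated"

_RULES = (
    ("CLPM", lambda qc, t: qc["CLPM"] <= t.clpm_max),
    ("ASMD", lambda qc, t: qc["ASMD"] >= t.asmd_min),
    ("MAPQ", lambda qc, t: qc["MAPQ"] >= t.mapq_min),
    ("BASEQ", lambda qc, t: qc["BASEQ"] >= t.baseq_min),
)


def apply_quality_filters(
    table: CohortTable,
    thresholds: QualityThresholds = QualityThresholds(),
) -> tuple[CohortTable, pd.DataFrame]:
    """Apply the SNV quality cascade.

    Returns the passing sub-table and an exhaustive per-site report with
    columns ``site``, ``variant_class``, ``passed`` and ``failed_rules``
    (comma-joined rule names, or a pass-through flag for non-SNVs).
    The verdict depends only on QC annotations, never on read counts.
    """
    keep = np.zeros(table.n_sites, dtype=bool)
    rows = []
    for i, site in enumerate(table.sites):
        if not site.is_snv:
            keep[i] = True
            rows.append((site.label(), site.variant_class, True, NOT_QUALITY_FILTERED))
            continue
        missing = [name for name, _ in _RULES if name not in site.qc]
        if missing:
            rows.append((site.label(), site.variant_class, False, UNANNOTATED))
            continue
        failed = [name for name, rule in _RULES if not rule(site.qc, thresholds)]
        keep[i] = not failed
        rows.append(
            (site.label(), site.variant_class, not failed, ",".join(failed))
        )
    report = pd.DataFrame(
        rows, columns=["site", "variant_class", "passed", "failed_rules"]
    )
    return table.subset_sites(keep), report
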