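"""Embryonic timing of the tumours' most recent common ancestor.

Three ingredients, mirroring how a shared-trunk burden is read against
developmental landmarks:

* **Detectability** of each shared variant in the normal tissues
  (kidney and blood).  Variants acquired before the blood/kidney
  lineage split (~gastrulation, week 3) are expected in both tissues;
  later kidney-lineage variants only in kidney; the latest in neither.
* **VAF ordering**: in a polyclonal normal tissue, earlier variants
  occupy larger cell fractions, so sorting by reference-tissue VAF
  approximates acquisition order and detectability categories should be
  monotone along it.  Violations are counted, never silently repaired.
* **Burden calibration**: a piecewise-linear curve through anchor
  points (weeks post-conception, expected mutation burden) — by default
  (0, 0) and (8, 25), i.e. mesodermal cells carry ~25 mutations at
  8 weeks — converts the trunk burden into weeks, with an exact Poisson
  95% CI on the burden mapped through the same curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortError, CohortTable, VariantSite

BOTH_TISSUES = "both_tissues"
KIDNEY_ONLY = "kidney_only"
BLOOD_ONLY = "blood_only"  # inconsistent with a kidney-fated MRCA; flagged
NEITHER = "neither"
CATEGORIES = (BOTH_TISSUES, KIDNEY_ONLY, BLOOD_ONLY, NEITHER)

_CATEGORY_RANK = {BOTH_TISSUES: 2, KIDNEY_ONLY: 1, BLOOD_ONLY: 1, NEITHER: 0}


@dataclass(frozen=True)
class DetectabilityCall:
    site: VariantSite
    category: str
    kidney_vaf: float
    blood_vaf: float
    kidney_p: float
    blood_p: float
    flag: str = ""


def _tissue_presence(alt, depth, min_alt_reads, error_rate, alpha):
    tail = float(stats.binom.sf(alt - 1, max(depth, 1), error_rate))
    present = depth > 0 and alt >= min_alt_reads and tail < alpha
    return present, tail


def classify_detectability(
    shared: list[VariantSite],
    table: CohortTable,
    kidney_sample: str | None = None,
    blood_sample: str | None = None,
    min_alt_reads: int = 3,
    error_rate: float = 1e-3,
    alpha: float = 0.01,
) -> list[DetectabilityCall]:
    """Classify each shared variant's detectability in the normal tissues.

    Uses the same presence rule as tree building, applied per tissue.
    A variant detectable in blood but not kidney contradicts the nesting
    expected when the MRCA is kidney-fated and is flagged
    ``inconsistent_with_lineage``.
    """
    kidney = kidney_sample or _single_role(table, "normal_kidney")
    blood = blood_sample or _single_role(table, "blood")
    ki, bi = table.sample_index(kidney), table.sample_index(blood)
    index = table.site_index()
    calls = []
    for site in shared:
        i = index[site.key]
        if table.depth[i, ki] == 0 or table.depth[i, bi] == 0:
            raise CohortError(f"no normal-tissue coverage at {site.label()}")
        kp, k_tail = _tissue_presence(
            int(table.alt[i, ki]), int(table.depth[i, ki]), min_alt_reads, error_rate, alpha
        )
        bp, b_tail = _tissue_presence(
            int(table.alt[i, bi]), int(table.depth[i, bi]), min_alt_reads, error_rate, alpha
        )
        if kp and bp:
            cat, flag = BOTH_TISSUES, ""
        elif kp:
            cat, flag = KIDNEY_ONLY, ""
        elif bp:
            cat, flag = BLOOD_ONLY, "inconsistent_with_lineage"
        else:
            cat, flag = NEITHER, ""
        calls.append(
            DetectabilityCall(
                site=site,
                category=cat,
                kidney_vaf=table.alt[i, ki] / table.depth[i, ki],
                blood_vaf=table.alt[i, bi] / table.depth[i, bi],
                kidney_p=k_tail,
                blood_p=b_tail,
                flag=flag,
            )
        )
    return calls


def _single_role(table: CohortTable, role: str) -> str:
    ids = table.samples_with_role(role)
    if len(ids) != 1:
        raise CohortError(f"expected exactly one {role} sample, found {len(ids)}")
    return ids[0]


def vaf_ordering(calls: list[DetectabilityCall]) -> tuple[pd.DataFrame, int]:
    """Sort shared variants by descending reference-tissue (kidney) VAF.

    Returns the ordered table and the number of monotonicity violations:
    pairs (i earlier than j in the sort) whose detectability ranks are
    inverted (a later variant seen in *more* tissues than an earlier
    one).  Ties in VAF break by genomic coordinate.
    """
    ordered = sorted(
        calls, key=lambda c: (-c.kidney_vaf, c.site.key)
    )
    ranks = [_CATEGORY_RANK[c.category] for c in ordered]
    violations = sum(
        1
        for i in range(len(ranks))
        for j in range(i + 1, len(ranks))
        if ranks[i] < ranks[j]
    )
    frame = pd.DataFrame(
        {
            "site": [c.site.label() for c in ordered],
            "kidney_vaf": [c.kidney_vaf for c in ordered],
            "blood_vaf": [c.blood_vaf for c in ordered],
            "category": [c.category for c in ordered],
            "flag": [c.flag for c in ordered],
        }
    )
    return frame, violations


# ----------------------------------------------------------------------
# Burden -> weeks calibration
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TimingCalibration:
    """Anchors mapping mutation burden to weeks post-conception.

    ``anchors`` must be strictly increasing in both coordinates; the
    default ties zero burden to conception and 25 mutations to week 8
    (the mesodermal average).  ``tissue_split_anchors`` place anatomical
    events on the same week axis.
    """

    anchors: tuple[tuple[float, float], ...] = ((0.0, 0.0), (8.0, 25.0))
    tissue_split_anchors: dict = field(
        default_factory=lambda: {
            "blood_kidney_split": 3.0,
            "left_right_kidney_split": 3.5,
        }
    )

    def __post_init__(self) -> None:
        weeks = [w for w, _ in self.anchors]
        burdens = [b for _, b in self.anchors]
        if len(self.anchors) < 2:
            raise CohortError("calibration needs >= 2 anchors")
        if any(b2 <= b1 for b1, b2 in zip(burdens, burdens[1:])) or any(
            w2 <= w1 for w1, w2 in zip(weeks, weeks[1:])
        ):
            raise CohortError("anchors must be strictly increasing in both axes")

    def weeks_at(self, burden: float) -> float:
        weeks = np.array([w for w, _ in self.anchors])
        burdens = np.array([b for _, b in self.anchors])
        if burden > burdens[-1]:
            slope = (weeks[-1] - weeks[-2]) / (burdens[-1] - burdens[-2])
            return float(weeks[-1] + (burden - burdens[-1]) * slope)
        return float(np.interp(burden, burdens, weeks))


def poisson_interval(k: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson CI for an observed count."""
    a = 1.0 - confidence
    lo = 0.0 if k == 0 else stats.chi2.ppf(a / 2, 2 * k) / 2.0
    hi = stats.chi2.ppf(1 - a / 2, 2 * k + 2) / 2.0
    return lo, hi


def time_from_burden(
    burden: int, calibration: TimingCalibration = TimingCalibration()
) -> tuple[float, tuple[float, float]]:
    """Point estimate and 95% interval (weeks) for a trunk burden.

    The exact Poisson CI of the observed burden is mapped through the
    same monotone calibration curve as the point estimate.
    """
    if burden < 0:
        raise CohortError("burden must be >= 0")
    point = calibration.weeks_at(burden)
    lo, hi = poisson_interval(burden)
    return point, (calibration.weeks_at(lo), calibration.weeks_at(hi))


# ----------------------------------------------------------------------
# Report
# ----------------------------------------------------------------------

@dataclass
class TimingReport:
    mrca_burden: int
    point_estimate_weeks: float
    interval_weeks: tuple[float, float]
    category_counts: dict
    ordering: pd.DataFrame
    monotonicity_violations: int
    notes: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "mrca_burden": self.mrca_burden,
                "point_estimate_weeks": self.point_estimate_weeks,
                "interval_weeks": list(self.interval_weeks),
                "category_counts": self.category_counts,
                "monotonicity_violations": self.monotonicity_violations,
                "ordering": self.ordering.to_dict(orient="records"),
                "notes": self.notes,
            },
            indent=2,
        )

    def to_text(self) -> str:
        lo, hi = self.interval_weeks
        lines = [
            f"MRCA trunk burden: {self.mrca_burden} mutations",
            f"Timing point estimate: {self.point_estimate_weeks:.1f} weeks "
            f"post-conception (95% CI {lo:.1f}-{hi:.1f})",
            "Detectability: "
            + ", ".join(f"{k}={v}" for k, v in self.category_counts.items()),
            f"Monotonicity violations in VAF ordering: {self.monotonicity_violations}",
        ]
        lines += [f"Note: {n}" for n in self.notes]
        return "\n".join(lines)


def timing_report(
    shared: list[VariantSite],
    table: CohortTable,
    calibration: TimingCalibration = TimingCalibration(),
    **presence_kwargs,
) -> TimingReport:
    """Assemble the full developmental-timing report for a shared set."""
    burden = len(shared)
    point, interval = time_from_burden(burden, calibration)
    if shared:
        calls = classify_detectability(shared, table, **presence_kwargs)
        ordering, violations = vaf_ordering(calls)
    else:
        calls, violations = [], 0
        ordering = pd.DataFrame(
            columns=["site", "kidney_vaf", "blood_vaf", "category", "flag"]
        )
    counts = {cat: 0 for cat in CATEGORIES}
    for c in calls:
        counts[c.category] += 1

    notes = []
    split = calibration.tissue_split_anchors.get("blood_kidney_split")
    if split is not None and counts[BOTH_TISSUES] > 0:
        if counts[BOTH_TISSUES] == burden and burden > 0:
            notes.append(
                f"all shared variants are detectable in blood: MRCA <= "
                f"blood/kidney split (~week {split:g})"
            )
        else:
            notes.append(
                f"{counts[BOTH_TISSUES]} shared variants are detectable in blood "
                f"and predate the blood/kidney split (~week {split:g})"
            )
    if counts[KIDNEY_ONLY] > 0 and split is not None:
        notes.append(
            f"{counts[KIDNEY_ONLY]} kidney-only variants postdate the "
            f"blood/kidney split (~week {split:g}): MRCA is kidney-fated"
        )
    if counts[BLOOD_ONLY] > 0:
        notes.append(
            f"{counts[BLOOD_ONLY]} variants detectable in blood but not kidney "
            "are inconsistent with a kidney-fated MRCA"
        )
    return TimingReport(
        mrca_burden=burden,
        point_estimate_weeks=point,
        interval_weeks=interval,
        category_counts=counts,
        ordering=ordering,
        monotonicity_violations=violations,
        notes=notes,
    )
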