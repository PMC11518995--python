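"""Copy-number- and purity-aware VAF adjustment and clonality testing.

A somatic variant present in every tumour cell at multiplicity ``m`` on
a segment of total copy number ``n_t`` in a sample of purity ``rho`` has
expected VAF

    E[VAF] = f * rho * m / (rho * n_t + 2 * (1 - rho))

where ``f`` is the fraction of tumour cells carrying the variant
(1 for clonal).  Dividing the observed VAF by this expectation and
rescaling by 0.5 maps every clonal variant to a theoretical mean of 0.5
regardless of local copy number — the scale on which clonality is
tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import CohortError


@dataclass(frozen=True)
class AdjustedVAF:
    raw_vaf: float
    expected_clonal_vaf: float
    adjusted_vaf: float
    total_cn: int
    multiplicity: int
    purity: float
    flag: str = ""


def expected_clonal_vaf(
    multiplicity: int,
    total_cn: int,
    purity: float,
    cell_fraction: float = 1.0,
) -> float:
    """Expected VAF of a variant at the given multiplicity and context.

    ``cell_fraction`` is the fraction of *tumour* cells carrying the
    variant (for a normal polyclonal tissue, pass purity=1 and the
    tissue cell fraction here).
    """
    if multiplicity < 0 or total_cn < 1:
        raise CohortError("multiplicity must be >= 0 and total_cn >= 1")
    if multiplicity > total_cn:
        raise CohortError(
            f"multiplicity {multiplicity} exceeds total_cn {total_cn}"
        )
    if not 0.0 <= purity <= 1.0 or not 0.0 <= cell_fraction <= 1.0:
        raise CohortError("purity and cell_fraction must lie in [0, 1]")
    denom = purity * total_cn + 2.0 * (1.0 - purity)
    if denom == 0.0:
        return 0.0
    return cell_fraction * purity * multiplicity / denom


def adjust_vaf(
    alt: int,
    depth: int,
    cn: tuple[int, int],
    purity: float = 1.0,
    multiplicity: int | None = None,
) -> AdjustedVAF:
    """Adjust one observation to the theoretical clonal mean of 0.5.

    Default multiplicity is 1: shared embryonic variants are
    heterozygous point events that predate any tumour copy-number
    change.  On a lost-allele background (total_cn == 1) a raw VAF near
    1 is consistent with retention of the mutant allele and keeps m=1;
    a raw VAF near 0 means the mutant allele was lost and the
    adjustment is flagged rather than inflated.
    """
    if depth == 0:
        raise CohortError("adjust_vaf requires depth > 0")
    total_cn, _minor = cn
    raw = alt / depth
    flag = ""
    if multiplicity is None:
        multiplicity = 1
        if total_cn == 1 and purity >= 0.5 and raw < 0.25:
            # mutant allele likely on the lost homologue
            flag = "allele_likely_lost"
    exp = expected_clonal_vaf(multiplicity, total_cn, purity)
    if exp == 0.0:
        return AdjustedVAF(raw, exp, float("nan"), total_cn, multiplicity, purity,
                           flag or "undefined_adjustment")
    return AdjustedVAF(raw, exp, raw * 0.5 / exp, total_cn, multiplicity, purity, flag)


CLONAL = "clonal"
SUBCLONAL = "subclonal"


def clonality_test(
    observations: list[tuple[int, int, float]],
    alpha: float = 0.05,
) -> str:
    """Clonality verdict across tumours for one variant.

    ``observations`` holds (alt, depth, expected_clonal_vaf) per tumour.
    The exact (Clopper-Pearson) binomial CI of the raw proportion is
    transformed to the adjusted scale; the variant is clonal iff the
    transformed CI contains 0.5 in *every* tumour.  ``alpha`` is the
    per-variant error rate: with m tumours each CI is taken at Sidak
    confidence (1-alpha)^(1/m), so a truly clonal variant is mislabelled
    with probability <= alpha however many tumours are tested.
    """
    if not observations:
        raise CohortError("clonality_test needs at least one tumour observation")
    confidence = (1.0 - alpha) ** (1.0 / len(observations))
    for alt, depth, exp in observations:
        if depth == 0 or exp <= 0:
            raise CohortError("clonality_test needs depth > 0 and expected VAF > 0")
        ci = stats.binomtest(alt, depth).proportion_ci(
            confidence_level=confidence, method="exact"
        )
        scale = 0.5 / exp
        lo, hi = ci.low * scale, ci.high * scale
        if not (lo <= 0.5 <= hi):
            return SUBCLONAL
    return CLONAL


def adjusted_vaf_table(rows: list[dict]) -> "np.ndarray":
    """Mean adjusted VAF over a variant x sample long table.

    ``rows`` carry at least ``adjusted_vaf``; used to reproduce summary
    figures such as the mean adjusted VAF of the shared set.
    """
    vals = np.array([r["adjusted_vaf"] for r in rows], dtype=float)
    return float(np.nanmean(vals)) if len(vals) else float("nan")
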