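"""Germline/somatic classification, panel-of-normals artifact filtering,
and selection of tumour-shared somatic variants.

The cascade applied to every quality-passing variant:

1. **Exact binomial germline test** on the blood counts.  A germline
   heterozygous variant in a diploid genome has expected VAF 0.5; a
   variant is labelled germline when the two-sided exact binomial test
   against p=0.5 is non-significant *and* the observed VAF lies inside a
   [0.3, 0.7] guard band.  Everything else is a somatic candidate.
2. **Panel-of-normals artifact test** ("Shearwater-like").  Per site, a
   beta-binomial error model is fitted to an unrelated normal panel by
   method of moments; a sample's counts are "real" only when their
   upper-tail probability under that background is below a stringent
   alpha (default 1e-5).
3. **Tumour-enrichment Fisher test**: one-sided Fisher's exact test of
   aggregated renal counts (tumours + normal kidney) versus blood,
   selecting variants enriched in the renal lineage (default p < 0.01).
4. **Presence in all tumours** (rule from :mod:`embryophylo.phylo`).

A variant passing 1-4 is "shared": a candidate embryonic mutation of the
tumours' most recent common ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, CohortError, VariantSite

# ----------------------------------------------------------------------
# 1. Exact binomial germline test
# ----------------------------------------------------------------------

GERMLINE = "germline"
SOMATIC_CANDIDATE = "somatic_candidate"
NO_COVERAGE = "no_coverage"


@dataclass(frozen=True)
class BinomialVerdict:
    p_value: float
    label: str


def binomial_pvalue_two_sided(alt: int, depth: int, p: float = 0.5) -> float:
    """Two-sided exact binomial p-value, minimum-likelihood rule.

    Sums P(X = k) over all outcomes whose probability does not exceed
    that of the observed count (with a small relative tolerance for
    floating-point ties, as in standard exact-test implementations).
    """
    return stats.binomtest(alt, depth, p, alternative="two-sided").pvalue


def binomial_germline_test(
    alt: int,
    depth: int,
    expected_het_vaf: float = 0.5,
    alpha: float = 1e-3,
    guard_band: tuple[float, float] = (0.3, 0.7),
) -> BinomialVerdict:
    """Classify one sample's counts as germline-het compatible or not.

    Germline requires both a non-significant exact test against the
    expected heterozygous VAF and an observed VAF inside the guard band;
    the band protects against high-depth cases where tiny deviations
    from 0.5 are formally significant, and against low-depth cases
    where mosaic VAFs are not.
    """
    if depth == 0:
        return BinomialVerdict(p_value=float("nan"), label=NO_COVERAGE)
    p = binomial_pvalue_two_sided(alt, depth, expected_het_vaf)
    vaf = alt / depth
    lo, hi = guard_band
    label = GERMLINE if (p >= alpha and lo <= vaf <= hi) else SOMATIC_CANDIDATE
    return BinomialVerdict(p_value=p, label=label)


# ----------------------------------------------------------------------
# 2. Panel-of-normals beta-binomial artifact filter
# ----------------------------------------------------------------------

RHO_FLOOR = 1e-6
RHO_CEIL = 0.99
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class BetaBinomBackground:
    mean_error: float
    overdispersion_rho: float
    n_panel: int


def fit_panel_background(
    panel_alt: np.ndarray, panel_depth: np.ndarray
) -> BetaBinomBackground:
    """Method-of-moments beta-binomial fit to panel counts at one site.

    The mean error rate uses a half-count pseudocount so an all-zero
    panel still yields a strictly positive rate; the intra-class
    correlation rho comes from the depth-weighted moment estimator and
    is clamped to [1e-6, 0.99].  Requires >= 2 panel samples with
    depth > 0.
    """
    mu, rho, n = _fit_panel_background_arrays(
        np.asarray(panel_alt, dtype=float)[None, :],
        np.asarray(panel_depth, dtype=float)[None, :],
    )
    return BetaBinomBackground(float(mu[0]), float(rho[0]), int(n[0]))


def _fit_panel_background_arrays(
    alt: np.ndarray, depth: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised panel fit: inputs are (n_sites, n_panel) matrices."""
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    usable = depth > 0
    n_usable = usable.sum(axis=1)
    if (n_usable < 2).any():
        bad = int(np.flatnonzero(n_usable < 2)[0])
        raise CohortError(
            f"panel background needs >= 2 samples with depth > 0 "
            f"(site index {bad} has {int(n_usable[bad])})"
        )
    W = depth.sum(axis=1)
    A = alt.sum(axis=1)
    mu = (A + PSEUDOCOUNT) / (W + PSEUDOCOUNT)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.where(usable, alt / np.maximum(depth, 1.0), 0.0)
        S = (depth * (p_i - mu[:, None]) ** 2 * usable).sum(axis=1)
        # E[S] = mu(1-mu) [ sum(1 - d_i/W) + rho * sum((d_i-1)(1 - d_i/W)) ]
        c0 = ((1.0 - depth / W[:, None]) * usable).sum(axis=1)
        c1 = ((depth - 1.0) * (1.0 - depth / W[:, None]) * usable).sum(axis=1)
        rho = (S / (mu * (1.0 - mu)) - c0) / np.maximum(c1, 1e-12)
    rho = np.clip(np.nan_to_num(rho, nan=RHO_FLOOR), RHO_FLOOR, RHO_CEIL)
    return mu, rho, n_usable.astype(int)


REAL = "real"
ARTIFACT = "artifact"


def _betabinom_params(mu: np.ndarray, rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # mean mu and intra-class correlation rho -> (a, b) shape parameters
    s = 1.0 / rho - 1.0
    return mu * s, (1.0 - mu) * s


def artifact_pvalues(
    alt: np.ndarray,
    depth: np.ndarray,
    mean_error: np.ndarray,
    rho: np.ndarray,
) -> np.ndarray:
    """Upper-tail beta-binomial P(X >= alt) under the panel background.

    Computed by direct log-pmf summation rather than the library
    survival function: the 1-cdf route loses all precision once the
    tail probability drops below ~1e-9, which matters at the stringent
    significance levels this filter uses.
    """
    from scipy.special import betaln, gammaln

    alt = np.atleast_1d(np.asarray(alt))
    depth = np.atleast_1d(np.asarray(depth))
    shape = np.broadcast_shapes(alt.shape, depth.shape, np.shape(mean_error), np.shape(rho))
    a, b = _betabinom_params(
        np.broadcast_to(np.asarray(mean_error, float), shape).ravel(),
        np.broadcast_to(np.asarray(rho, float), shape).ravel(),
    )
    alt_f = np.broadcast_to(alt, shape).ravel()
    dep_f = np.broadcast_to(depth, shape).ravel()
    p = np.ones(alt_f.shape)
    todo = np.flatnonzero(alt_f > 0)  # alt = 0 -> p = 1 (empty upper tail)
    chunk = max(1, 2_000_000 // (int(dep_f.max(initial=1)) + 1))
    for start in range(0, todo.size, chunk):
        idx = todo[start:start + chunk]
        d = dep_f[idx][:, None]
        k = np.arange(int(dep_f[idx].max()) + 1)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            logpmf = (
                gammaln(d + 1) - gammaln(k + 1) - gammaln(d - k + 1)
                + betaln(k + a[idx][:, None], d - k + b[idx][:, None])
                - betaln(a[idx], b[idx])[:, None]
            )
        mask = (k >= alt_f[idx][:, None]) & (k <= d)
        p[idx] = np.where(mask, np.exp(logpmf), 0.0).sum(axis=1)
    return np.minimum(p.reshape(shape), 1.0)


def artifact_test(
    alt: int,
    depth: int,
    background: BetaBinomBackground,
    alpha: float = 1e-5,
) -> tuple[str, float]:
    """Judge a sample's signal against panel noise.

    "real" only when the upper-tail probability of seeing >= alt reads
    under the panel beta-binomial is below alpha; zero alt reads are
    always an artifact call (no signal to defend).
    """
    p = float(
        artifact_pvalues(
            np.array([alt]),
            np.array([depth]),
            np.array([background.mean_error]),
            np.array([background.overdispersion_rho]),
        )[0]
    )
    return (REAL if p < alpha else ARTIFACT), p


# ----------------------------------------------------------------------
# 3. Fisher tumour-enrichment test
# ----------------------------------------------------------------------

TUMOUR_ENRICHED = "tumour_enriched"
NOT_ENRICHED = "not_enriched"


@dataclass(frozen=True)
class EnrichmentResult:
    p_value: float
    odds_direction: str
    contingency: tuple[tuple[int, int], tuple[int, int]]


def tumour_enrichment_test(
    renal_alt: int,
    renal_depth: int,
    blood_alt: int,
    blood_depth: int,
    alpha: float = 0.01,
) -> EnrichmentResult:
    """One-sided Fisher's exact test of renal (tumour + normal kidney)
    alt-read excess over blood."""
    if renal_depth == 0 or blood_depth == 0:
        raise CohortError("tumour_enrichment_test requires depth > 0 on both sides")
    table = [
        [renal_alt, renal_depth - renal_alt],
        [blood_alt, blood_depth - blood_alt],
    ]
    _, p = stats.fisher_exact(table, alternative="greater")
    direction = TUMOUR_ENRICHED if p < alpha else NOT_ENRICHED
    return EnrichmentResult(
        p_value=float(p),
        odds_direction=direction,
        contingency=tuple(tuple(r) for r in table),
    )


# ----------------------------------------------------------------------
# 4. Shared-variant selection
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifyConfig:
    """All thresholds of the classification cascade."""

    germline_alpha: float = 1e-3
    expected_het_vaf: float = 0.5
    guard_band: tuple[float, float] = (0.3, 0.7)
    artifact_alpha: float = 1e-5
    fisher_alpha: float = 0.01
    presence_min_alt_reads: int = 3
    presence_error_rate: float = 1e-3
    presence_alpha: float = 0.01


def select_shared_variants(
    table: CohortTable,
    config: ClassifyConfig = ClassifyConfig(),
) -> tuple[list[VariantSite], pd.DataFrame]:
    """Run the full cascade and return tumour-shared variants + audit trail.

    A variant is *shared* iff it is (a) not germline in blood, (b) real
    (not a panel artifact) in at least one tumour, (c) enriched in the
    renal samples versus blood, and (d) present in every tumour sample
    by the presence rule.  The trail records the verdict of every test
    for every variant, including variants failing earlier steps.
    """
    from .phylo import call_presence  # presence rule lives with the phylogeny

    tumours = table.samples_with_role("tumour")
    blood = table.samples_with_role("blood")
    kidney = table.samples_with_role("normal_kidney")
    panel = table.samples_with_role("panel_normal")
    if not blood:
        raise CohortError("cohort has no blood sample; cannot classify")
    if not tumours:
        raise CohortError("cohort has no tumour samples")
    if len(blood) > 1:
        raise CohortError("expected exactly one blood sample")
    b = table.sample_index(blood[0])
    t_idx = [table.sample_index(s) for s in tumours]
    renal_idx = t_idx + [table.sample_index(s) for s in kidney]
    p_idx = [table.sample_index(s) for s in panel]

    n = table.n_sites
    germ_p = np.full(n, np.nan)
    germ_label = np.empty(n, dtype=object)
    for i in range(n):
        v = binomial_germline_test(
            int(table.alt[i, b]),
            int(table.depth[i, b]),
            expected_het_vaf=config.expected_het_vaf,
            alpha=config.germline_alpha,
            guard_band=config.guard_band,
        )
        germ_p[i] = v.p_value
        germ_label[i] = v.label

    # panel background + per-tumour artifact p-values (vectorised)
    if len(p_idx) >= 2:
        mu, rho, _ = _fit_panel_background_arrays(
            table.alt[:, p_idx], table.depth[:, p_idx]
        )
        art_p = np.ones((n, len(t_idx)))
        for j, tj in enumerate(t_idx):
            dep = table.depth[:, tj]
            with np.errstate(invalid="ignore"):
                pj = artifact_pvalues(table.alt[:, tj], np.maximum(dep, 1), mu, rho)
            art_p[:, j] = np.where(dep > 0, pj, 1.0)
        real_any = (art_p < config.artifact_alpha).any(axis=1)
        min_art_p = art_p.min(axis=1)
    else:
        # no usable panel: the artifact filter cannot reject anything
        real_any = np.ones(n, dtype=bool)
        min_art_p = np.full(n, np.nan)

    renal_alt = table.alt[:, renal_idx].sum(axis=1)
    renal_dep = table.depth[:, renal_idx].sum(axis=1)
    blood_alt = table.alt[:, b]
    blood_dep = table.depth[:, b]
    fisher_p = np.full(n, np.nan)
    enriched = np.zeros(n, dtype=bool)
    for i in range(n):
        if renal_dep[i] == 0 or blood_dep[i] == 0:
            continue
        res = tumour_enrichment_test(
            int(renal_alt[i]),
            int(renal_dep[i]),
            int(blood_alt[i]),
            int(blood_dep[i]),
            alpha=config.fisher_alpha,
        )
        fisher_p[i] = res.p_value
        enriched[i] = res.odds_direction == TUMOUR_ENRICHED

    pm = call_presence(
        table.subset_samples(tumours),
        min_alt_reads=config.presence_min_alt_reads,
        error_rate=config.presence_error_rate,
        alpha=config.presence_alpha,
    )
    present_all = (pm.present == 1).all(axis=1) & ~pm.unknown.any(axis=1)
    n_tumours_present = (pm.present == 1).sum(axis=1)

    not_germline = np.array([lab == SOMATIC_CANDIDATE for lab in germ_label])
    shared_mask = not_germline & real_any & enriched & present_all
    shared = [table.sites[i] for i in np.flatnonzero(shared_mask)]

    trail = pd.DataFrame(
        {
            "site": [s.label() for s in table.sites],
            "variant_class": [s.variant_class for s in table.sites],
            "germline_p": germ_p,
            "germline_label": germ_label,
            "artifact_min_p": min_art_p,
            "artifact_real_any_tumour": real_any,
            "fisher_p": fisher_p,
            "tumour_enriched": enriched,
            "n_tumours_present": n_tumours_present,
            "present_all_tumours": present_all,
            "shared": shared_mask,
        }
    )
    return shared, trail


# ----------------------------------------------------------------------
# 5. Germline predisposition screen
# ----------------------------------------------------------------------

PREDISPOSITION_GENES = (
    "FH", "TSC1", "TSC2", "FLCN", "SDHA", "SDHB", "SDHC", "SDHD", "BAP1", "PTEN",
)

#: coding consequences that can plausibly disrupt protein function
NON_SYNONYMOUS = (
    "missense", "stop_gain", "stop_gained", "stop_lost", "start_lost",
    "frameshift", "inframe_insertion", "inframe_deletion", "inframe_duplication",
    "splice_acceptor", "splice_donor",
)


@dataclass
class PredispositionScreen:
    gene_list: tuple[str, ...]
    hits: list[tuple[str, str, str, str]] = field(default_factory=list)
    verdict: str = "no definitive predisposition"


def screen_predisposition(
    germline_variants: list[dict],
    gene_list: tuple[str, ...] = PREDISPOSITION_GENES,
) -> PredispositionScreen:
    """Screen germline calls for coding hits in kidney-cancer genes.

    Each input record needs ``gene``, ``variant``, ``consequence`` and
    ``pathogenicity`` keys (annotation is upstream of this package; the
    pathogenicity label is preserved verbatim).  The verdict is
    "possible predisposition" only when a hit's label asserts
    pathogenicity without contradiction (e.g. not "Benign-Likely
    Benign" or "Conflicting").
    """
    screen = PredispositionScreen(gene_list=tuple(gene_list))
    for rec in germline_variants:
        gene = rec.get("gene", "")
        if gene not in gene_list:
            continue
        consequence = str(rec.get("consequence", "")).lower()
        if consequence not in NON_SYNONYMOUS:
            continue
        label = str(rec.get("pathogenicity", ""))
        screen.hits.append((gene, rec.get("variant", ""), consequence, label))
        norm = label.lower()
        if "pathogenic" in norm and "benign" not in norm and "conflict" not in norm:
            screen.verdict = "possible predisposition"
    return screen
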