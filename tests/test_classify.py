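"""Classification cascade: exact-test oracles, panel background fitting,
enrichment testing and shared-variant selection."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

from embryophylo.classify import (
    ARTIFACT,
    GERMLINE,
    NO_COVERAGE,
    REAL,
    SOMATIC_CANDIDATE,
    artifact_test,
    binomial_germline_test,
    binomial_pvalue_two_sided,
    fit_panel_background,
    screen_predisposition,
    select_shared_variants,
    tumour_enrichment_test,
)
from embryophylo.cohort import CohortError, CohortTable, SampleMeta

from conftest import make_site


# ----------------------------------------------------------------------
# independent brute-force oracles (exact rational arithmetic where possible)
# ----------------------------------------------------------------------

def binom_two_sided_oracle(a: int, n: int) -> float:
    """Minimum-likelihood two-sided p at p=0.5 by full pmf enumeration."""
    pmf = [Fraction(comb(n, k), 2**n) for k in range(n + 1)]
    return float(sum(q for q in pmf if q <= pmf[a]))


def betabinom_sf_oracle(a: int, n: int, al: float, be: float) -> float:
    """P(X >= a) from the pmf product/ratio recurrence (no scipy)."""
    pmf = 1.0
    for j in range(n):
        pmf *= (be + j) / (al + be + j)
    total = pmf if 0 >= a else 0.0
    for k in range(n):
        pmf *= (n - k) / (k + 1) * (al + k) / (be + n - k - 1)
        if k + 1 >= a:
            total += pmf
    return total


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p by full hypergeometric enumeration (exact)."""
    n1, n2, K, N = a + b, c + d, a + c, a + b + c + d
    tot = Fraction(comb(N, K))
    s = sum(Fraction(comb(n1, k) * comb(n2, K - k))
            for k in range(a, min(n1, K) + 1))
    return float(s / tot)


class TestBinomialGermline:
    def test_pvalues_match_enumeration_oracle(self):
        for n in range(1, 31):
            for a in range(n + 1):
                assert binomial_pvalue_two_sided(a, n) == pytest.approx(
                    binom_two_sided_oracle(a, n), abs=1e-12
                )

    def test_symmetric_centre_is_germline(self):
        v = binomial_germline_test(50, 100)
        assert v.p_value > 0.9 and v.label == GERMLINE

    def test_zero_alt_small_depth(self):
        v = binomial_germline_test(0, 10)
        assert v.p_value == pytest.approx(2 * 0.5**10)
        assert v.label == SOMATIC_CANDIDATE

    def test_guard_band_keeps_low_depth_het(self):
        # 3/8: p ~ 0.727 and VAF 0.375 inside [0.3, 0.7] -> germline
        v = binomial_germline_test(3, 8)
        assert v.p_value == pytest.approx(0.7265625)
        assert v.label == GERMLINE

    def test_guard_band_overrides_nonsignificant_p(self):
        # tiny depth: p >= alpha but VAF 0 outside the band -> somatic
        v = binomial_germline_test(0, 3)
        assert v.p_value >= 1e-3 and v.label == SOMATIC_CANDIDATE

    def test_no_coverage(self):
        assert binomial_germline_test(0, 0).label == NO_COVERAGE


class TestPanelBackground:
    def test_all_zero_panel_pseudocount(self):
        bg = fit_panel_background(np.zeros(21, int), np.full(21, 100))
        assert bg.mean_error == pytest.approx(0.5 / 2100.5)
        assert bg.overdispersion_rho == pytest.approx(1e-6)
        assert bg.n_panel == 21

    def test_moments_close_to_grid_mle(self):
        """MoM estimates agree with a grid-search ML oracle on a bimodal
        panel (alternating 5% and 0% samples)."""
        alt = np.array([5 if i % 2 == 0 else 0 for i in range(21)])
        dep = np.full(21, 100)
        bg = fit_panel_background(alt, dep)
        mus = np.linspace(0.001, 0.1, 200)
        rhos = np.linspace(1e-4, 0.3, 200)
        best, best_ll = None, -np.inf
        for mu in mus:
            s = 1 / rhos - 1
            ll = stats.betabinom.logpmf(
                alt[:, None], 100, (mu * s)[None, :], ((1 - mu) * s)[None, :]
            ).sum(axis=0)
            if ll.max() > best_ll:
                best_ll = ll.max()
                best = (mu, rhos[ll.argmax()])
        assert bg.mean_error == pytest.approx(best[0], abs=0.005)
        assert bg.overdispersion_rho == pytest.approx(best[1], abs=0.05)

    def test_single_sample_rejected(self):
        with pytest.raises(CohortError):
            fit_panel_background(np.array([0]), np.array([100]))


class TestArtifactTest:
    def test_strong_signal_vs_clean_panel_is_real(self):
        bg = fit_panel_background(np.zeros(21, int), np.full(21, 100))
        verdict, p = artifact_test(10, 100, bg)
        assert verdict == REAL and p < 1e-5
        assert p == pytest.approx(
            betabinom_sf_oracle(10, 100, *_ab(bg)), abs=1e-10
        )

    def test_recurrent_panel_error_is_artifact(self):
        rng = np.random.default_rng(0)
        alt = rng.binomial(100, 0.05, size=21)
        bg = fit_panel_background(alt, np.full(21, 100))
        verdict, p = artifact_test(5, 100, bg)
        assert verdict == ARTIFACT and p > 1e-3

    def test_zero_alt_is_artifact_with_p_one(self):
        bg = fit_panel_background(np.zeros(21, int), np.full(21, 100))
        verdict, p = artifact_test(0, 100, bg)
        assert verdict == ARTIFACT and p == 1.0

    def test_tail_matches_recurrence_oracle_on_grid(self):
        bg = fit_panel_background(
            np.array([2, 0, 1, 0, 3, 0, 0, 1, 0, 0]), np.full(10, 150)
        )
        al, be = _ab(bg)
        for n in (50, 120, 200):
            for a in (0, 1, 3, 7, 15):
                p = artifact_test(a, n, bg)[1]
                assert p == pytest.approx(
                    betabinom_sf_oracle(a, n, al, be), abs=1e-10
                )


def _ab(bg):
    s = 1.0 / bg.overdispersion_rho - 1.0
    return bg.mean_error * s, (1.0 - bg.mean_error) * s


class TestEnrichment:
    @pytest.mark.parametrize(
        "table,enriched",
        [((10, 100, 0, 500), True), ((5, 100, 25, 500), False),
         ((0, 100, 0, 500), False)],
    )
    def test_examples_match_enumeration(self, table, enriched):
        ra, rd, ba, bd = table
        res = tumour_enrichment_test(ra, rd, ba, bd)
        oracle = fisher_greater_oracle(ra, rd - ra, ba, bd - ba)
        assert res.p_value == pytest.approx(oracle, abs=1e-10)
        assert (res.odds_direction == "tumour_enriched") == enriched

    def test_no_alt_anywhere_p_one(self):
        assert tumour_enrichment_test(0, 100, 0, 500).p_value == 1.0

    def test_zero_depth_rejected(self):
        with pytest.raises(CohortError):
            tumour_enrichment_test(0, 0, 5, 100)

    def test_grid_against_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            rd = int(rng.integers(1, 200))
            bd = int(rng.integers(1, 200))
            ra = int(rng.integers(0, rd + 1))
            ba = int(rng.integers(0, bd + 1))
            res = tumour_enrichment_test(ra, rd, ba, bd)
            assert res.p_value == pytest.approx(
                fisher_greater_oracle(ra, rd - ra, ba, bd - ba), abs=1e-10
            )


# ----------------------------------------------------------------------
# shared-variant selection on a hand-built cohort
# ----------------------------------------------------------------------

def _mini_cohort():
    samples = (
        [SampleMeta(t, "tumour") for t in "ACDE"]
        + [SampleMeta("K", "normal_kidney"), SampleMeta("B", "blood")]
        + [SampleMeta(f"P{i}", "panel_normal") for i in range(4)]
    )
    # rows: trunk-like shared, germline, present in 3 of 4 tumours,
    #       panel-recurrent artifact
    alt = np.array([
        [35, 38, 33, 36, 50, 30, 0, 0, 0, 0],
        [36, 40, 38, 35, 250, 265, 0, 0, 0, 0],
        [34, 37, 36, 0, 0, 0, 0, 0, 0, 0],
        [4, 5, 3, 4, 25, 28, 2, 3, 2, 2],
    ])
    depth = np.array([
        [75, 80, 72, 78, 500, 530, 40, 40, 40, 40],
        [74, 81, 76, 70, 500, 530, 40, 40, 40, 40],
        [70, 75, 74, 77, 500, 530, 40, 40, 40, 40],
        [75, 78, 74, 76, 500, 530, 40, 40, 40, 40],
    ])
    sites = [make_site(pos=100 + i) for i in range(4)]
    return CohortTable(sites, samples, alt, depth)


class TestSelectShared:
    def test_cascade_verdicts(self):
        shared, trail = select_shared_variants(_mini_cohort())
        assert [s.pos for s in shared] == [100]
        t = trail.set_index("site")
        assert t.loc["1:101:A>T", "germline_label"] == "germline"
        assert not t.loc["1:102:A>T", "present_all_tumours"]
        assert t.loc["1:102:A>T", "n_tumours_present"] == 3
        assert not t.loc["1:103:A>T", "artifact_real_any_tumour"]

    def test_blood_required(self):
        table = _mini_cohort().subset_samples(
            ["A", "C", "D", "E", "K", "P0", "P1"]
        )
        with pytest.raises(CohortError, match="blood"):
            select_shared_variants(table)

    def test_case_study_recovers_planted_trunk(self, case_study, case_study_passed):
        _table, _cn, truth = case_study
        shared, _ = select_shared_variants(case_study_passed)
        assert {v.key for v in shared} == {v.key for v in truth.shared_truth}

    def test_sensitivity_precision_over_replicates(self):
        """Embryonic shared variants are recovered with sensitivity and
        precision >= 0.95 across random synthetic embryos."""
        from embryophylo.quality import apply_quality_filters
        from embryophylo.simulate import embryo_params, simulate_cohort

        tp = fp = fn = 0
        rng = np.random.default_rng(1234)
        for _ in range(10):
            table, _cn, truth = simulate_cohort(
                embryo_params(int(rng.integers(2**31 - 1)))
            )
            passed, _ = apply_quality_filters(table)
            shared, _ = select_shared_variants(passed)
            got = {v.key for v in shared}
            want = {v.key for v in truth.shared_truth}
            tp += len(got & want)
            fp += len(got - want)
            fn += len(want - got)
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95


class TestPredispositionScreen:
    def test_benign_hit_reported_but_not_predisposing(self):
        recs = [{"gene": "FLCN", "variant": "17:17118598:C>T",
                 "consequence": "missense",
                 "pathogenicity": "Benign-Likely Benign"}]
        screen = screen_predisposition(recs)
        assert len(screen.hits) == 1
        assert screen.hits[0][3] == "Benign-Likely Benign"
        assert screen.verdict == "no definitive predisposition"

    def test_empty_input(self):
        assert screen_predisposition([]).hits == []

    def test_pathogenic_stop_gain_flags_predisposition(self):
        recs = [{"gene": "TSC2", "variant": "16:2100000:C>T",
                 "consequence": "stop_gain", "pathogenicity": "Pathogenic"}]
        assert screen_predisposition(recs).verdict == "possible predisposition"

    def test_synonymous_and_off_list_ignored(self):
        recs = [
            {"gene": "TSC2", "variant": "x", "consequence": "synonymous",
             "pathogenicity": "Pathogenic"},
            {"gene": "BRCA1", "variant": "y", "consequence": "missense",
             "pathogenicity": "Pathogenic"},
        ]
        screen = screen_predisposition(recs)
        assert screen.hits == [] and screen.verdict == "no definitive predisposition"
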