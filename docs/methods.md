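# Methods

`embryophylo` reconstructs the shared embryonic history of multiple
synchronous tumours from bulk sequencing read counts. This note records
the models, the parameters that matter, the numerical choices, and what
the synthetic-data experiments do and do not demonstrate.

## Problem setting

Four renal tumours, one normal kidney sample, one blood sample and an
unrelated normal panel are deeply sequenced (tumours ~75x, normals
~500–550x, panel ~40x). If the tumours descend from a single embryonic
cell, they share that cell's somatic mutations; those same mutations are
present as low-VAF mosaicism in normal tissues, at cell fractions set by
how much of each tissue descends from the mutated lineage. The pipeline
(i) isolates the somatic variants shared by every tumour, (ii) arranges
all somatic variants on a tumour phylogeny, and (iii) converts the
shared ("trunk") burden plus normal-tissue detectability into an
embryonic timing of the tumours' most recent common ancestor (MRCA).

## Filter cascade

**Quality filters.** SNVs must satisfy CLPM ≤ 0 (no clipped supporting
reads), ASMD ≥ 140 (median alignment score), MAPQ ≥ 30 and BASEQ ≥ 25,
all boundaries inclusive. Non-SNV classes (DNV, indel, duplication) are
assumed to have passed their caller's own filters and pass through
flagged `not_quality_filtered`. The filter is monotone in its
thresholds and never inspects read counts.

**Germline test.** Exact binomial test of the blood counts against the
heterozygous expectation VAF = 0.5, two-sided by the minimum-likelihood
rule, at α = 1e-3, with a guard band requiring the observed VAF in
[0.3, 0.7]. The guard band serves both directions: at very high depth,
trivial deviations from 0.5 are formally significant but still
germline; at low depth a mosaic VAF of 0.2 can be non-significant but
should not be called germline.

**Panel artifact filter.** Per site, a beta-binomial error model is
fitted to the unrelated normal panel by method of moments: mean error
μ = (Σalt + ½)/(Σdepth + ½) (the half-count keeps an all-zero panel
strictly positive) and intra-class correlation ρ from the
depth-weighted moment identity
E[S] = μ(1−μ)[Σ(1−dᵢ/W) + ρ Σ(dᵢ−1)(1−dᵢ/W)], with
S = Σdᵢ(pᵢ−μ)², clamped to [1e-6, 0.99]. A tumour's counts are *real*
only if the upper-tail beta-binomial probability of ≥ alt reads is
below α = 1e-5. The tail is computed by direct log-pmf summation; the
library survival function (1 − cdf) loses all precision below ~1e-9,
which is exactly the regime this α operates in.

**Enrichment test.** One-sided Fisher's exact test of aggregated renal
counts (all tumours + normal kidney, summed) against blood, selecting
renal excess at p < 0.01. No multiple-testing correction is applied on
this cascade: the artifact filter's stringency (α = 1e-5) carries the
burden of genome-wide error control, and the enrichment cut-off is a
raw threshold by design.

**Shared set.** A variant is shared iff it is non-germline, real in at
least one tumour, renal-enriched, and *present* in every tumour.
Presence in a sample requires alt ≥ 3 reads **and** a binomial
upper-tail probability < 0.01 under a per-base error rate of 1e-3. The
read floor protects 75x tumours; the tail test protects 500x+ normals,
where 3 error reads are unremarkable. Depth 0 is "unknown", never
"absent".

## Clonality

A variant present in every tumour cell at multiplicity m on total copy
number n_t in a sample of purity ρ has expected VAF
f·ρ·m / (ρ·n_t + 2(1−ρ)) with f the carrying cell fraction. Observed
VAFs are rescaled by 0.5/expected so every clonal variant targets 0.5
regardless of local copy number. Default multiplicity is 1 — shared
embryonic variants are heterozygous point events predating tumour
copy-number changes; on a monosomic background a raw VAF near 0 is
flagged `allele_likely_lost` rather than inflated. Purity defaults to
1.0 when the copy-number input carries none.

The clonality verdict transforms each tumour's exact Clopper–Pearson
CI to the adjusted scale and requires 0.5 inside every interval. α is
interpreted per *variant*: with m tumours each CI uses Šidák confidence
(1−α)^(1/m). A literal per-tumour 95% CI would mislabel a truly clonal
variant with probability ≈ 1−0.95⁴ ≈ 0.14, so a 15-variant all-clonal
trunk would routinely fail somewhere by construction — per-variant
control is the convention that matches the scientific claim being
tested.

## Phylogeny

**Perfect phylogeny.** Variants are grouped by their tumour presence
pattern; patterns must be pairwise laminar (nested or disjoint — the
three-gamete condition). The unique minimal tree is assembled by
containment, with variants mapped to the branch whose clade equals
their pattern and branch lengths equal to mutation counts (Newick
export). Conflicts raise a structured error naming the incompatible
pattern pairs; variants with an unknown cell are set aside and
reported, not guessed.

**Dirichlet-process clustering.** The sampler route groups somatic SNVs
by their joint VAF vector across tumours: a DP mixture with per-sample
binomial likelihood alt ~ Binom(depth, q_ks), uniform Beta(1,1) base
measure per sample (conjugate, so cluster VAFs integrate out), and a
Gamma(1,1) hyperprior on the concentration resampled by the
Escobar–West auxiliary-variable step. Collapsed Gibbs, default 20,000
sweeps with a 10,000-sweep burn-in, initialised from the one-cluster
partition. The reported partition is the posterior *mode* over
post-burn-in sweeps, ties broken by earliest occurrence (labels are
canonicalised by first appearance, so label permutation cannot split a
partition's count); cluster VAFs are posterior means given that
partition. Joint clustering across the four tumours is used — with
only four samples, the cross-sample signature is what separates trunk,
branch and private clones.

**Reconciliation.** Per tree branch, the fraction of its variants whose
cluster VAF is ≈0 (≤ 0.05 by default) in every sample outside the
branch's clade.

## Embryonic timing

Shared variants are classified `both_tissues` / `kidney_only` /
`neither` by the presence rule applied to normal kidney and blood; a
blood-positive-kidney-negative call gets its own category
(`blood_only`) and an `inconsistent_with_lineage` flag, since it
violates the nesting expected of a kidney-fated MRCA — forcing it into
the three expected categories would hide the inconsistency. Variants
are ordered by descending kidney VAF (ties by coordinate) and category
ranks are checked for monotonicity along the order; inversions are
counted, never repaired.

Burden maps to weeks post-conception through a piecewise-linear curve
over anchors (weeks, expected burden), default (0, 0) and (8, 25) —
mesodermal cells carry on average 25 mutations by week 8 — with
extrapolation at the last segment's slope and the exact (Garwood)
Poisson 95% CI of the burden mapped through the same curve. A trunk of
15 mutations gives 4.8 weeks (95% CI ≈ 2.7–7.9). The anatomical anchors
(blood/kidney split ≈ week 3 at gastrulation, left/right kidney split ≈
week 3.5) are reported alongside, not forced into the point estimate:
the curve makes the informal "well before 8 weeks" reasoning computable
without pretending more precision than the calibration has.

## Synthetic embryo generator

Lineage nodes are binary strings (zygote = ""), one edge per division,
Poisson(1.5) mutations per division at unique loci of a toy genome
(10 Mb over 23 chromosomes — small enough for desk-scale files).
Tissues are mixtures of contributions from named nodes; a variant's
cell fraction in a tissue is the summed contribution of nodes inside
its branch's subtree, which makes nested lineages produce nested
fractions by construction. Tumours are clonal expansions seeded from
nodes below the MRCA, with private mutations, optional whole-chromosome
losses (a pre-existing het variant on a monosomic chromosome is
retained or lost with equal probability; post-loss mutations sit on
the surviving homologue) and a purity entering the expected-VAF
formula together with normal-cell contamination. Read counts are
depth ~ Poisson(coverage), alt ~ Binom(depth, q + error/3). Panel
artifact sites carry a site-specific Beta-distributed error rate shared
by panel *and* patient samples — recurrence across unrelated samples is
precisely what makes them filterable.

**Division-to-week schedule.** Divisions map to weeks via a
divisions-per-week schedule, default (3, 2): three divisions in week 1,
then two per week. At 1.5 mutations/division this accrues ≈25 mutations
by week 8 — deliberately consistent with the burden calibration the
estimator uses. A strongly front-loaded schedule (e.g. daily cleavage
divisions all of week 1) would make burden linear in divisions but
far-from-linear in weeks, contradicting the linear anchor curve and
building a systematic multi-week bias into every timing estimate; the
package treats the effective mutationally-relevant division rate as
roughly uniform on the week scale, which is what the (0,0)–(8,25)
anchor pair asserts.

**Packaged case study.** `case_study_config()` pins the trunk at 15
mutations (13 SNV, 1 DNV, 1 twelve-bp in-frame duplication) over ten
divisions, MRCA at week 4.5. Blood contributions make divisions 1–4
(7 variants) blood-detectable with VAFs decaying from ≈0.13; kidney
contributions extend through division 7 (5 further variants
kidney-only); divisions 8–10 (3 variants) are in neither normal
tissue. Four tumours seed from grandchildren of the MRCA (two cherries),
with 22–31 private mutations each and whole-chromosome losses (chr1;
chr1+chr14) in the two oncocytoma-like lesions. Embryonic-lineage
variants are placed on chromosomes unaffected by those losses so the
planted truth "shared by all four tumours" is invariant to the CN
events; QC failures are injected only at artifact loci (where
alignment-driven failures arise in real data). Cell-fraction margins
were chosen analytically — the smallest planted normal-tissue VAF is
0.03, giving an expected ≥15 alt reads at 500x against a detection
threshold of 4 — and the packaged seed is one under which the fixed
realisation reproduces the scenario's headline outputs.

## Problem sizes used in validation

- Statistic oracles: exhaustive to depth 30 and sampled to depth 200,
  exact rational or product-recurrence arithmetic, agreement ≤1e-10.
- Artifact-filter type-I error: 10⁵ pure-noise sites, 21-sample panel
  at 500x, per-base error 1e-3.
- DP co-clustering: two planted clusters of 100 variants at depth 100,
  1,500 sweeps (700 burn-in) — the separation is decided within the
  first tens of sweeps; the pipeline default chain is much longer.
- MRCA timing: 50 simulated embryos with MRCA depth uniform over 8–13
  divisions and Poisson trunks, full cascade re-run per embryo.
- Cascade sensitivity/precision: 10 random embryos (~200–250 sites
  each), pooled.

## What the synthetic experiments do not show

The generator emulates read-count statistics, not reads: no alignment
error structure (artifact QC values are injected, not computed), no
strand information (the artifact filter is strand-pooled), no subclonal
copy number within a segment, no sequencing-depth GC waviness, and
tissue cell fractions follow the plan exactly rather than a stochastic
developmental bottleneck model. Passing the packaged recovery tests
shows the inference chain is correct under its own model assumptions at
realistic depths; it does not validate the upstream callers those
counts come from, nor the biological calibration constants (25
mutations at 8 weeks; week-3 gastrulation split), which are inputs.

## Known limitations

- Embryonic variants falling on a chromosome later lost by a tumour
  drop out of the detectable shared set; real analyses should inspect
  the `n_tumours_present` trail column for near-trunk variants.
- The DNV representation accepts either merged MNV records or separate
  SNVs on input, but the simulator always emits merged records.
- The germline guard band [0.3, 0.7] presumes diploid germline loci;
  a germline variant inside a constitutional CNV could leak through.
- `blood_only` calls are reported but not modelled; systematically
  non-zero counts there would indicate sample swap or contamination,
  which the pipeline flags but cannot diagnose.
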