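"""Ground-truthed synthetic embryogenesis and sequencing cohorts.

The generator emulates the statistical structure the pipeline assumes:

* a binary embryonic lineage in which every cell division deposits a
  Poisson number of new mutations on unique loci of a toy genome;
* asymmetric tissue composition — blood and normal kidney are mixtures
  of contributions from named lineage nodes, so early mutations occupy
  large cell fractions and late ones vanish (the VAF-decay pattern of
  developmental mosaicism);
* four tumours seeded from cells below one ancestral lineage cell (the
  MRCA), each with private clonal mutations, optional whole-chromosome
  losses and a purity;
* depth- and error-aware read sampling: per-sample Poisson depths
  (tumours ~75x, normals ~500-550x, panel ~40x) with binomial alt
  counts at the expected allele fraction plus a per-base error rate;
* recurrent panel artifacts: loci with an inflated site-specific error
  rate shared by the unrelated normal panel *and* the patient samples —
  which is exactly what makes them filterable.

Lineage nodes are addressed by binary strings: ``""`` is the zygote and
children of node ``x`` are ``x+"0"`` and ``x+"1"``.  Only the ancestor
closure of referenced nodes is materialised; one edge = one division.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import (
    CohortError,
    CohortTable,
    CopyNumberProfile,
    SampleMeta,
    VariantSite,
)

BASES = "ACGT"

DEFAULT_CHROMS = tuple(str(c) for c in range(1, 23)) + ("X",)


@dataclass(frozen=True)
class TumourPlan:
    """One tumour: seeding lineage node, private burden, CN losses, purity."""

    seed_node: str
    n_private_mutations: int = 25
    loss_chroms: tuple[str, ...] = ()
    purity: float = 1.0


@dataclass
class SimParams:
    """All knobs of the synthetic embryo + sequencing generator.

    ``tissue_plan`` maps a normal-tissue name to (lineage node,
    contribution fraction) pairs; fractions per tissue must sum to at
    most 1.  ``divisions_per_week`` gives divisions in week 1, then in
    every later week (last entry repeats), tying division depth to
    weeks post-conception; the default (3, 2) accrues ~25 mutations by
    week 8 at 1.5 mutations/division, consistent with the burden
    calibration used for timing.
    """

    mutations_per_division: float = 1.5
    divisions_to_mrca: int = 10
    tissue_plan: dict = field(default_factory=dict)
    tumour_plan: dict = field(default_factory=dict)
    fixed_branch_mutations: dict = field(default_factory=dict)
    non_snv_trunk: dict = field(default_factory=dict)
    coverage: dict = field(default_factory=dict)
    tumour_coverage: float = 75.0
    kidney_coverage: float = 500.0
    blood_coverage: float = 530.0
    panel_coverage: float = 40.0
    n_panel: int = 21
    seq_error: float = 1e-3
    n_germline_sites: int = 60
    panel_artifact_sites: int = 25
    artifact_error: float = 0.05
    qc_fail_fraction: float = 0.1
    genome_size: int = 10_000_000
    chroms: tuple[str, ...] = DEFAULT_CHROMS
    lineage_chroms: tuple[str, ...] | None = None
    divisions_per_week: tuple[int, ...] = (3, 2)
    kidney_id: str = "K"
    blood_id: str = "B"
    seed: int = 0

    def validate(self) -> None:
        if self.mutations_per_division < 0:
            raise CohortError("mutations_per_division must be >= 0")
        for tissue, plan in self.tissue_plan.items():
            total = sum(f for _, f in plan)
            if total > 1.0 + 1e-9:
                raise CohortError(f"{tissue} contributions sum to {total} > 1")
            if any(f < 0 for _, f in plan):
                raise CohortError(f"{tissue} has a negative contribution")
        if not all(v > 0 for v in self.divisions_per_week):
            raise CohortError("divisions_per_week entries must be positive")
        if not 0.0 <= self.seq_error < 1.0:
            raise CohortError("seq_error must lie in [0, 1)")

    @property
    def chrom_length(self) -> int:
        return self.genome_size // len(self.chroms)

    def week_of_division(self, division: int) -> float:
        """Map a division index to weeks post-conception."""
        if division <= 0:
            return 0.0
        sched = self.divisions_per_week
        week, done = 0, 0
        while True:
            per = sched[min(week, len(sched) - 1)]
            if done + per >= division:
                return week + (division - done) / per
            done += per
            week += 1


@dataclass
class SyntheticTruth:
    """Everything the generator knows and the pipeline must recover."""

    params: SimParams
    branch_mutations: dict              # node id -> [VariantSite]
    variant_branch: dict                # (chrom,pos,ref,alt) -> node id
    mrca_node: str
    mrca_week: float
    shared_truth: list                  # trunk variants (root -> MRCA path)
    tissue_cell_fractions: dict = field(default_factory=dict)
    tumour_private: dict = field(default_factory=dict)
    germline_sites: list = field(default_factory=list)
    artifact_sites: list = field(default_factory=list)
    cn_profiles: dict = field(default_factory=dict)

    @property
    def mrca_division(self) -> int:
        return len(self.mrca_node)

    def truth_detectability(self) -> dict:
        """Planted detectability category per trunk variant, from the
        noiseless cell fractions (blood+kidney / kidney only / neither)."""
        kid = self.tissue_cell_fractions.get("normal_kidney", {})
        blo = self.tissue_cell_fractions.get("blood", {})
        out = {}
        for v in self.shared_truth:
            k = kid.get(v.key, 0.0) > 0
            b = blo.get(v.key, 0.0) > 0
            out[v.key] = (
                "both_tissues" if (k and b)
                else "kidney_only" if k
                else "blood_only" if b
                else "neither"
            )
        return out


# ----------------------------------------------------------------------
# Lineage simulation
# ----------------------------------------------------------------------

def _ancestor_closure(nodes) -> list[str]:
    closure = set()
    for node in nodes:
        for i in range(len(node) + 1):
            closure.add(node[:i])
    return sorted(closure, key=lambda n: (len(n), n))


def _draw_locus(rng, params: SimParams, used: set, chroms) -> tuple[str, int]:
    for _ in range(10000):
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(1, params.chrom_length + 1))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return chrom, pos
    raise CohortError("toy genome exhausted; increase genome_size")


def _make_variant(rng, chrom, pos, variant_class="SNV") -> VariantSite:
    if variant_class == "SNV":
        ref = BASES[rng.integers(4)]
        alt = BASES[(BASES.index(ref) + 1 + rng.integers(3)) % 4]
    elif variant_class == "DNV":
        r1, r2 = rng.integers(4), rng.integers(4)
        ref = BASES[r1] + BASES[r2]
        alt = BASES[(r1 + 1 + rng.integers(3)) % 4] + BASES[(r2 + 1 + rng.integers(3)) % 4]
    elif variant_class == "duplication":
        ref = BASES[rng.integers(4)]
        alt = ref + "".join(BASES[rng.integers(4)] for _ in range(12))
    else:
        raise CohortError(f"unsupported simulated class {variant_class}")
    return VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt,
                       variant_class=variant_class)


def simulate_lineage(params: SimParams) -> SyntheticTruth:
    """Build the lineage tree and deposit mutations on its branches.

    Only branches on paths to referenced nodes (tissue plan, tumour
    seeds) are materialised; each such branch represents one division
    and acquires Poisson(mutations_per_division) mutations at unique
    loci — unless the branch has a fixed count override, which the
    packaged case study uses to pin the trunk burden.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    referenced = set(params.fixed_branch_mutations)
    for plan in params.tissue_plan.values():
        referenced.update(node for node, _ in plan)
    seeds = {t: p.seed_node for t, p in params.tumour_plan.items()}
    referenced.update(seeds.values())
    nodes = _ancestor_closure(referenced)
    for tissue, plan in params.tissue_plan.items():
        for node, _ in plan:
            if node not in nodes:  # closure always contains them; guard anyway
                raise CohortError(f"{tissue} references missing node {node!r}")

    if not seeds:
        mrca = ""
    else:
        vals = list(seeds.values())
        mrca = vals[0]
        for s in vals[1:]:
            i = 0
            while i < min(len(mrca), len(s)) and mrca[i] == s[i]:
                i += 1
            mrca = mrca[:i]

    chroms = params.lineage_chroms or params.chroms
    used: set[tuple[str, int]] = set()
    branch_mutations: dict[str, list[VariantSite]] = {}
    variant_branch: dict[tuple, str] = {}
    trunk: list[VariantSite] = []
    trunk_nodes = [mrca[:i] for i in range(len(mrca) + 1)]
    trunk_idx = 0
    for node in nodes:
        if node == "" and node not in params.fixed_branch_mutations:
            continue  # the zygote has no entering branch
        if node in params.fixed_branch_mutations:
            count = int(params.fixed_branch_mutations[node])
        else:
            count = int(rng.poisson(params.mutations_per_division))
        muts = []
        on_trunk = node in trunk_nodes
        for _ in range(count):
            vclass = "SNV"
            if on_trunk and trunk_idx in params.non_snv_trunk:
                vclass = params.non_snv_trunk[trunk_idx]
            chrom, pos = _draw_locus(rng, params, used, chroms)
            v = _make_variant(rng, chrom, pos, vclass)
            muts.append(v)
            variant_branch[v.key] = node
            if on_trunk:
                trunk.append(v)
                trunk_idx += 1
        branch_mutations[node] = muts

    truth = SyntheticTruth(
        params=params,
        branch_mutations=branch_mutations,
        variant_branch=variant_branch,
        mrca_node=mrca,
        mrca_week=params.week_of_division(len(mrca)),
        shared_truth=trunk,
    )
    realise_tissues(truth)
    return truth


def realise_tissues(truth: SyntheticTruth) -> dict:
    """Per-tissue, per-variant cell fractions from the tissue plan.

    A variant on the branch entering node ``n`` is carried by a plan
    contribution at node ``m`` iff ``m`` lies in the subtree of ``n``
    (``m`` has prefix ``n``); its cell fraction in the tissue is the sum
    of such contributions.  Nesting of lineages therefore produces
    nested cell fractions automatically.
    """
    params = truth.params
    fractions: dict[str, dict[tuple, float]] = {}
    for tissue, plan in params.tissue_plan.items():
        per_variant: dict[tuple, float] = {}
        for branch, muts in truth.branch_mutations.items():
            cf = sum(f for node, f in plan if node.startswith(branch))
            for v in muts:
                per_variant[v.key] = cf
        fractions[tissue] = per_variant
    truth.tissue_cell_fractions = fractions
    return fractions


# ----------------------------------------------------------------------
# Sequencing
# ----------------------------------------------------------------------

def _multiplicity(rng, carried: bool, total_cn: int, post_cn_event: bool) -> int:
    """Mutant-allele copies in tumour cells at a (possibly lost) locus.

    A pre-existing heterozygous variant on a monosomic chromosome was
    retained or lost with equal probability; mutations acquired after
    the loss sit on the surviving homologue.
    """
    if not carried:
        return 0
    if total_cn == 2 or post_cn_event:
        return 1
    return int(rng.integers(2))  # total_cn == 1: retained or lost


def sequence_cohort(
    truth: SyntheticTruth,
) -> tuple[CohortTable, dict[str, CopyNumberProfile]]:
    """Sample read counts for every site and sample.

    Depth ~ Poisson(coverage); alt ~ Binomial(depth, q) with q the
    expected allele fraction given cell fractions, copy number and
    purity, plus a per-base error contribution.  Adds germline
    heterozygous sites, tumour-private and branch mutations, and
    recurrent panel-artifact loci; emits QC annotations that pass the
    default thresholds except for a configurable fraction of artifact
    sites that deliberately fail.
    """
    params = truth.params
    rng = np.random.default_rng(params.seed + 1)
    tumours = sorted(params.tumour_plan)
    kid, blo = params.kidney_id, params.blood_id
    panel_ids = [f"P{i+1:02d}" for i in range(params.n_panel)]

    samples = (
        [SampleMeta(t, "tumour", params.coverage.get(t, params.tumour_coverage))
         for t in tumours]
        + [SampleMeta(kid, "normal_kidney", params.kidney_coverage),
           SampleMeta(blo, "blood", params.blood_coverage)]
        + [SampleMeta(p, "panel_normal", params.panel_coverage) for p in panel_ids]
    )
    coverage = {s.sample_id: s.mean_coverage for s in samples}

    cn_profiles = {}
    for t in tumours:
        plan = params.tumour_plan[t]
        segs = [
            (c, 1, params.chrom_length, 1, 0) for c in plan.loss_chroms
        ]
        cn_profiles[t] = CopyNumberProfile(sample_id=t, purity=plan.purity,
                                           segments=segs)
    truth.cn_profiles = cn_profiles

    used = set(truth.variant_branch)
    used = {(c, p) for c, p, _, _ in used}

    # tumour-private clonal mutations (drawn over the whole toy genome)
    truth.tumour_private = {}
    for t in tumours:
        plan = params.tumour_plan[t]
        muts = []
        for _ in range(plan.n_private_mutations):
            chrom, pos = _draw_locus(rng, params, used, params.chroms)
            muts.append(_make_variant(rng, chrom, pos))
        truth.tumour_private[t] = muts

    truth.germline_sites = []
    for _ in range(params.n_germline_sites):
        chrom, pos = _draw_locus(rng, params, used, params.chroms)
        truth.germline_sites.append(_make_variant(rng, chrom, pos))

    truth.artifact_sites = []
    art_rates = []
    for _ in range(params.panel_artifact_sites):
        chrom, pos = _draw_locus(rng, params, used, params.chroms)
        truth.artifact_sites.append(_make_variant(rng, chrom, pos))
        # site-specific recurrent error rate, mean params.artifact_error
        m = params.artifact_error
        art_rates.append(rng.beta(100 * m, 100 * (1 - m)))

    kid_cf = truth.tissue_cell_fractions.get("normal_kidney", {})
    blo_cf = truth.tissue_cell_fractions.get("blood", {})

    sites: list[VariantSite] = []
    q_rows: list[np.ndarray] = []
    err = params.seq_error / 3.0
    sample_ids = [s.sample_id for s in samples]

    def q_for(site, kind, owner=None, art_rate=0.0) -> np.ndarray:
        q = np.zeros(len(sample_ids))
        for j, sid in enumerate(sample_ids):
            meta = samples[j]
            if kind == "artifact":
                q[j] = art_rate
                continue
            if meta.tissue_role == "panel_normal":
                q[j] = 0.0
                continue
            if meta.tissue_role == "normal_kidney":
                cf = 1.0 if kind == "germline" else (
                    kid_cf.get(site.key, 0.0) if kind == "lineage" else 0.0)
                q[j] = 0.5 * cf
                continue
            if meta.tissue_role == "blood":
                cf = 1.0 if kind == "germline" else (
                    blo_cf.get(site.key, 0.0) if kind == "lineage" else 0.0)
                q[j] = 0.5 * cf
                continue
            # tumour sample
            plan = params.tumour_plan[sid]
            rho = plan.purity
            total, _minor = cn_profiles[sid].cn_at(site.chrom, site.pos)
            if kind == "germline":
                m = _multiplicity(rng, True, total, post_cn_event=False)
                normal_copies = 1.0
            elif kind == "lineage":
                branch = truth.variant_branch[site.key]
                carried = plan.seed_node.startswith(branch)
                m = _multiplicity(rng, carried, total, post_cn_event=False)
                normal_copies = kid_cf.get(site.key, 0.0)
            else:  # private
                carried = owner == sid
                m = _multiplicity(rng, carried, total, post_cn_event=True)
                normal_copies = 0.0
            denom = rho * total + 2.0 * (1.0 - rho)
            q[j] = (rho * m + (1.0 - rho) * normal_copies) / denom
        return q

    for branch, muts in truth.branch_mutations.items():
        for v in muts:
            sites.append(v)
            q_rows.append(q_for(v, "lineage"))
    for t in tumours:
        for v in truth.tumour_private[t]:
            sites.append(v)
            q_rows.append(q_for(v, "private", owner=t))
    for v in truth.germline_sites:
        sites.append(v)
        q_rows.append(q_for(v, "germline"))
    for v, rate in zip(truth.artifact_sites, art_rates):
        sites.append(v)
        q_rows.append(q_for(v, "artifact", art_rate=rate))

    q = np.clip(np.asarray(q_rows) + err, 0.0, 1.0) if sites else np.zeros((0, len(sample_ids)))
    cov = np.array([coverage[s] for s in sample_ids])
    depth = rng.poisson(np.broadcast_to(cov, q.shape))
    alt = rng.binomial(depth, q)

    # QC annotations: realistic passing values; a fraction of artifact
    # sites deliberately fail (clipped reads / low alignment score)
    n_art = len(truth.artifact_sites)
    fail = rng.random(n_art) < params.qc_fail_fraction
    art_keys = {v.key for v, f in zip(truth.artifact_sites, fail) if f}
    for site in sites:
        if site.key in art_keys:
            site.qc.update(
                CLPM=2.0,
                ASMD=float(np.round(np.clip(rng.normal(110.0, 5.0), None, 139.5), 1)),
                MAPQ=60.0,
                BASEQ=float(np.round(np.clip(rng.normal(34.0, 2.0), 25.5, None), 1)),
            )
        else:
            # truncated clear of the filter thresholds: true variants fail
            # QC through alignment artifacts, which only artifact loci model
            site.qc.update(
                CLPM=0.0,
                ASMD=float(np.round(np.clip(rng.normal(160.0, 8.0), 140.5, None), 1)),
                MAPQ=60.0,
                BASEQ=float(np.round(np.clip(rng.normal(37.0, 2.0), 25.5, None), 1)),
            )

    table = CohortTable(sites=sites, samples=samples, alt=alt, depth=depth).sorted()
    return table, cn_profiles


def simulate_cohort(params: SimParams) -> tuple[CohortTable, dict, SyntheticTruth]:
    """Convenience wrapper: lineage + tissues + sequencing in one call."""
    truth = simulate_lineage(params)
    table, cn = sequence_cohort(truth)
    return table, cn, truth


# ----------------------------------------------------------------------
# Packaged configurations
# ----------------------------------------------------------------------

_TRUNK = "0" * 10


def case_study_config(seed: int = 1) -> SimParams:
    """The packaged four-tumour case-study configuration.

    A fixed-seed scenario built to mirror the analysed case: a trunk of
    15 shared mutations (13 SNV, 1 DNV, 1 in-frame duplication) on the
    path from zygote to an MRCA at division 10 (~week 4.5); blood and
    kidney composed so that 7 trunk variants are detectable in both
    normal tissues, 5 in kidney only and 3 in neither, with normal-
    tissue VAFs decaying from ~0.13; four tumours (two with whole-
    chromosome losses, as in the oncocytoma-like lesions) seeded from
    cells just below the MRCA, each with its own private clonal
    mutations.
    """
    trunk_counts = [2, 2, 2, 1, 2, 1, 2, 1, 1, 1]  # sums to 15
    fixed = {_TRUNK[: i + 1]: c for i, c in enumerate(trunk_counts)}
    fixed[_TRUNK + "0"] = 3   # branch shared by tumours A and C
    fixed[_TRUNK + "1"] = 3   # branch shared by tumours D and E
    blood_plan = [
        ("1", 0.47), ("01", 0.10), ("001", 0.06), ("0001", 0.05), ("00001", 0.06),
    ]
    kidney_plan = [
        ("1", 0.60), ("01", 0.07), ("001", 0.035), ("0001", 0.03),
        ("00001", 0.03), ("000001", 0.035), ("0000001", 0.035),
        ("00000001", 0.06),
    ]
    tumour_plan = {
        "A": TumourPlan(_TRUNK + "00", n_private_mutations=26,
                        loss_chroms=("1",), purity=1.0),
        "C": TumourPlan(_TRUNK + "01", n_private_mutations=31, purity=1.0),
        "D": TumourPlan(_TRUNK + "10", n_private_mutations=24,
                        loss_chroms=("1", "14"), purity=1.0),
        "E": TumourPlan(_TRUNK + "11", n_private_mutations=28, purity=1.0),
    }
    lineage_chroms = tuple(c for c in DEFAULT_CHROMS if c not in ("1", "14"))
    return SimParams(
        mutations_per_division=1.5,
        divisions_to_mrca=10,
        tissue_plan={"blood": blood_plan, "normal_kidney": kidney_plan},
        tumour_plan=tumour_plan,
        fixed_branch_mutations=fixed,
        non_snv_trunk={2: "DNV", 4: "duplication"},
        lineage_chroms=lineage_chroms,
        seed=seed,
    )


def embryo_params(seed: int, divisions_to_mrca: int | None = None) -> SimParams:
    """A randomised embryo scenario for repeated-simulation experiments.

    Same tissue architecture as the case study but with Poisson trunk
    mutation counts (no fixed overrides) and a variable MRCA depth, so
    the trunk burden and true MRCA week vary across seeds.
    """
    rng = np.random.default_rng(seed)
    d = int(divisions_to_mrca if divisions_to_mrca is not None
            else rng.integers(8, 14))
    base = case_study_config(seed=int(rng.integers(2**31 - 1)))
    trunk = "0" * d
    tumour_plan = {
        t: replace(p, seed_node=trunk + p.seed_node[len(_TRUNK):],
                   n_private_mutations=12)
        for t, p in base.tumour_plan.items()
    }
    return replace(
        base,
        divisions_to_mrca=d,
        tumour_plan=tumour_plan,
        fixed_branch_mutations={},
        non_snv_trunk={},
        n_germline_sites=30,
        panel_artifact_sites=10,
    )
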