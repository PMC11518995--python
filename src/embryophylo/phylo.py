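"""Tumour phylogeny from variant presence patterns and from
Dirichlet-process clustering of VAF vectors.

Two independent routes, as in a manual-plus-sampler analysis:

* **Perfect phylogeny** over binary presence patterns.  Each variant's
  pattern (the set of tumours carrying it) must be pairwise laminar
  (nested or disjoint) with every other pattern — the classic
  three-gamete condition for characters that arise once and never
  revert.  The unique minimal tree is built by containment.
* **Dirichlet-process mixture** over per-sample binomial read counts:
  a collapsed Gibbs sampler with a uniform Beta(1, 1) base measure per
  sample and a Gamma(1, 1) hyperprior on the concentration.  Variants
  on the same branch share a latent VAF vector and co-cluster.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln

from .cohort import CohortError, CohortTable, VariantSite


# ----------------------------------------------------------------------
# Presence calling
# ----------------------------------------------------------------------

@dataclass
class PresenceMatrix:
    """Binary variant x sample presence with an explicit unknown mask.

    ``present`` holds 0/1 calls; a cell with depth 0 carries no
    information and is marked in ``unknown`` (and left 0 in
    ``present``) — "no coverage" is never conflated with "absent".
    """

    sites: list[VariantSite]
    sample_ids: list[str]
    present: np.ndarray
    unknown: np.ndarray
    min_alt_reads: int
    error_rate: float
    alpha: float


def call_presence(
    table: CohortTable,
    min_alt_reads: int = 3,
    error_rate: float = 1e-3,
    alpha: float = 0.01,
) -> PresenceMatrix:
    """Call a variant present in a sample when the alt count both meets a
    read floor and is inconsistent with sequencing error.

    Present iff alt >= min_alt_reads and the upper-tail binomial
    probability of >= alt reads at the per-base error rate is < alpha.
    The read floor protects low-depth samples; the tail test protects
    very deep ones, where even 3 error reads are unremarkable.
    """
    alt, depth = table.alt, table.depth
    with np.errstate(invalid="ignore"):
        tail = stats.binom.sf(alt - 1, np.maximum(depth, 1), error_rate)
    present = (alt >= min_alt_reads) & (tail < alpha) & (depth > 0)
    return PresenceMatrix(
        sites=list(table.sites),
        sample_ids=list(table.sample_ids),
        present=present.astype(np.int8),
        unknown=(depth == 0),
        min_alt_reads=min_alt_reads,
        error_rate=error_rate,
        alpha=alpha,
    )


# ----------------------------------------------------------------------
# Perfect phylogeny
# ----------------------------------------------------------------------

class PhylogenyConflictError(CohortError):
    """Raised when two presence patterns violate pairwise compatibility."""

    def __init__(self, conflicts: list[tuple[frozenset, frozenset]]):
        self.conflicts = conflicts
        pairs = "; ".join(
            f"{sorted(a)} vs {sorted(b)}" for a, b in conflicts[:5]
        )
        super().__init__(f"incompatible presence patterns: {pairs}")


@dataclass
class CladeNode:
    """A branch of the tumour tree: the clade of samples below it and the
    variants mapped onto the branch entering it."""

    samples: frozenset
    variants: list[VariantSite] = field(default_factory=list)
    children: list["CladeNode"] = field(default_factory=list)

    @property
    def name(self) -> str:
        if len(self.samples) == 1:
            return next(iter(self.samples))
        return "+".join(sorted(self.samples))

    @property
    def n_mutations(self) -> int:
        return len(self.variants)


@dataclass
class PhyloTree:
    root: CladeNode
    sample_ids: list[str]
    set_aside: list[VariantSite] = field(default_factory=list)

    def clades(self) -> list[CladeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out

    def clade_sets(self) -> set[frozenset]:
        return {n.samples for n in self.clades()}

    def trunk_variants(self) -> list[VariantSite]:
        return list(self.root.variants)

    def to_newick(self) -> str:
        """Newick string with branch lengths = mutation counts."""

        def fmt(node: CladeNode) -> str:
            if not node.children:
                return f"{node.name}:{node.n_mutations}"
            inner = ",".join(fmt(c) for c in node.children)
            return f"({inner}):{node.n_mutations}"

        return fmt(self.root) + ";"

    def presence_patterns(self) -> dict[tuple, frozenset]:
        """Re-encode the tree as variant -> clade pattern (for checking
        that construction preserved the input matrix)."""
        out: dict[tuple, frozenset] = {}
        for node in self.clades():
            for v in node.variants:
                out[v.key] = node.samples
        return out


def build_perfect_phylogeny(
    pm: PresenceMatrix, samples: Sequence[str] | None = None
) -> PhyloTree:
    """Build the unique minimal perfect phylogeny from presence patterns.

    Variants with an unknown cell among the used samples are set aside
    (reported on the tree, not placed); all-absent variants are ignored.
    Raises :class:`PhylogenyConflictError` when two patterns overlap
    without nesting.
    """
    use = list(samples) if samples is not None else list(pm.sample_ids)
    cols = [pm.sample_ids.index(s) for s in use]
    patterns: dict[frozenset, list[VariantSite]] = {}
    set_aside: list[VariantSite] = []
    for i, site in enumerate(pm.sites):
        if pm.unknown[i, cols].any():
            set_aside.append(site)
            continue
        pat = frozenset(s for s, c in zip(use, cols) if pm.present[i, c])
        if not pat:
            continue
        patterns.setdefault(pat, []).append(site)

    pats = list(patterns)
    conflicts = [
        (p, q)
        for a, p in enumerate(pats)
        for q in pats[a + 1:]
        if not (p <= q or q <= p or p.isdisjoint(q))
    ]
    if conflicts:
        raise PhylogenyConflictError(conflicts)

    full = frozenset(use)
    node_sets = {full} | set(pats) | {frozenset([s]) for s in use}
    nodes = {s: CladeNode(samples=s, variants=patterns.get(s, [])) for s in node_sets}
    # attach each clade to its smallest strict superset
    for s in sorted(node_sets, key=len):
        if s == full:
            continue
        parent = min(
            (t for t in node_sets if s < t), key=len
        )
        nodes[parent].children.append(nodes[s])
    for node in nodes.values():
        node.children.sort(key=lambda c: c.name)
    return PhyloTree(root=nodes[full], sample_ids=use, set_aside=set_aside)


# ----------------------------------------------------------------------
# Dirichlet-process clustering of VAF vectors
# ----------------------------------------------------------------------

@dataclass
class DPClustering:
    n_iterations: int
    burn_in: int
    assignments: np.ndarray          # variant -> cluster id (posterior mode)
    cluster_vafs: np.ndarray         # (n_clusters, n_samples) posterior means
    sample_ids: list[str]
    sites: list[VariantSite]
    seed: int
    concentration_trace: np.ndarray = field(default=None, repr=False)

    @property
    def n_clusters(self) -> int:
        return int(self.assignments.max()) + 1 if len(self.assignments) else 0

    def coclustering(self) -> np.ndarray:
        z = self.assignments
        return (z[:, None] == z[None, :]).astype(float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, site in enumerate(self.sites):
            row = {"site": site.label(), "cluster": int(self.assignments[i])}
            for j, sid in enumerate(self.sample_ids):
                row[f"vaf.{sid}"] = self.cluster_vafs[self.assignments[i], j]
            rows.append(row)
        return pd.DataFrame(rows)


def _canonical_partition(z: np.ndarray) -> tuple:
    relabel: dict[int, int] = {}
    out = []
    for zi in z:
        if zi not in relabel:
            relabel[zi] = len(relabel)
        out.append(relabel[zi])
    return tuple(out)


def dp_cluster_vafs(
    table: CohortTable,
    iterations: int = 20000,
    burn_in: int = 10000,
    seed: int = 0,
    concentration_prior: tuple[float, float] = (1.0, 1.0),
) -> DPClustering:
    """Collapsed Gibbs sampling of a Dirichlet-process binomial mixture.

    Each variant i carries counts (alt_is, depth_is) across samples s;
    variants in a cluster share a latent VAF per sample with a uniform
    Beta(1, 1) base measure, so the predictive is beta-binomial and the
    latent VAFs integrate out.  The concentration is resampled each
    sweep by the auxiliary-variable scheme of Escobar & West under a
    Gamma(a, b) hyperprior.

    Returns the posterior-*mode* partition over post-burn-in sweeps
    (ties broken by earliest occurrence), with cluster VAF vectors set
    to their posterior means conditional on that partition.
    """
    if iterations <= 0 or burn_in < 0 or burn_in >= iterations:
        raise CohortError("need 0 <= burn_in < iterations")
    if table.n_sites < 1 or table.n_samples < 1:
        raise CohortError("dp_cluster_vafs needs >= 1 variant and >= 1 sample")
    if (table.depth == 0).any():
        raise CohortError("dp_cluster_vafs requires depth > 0 everywhere")

    rng = np.random.default_rng(seed)
    a_conc, b_conc = concentration_prior
    alt = table.alt.astype(float)
    ref = (table.depth - table.alt).astype(float)
    n, S = alt.shape

    # preallocated cluster sufficient statistics; K tracks active clusters
    cap = n + 1
    A = np.zeros((cap, S))
    R = np.zeros((cap, S))
    sizes = np.zeros(cap)
    lden = np.zeros(cap)

    # start from the one-cluster partition; Gibbs splits as needed
    z = np.zeros(n, dtype=int)
    K = 1
    A[0] = alt.sum(axis=0)
    R[0] = ref.sum(axis=0)
    sizes[0] = n
    lden[0] = betaln(1.0 + A[0], 1.0 + R[0]).sum()
    # marginal likelihood of a variant alone in a fresh cluster
    lnew = betaln(1.0 + alt, 1.0 + ref).sum(axis=1)
    alpha = 1.0
    kept: Counter = Counter()
    first_seen: dict[tuple, int] = {}
    conc_trace = np.empty(iterations)
    uniforms = None

    for it in range(iterations):
        order = rng.permutation(n)
        uniforms = rng.random(n)
        for step, i in enumerate(order):
            k = z[i]
            sizes[k] -= 1
            A[k] -= alt[i]
            R[k] -= ref[i]
            if sizes[k] == 0:
                # drop empty cluster, relabel the tail one into its slot
                K -= 1
                if k != K:
                    A[k] = A[K]
                    R[k] = R[K]
                    sizes[k] = sizes[K]
                    lden[k] = lden[K]
                    z[z == K] = k
            else:
                lden[k] = betaln(1.0 + A[k], 1.0 + R[k]).sum()
            lp = np.empty(K + 1)
            lp[:K] = (
                np.log(sizes[:K])
                + betaln(1.0 + A[:K] + alt[i], 1.0 + R[:K] + ref[i]).sum(axis=1)
                - lden[:K]
            )
            lp[K] = np.log(alpha) + lnew[i]
            w = np.exp(lp - lp.max())
            w = np.cumsum(w)
            k_new = int(np.searchsorted(w, uniforms[step] * w[-1], side="right"))
            if k_new == K:
                A[K] = alt[i]
                R[K] = ref[i]
                sizes[K] = 1
                lden[K] = lnew[i]
                K += 1
            else:
                A[k_new] += alt[i]
                R[k_new] += ref[i]
                sizes[k_new] += 1
                lden[k_new] = betaln(1.0 + A[k_new], 1.0 + R[k_new]).sum()
            z[i] = k_new

        # Escobar-West concentration update
        eta = rng.beta(alpha + 1.0, n)
        odds = (a_conc + K - 1.0) / (n * (b_conc - np.log(eta)))
        shape = a_conc + K if rng.random() < odds / (1.0 + odds) else a_conc + K - 1.0
        alpha = rng.gamma(shape, 1.0 / (b_conc - np.log(eta)))
        conc_trace[it] = alpha

        if it >= burn_in:
            part = _canonical_partition(z)
            kept[part] += 1
            first_seen.setdefault(part, it)

    # most frequent post-burn-in partition; ties -> earliest occurrence
    mode = max(kept, key=lambda part: (kept[part], -first_seen[part]))
    zmode = np.asarray(mode, dtype=int)

    Kmode = zmode.max() + 1
    vafs = np.empty((Kmode, S))
    for k in range(Kmode):
        members = zmode == k
        Ak = alt[members].sum(axis=0)
        Rk = ref[members].sum(axis=0)
        vafs[k] = (1.0 + Ak) / (2.0 + Ak + Rk)
    return DPClustering(
        n_iterations=iterations,
        burn_in=burn_in,
        assignments=zmode,
        cluster_vafs=vafs,
        sample_ids=list(table.sample_ids),
        sites=list(table.sites),
        seed=seed,
        concentration_trace=conc_trace,
    )


# ----------------------------------------------------------------------
# Reconciliation of the two routes
# ----------------------------------------------------------------------

def reconcile(
    tree: PhyloTree, clustering: DPClustering, zero_tol: float = 0.05
) -> pd.DataFrame:
    """Per-branch concordance between the tree and the DP clustering.

    A variant is branch-consistent when its cluster's posterior VAF is
    ~0 (<= zero_tol) in every sample outside the branch's clade.
    Returns one row per branch with the fraction of consistent variants.
    """
    cluster_of = {s.key: int(z) for s, z in zip(clustering.sites, clustering.assignments)}
    rows = []
    for node in tree.clades():
        if not node.variants:
            continue
        outside = [
            j for j, sid in enumerate(clustering.sample_ids) if sid not in node.samples
        ]
        ok = 0
        considered = 0
        for v in node.variants:
            k = cluster_of.get(v.key)
            if k is None:
                continue
            considered += 1
            if all(clustering.cluster_vafs[k, j] <= zero_tol for j in outside):
                ok += 1
        rows.append(
            {
                "branch": node.name,
                "n_variants": considered,
                "concordance": ok / considered if considered else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["branch", "n_variants", "concordance"])
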