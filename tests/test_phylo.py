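"""Presence calling, perfect phylogeny and DP clustering."""

import numpy as np
import pytest
from scipy import stats

from embryophylo.cohort import CohortError, CohortTable, SampleMeta
from embryophylo.phylo import (
    PhylogenyConflictError,
    build_perfect_phylogeny,
    call_presence,
    dp_cluster_vafs,
    reconcile,
)

from conftest import make_site


def _table(alt, depth, sample_names=None):
    alt = np.asarray(alt)
    names = sample_names or [f"T{j}" for j in range(alt.shape[1])]
    sites = [make_site(pos=1 + i) for i in range(alt.shape[0])]
    samples = [SampleMeta(n, "tumour") for n in names]
    return CohortTable(sites, samples, alt, np.asarray(depth))


class TestCallPresence:
    def test_deep_zero_is_absent(self):
        pm = call_presence(_table([[0]], [[500]]))
        assert pm.present[0, 0] == 0 and not pm.unknown[0, 0]

    def test_three_reads_at_75x_present_and_matches_tail(self):
        pm = call_presence(_table([[3]], [[75]]))
        assert pm.present[0, 0] == 1
        assert stats.binom.sf(2, 75, 1e-3) < 0.01  # the rule's own premise

    def test_below_read_floor_absent(self):
        pm = call_presence(_table([[2]], [[75]]))
        assert pm.present[0, 0] == 0

    def test_deep_sample_needs_more_than_floor(self):
        # 3 error reads in 530x are unremarkable at error 1e-3
        pm = call_presence(_table([[3]], [[530]]))
        assert pm.present[0, 0] == 0

    def test_zero_depth_is_unknown_not_absent(self):
        pm = call_presence(_table([[0]], [[0]]))
        assert pm.unknown[0, 0] and pm.present[0, 0] == 0


def _presence(patterns, samples="ACDE"):
    """Build a PresenceMatrix from variant->set-of-samples patterns."""
    names = list(samples)
    alt = np.array(
        [[40 if s in pat else 0 for s in names] for pat in patterns]
    ).reshape(len(patterns), len(names))
    depth = np.full(alt.shape, 80)
    return call_presence(_table(alt, depth, names))


class TestPerfectPhylogeny:
    def test_star_with_trunk(self):
        pm = _presence(["ACDE", "ACDE", "A", "D"])
        tree = build_perfect_phylogeny(pm)
        assert len(tree.trunk_variants()) == 2
        assert tree.clade_sets() == {
            frozenset("ACDE"), frozenset("A"), frozenset("C"),
            frozenset("D"), frozenset("E"),
        }

    def test_nested_clades(self):
        pm = _presence(["ACDE", "AC", "AC", "A", "E"])
        tree = build_perfect_phylogeny(pm)
        assert frozenset("AC") in tree.clade_sets()
        by_clade = {n.samples: n.n_mutations for n in tree.clades()}
        assert by_clade[frozenset("AC")] == 2

    def test_three_gamete_conflict_raises(self):
        pm = _presence(["AC", "CD"])
        with pytest.raises(PhylogenyConflictError) as err:
            build_perfect_phylogeny(pm)
        assert err.value.conflicts

    def test_reencoding_reproduces_input(self):
        """Mapping tree branches back to presence patterns is the identity
        on conflict-free matrices."""
        rng = np.random.default_rng(3)
        # random laminar family over 4 samples
        clades = [frozenset("ACDE"), frozenset("AC"), frozenset("A"),
                  frozenset("C"), frozenset("D"), frozenset("E")]
        patterns = ["".join(sorted(clades[rng.integers(len(clades))]))
                    for _ in range(30)]
        pm = _presence(patterns)
        tree = build_perfect_phylogeny(pm)
        got = tree.presence_patterns()
        for site, pat in zip(pm.sites, patterns):
            assert got[site.key] == frozenset(pat)

    def test_unknown_cells_set_variant_aside(self):
        names = list("ACDE")
        alt = np.array([[40, 40, 40, 40], [40, 0, 40, 40]])
        depth = np.array([[80, 80, 80, 80], [80, 0, 80, 80]])
        pm = call_presence(_table(alt, depth, names))
        tree = build_perfect_phylogeny(pm)
        assert len(tree.set_aside) == 1
        assert len(tree.trunk_variants()) == 1

    def test_newick_parses_with_external_library(self):
        dendropy = pytest.importorskip("dendropy")
        pm = _presence(["ACDE", "AC", "A", "D"])
        tree = build_perfect_phylogeny(pm)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set("ACDE")


class TestDPClustering:
    def _two_cluster_table(self, seed=0, n=60, depth=100):
        rng = np.random.default_rng(seed)
        vafs = np.array([[0.5, 0.5, 0.5, 0.5], [0.25, 0.0, 0.0, 0.0]])
        labels = np.repeat([0, 1], n)
        d = np.full((2 * n, 4), depth)
        a = rng.binomial(d, vafs[labels])
        return _table(a, d), labels

    def test_deterministic_under_seed(self):
        table, _ = self._two_cluster_table()
        f1 = dp_cluster_vafs(table, iterations=200, burn_in=100, seed=9)
        f2 = dp_cluster_vafs(table, iterations=200, burn_in=100, seed=9)
        assert np.array_equal(f1.assignments, f2.assignments)
        assert np.allclose(f1.cluster_vafs, f2.cluster_vafs)

    def test_two_planted_clusters_recovered(self):
        table, labels = self._two_cluster_table(seed=4)
        fit = dp_cluster_vafs(table, iterations=800, burn_in=400, seed=2)
        co = fit.assignments[:, None] == fit.assignments[None, :]
        truth = labels[:, None] == labels[None, :]
        assert (co == truth).mean() >= 0.95

    def test_single_cluster_not_oversplit(self):
        """50 variants from one clone yield a one-cluster posterior mode
        in >= 90% of seeds."""
        rng = np.random.default_rng(7)
        ones = 0
        n_seeds = 10
        for s in range(n_seeds):
            d = np.full((50, 4), 100)
            a = rng.binomial(d, 0.5)
            fit = dp_cluster_vafs(_table(a, d), iterations=400, burn_in=200, seed=s)
            ones += fit.n_clusters == 1
        assert ones >= 0.9 * n_seeds

    def test_depth_sharpens_separation(self):
        """Co-clustering accuracy on distinct VAF vectors improves from
        shallow to deep sequencing."""
        def acc(depth, seed):
            rng = np.random.default_rng(seed)
            vafs = np.array([[0.5, 0.4, 0.5, 0.4], [0.35, 0.5, 0.35, 0.5]])
            labels = np.repeat([0, 1], 40)
            d = np.full((80, 4), depth)
            a = rng.binomial(d, vafs[labels])
            fit = dp_cluster_vafs(_table(a, d), iterations=500, burn_in=250, seed=3)
            co = fit.assignments[:, None] == fit.assignments[None, :]
            return ((labels[:, None] == labels[None, :]) == co).mean()

        assert acc(1000, 11) >= acc(10, 11)
        assert acc(1000, 11) >= 0.95

    def test_invalid_iteration_config_rejected(self):
        table, _ = self._two_cluster_table()
        with pytest.raises(CohortError):
            dp_cluster_vafs(table, iterations=100, burn_in=100)
        with pytest.raises(CohortError):
            dp_cluster_vafs(table, iterations=0, burn_in=0)


class TestReconcile:
    def test_clean_case_full_concordance(self):
        pm = _presence(["ACDE", "ACDE", "A"])
        tree = build_perfect_phylogeny(pm)
        alt = np.array([[40, 40, 40, 40], [40, 40, 40, 40], [40, 0, 0, 0]])
        depth = np.full((3, 4), 80)
        fit = dp_cluster_vafs(
            _table(alt, depth, list("ACDE")), iterations=300, burn_in=150, seed=0
        )
        rep = reconcile(tree, fit)
        trunk = rep.set_index("branch").loc["A+C+D+E", "concordance"]
        assert trunk == 1.0

    def test_empty_tree_report(self):
        pm = _presence([])
        tree = build_perfect_phylogeny(pm)
        alt = np.array([[40, 40, 40, 40]])
        fit = dp_cluster_vafs(
            _table(alt, np.full((1, 4), 80), list("ACDE")),
            iterations=100, burn_in=50, seed=0,
        )
        assert reconcile(tree, fit).empty
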