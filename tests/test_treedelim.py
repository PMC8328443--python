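"""NJ, midpoint rooting, PTP/bPTP/mPTP and monophyly."""

import math

import numpy as np
import pytest

from motudelim import (
    SpecimenTable,
    ValidationError,
    build_nj,
    midpoint_root,
    monophyly_report,
    mptp_ml,
    ptp_mcmc_support,
    ptp_ml,
    McmcConfig,
)
from motudelim.distances import DistanceMatrix
from motudelim.io import parse_newick
from motudelim.treedelim import (
    _TreeIndex,
    enumerate_delimitations,
    mptp_loglik,
    ptp_loglik,
)

FOUR_TIP = "((A:0.01,B:0.01):0.30,(C:0.01,D:0.01):0.30);"


def random_tree_newick(n_tips, rng, scale=0.2):
    """Random binary topology with uniform branch lengths."""
    nodes = [f"t{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        la, lb = rng.uniform(0.001, scale, size=2)
        nodes.append(f"({a}:{la:.6f},{b}:{lb:.6f})")
    return nodes[0] + ";"


def tip_distances(t):
    pdm = t.tree.phylogenetic_distance_matrix()
    taxa = sorted(t.tree.taxon_namespace, key=lambda x: x.label)
    return {
        (a.label, b.label): pdm.distance(a, b)
        for i, a in enumerate(taxa)
        for b in taxa[i + 1 :]
    }


class TestNj:
    def test_recovers_additive_four_taxon_matrix(self):
        src = parse_newick("((A:2,B:3):1,(C:4,D:5):1);")
        dist = tip_distances(src)
        ids = ["A", "B", "C", "D"]
        d = np.zeros((4, 4))
        for i, a in enumerate(ids):
            for j in range(i + 1, 4):
                d[i, j] = d[j, i] = dist[(a, ids[j])]
        nj = build_nj(DistanceMatrix(ids=ids, d=d, model="p"))
        assert dict(tip_distances(nj)) == pytest.approx(dist, abs=1e-9)

    def test_three_taxa(self):
        d = np.array([[0, 2.0, 3.0], [2.0, 0, 3.0], [3.0, 3.0, 0]])
        nj = build_nj(DistanceMatrix(ids=["A", "B", "C"], d=d, model="p"))
        assert sorted(nj.tip_names()) == ["A", "B", "C"]

    def test_too_few_specimens(self):
        d = np.array([[0, 1.0], [1.0, 0]])
        with pytest.raises(ValidationError):
            build_nj(DistanceMatrix(ids=["A", "B"], d=d, model="p"))


class TestMidpoint:
    def test_two_tip_arithmetic(self):
        r = midpoint_root(parse_newick("(A:1,B:3);"))
        depths = {
            lf.taxon.label: lf.distance_from_root() for lf in r.tree.leaf_node_iter()
        }
        assert depths == pytest.approx({"A": 2.0, "B": 2.0})

    def test_fixed_point(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        r = midpoint_root(t)
        assert tip_distances(r) == pytest.approx(tip_distances(t), abs=1e-9)
        # the root already splits every longest path at its midpoint
        sides = [
            max(
                lf.distance_from_root()
                for lf in c.leaf_iter()
            ) + c.edge.length
            for c in r.tree.seed_node.child_nodes()
        ]
        assert len(r.tree.seed_node.child_nodes()) == 2

    def test_path_lengths_preserved_on_random_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            t = parse_newick(random_tree_newick(int(rng.integers(3, 12)), rng))
            r = midpoint_root(t)
            assert tip_distances(r) == pytest.approx(tip_distances(t), abs=1e-9)
            # the root halves the longest path, so the deepest tip sits at
            # exactly half of it
            deepest = max(lf.distance_from_root() for lf in r.tree.leaf_node_iter())
            longest = max(tip_distances(r).values())
            assert deepest == pytest.approx(longest / 2, abs=1e-9)

    def test_all_zero_lengths_rejected(self):
        with pytest.raises(ValidationError):
            midpoint_root(parse_newick("(A:0,B:0);"))

    def test_deterministic_on_ties(self):
        # symmetric tree with several equally long tip pairs
        nwk = "((A:2,B:2):1,(C:2,D:2):1);"
        a = midpoint_root(parse_newick(nwk)).as_newick()
        b = midpoint_root(parse_newick(nwk)).as_newick()
        assert a == b


class TestPtpOracle:
    """ptp_ml / mptp_ml must equal brute-force enumeration on small trees."""

    @pytest.mark.parametrize("n_trees,max_tips", [(60, 8)])
    def test_ml_equals_enumeration(self, n_trees, max_tips):
        rng = np.random.default_rng(123)
        for k in range(n_trees):
            n = int(rng.integers(3, max_tips + 1))
            t = parse_newick(random_tree_newick(n, rng))
            ix = _TreeIndex(t)
            delims = enumerate_delimitations(ix)
            best_ptp = max(ptp_loglik(ix, r) for r in delims)
            best_mptp = max(mptp_loglik(ix, r) for r in delims)
            assert ptp_ml(t).log_likelihood == pytest.approx(best_ptp, abs=1e-9)
            assert mptp_ml(t).log_likelihood == pytest.approx(best_mptp, abs=1e-9)

    def test_four_tip_partition(self):
        d = ptp_ml(parse_newick(FOUR_TIP))
        assert d.partition.as_sets() == {frozenset("AB"), frozenset("CD")}
        d2 = mptp_ml(parse_newick(FOUR_TIP))
        assert d2.partition.as_sets() == {frozenset("AB"), frozenset("CD")}

    def test_beats_one_species_null(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            t = parse_newick(random_tree_newick(int(rng.integers(4, 10)), rng))
            ix = _TreeIndex(t)
            null = ptp_loglik(ix, [ix.root])
            assert ptp_ml(t).log_likelihood >= null - 1e-9

    def test_two_tip_best_of_both(self):
        t = parse_newick("(A:0.05,B:0.4);")
        ix = _TreeIndex(t)
        best = max(ptp_loglik(ix, r) for r in enumerate_delimitations(ix))
        assert ptp_ml(t).log_likelihood == pytest.approx(best, abs=1e-12)

    def test_multi_rate_nests_single_rate(self):
        t = parse_newick(
            "((A:0.001,B:0.001):0.3,(C:0.05,D:0.05):0.3);"
        )
        ix = _TreeIndex(t)
        for roots in enumerate_delimitations(ix):
            assert mptp_loglik(ix, roots) >= ptp_loglik(ix, roots) - 1e-9

    def test_likelihood_invariant_to_rotation(self):
        a = parse_newick("((A:0.01,B:0.02):0.3,(C:0.01,D:0.01):0.25);")
        b = parse_newick("((D:0.01,C:0.01):0.25,(B:0.02,A:0.01):0.3);")
        assert ptp_ml(a).log_likelihood == pytest.approx(
            ptp_ml(b).log_likelihood, abs=1e-12
        )
        assert mptp_ml(a).log_likelihood == pytest.approx(
            mptp_ml(b).log_likelihood, abs=1e-12
        )

    def test_unrooted_rejected(self):
        with pytest.raises(ValidationError, match="midpoint"):
            ptp_ml(parse_newick("(A:1,B:1,C:1);"))

    def test_singletons_always_feasible(self):
        t = parse_newick(FOUR_TIP)
        ix = _TreeIndex(t)
        tips = [i for i in range(len(ix.nodes)) if ix.tipname.get(i)]
        assert math.isfinite(mptp_loglik(ix, tips))


class TestMcmc:
    def test_supports_in_unit_interval_and_deterministic(self):
        t = parse_newick(FOUR_TIP)
        cfg = McmcConfig(generations=5000, thinning=10, seed=7)
        a = ptp_mcmc_support(t, cfg)
        b = ptp_mcmc_support(t, cfg)
        assert a.support == b.support
        assert all(0.0 <= v <= 1.0 for v in a.support.values())

    def test_dominant_mode_high_support(self):
        a = ptp_mcmc_support(parse_newick(FOUR_TIP), McmcConfig())
        assert a.partition.as_sets() == {frozenset("AB"), frozenset("CD")}
        assert all(v >= 0.95 for v in a.support.values())

    def test_different_seeds_may_differ_but_stay_valid(self):
        t = parse_newick(FOUR_TIP)
        a = ptp_mcmc_support(t, McmcConfig(generations=2000, thinning=10, seed=1))
        assert set(a.support) == {"A", "C"}


class TestMonophyly:
    def test_clean_species_monophyletic(self):
        t = parse_newick("((A1:1,A2:1):1,(B1:1,B2:1):1);")
        s = SpecimenTable({"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
        assert monophyly_report(t, s) == {"A": "monophyletic", "B": "monophyletic"}

    def test_interleaved_species_non_monophyletic(self):
        t = parse_newick("((A1:1,B1:1):1,(A2:1,B2:1):1);")
        s = SpecimenTable({"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
        assert monophyly_report(t, s) == {
            "A": "non-monophyletic",
            "B": "non-monophyletic",
        }

    def test_singleton_and_untested(self):
        t = parse_newick("((A1:1,A2:1):1,B1:2);")
        s = SpecimenTable({"A1": "A", "A2": "A", "B1": "B", "C1": "C"})
        rep = monophyly_report(t, s)
        assert rep["B"] == "singleton" and rep["C"] == "untested"

    def test_sharing_event_flags_donor_and_recipient(self):
        from motudelim import SimulationConfig, simulate_genealogy

        cfg = SimulationConfig(n_species=12, n_singletons=2, sharing_prob=1.0)
        tree, truth = simulate_genealogy(cfg, 3)
        assert truth.shared_haplotype_species
        rep = monophyly_report(tree, truth.labels)
        flagged = {sp for sp, v in rep.items() if v == "non-monophyletic"}
        for donor, recipient in truth.shared_haplotype_species:
            assert recipient in flagged or donor in flagged
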