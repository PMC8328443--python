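"""Threshold clustering, ABGD and statistical parsimony."""

import numpy as np
import pytest

from motudelim import (
    Alignment,
    Partition,
    pairwise_distances,
    tcs_connection_limit,
    tcs_partition,
    threshold_cluster,
)
from motudelim.cluster import (
    AbgdConfig,
    TcsConfig,
    abgd_partition,
    abgd_scan,
    abgd_select_best,
    parsimony_probability,
)
from motudelim.distances import DistanceMatrix


def _dm(ids, d):
    return DistanceMatrix(ids=list(ids), d=np.array(d, float), model="p")


def _brute_components(ids, d, t):
    """Independent check: transitive closure of the <=t adjacency matrix."""
    n = len(ids)
    adj = (np.asarray(d) <= t) | np.eye(n, dtype=bool)
    reach = adj.copy()
    for _ in range(n):
        reach = reach @ adj
    blocks = set()
    for i in range(n):
        blocks.add(frozenset(ids[j] for j in range(n) if reach[i, j]))
    return blocks


class TestThreshold:
    def test_all_one_group_when_t_large(self):
        dm = _dm("abc", [[0, 0.1, 0.2], [0.1, 0, 0.15], [0.2, 0.15, 0]])
        assert threshold_cluster(dm, 0.5).n_groups == 1

    def test_all_singletons_at_zero(self):
        dm = _dm("abc", [[0, 0.1, 0.2], [0.1, 0, 0.15], [0.2, 0.15, 0]])
        assert threshold_cluster(dm, 0.0).n_groups == 3

    def test_single_linkage_chain(self):
        dm = _dm("ABC", [[0, 0.02, 0.04], [0.02, 0, 0.02], [0.04, 0.02, 0]])
        part = threshold_cluster(dm, 0.03)
        assert part.as_sets() == {frozenset("ABC")}

    def test_negative_threshold_rejected(self):
        dm = _dm("ab", [[0, 0.1], [0.1, 0]])
        with pytest.raises(ValueError):
            threshold_cluster(dm, -0.01)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(4, 12))
            x = rng.random((n, 2))
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            ids = [f"s{i}" for i in range(n)]
            t = float(rng.uniform(0.05, 0.8))
            part = threshold_cluster(DistanceMatrix(ids=ids, d=d, model="p"), t)
            assert part.as_sets() == _brute_components(ids, d, t)

    def test_monotone_coarsening(self, easy_assemblage):
        aln, _ = easy_assemblage
        dm = pairwise_distances(
            Alignment({k: aln.records[k] for k in aln.ids[:60]}), "k80"
        )
        prev = threshold_cluster(dm, 0.01)
        for t in (0.03, 0.08, 0.2):
            cur = threshold_cluster(dm, t)
            lookup = cur.group_of()
            for block in prev.groups.values():
                assert len({lookup[s] for s in block}) == 1
            prev = cur

    def test_order_invariance(self, easy_assemblage):
        aln, _ = easy_assemblage
        ids = aln.ids[:40]
        dm = pairwise_distances(Alignment({k: aln.records[k] for k in ids}), "k80")
        rng = np.random.default_rng(0)
        perm = [ids[i] for i in rng.permutation(len(ids))]
        assert threshold_cluster(dm, 0.03) == threshold_cluster(
            dm.submatrix(perm), 0.03
        )


class TestAbgd:
    def test_two_clusters_across_priors(self):
        # two tight clusters (internal <= 0.01) separated by >= 0.15
        rng = np.random.default_rng(1)
        ids = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
        d = np.zeros((10, 10))
        for i in range(10):
            for j in range(i + 1, 10):
                same = (i < 5) == (j < 5)
                d[i, j] = d[j, i] = (
                    rng.uniform(0.001, 0.01) if same else rng.uniform(0.15, 0.17)
                )
        dm = DistanceMatrix(ids=ids, d=d, model="p")
        for prior in (0.02, 0.05, 0.1):
            part = abgd_partition(dm, prior)
            assert part.as_sets() == {
                frozenset(ids[:5]),
                frozenset(ids[5:]),
            }

    def test_identical_sequences_one_group(self):
        aln = Alignment({f"s{i}": "ACGTACGT" for i in range(4)})
        dm = pairwise_distances(aln, "jc69")
        for _, part in abgd_scan(dm, AbgdConfig(steps=5)):
            assert part.n_groups == 1

    def test_counts_non_increasing_in_prior(self, easy_assemblage):
        aln, _ = easy_assemblage
        dm = pairwise_distances(
            Alignment({k: aln.records[k] for k in aln.ids[:80]}), "jc69"
        )
        counts = [p.n_groups for _, p in abgd_scan(dm, AbgdConfig())]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_recursion_refines_single_pass(self, easy_assemblage):
        aln, _ = easy_assemblage
        dm = pairwise_distances(
            Alignment({k: aln.records[k] for k in aln.ids[:80]}), "jc69"
        )
        for prior in (0.005, 0.02):
            initial = abgd_partition(dm, prior, recursive=False)
            recursive = abgd_partition(dm, prior, recursive=True)
            lookup = initial.group_of()
            for block in recursive.groups.values():
                assert len({lookup[s] for s in block}) == 1

    def test_select_best_longest_run(self):
        def fake(n):
            return Partition(
                groups={f"g{i}": frozenset({f"x{i}"}) for i in range(n)}
            )

        scan = [(p / 100, fake(c)) for p, c in zip(range(6), [10, 10, 10, 10, 2, 2])]
        assert abgd_select_best(scan).n_groups == 10

    def test_select_best_tie_to_smaller_prior(self):
        def fake(n):
            return Partition(
                groups={f"g{i}": frozenset({f"x{i}"}) for i in range(n)}
            )

        scan = [(p / 100, fake(c)) for p, c in zip(range(4), [5, 5, 3, 3])]
        assert abgd_select_best(scan).n_groups == 5

    def test_recovers_truth_on_easy_regime(self, easy_assemblage):
        aln, truth = easy_assemblage
        dm = pairwise_distances(aln, "jc69")
        best = abgd_select_best(abgd_scan(dm, AbgdConfig()))
        assert best == truth.labels.to_partition()


class TestTcs:
    def test_limit_zero_always_connects(self):
        assert parsimony_probability(0, 100) == 1.0
        assert tcs_connection_limit(TcsConfig(alignment_length=10)) >= 0

    def test_frozen_limit_for_barcode_length(self):
        # regression value computed once from the probability-of-parsimony
        # formula at 658 sites, 95% cutoff
        assert tcs_connection_limit(TcsConfig(alignment_length=658)) == 9

    def test_limit_monotone_in_cutoff_and_length(self):
        l95 = tcs_connection_limit(TcsConfig(0.95, 658))
        l99 = tcs_connection_limit(TcsConfig(0.99, 658))
        assert l99 <= l95
        assert tcs_connection_limit(TcsConfig(0.95, 300)) <= l95

    def test_identical_specimens_share_group(self):
        aln = Alignment({"x": "ACGT" * 10, "y": "ACGT" * 10})
        part = tcs_partition(aln)
        assert part.n_groups == 1

    def test_separated_haplotypes_split(self):
        L = 100
        limit = tcs_connection_limit(TcsConfig(alignment_length=L))
        seq = "A" * L
        far = "G" * (limit + 1) + "A" * (L - limit - 1)
        part = tcs_partition(Alignment({"x": seq, "y": far}))
        assert part.n_groups == 2

    def test_chain_transitivity(self):
        L = 200
        limit = tcs_connection_limit(TcsConfig(alignment_length=L))
        h1 = "A" * L
        h2 = "G" * limit + "A" * (L - limit)
        h3 = "G" * (2 * limit) + "A" * (L - 2 * limit)
        part = tcs_partition(Alignment({"a": h1, "b": h2, "c": h3}))
        assert part.n_groups == 1  # a-b and b-c within limit; a-c linked via b

    def test_components_match_brute_force(self, easy_assemblage):
        aln, _ = easy_assemblage
        sub = Alignment({k: aln.records[k] for k in aln.ids[:50]})
        part = tcs_partition(sub)
        # brute force: single linkage on the hamming matrix at the limit
        limit = tcs_connection_limit(TcsConfig(alignment_length=sub.length))
        ids = sub.ids
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                a, b = sub.records[ids[i]], sub.records[ids[j]]
                d[i, j] = d[j, i] = sum(x != y for x, y in zip(a, b))
        assert part.as_sets() == _brute_components(ids, d, limit)
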