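"""Tree handling and Poisson-tree-process species delimitation.

A delimitation of a rooted tree assigns every edge to a *speciation* class
or a *within-species* (coalescent) class such that the speciation edges
form a connected subgraph containing the root and each within-species
region is a tip-bearing clade.  Equivalently, a delimitation is a set of
"species root" nodes forming an antichain that covers every tip; the
species are the tip sets of those clades.

Branch lengths in each class are modelled as exponential draws.  With the
rate of each class at its closed-form maximum (rate = n/sum of lengths),
the profile log-likelihood of a class with n edges of total length S is
``n log(n/S) - n`` (zero for an empty class).  The single-rate model (PTP)
pools all within-species edges under one coalescent rate; the multi-rate
model (mPTP) gives each species its own rate.  Both maximizations here are
exact dynamic programs over the rooted tree, and are cross-checked against
brute-force enumeration in the test suite.  Bayesian-flavoured support
values (bPTP style) come from a Metropolis-Hastings walk over
delimitations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .distances import DistanceMatrix
from .io import Partition, PhyloTree, SpecimenTable, ValidationError, canonical_partition, parse_newick

#: floor applied to branch lengths before likelihood computation; identical
#: haplotypes create zero-length branches whose exponential density would
#: otherwise be degenerate
BRANCH_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# tree indexing


class _TreeIndex:
    """Array view of a rooted dendropy tree for the delimitation DPs.

    ``minbr`` excludes branches shorter than the given length from the
    likelihood entirely (both classes): a branch the locus cannot resolve
    (less than about one expected substitution) carries no information
    about rate classes, and counting it lets the profile likelihood chase
    degenerate tiny-rate species.  Zero by default; the multi-rate model
    is the intended consumer.
    """

    def __init__(self, t: PhyloTree, floor: float = BRANCH_FLOOR, minbr: float = 0.0):
        if not t.rooted:
            raise ValidationError(
                "tree-based delimitation needs a rooted tree; midpoint_root() it first"
            )
        nodes = list(t.tree.postorder_node_iter())
        if sum(1 for n in nodes if n.is_leaf()) < 2:
            raise ValidationError("need at least 2 tips")
        self.nodes = nodes
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.parent = [None] * len(nodes)
        self.children: List[List[int]] = [[] for _ in nodes]
        self.length = [0.0] * len(nodes)  # stem length of each node
        self.tipname: Dict[int, str] = {}
        self.root = self.index[id(t.tree.seed_node)]
        for i, n in enumerate(nodes):
            if n.is_leaf():
                self.tipname[i] = n.taxon.label
            for c in n.child_nodes():
                ci = self.index[id(c)]
                self.parent[ci] = i
                self.children[i].append(ci)
                self.length[ci] = max(float(c.edge.length or 0.0), floor)
        # per-edge likelihood weights: excluded branches contribute nothing
        self.cnt = [1 if l >= minbr else 0 for l in self.length]
        self.len_eff = [l if c else 0.0 for l, c in zip(self.length, self.cnt)]
        # subtree (included) edge counts and length sums
        self.m = [0] * len(nodes)
        self.T = [0.0] * len(nodes)
        for i, n in enumerate(nodes):  # postorder
            for ci in self.children[i]:
                self.m[i] += self.m[ci] + self.cnt[ci]
                self.T[i] += self.T[ci] + self.len_eff[ci]
        self.n_edges = self.m[self.root]
        self.total_len = self.T[self.root]
        self.tips_below: List[FrozenSet[str]] = [frozenset()] * len(nodes)
        for i in range(len(nodes)):
            if i in self.tipname:
                self.tips_below[i] = frozenset([self.tipname[i]])
            else:
                s: Set[str] = set()
                for ci in self.children[i]:
                    s |= self.tips_below[ci]
                self.tips_below[i] = frozenset(s)

    def partition(self, roots: Sequence[int], method: str) -> Partition:
        return canonical_partition([self.tips_below[r] for r in roots], method=method)


def _class_ll(n: int, s: float) -> float:
    return 0.0 if n == 0 else n * math.log(n / s) - n


@dataclass
class PtpDelimitation:
    partition: Partition
    log_likelihood: float
    speciation_rate: Optional[float]
    coalescent_rates: Dict[str, float]
    support: Optional[Dict[str, float]] = None


# ---------------------------------------------------------------------------
# likelihoods of a given delimitation (shared by the DPs, the enumerators
# and the MCMC)


def _delim_stats(ix: _TreeIndex, roots: Sequence[int]) -> Tuple[int, float]:
    """(#within-species edges, their total length) for a species-root set."""
    n_in = sum(ix.m[r] for r in roots)
    s_in = sum(ix.T[r] for r in roots)
    return n_in, s_in


def ptp_loglik(ix: _TreeIndex, roots: Sequence[int]) -> float:
    n_in, s_in = _delim_stats(ix, roots)
    n_sp, s_sp = ix.n_edges - n_in, ix.total_len - s_in
    return _class_ll(n_sp, s_sp) + _class_ll(n_in, s_in)


def mptp_loglik(ix: _TreeIndex, roots: Sequence[int]) -> float:
    n_in, s_in = _delim_stats(ix, roots)
    n_sp, s_sp = ix.n_edges - n_in, ix.total_len - s_in
    ll = _class_ll(n_sp, s_sp)
    for r in roots:
        ll += _class_ll(ix.m[r], ix.T[r])
    return ll


def enumerate_delimitations(ix: _TreeIndex) -> List[Tuple[int, ...]]:
    """All species-root antichains covering the tips (exponential; tests only)."""
    memo: Dict[int, List[Tuple[int, ...]]] = {}

    def covers(v: int) -> List[Tuple[int, ...]]:
        if v in memo:
            return memo[v]
        out = [(v,)]
        if ix.children[v]:
            parts = [covers(c) for c in ix.children[v]]
            combos: List[Tuple[int, ...]] = [()]
            for p in parts:
                combos = [a + b for a in combos for b in p]
            out.extend(combos)
        memo[v] = out
        return out

    return covers(ix.root)


# ---------------------------------------------------------------------------
# exact single-rate maximization
#
# The joint profile log-likelihood depends on a delimitation only through
# (n, S) = (number, total length) of speciation edges, because the
# within-species class is the complement.  For fixed n the objective
# n log(n/S) - n + (E-n) log((E-n)/(L-S)) - (E-n) is convex in S, so its
# maximum over the achievable S values is attained at the minimum or
# maximum achievable S.  Both extremes (and one witness delimitation for
# each) are computed exactly by a knapsack-style DP over the tree.


def _ptp_dp(ix: _TreeIndex):
    """Per node and side (0=min, 1=max): dict n -> achievable extreme S.

    Returns (tables, back) where tables[side][v][n] is the extreme total
    speciation length for n speciation edges below v, and back[side][v][n]
    is None when the witness is "v is a species root" and otherwise a list
    of (child, n_child) choices.
    """
    tables = [[None] * len(ix.nodes) for _ in range(2)]
    back = [[None] * len(ix.nodes) for _ in range(2)]
    for side in (0, 1):
        better = (lambda a, b: a < b) if side == 0 else (lambda a, b: a > b)
        for v in range(len(ix.nodes)):  # postorder
            st: Dict[int, float] = {0: 0.0}
            bk: Dict[int, Optional[List[Tuple[int, int]]]] = {0: None}
            if ix.children[v]:
                prefix: Dict[int, Tuple[float, List[Tuple[int, int]]]] = {0: (0.0, [])}
                for c in ix.children[v]:
                    cst = tables[side][c]
                    nxt: Dict[int, Tuple[float, List[Tuple[int, int]]]] = {}
                    for n0, (s0, w0) in prefix.items():
                        for nc, sc in cst.items():
                            n1, s1 = n0 + nc + ix.cnt[c], s0 + sc + ix.len_eff[c]
                            cur = nxt.get(n1)
                            if cur is None or better(s1, cur[0]):
                                nxt[n1] = (s1, w0 + [(c, nc)])
                    prefix = nxt
                for n1, (s1, wit) in prefix.items():
                    if n1 not in st or better(s1, st[n1]):
                        st[n1] = s1
                        bk[n1] = wit
            tables[side][v] = st
            back[side][v] = bk
    return tables, back


def _ptp_backtrack(back, side: int, v: int, n: int) -> List[int]:
    wit = back[side][v][n]
    if wit is None:
        return [v]
    roots: List[int] = []
    for c, nc in wit:
        roots.extend(_ptp_backtrack(back, side, c, nc))
    return roots


def ptp_ml(t: PhyloTree) -> PtpDelimitation:
    """Exact maximum-likelihood single-rate PTP delimitation.

    The profile log-likelihood depends on a delimitation only through the
    count n and total length S of its speciation edges, and is convex in S
    for fixed n, so the optimum over achievable S lies at an extreme; the
    DP tracks both extremes exactly.
    """
    ix = _TreeIndex(t)
    tables, back = _ptp_dp(ix)
    E, L = ix.n_edges, ix.total_len
    best = (-math.inf, 0, 0)
    for side in (0, 1):
        for n, s in tables[side][ix.root].items():
            ll = _class_ll(n, s) + _class_ll(E - n, L - s)
            if ll > best[0] + 1e-15:
                best = (ll, n, side)
    ll, n, side = best
    roots = sorted(_ptp_backtrack(back, side, ix.root, n))
    n_in, s_in = _delim_stats(ix, roots)
    part = ix.partition(roots, "ptp")
    return PtpDelimitation(
        partition=part,
        log_likelihood=ptp_loglik(ix, roots),
        speciation_rate=(E - n_in) / (L - s_in) if E - n_in else None,
        coalescent_rates={"pooled": n_in / s_in} if n_in else {},
    )


# ---------------------------------------------------------------------------
# exact multi-rate maximization (per-species coalescent rates)
#
# Here the within-species contribution is additive over species, so each
# node carries, for every achievable count of speciation edges below it, a
# Pareto frontier over (speciation length S, within-species score W): a
# state is kept unless another state with the same n has both smaller-or-
# equal S and larger-or-equal W.  The speciation term is decreasing in S,
# so no optimum is ever pruned.


class _MState:
    __slots__ = ("s", "w", "k", "kind", "refs")

    def __init__(self, s, w, k, kind, refs):
        self.s = s
        self.w = w
        self.k = k  # number of species in this partial delimitation
        self.kind = kind  # "root" | "join"
        self.refs = refs  # for "join": list of (child, state)


def _pareto(points: List[_MState]) -> List[_MState]:
    # ties in (S, W) resolve toward fewer species for determinism
    points.sort(key=lambda p: (p.s, -p.w, p.k))
    out: List[_MState] = []
    best_w = -math.inf
    for p in points:
        if p.w > best_w + 1e-15:
            out.append(p)
            best_w = p.w
    return out


def _beam(pl: List[_MState], cap: int) -> List[_MState]:
    """Thin a frontier to at most cap points, keeping its endpoints."""
    if len(pl) <= cap:
        return pl
    idx = np.linspace(0, len(pl) - 1, cap).round().astype(int)
    return [pl[i] for i in dict.fromkeys(idx.tolist())]


def _mptp_dp(ix: _TreeIndex, frontier_cap: Optional[int] = None):
    states: List[Dict[int, List[_MState]]] = [None] * len(ix.nodes)
    for v in range(len(ix.nodes)):
        st: Dict[int, List[_MState]] = {
            0: [_MState(0.0, _class_ll(ix.m[v], ix.T[v]), 1, "root", None)]
        }
        if ix.children[v]:
            prefix: Dict[int, List[_MState]] = {0: [_MState(0.0, 0.0, 0, "join", [])]}
            for c in ix.children[v]:
                nxt: Dict[int, List[_MState]] = {}
                for n0, plist in prefix.items():
                    for p0 in plist:
                        for nc, clist in states[c].items():
                            for pc in clist:
                                n1 = n0 + nc + ix.cnt[c]
                                nxt.setdefault(n1, []).append(
                                    _MState(
                                        p0.s + pc.s + ix.len_eff[c],
                                        p0.w + pc.w,
                                        p0.k + pc.k,
                                        "join",
                                        p0.refs + [(c, pc)],
                                    )
                                )
                prefix = {n1: _pareto(pl) for n1, pl in nxt.items()}
                if frontier_cap:
                    prefix = {n1: _beam(pl, frontier_cap) for n1, pl in prefix.items()}
            for n1, pl in prefix.items():
                st.setdefault(n1, []).extend(pl)
            st = {n1: _pareto(pl) for n1, pl in st.items()}
        states[v] = st
    return states


def _mptp_backtrack(v: int, state: _MState, out: List[int]) -> None:
    if state.kind == "root":
        out.append(v)
        return
    for c, cs in state.refs:
        _mptp_backtrack(c, cs, out)


#: above this many tips the mPTP frontier is thinned to a beam; the DP is
#: exact below (tested against enumeration), approximate but deterministic
#: above
MPTP_EXACT_TIPS = 48
MPTP_BEAM = 24


def mptp_ml(
    t: PhyloTree,
    minbr: float = 0.0,
    frontier_cap: Optional[int] = None,
) -> PtpDelimitation:
    """Maximum-likelihood multi-rate (per-species coalescent rate) delimitation.

    Exact on small trees; on trees with more than ``MPTP_EXACT_TIPS`` tips
    the per-node Pareto frontiers are thinned to a fixed-width beam, which
    keeps the search deterministic and near-exact at assemblage scale.
    ``minbr`` excludes branches the locus cannot resolve (e.g. 1/sites)
    from the likelihood; see :class:`_TreeIndex`.
    """
    ix = _TreeIndex(t, minbr=minbr)
    if frontier_cap is None and len(ix.tipname) > MPTP_EXACT_TIPS:
        frontier_cap = MPTP_BEAM
    states = _mptp_dp(ix, frontier_cap=frontier_cap)
    E, L = ix.n_edges, ix.total_len
    best: Tuple[float, Optional[_MState], int] = (-math.inf, None, 0)
    for n, plist in states[ix.root].items():
        for p in plist:
            ll = _class_ll(n, p.s) + p.w
            if ll > best[0] + 1e-15 or (
                best[1] is not None
                and abs(ll - best[0]) <= 1e-12
                and p.k < best[1].k
            ):
                best = (ll, p, n)
    ll, state, n = best
    roots: List[int] = []
    _mptp_backtrack(ix.root, state, roots)
    roots = sorted(roots)
    part = ix.partition(roots, "mptp")
    n_in, s_in = _delim_stats(ix, roots)
    rates = {
        min(ix.tips_below[r]): (ix.m[r] / ix.T[r] if ix.m[r] else math.nan)
        for r in roots
    }
    return PtpDelimitation(
        partition=part,
        log_likelihood=ll,
        speciation_rate=(E - n_in) / (L - s_in) if E - n_in else None,
        coalescent_rates={k: v for k, v in rates.items() if v == v},
    )


# ---------------------------------------------------------------------------
# bPTP-style MCMC support


@dataclass
class McmcConfig:
    generations: int = 100_000
    thinning: int = 100
    burn_in: float = 0.1
    seed: int = 123

    def __post_init__(self) -> None:
        if not (self.generations >= self.thinning >= 1):
            raise ValidationError("need generations >= thinning >= 1")
        if not (0 <= self.burn_in < 1):
            raise ValidationError("burn-in fraction must be in [0,1)")


def _legal_moves(ix: _TreeIndex, roots: Set[int]) -> List[Tuple[str, int]]:
    moves: List[Tuple[str, int]] = [
        ("down", v) for v in roots if ix.children[v]
    ]
    parents = {ix.parent[v] for v in roots if ix.parent[v] is not None}
    for p in parents:
        if all(c in roots for c in ix.children[p]):
            moves.append(("up", p))
    return sorted(moves)


def ptp_mcmc_support(t: PhyloTree, cfg: McmcConfig = McmcConfig()) -> PtpDelimitation:
    """Single-rate PTP ML delimitation with MCMC support values.

    A Metropolis-Hastings walk over delimitations (uniform prior, proposal
    = move one speciation/coalescent transition point up or down one edge)
    is run for ``cfg.generations`` steps; after burn-in, every
    ``cfg.thinning``-th state is sampled.  The support of each group in
    the ML delimitation is the fraction of samples containing exactly that
    group.  Identical seed and config give identical output.
    """
    ml = ptp_ml(t)
    ix = _TreeIndex(t)
    # locate ML species roots by tip set
    by_tips = {ix.tips_below[i]: i for i in range(len(ix.nodes))}
    ml_roots = {by_tips[g] for g in ml.partition.groups.values()}

    rng = np.random.default_rng(cfg.seed)
    roots = set(ml_roots)
    n_in, s_in = _delim_stats(ix, sorted(roots))
    E, L = ix.n_edges, ix.total_len

    def ll(n_in, s_in):
        return _class_ll(E - n_in, L - s_in) + _class_ll(n_in, s_in)

    cur_ll = ll(n_in, s_in)
    burn = int(cfg.burn_in * cfg.generations)
    counts = {r: 0 for r in ml_roots}
    n_samples = 0
    for gen in range(1, cfg.generations + 1):
        moves = _legal_moves(ix, roots)
        kind, v = moves[rng.integers(len(moves))]
        if kind == "down":
            d_n = -len(ix.children[v])
            d_s = -sum(ix.length[c] for c in ix.children[v])
        else:
            d_n = len(ix.children[v])
            d_s = sum(ix.length[c] for c in ix.children[v])
        new_ll = ll(n_in + d_n, s_in + d_s)
        # count reverse moves for the Hastings ratio
        if kind == "down":
            new_roots = roots - {v} | set(ix.children[v])
        else:
            new_roots = roots - set(ix.children[v]) | {v}
        n_rev = len(_legal_moves(ix, new_roots))
        log_alpha = new_ll - cur_ll + math.log(len(moves)) - math.log(n_rev)
        if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
            roots = new_roots
            n_in += d_n
            s_in += d_s
            cur_ll = new_ll
        if gen > burn and gen % cfg.thinning == 0:
            n_samples += 1
            for r in ml_roots:
                if r in roots:
                    counts[r] += 1

    support = {
        min(ix.tips_below[r]): (counts[r] / n_samples if n_samples else math.nan)
        for r in ml_roots
    }
    return PtpDelimitation(
        partition=Partition(groups=dict(ml.partition.groups), method="bptp"),
        log_likelihood=ml.log_likelihood,
        speciation_rate=ml.speciation_rate,
        coalescent_rates=ml.coalescent_rates,
        support=support,
    )


# ---------------------------------------------------------------------------
# neighbor joining and midpoint rooting


def build_nj(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree (fallback when no ML tree is supplied).

    Negative estimated branch lengths are clamped to zero.  The result is
    unrooted (trifurcating seed node); midpoint_root() before tree-based
    delimitation.
    """
    import warnings

    from skbio import DistanceMatrix as _SkDM
    from skbio.tree import nj as _sknj

    if len(dm.ids) < 3:
        raise ValidationError("neighbor joining needs at least 3 specimens")
    sk = _SkDM(dm.d, ids=dm.ids)
    tree = _sknj(sk)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(f"clamped {clamped} negative NJ branch lengths to 0")
    return parse_newick(str(tree))


def _adjacency(t: PhyloTree):
    adj: Dict[int, List[Tuple[int, float]]] = {}
    ix = {}
    nodes = list(t.tree.preorder_node_iter())
    for i, n in enumerate(nodes):
        ix[id(n)] = i
    for n in nodes:
        i = ix[id(n)]
        for c in n.child_nodes():
            j = ix[id(c)]
            w = float(c.edge.length or 0.0)
            adj.setdefault(i, []).append((j, w))
            adj.setdefault(j, []).append((i, w))
    return nodes, ix, adj


def midpoint_root(t: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest tip-to-tip path.

    Ties between equally long paths are broken toward the
    lexicographically smallest (sorted) tip-name pair.  All pairwise tip
    path lengths are preserved.
    """
    t = t.clone()
    nodes, ix, adj = _adjacency(t)
    tips = [(i, n.taxon.label) for i, n in enumerate(nodes) if n.is_leaf()]
    if len(tips) < 2:
        raise ValidationError("midpoint rooting needs at least 2 tips")
    if all(w == 0 for nbrs in adj.values() for _, w in nbrs):
        raise ValidationError("all branch lengths are zero; midpoint undefined")

    def paths_from(src: int):
        dist = {src: 0.0}
        prev = {src: None}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    prev[v] = u
                    stack.append(v)
        return dist, prev

    best = None  # (distance, (nameA, nameB), tipA_idx, tipB_idx, prev-map)
    for i, name_i in tips:
        dist, prev = paths_from(i)
        for j, name_j in tips:
            if j == i or name_i > name_j:  # walk from the smaller-named tip
                continue
            cand = (dist[j], (name_i, name_j))
            if (
                best is None
                or cand[0] > best[0] + 1e-15
                or (abs(cand[0] - best[0]) <= 1e-15 and cand[1] < best[1])
            ):
                best = (dist[j], cand[1], i, j, prev)
    total, key, a, b, prev = best
    path = [b]
    while path[-1] != a:
        path.append(prev[path[-1]])
    path.reverse()  # a ... b
    target = total / 2.0
    acc = 0.0
    weights = {(u, v): w for u in path for v, w in adj[u]}
    for k in range(len(path) - 1):
        u, v = path[k], path[k + 1]
        w = weights[(u, v)]
        if acc + w >= target - 1e-12:
            off = target - acc  # distance from u into the edge (u, v)
            nu, nv = nodes[u], nodes[v]
            if nv.parent_node is nu:  # u is the parent: off measures from tail
                child, from_parent = nv, off
            else:  # v is the parent of u: tail is v
                child, from_parent = nu, w - off
            if (
                child.parent_node is t.tree.seed_node
                and len(t.tree.seed_node.child_nodes()) == 2
                and abs(from_parent) <= 1e-12
            ):
                return PhyloTree(tree=t.tree, rooted=True)  # already at midpoint
            t.tree.reroot_at_edge(
                child.edge,
                length1=from_parent,
                length2=w - from_parent,
                update_bipartitions=False,
            )
            t.tree.suppress_unifurcations()
            t.tree.seed_node.edge.length = None
            return PhyloTree(tree=t.tree, rooted=True)
        acc += w
    raise AssertionError("midpoint not located; inconsistent path lengths")


# ---------------------------------------------------------------------------
# monophyly report


def monophyly_report(t: PhyloTree, table: SpecimenTable) -> Dict[str, str]:
    """Classify each species as monophyletic / non-monophyletic / singleton.

    A species is monophyletic when the MRCA of its tips subtends no other
    species' tips.  Species with any labeled specimen absent from the tree
    are reported as "untested".
    """
    ix = _TreeIndex(t) if t.rooted else _TreeIndex(midpoint_root(t))
    tipset = set(ix.tipname.values())
    unknown = tipset - set(table.labels)
    if unknown:
        raise ValidationError(f"tree tips not in specimen table: {sorted(unknown)}")
    out: Dict[str, str] = {}
    clades = {ix.tips_below[i] for i in range(len(ix.nodes))}
    for sp, ids in table.species.items():
        ids_in = [s for s in ids if s in tipset]
        if len(ids_in) < len(ids) or not ids_in:
            out[sp] = "untested"
        elif len(ids_in) == 1:
            out[sp] = "singleton"
        else:
            out[sp] = (
                "monophyletic"
                if frozenset(ids_in) in clades
                else "non-monophyletic"
            )
    return out
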