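"""Synthetic barcode assemblages with known species membership.

The generator emulates the statistical structure of a densely sampled
single-locality beetle assemblage: a few dozen species with 1-8 sequenced
specimens each (including a fixed number of singletons), shallow
within-species variation with a configurable fraction of species carrying
a deep basal split, optional haplotype sharing between close species, and
K80 sequence evolution over a fixed-length locus.

Construction is calibrated rather than free-running, so the knobs mean
what they say:

* the species tree is a pure-birth (Yule) realization rescaled so the
  mean tip-pair path length equals ``2 * interspecific_depth`` exactly;
  species stems are floored at ``0.25 * interspecific_depth`` (internal
  branches are shrunk to restore the mean), so distinct species remain
  identifiable unless deep splits or sharing are switched on;
* each within-species genealogy is a Kingman coalescent rescaled so the
  basal within-species divergence (tip-to-tip through the species
  ancestor) equals ``intraspecific_depth`` exactly; species pendants are
  shaved by the genealogy height, keeping specimen-level divergence
  centred on the species-tree calibration;
* deep-flagged species instead carry a basal two-deme split whose
  tip-to-tip divergence is drawn uniformly from ``deep_divergence``
  (default 4-7%, i.e. up to 0.035 per lineage);
* a sharing event grafts one recipient specimen as a zero-length sister
  of a specimen of the nearest other species (introgression-like), which
  yields shared haplotypes and non-monophyly while the truth labels keep
  the recipient species.

A single seeded generator drives the genealogy; sequence evolution uses a
seed derived from it.  Identical (config, seed) means identical output,
byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .io import Alignment, PhyloTree, SpecimenTable, ValidationError

#: sample-size distribution for non-singleton species (sizes 2..8); mean
#: ~4.2, matching a 3-5-per-species sequencing design with occasional extras
_SIZE_RANGE = np.arange(2, 9)
_SIZE_WEIGHTS = np.array([0.20, 0.20, 0.20, 0.15, 0.10, 0.10, 0.05])

#: species stems are floored at this multiple of interspecific_depth
_STEM_FLOOR = 0.25


@dataclass
class SimulationConfig:
    n_species: int = 56
    n_singletons: int = 14
    interspecific_depth: float = 0.085
    intraspecific_depth: float = 0.015
    deep_fraction: float = 0.21
    deep_divergence: Tuple[float, float] = (0.04, 0.07)
    sharing_prob: float = 0.0
    length: int = 658
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.n_species < 2 or not (0 <= self.n_singletons <= self.n_species):
            raise ValidationError("need n_species >= 2 and 0 <= singletons <= species")
        if min(self.interspecific_depth, self.intraspecific_depth) < 0:
            raise ValidationError("depths must be non-negative")
        if not (0 <= self.deep_fraction <= 1 and 0 <= self.sharing_prob <= 1):
            raise ValidationError("fractions must be in [0,1]")
        if self.length < 1:
            raise ValidationError("alignment length must be >= 1")


@dataclass
class TruthSet:
    labels: SpecimenTable
    genealogy: PhyloTree
    deep_species: List[str]
    shared_haplotype_species: List[Tuple[str, str]]  # (donor, recipient)

    @property
    def singletons(self) -> List[str]:
        return sorted(self.labels.singletons)

    def partition(self):
        return self.labels.to_partition(method="truth")


# ---------------------------------------------------------------------------
# genealogy specs: ("tip", name) at age 0, or ("node", age, [children])


def _spec_age(s) -> float:
    return 0.0 if s[0] == "tip" else s[1]


def _scale_spec(s, f: float):
    if s[0] == "tip":
        return s
    return ("node", s[1] * f, [_scale_spec(c, f) for c in s[2]])


def _kingman(ids: Sequence[str], rng: np.random.Generator):
    """Kingman coalescent over ids; ages in units of pairwise-coalescent time."""
    lineages: List = [("tip", sid) for sid in ids]
    k = len(lineages)
    t = 0.0
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(int(x) for x in rng.choice(k, size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        lineages.append(("node", t, [a, b]))
        k -= 1
    return lineages[0]


def _attach_spec(spec, parent: dendropy.Node, stem: float, taxa) -> None:
    """Graft a genealogy spec under ``parent`` with the given stem length."""
    nd = parent.new_child(edge_length=float(stem))
    if spec[0] == "tip":
        nd.taxon = taxa.new_taxon(spec[1])
        return
    for child in spec[2]:
        _attach_spec(child, nd, spec[1] - _spec_age(child), taxa)


# ---------------------------------------------------------------------------
# species tree


def _yule_topology(n: int, rng: np.random.Generator):
    """Forward pure-birth simulation; returns (root, children, stems, tips)."""
    next_id = 0
    root = next_id
    birth = {root: 0.0}
    children: Dict[int, List[Tuple[int, float]]] = {}
    active = [root]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        parent = active.pop(k)
        kids = []
        for _ in range(2):
            next_id += 1
            birth[next_id] = t
            kids.append(next_id)
            active.append(next_id)
        children[parent] = [(kid, t - birth[parent]) for kid in kids]
    t_end = t + rng.exponential(1.0 / len(active))  # tips extend past last split
    stems = {lin: t_end - birth[lin] for lin in active}
    return root, children, stems, active


def _mean_tip_pair_path(tree: dendropy.Tree) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    vals = [
        pdm.distance(a, b) for i, a in enumerate(taxa) for b in taxa[i + 1 :]
    ]
    return float(np.mean(vals))


def _species_tree(cfg: SimulationConfig, rng: np.random.Generator) -> dendropy.Tree:
    root, children, stems, tips = _yule_topology(cfg.n_species, rng)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodemap: Dict[int, dendropy.Node] = {root: tree.seed_node}
    stack = [root]
    while stack:
        nid = stack.pop()
        for cid, blen in children.get(nid, []):
            nodemap[cid] = nodemap[nid].new_child(edge_length=float(blen))
            stack.append(cid)
    for i, lin in enumerate(sorted(tips)):
        nd = nodemap[lin]
        nd.edge.length = float(stems[lin])
        nd.taxon = taxa.new_taxon(f"sp{i + 1:02d}")

    # calibrate: mean tip-pair path = 2 * interspecific_depth, stems floored
    target = 2.0 * cfg.interspecific_depth
    scale = target / _mean_tip_pair_path(tree)
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= scale
    floor = _STEM_FLOOR * cfg.interspecific_depth
    for lf in tree.leaf_node_iter():
        if lf.edge.length < floor:
            lf.edge.length = floor
    mean = _mean_tip_pair_path(tree)
    if mean > target:
        pend = [lf.edge.length for lf in tree.leaf_node_iter()]
        pend_contrib = 2.0 * float(np.mean(pend))  # E[pend_i + pend_j]
        internal_contrib = mean - pend_contrib
        if internal_contrib > 0:
            gamma = max(0.0, (target - pend_contrib) / internal_contrib)
            for e in tree.preorder_edge_iter():
                if e.length is not None and not e.head_node.is_leaf():
                    e.length *= gamma
    return tree


# ---------------------------------------------------------------------------
# assemblage genealogy


def simulate_genealogy(cfg: SimulationConfig, seed: int) -> Tuple[PhyloTree, TruthSet]:
    """Specimen-level gene tree with truth labels and per-species flags."""
    rng = np.random.default_rng(seed)
    sp_tree = _species_tree(cfg, rng)
    names = sorted(t.label for t in sp_tree.taxon_namespace)

    singleton_set = set(rng.choice(names, size=cfg.n_singletons, replace=False).tolist())
    sizes = {
        sp: 1 if sp in singleton_set else int(rng.choice(_SIZE_RANGE, p=_SIZE_WEIGHTS))
        for sp in names
    }
    multi = [sp for sp in names if sizes[sp] >= 2]
    n_deep = min(int(round(cfg.deep_fraction * cfg.n_species)), len(multi))
    deep_set = (
        set(rng.choice(multi, size=n_deep, replace=False).tolist()) if n_deep else set()
    )

    specimen_names = {
        sp: [f"{sp}_{k + 1}" for k in range(sizes[sp])] for sp in names
    }
    labels = {sid: sp for sp in names for sid in specimen_names[sp]}

    def species_spec(sp: str) -> Tuple[object, float]:
        """(genealogy spec, its age) for one species."""
        ids = specimen_names[sp]
        if len(ids) == 1:
            return ("tip", ids[0]), 0.0
        if sp in deep_set:
            div = float(rng.uniform(*cfg.deep_divergence))
            h = div / 2.0
            k1 = 1 + int(rng.integers(len(ids) - 1))
            demes = []
            for deme in (ids[:k1], ids[k1:]):
                if len(deme) == 1:
                    demes.append(("tip", deme[0]))
                else:
                    raw = _kingman(deme, rng)
                    h_deme = min(0.5 * cfg.intraspecific_depth, 0.9 * h)
                    demes.append(_scale_spec(raw, h_deme / _spec_age(raw)))
            return ("node", h, demes), h
        raw = _kingman(ids, rng)
        h = 0.5 * cfg.intraspecific_depth
        age = _spec_age(raw)
        return (_scale_spec(raw, h / age) if age > 0 else raw), (h if age > 0 else 0.0)

    taxa = dendropy.TaxonNamespace()
    gene = dendropy.Tree(taxon_namespace=taxa)

    def clone(src: dendropy.Node, dst: dendropy.Node):
        for c in src.child_nodes():
            if c.is_leaf():
                sp = c.taxon.label
                spec, age = species_spec(sp)
                stem = max(float(c.edge.length) - age, 1e-6)
                _attach_spec(spec, dst, stem, taxa)
            else:
                clone(c, dst.new_child(edge_length=float(c.edge.length)))

    clone(sp_tree.seed_node, gene.seed_node)

    shared: List[Tuple[str, str]] = []
    if cfg.sharing_prob > 0:
        for recipient in multi:
            if rng.random() >= cfg.sharing_prob:
                continue
            donor = _nearest_species(sp_tree, recipient)
            if donor is None:
                continue
            moved = specimen_names[recipient][-1]
            host = specimen_names[donor][0]
            _graft_zero_length(gene, moved, host)
            shared.append((donor, recipient))

    tree = PhyloTree(tree=gene, rooted=len(gene.seed_node.child_nodes()) <= 2)
    return tree, TruthSet(
        labels=SpecimenTable(labels=labels),
        genealogy=tree,
        deep_species=sorted(deep_set),
        shared_haplotype_species=shared,
    )


def _nearest_species(sp_tree: dendropy.Tree, recipient: str) -> Optional[str]:
    pdm = sp_tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in sp_tree.taxon_namespace}
    me = taxa[recipient]
    best = None
    for name in sorted(taxa):
        if name == recipient:
            continue
        d = pdm.distance(me, taxa[name])
        if best is None or d < best[0]:
            best = (d, name)
    return best[1] if best else None


def _graft_zero_length(gene: dendropy.Tree, moved: str, host: str) -> None:
    """Detach ``moved`` and re-insert it as a zero-length sister of ``host``."""
    nodes = {lf.taxon.label: lf for lf in gene.leaf_node_iter()}
    mnode, hnode = nodes[moved], nodes[host]
    mnode.parent_node.remove_child(mnode)
    gene.suppress_unifurcations()
    hparent = hnode.parent_node
    hlen = hnode.edge.length
    hparent.remove_child(hnode)
    joint = hparent.new_child(edge_length=hlen)
    joint.add_child(hnode)
    hnode.edge.length = 0.0
    mnode.edge.length = 0.0
    joint.add_child(mnode)


# ---------------------------------------------------------------------------
# sequence evolution (K80)


def _k80_probs(t: float, kappa: float) -> Tuple[float, float]:
    """(P(transition), P(each transversion)) after branch length t.

    Branch lengths are in expected substitutions/site: the transition rate
    is kappa times each transversion rate, normalised so the total
    substitution rate is 1 per unit length.
    """
    e1 = math.exp(-4.0 * t / (kappa + 2.0))
    e2 = math.exp(-2.0 * t * (kappa + 1.0) / (kappa + 2.0))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    return p_ts, p_tv


def k80_expected_p(t: float, kappa: float) -> float:
    """Expected proportion of observed differences at path length t."""
    p_ts, p_tv = _k80_probs(t, kappa)
    return p_ts + 2.0 * p_tv


def evolve_sequences(g: PhyloTree, cfg: SimulationConfig, seed: int) -> Alignment:
    """Simulate K80 evolution over the genealogy from a random root sequence."""
    rng = np.random.default_rng(seed)
    L = cfg.length
    ts_partner = np.array([2, 3, 0, 1])  # A<->G, C<->T with A0 C1 G2 T3
    tv1 = np.array([1, 0, 1, 0])
    tv2 = np.array([3, 2, 3, 2])

    seqs: Dict[str, np.ndarray] = {}

    def walk(node: dendropy.Node, seq: np.ndarray):
        for c in node.child_nodes():
            t = float(c.edge.length or 0.0)
            p_ts, p_tv = _k80_probs(t, cfg.kappa)
            u = rng.random(L)
            child = seq.copy()
            m_ts = u < p_ts
            m_tv1 = (u >= p_ts) & (u < p_ts + p_tv)
            m_tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
            child[m_ts] = ts_partner[seq[m_ts]]
            child[m_tv1] = tv1[seq[m_tv1]]
            child[m_tv2] = tv2[seq[m_tv2]]
            if c.is_leaf():
                seqs[c.taxon.label] = child
            walk(c, child)

    walk(g.tree.seed_node, rng.integers(0, 4, size=L))
    alpha = np.array(list("ACGT"))
    return Alignment(records={sid: "".join(alpha[seqs[sid]]) for sid in sorted(seqs)})


def simulate_assemblage(cfg: SimulationConfig, seed: int) -> Tuple[Alignment, TruthSet]:
    """Genealogy plus evolved sequences; the one-call entry point."""
    genealogy, truth = simulate_genealogy(cfg, seed)
    aln = evolve_sequences(genealogy, cfg, seed=int(seed) + 1_000_003)
    return aln, truth


def easy_config(**overrides) -> SimulationConfig:
    """A cleanly separated regime: no deep splits, no sharing, shallow
    within-species variation against deep species divergences."""
    base = dict(
        deep_fraction=0.0,
        sharing_prob=0.0,
        intraspecific_depth=0.005,
        interspecific_depth=0.15,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def deep_config(**overrides) -> SimulationConfig:
    """Half the species carry a deep basal split (hard regime)."""
    base = dict(deep_fraction=0.5)
    base.update(overrides)
    return SimulationConfig(**base)
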