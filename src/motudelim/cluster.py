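"""Distance- and graph-based species delimitation.

Three methods live here:

* fixed-threshold single-linkage clustering (connected components of the
  graph linking specimens at pairwise distance <= t, the semantics of the
  classic ``tclust`` approach used with a 3% K2P threshold),
* Automatic Barcode Gap Discovery (ABGD): for a log-spaced range of prior
  intraspecific divergences, find the first significant gap in the ranked
  pairwise distances above the prior, cluster below the gap, and recurse
  within groups until nothing splits,
* statistical parsimony (TCS): collapse specimens into haplotypes, link
  haplotypes whose nucleotide difference is within the 95% parsimony
  connection limit, and take connected components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .distances import DistanceMatrix, pairwise_distances
from .io import Alignment, Partition, ValidationError, canonical_partition

# ---------------------------------------------------------------------------
# threshold clustering


def threshold_cluster(dm: DistanceMatrix, t: float = 0.03) -> Partition:
    """Single-linkage clusters: components of the graph with edges d <= t.

    The boundary is inclusive (d == t links), and group ids are the
    lexicographically lowest member id, so output is deterministic and
    invariant to specimen input order.
    """
    if t < 0:
        raise ValueError(f"negative threshold {t}")
    g = nx.Graph()
    g.add_nodes_from(dm.ids)
    n = len(dm.ids)
    for i in range(n):
        for j in range(i + 1, n):
            if dm.d[i, j] <= t:
                g.add_edge(dm.ids[i], dm.ids[j])
    return canonical_partition(nx.connected_components(g), method=f"threshold_{t:g}")


# ---------------------------------------------------------------------------
# ABGD


@dataclass
class AbgdConfig:
    """Priors and gap rule for the barcode-gap scan (web-server defaults)."""

    p_min: float = 0.001
    p_max: float = 0.1
    steps: int = 50
    x: float = 1.0  # relative gap width
    nb_bins: int = 20
    model: str = "jc69"

    def __post_init__(self) -> None:
        if not (0 < self.p_min < self.p_max < 0.75):
            raise ValidationError("need 0 < p_min < p_max < 0.75")
        if self.steps < 2:
            raise ValidationError("need at least 2 prior steps")
        if self.x <= 0:
            raise ValidationError("relative gap width must be positive")

    def priors(self) -> np.ndarray:
        return np.exp(
            np.linspace(math.log(self.p_min), math.log(self.p_max), self.steps)
        )


#: trailing window (number of preceding candidate gaps) for the local
#: average gap width in the gap-significance rule
_GAP_WINDOW = 10


def _find_gap(sorted_d: np.ndarray, prior: float, x: float) -> Optional[float]:
    """First significant gap above the prior; returns the link threshold.

    Candidate gaps are those between consecutive ranked distances whose
    upper edge exceeds the prior.  A candidate is significant when its
    width exceeds ``x`` times the local average gap width (trailing window
    of candidate gaps; for the first candidate, the mean of the remaining
    candidate widths is used).  Ties in the rule are resolved toward the
    lowest-distance gap simply by scanning in rank order.
    """
    lo = sorted_d[:-1]
    hi = sorted_d[1:]
    widths = hi - lo
    cand = np.nonzero((hi > prior) & (widths > 0))[0]
    if len(cand) == 0:
        return None
    cand_w = widths[cand]
    for k, i in enumerate(cand):
        if k == 0:
            others = cand_w[1:]
            local = float(others.mean()) if len(others) else 0.0
        else:
            win = cand_w[max(0, k - _GAP_WINDOW) : k]
            local = float(win.mean())
        if widths[i] > x * local:
            return float(lo[i])
    return None


def _abgd_split(dm: DistanceMatrix, prior: float, x: float) -> List[List[str]]:
    vals = np.sort(dm.d[np.triu_indices(len(dm.ids), k=1)])
    thr = _find_gap(vals, prior, x)
    if thr is None:
        return [list(dm.ids)]
    part = threshold_cluster(dm, thr)
    return [sorted(m) for m in part.groups.values()]


def abgd_partition(dm: DistanceMatrix, prior: float, x: float = 1.0,
                   recursive: bool = True) -> Partition:
    """ABGD partition at a single prior (recursive by default)."""
    blocks: List[List[str]] = []
    stack = [list(dm.ids)]
    while stack:
        ids = stack.pop()
        if len(ids) < 3:
            blocks.append(ids)
            continue
        pieces = _abgd_split(dm.submatrix(ids), prior, x)
        if len(pieces) == 1 or not recursive:
            blocks.extend(pieces)
        else:
            stack.extend(pieces)
    return canonical_partition(blocks, method=f"abgd_P{prior:g}")


def abgd_scan(dm: DistanceMatrix, cfg: AbgdConfig = AbgdConfig()) -> List[Tuple[float, Partition]]:
    """Recursive ABGD partition for each prior on the log-spaced grid."""
    if len(dm.ids) < 3:
        raise ValidationError("ABGD needs at least 3 specimens")
    return [(float(p), abgd_partition(dm, float(p), cfg.x)) for p in cfg.priors()]


def abgd_select_best(scan: Sequence[Tuple[float, Partition]]) -> Partition:
    """Partition whose group count persists over the longest run of priors.

    Ties are broken toward the run starting at the smaller prior.  The
    chosen prior range is recorded in the partition's method tag.
    """
    if not scan:
        raise ValidationError("empty ABGD scan")
    runs: List[Tuple[int, int, int]] = []  # (length, start_idx, end_idx)
    start = 0
    for i in range(1, len(scan) + 1):
        if i == len(scan) or scan[i][1].n_groups != scan[start][1].n_groups:
            runs.append((i - start, start, i - 1))
            start = i
    best_len = max(r[0] for r in runs)
    length, s, e = next(r for r in runs if r[0] == best_len)
    chosen = scan[s][1]
    return Partition(
        groups=dict(chosen.groups),
        method=f"abgd_best_P[{scan[s][0]:g},{scan[e][0]:g}]",
    )


# ---------------------------------------------------------------------------
# statistical parsimony (TCS)


@dataclass
class TcsConfig:
    connection_probability: float = 0.95
    alignment_length: int = 658

    def __post_init__(self) -> None:
        if not (0 < self.connection_probability < 1):
            raise ValidationError("connection probability must be in (0,1)")
        if self.alignment_length < 1:
            raise ValidationError("alignment length must be >= 1")


def parsimony_probability(j: int, m: int) -> float:
    """Probability that j observed differences over m sites are parsimonious.

    Each site accumulates substitutions as an independent Poisson process
    under a Jukes-Cantor four-state model along the path joining the two
    haplotypes.  The per-site substitution expectation mu is estimated by
    inverting the observed mismatch proportion j/m, and the probability of
    parsimony is the conditional probability that a site which shows a
    difference experienced exactly one substitution, taken jointly over
    the j observed differences:

        P_j = [ mu e^{-mu} / ((3/4)(1 - e^{-4 mu / 3})) ]^j

    This is the probability that the j-step path between the haplotypes
    involves no superimposed (homoplastic) change at the observed sites.
    """
    if j == 0:
        return 1.0
    p = j / m
    if p >= 0.75:
        return 0.0
    mu = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    p_diff = 0.75 * (1.0 - math.exp(-4.0 * mu / 3.0))
    return (mu * math.exp(-mu) / p_diff) ** j


def tcs_connection_limit(cfg: TcsConfig) -> int:
    """Largest number of steps with parsimony probability >= the cutoff."""
    j = 0
    while parsimony_probability(j + 1, cfg.alignment_length) >= cfg.connection_probability:
        j += 1
        if j >= cfg.alignment_length:  # degenerate cutoff; cannot exceed m
            break
    return j


def _haplotype_groups(aln: Alignment) -> List[List[str]]:
    """Group specimens whose sequences agree at all mutually unambiguous sites."""
    from .distances import _encode

    ids, mat = _encode(aln)
    groups: List[List[str]] = []
    reps: List[np.ndarray] = []
    for k, sid in enumerate(ids):
        row = mat[k]
        placed = False
        for gi, rep in enumerate(reps):
            ok = (row >= 0) & (rep >= 0)
            if not np.any(row[ok] != rep[ok]):
                groups[gi].append(sid)
                # keep the most informative representative
                reps[gi] = np.where(rep >= 0, rep, row)
                placed = True
                break
        if not placed:
            groups.append([sid])
            reps.append(row.copy())
    return groups


def tcs_partition(aln: Alignment, cfg: Optional[TcsConfig] = None) -> Partition:
    """Statistical-parsimony clusters (component membership only).

    Identical specimens (comparing only mutually unambiguous sites) are
    collapsed into haplotypes; haplotypes are linked when their absolute
    nucleotide difference is within the connection limit; clusters are
    the connected components, expanded back to specimens.  The full
    network topology (inferred intermediates, loops) is not built -- it
    does not affect component membership.
    """
    from .distances import _encode

    if cfg is None:
        cfg = TcsConfig(alignment_length=aln.length)
    limit = tcs_connection_limit(cfg)
    haps = _haplotype_groups(aln)
    ids, mat = _encode(aln)
    idx = {s: i for i, s in enumerate(ids)}
    g = nx.Graph()
    g.add_nodes_from(range(len(haps)))
    for a in range(len(haps)):
        ra = mat[idx[haps[a][0]]]
        for b in range(a + 1, len(haps)):
            rb = mat[idx[haps[b][0]]]
            ok = (ra >= 0) & (rb >= 0)
            diff = int(np.sum(ra[ok] != rb[ok]))
            if diff <= limit:
                g.add_edge(a, b)
    blocks = [
        [sid for h in comp for sid in haps[h]] for comp in nx.connected_components(g)
    ]
    return canonical_partition(blocks, method=f"tcs_{cfg.connection_probability:g}_limit{limit}")
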