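"""Pairwise genetic distances and infra/interspecific summaries.

Distances are computed with pairwise deletion: for each pair of sequences
only sites where both residues are unambiguous bases (A, C, G, T) are
compared; gaps, Ns and IUPAC ambiguity codes never count as partial
matches.  Three models are supported:

``p``
    raw mismatch proportion over compared sites,
``jc69``
    d = -(3/4) ln(1 - 4p/3),
``k80``
    d = -(1/2) ln((1 - 2P - Q) sqrt(1 - 2Q)) with P and Q the transition
    and transversion proportions (Kimura's two-parameter correction, the
    "K2P" of barcoding practice).

Distances saturate when the log argument is non-positive (p >= 3/4 for
JC69).  By default a saturated pair raises an error, since empirical
barcode data sit far below saturation and saturation indicates bad input;
a cap-at-maximum policy is available for exploratory runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .io import Alignment, SpecimenTable, ValidationError

MODELS = ("p", "jc69", "k80")

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}

#: distance assigned to a saturated pair under the "cap" policy
SATURATION_CAP = 5.0


class SaturatedDistanceError(ValueError):
    """A pair's divergence is beyond the model's valid range."""


@dataclass
class DistanceMatrix:
    ids: List[str]
    d: np.ndarray
    model: str

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(self.d)):
            raise ValidationError("non-finite distances")
        if np.any(self.d < 0):
            raise ValidationError("negative distances")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValidationError("non-zero diagonal")

    def index(self) -> Dict[str, int]:
        return {sid: i for i, sid in enumerate(self.ids)}

    def submatrix(self, keep: List[str]) -> "DistanceMatrix":
        idx = self.index()
        sel = [idx[s] for s in keep]
        return DistanceMatrix(ids=list(keep), d=self.d[np.ix_(sel, sel)], model=self.model)

    def pairs(self):
        """Yield (id_i, id_j, distance) over the upper triangle."""
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                yield self.ids[i], self.ids[j], self.d[i, j]


def _encode(aln: Alignment) -> Tuple[List[str], np.ndarray]:
    """Encode to integers: 0..3 = ACGT, -1 = anything ambiguous/missing."""
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    ids = aln.ids
    mat = np.vstack(
        [lut[np.frombuffer(aln.records[s].encode(), dtype=np.uint8)] for s in ids]
    )
    return ids, mat


def _pair_counts(a: np.ndarray, b: np.ndarray) -> Tuple[int, int, int]:
    """(compared sites, transitions, transversions) under pairwise deletion."""
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    diff = ok & (a != b)
    # purines are codes 0 (A) and 2 (G); pyrimidines 1 (C) and 3 (T)
    ts = int((diff & ((a % 2) == (b % 2))).sum())
    tv = int(diff.sum()) - ts
    return n, ts, tv


def model_distance(n: int, ts: int, tv: int, model: str, saturation: str = "error"):
    """Distance for one pair from compared-site counts."""
    if n == 0:
        raise ValidationError("zero comparable sites")
    p = (ts + tv) / n
    if model == "p":
        return p
    if model == "jc69":
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            if saturation == "cap":
                return SATURATION_CAP
            raise SaturatedDistanceError(f"JC69 saturated at p={p:.4f}")
        return -0.75 * math.log(arg)
    if model == "k80":
        P, Q = ts / n, tv / n
        a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if a1 <= 0 or a2 <= 0:
            if saturation == "cap":
                return SATURATION_CAP
            raise SaturatedDistanceError(f"K80 saturated at P={P:.4f}, Q={Q:.4f}")
        return -0.5 * math.log(a1 * math.sqrt(a2))
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def pairwise_distances(
    aln: Alignment, model: str = "k80", saturation: str = "error"
) -> DistanceMatrix:
    """Pairwise distance matrix for an alignment under one model."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if len(aln) < 2:
        raise ValidationError("need at least 2 records for distances")
    ids, mat = _encode(aln)
    n = len(ids)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            cmpn, ts, tv = _pair_counts(mat[i], mat[j])
            if cmpn == 0:
                raise ValidationError(
                    f"zero comparable sites between {ids[i]!r} and {ids[j]!r}"
                )
            d[i, j] = d[j, i] = model_distance(cmpn, ts, tv, model, saturation)
    return DistanceMatrix(ids=ids, d=d, model=model)


# ---------------------------------------------------------------------------
# Table-1-style summaries


@dataclass
class ScopeStats:
    n_pairs: int
    min: float
    max: float
    mean: float
    median: float


@dataclass
class DistanceSummary:
    """Infra/interspecific distance statistics of a labeled assemblage.

    ``n_species_infra_gt_t`` counts species whose maximum infraspecific
    distance strictly exceeds ``t``; ``n_pairs_inter_lt_t`` counts species
    pairs whose minimum interspecific distance is strictly below ``t``
    (species pairs, not specimen pairs).
    """

    t: float
    infraspecific: Optional[ScopeStats]
    interspecific: Optional[ScopeStats]
    n_species_infra_gt_t: Optional[int]
    n_pairs_inter_lt_t: Optional[int]
    histogram: Dict[str, np.ndarray] = field(default_factory=dict)
    bin_width: float = 0.01


def _scope_stats(vals: np.ndarray) -> ScopeStats:
    return ScopeStats(
        n_pairs=len(vals),
        min=float(vals.min()),
        max=float(vals.max()),
        mean=float(vals.mean()),
        median=float(np.median(vals)),
    )


def distance_summary(
    dm: DistanceMatrix, table: SpecimenTable, t: float = 0.03, bin_width: float = 0.01
) -> DistanceSummary:
    idx = dm.index()
    unlabeled = [s for s in dm.ids if s not in table.labels]
    if unlabeled:
        raise ValidationError(f"unlabeled specimens in matrix: {unlabeled}")
    species = {
        sp: [s for s in ids if s in idx] for sp, ids in table.species.items()
    }
    species = {sp: ids for sp, ids in species.items() if ids}

    infra_vals: List[float] = []
    per_species_max: Dict[str, float] = {}
    for sp, ids in species.items():
        if len(ids) < 2:
            continue
        sub = dm.submatrix(ids).d
        vals = sub[np.triu_indices(len(ids), k=1)]
        infra_vals.extend(vals.tolist())
        per_species_max[sp] = float(vals.max())

    inter_vals: List[float] = []
    pair_min: Dict[Tuple[str, str], float] = {}
    names = sorted(species)
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            a, b = names[a_i], names[b_i]
            ra = [idx[s] for s in species[a]]
            rb = [idx[s] for s in species[b]]
            block = dm.d[np.ix_(ra, rb)]
            inter_vals.extend(block.ravel().tolist())
            pair_min[(a, b)] = float(block.min())

    infra = np.array(infra_vals) if infra_vals else None
    inter = np.array(inter_vals) if inter_vals else None
    hist: Dict[str, np.ndarray] = {}
    top = max(
        [v.max() for v in (infra, inter) if v is not None and len(v)], default=0.0
    )
    nbins = max(1, int(math.ceil(top / bin_width)) or 1)
    edges = np.arange(0, (nbins + 1) * bin_width, bin_width)[: nbins + 1]
    for name, vals in (("infraspecific", infra), ("interspecific", inter)):
        if vals is not None:
            hist[name], _ = np.histogram(vals, bins=edges)

    return DistanceSummary(
        t=t,
        infraspecific=_scope_stats(infra) if infra is not None else None,
        interspecific=_scope_stats(inter) if inter is not None else None,
        n_species_infra_gt_t=(
            sum(1 for v in per_species_max.values() if v > t) if infra is not None else None
        ),
        n_pairs_inter_lt_t=(
            sum(1 for v in pair_min.values() if v < t) if inter is not None else None
        ),
        histogram=hist,
        bin_width=bin_width,
    )


def summary_table(s: DistanceSummary) -> str:
    """Render a summary as a TSV mirroring the usual min/max/mean/median rows."""
    def fmt(x):
        return "" if x is None else f"{x:.6g}"

    rows = ["\tinterspecific\tinfraspecific"]
    for stat in ("min", "max", "mean", "median"):
        rows.append(
            f"{stat}\t"
            + fmt(getattr(s.interspecific, stat, None) if s.interspecific else None)
            + "\t"
            + fmt(getattr(s.infraspecific, stat, None) if s.infraspecific else None)
        )
    rows.append(f"n_species_infra_gt_{s.t:g}\t\t" + fmt(s.n_species_infra_gt_t))
    rows.append(f"n_pairs_inter_lt_{s.t:g}\t" + fmt(s.n_pairs_inter_lt_t) + "\t")
    return "\n".join(rows) + "\n"


def write_distances_tsv(dm: DistanceMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("specimen_id\t" + "\t".join(dm.ids) + "\n")
        for i, sid in enumerate(dm.ids):
            fh.write(sid + "\t" + "\t".join(f"{x:.8f}" for x in dm.d[i]) + "\n")


def write_phylip(dm: DistanceMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for i, sid in enumerate(dm.ids):
            fh.write(sid + "  " + "  ".join(f"{x:.8f}" for x in dm.d[i]) + "\n")
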