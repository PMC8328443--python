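"""Agreement between a MOTU partition and the reference morphospecies.

The headline statistic is the match ratio 2*N_match/(N_MOTU + N_morph): a
Dice-style score over exactly matching groups, where an exact match means
a morphospecies and a MOTU contain identical specimen sets.  Per-species
agreement classes refine the picture: a species is *split* when its
specimens span several MOTUs that are each wholly inside the species,
*lumped* when it shares its single MOTU with other species, and *mixed*
for any other disagreement (non-nesting overlaps, as arise from
non-monophyletic species).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict

from .io import Partition, ValidationError


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero to ``ndigits`` decimals (report convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _check_cover(motu: Partition, morph: Partition) -> None:
    a, b = motu.specimens, morph.specimens
    if a != b:
        raise ValidationError(
            f"partitions cover different specimens; symmetric difference: "
            f"{sorted(a ^ b)}"
        )


def exact_matches(motu: Partition, morph: Partition) -> int:
    """Number of groups whose specimen sets are identical in both partitions."""
    _check_cover(motu, morph)
    return len(motu.as_sets() & morph.as_sets())


def match_ratio(n_match: int, n_motu: int, n_morph: int) -> float:
    if min(n_match, n_motu, n_morph) < 0 or n_motu + n_morph == 0:
        raise ValidationError("counts must be non-negative with n_motu+n_morph > 0")
    if n_match > min(n_motu, n_morph):
        raise ValidationError(
            f"n_match={n_match} exceeds min(n_motu, n_morph)={min(n_motu, n_morph)}"
        )
    return 2.0 * n_match / (n_motu + n_morph)


def agreement_classes(motu: Partition, morph: Partition) -> Dict[str, str]:
    """Per reference species: match / split / lumped / mixed."""
    _check_cover(motu, morph)
    motu_of = motu.group_of()
    out: Dict[str, str] = {}
    for sp, members in morph.groups.items():
        touched = {motu_of[s] for s in members}
        pure = all(motu.groups[g] <= members for g in touched)
        if len(touched) == 1:
            g = next(iter(touched))
            out[sp] = "match" if motu.groups[g] == members else "lumped"
        else:
            out[sp] = "split" if pure else "mixed"
    return out


@dataclass
class MatchReport:
    method: str
    n_match: int
    n_motu: int
    n_morph: int
    ratio: float
    classes: Dict[str, str]

    @property
    def ratio_2dp(self) -> float:
        return round_half_up(self.ratio, 2)


def compare_partitions(motu: Partition, morph: Partition) -> MatchReport:
    n_match = exact_matches(motu, morph)
    return MatchReport(
        method=motu.method,
        n_match=n_match,
        n_motu=motu.n_groups,
        n_morph=morph.n_groups,
        ratio=match_ratio(n_match, motu.n_groups, morph.n_groups),
        classes=agreement_classes(motu, morph),
    )


def report_table(reports) -> str:
    """TSV summary with one row per method (counts and 2-dp match ratio)."""
    lines = ["method\tn_match\tn_motu\tn_morph\tmatch_ratio"]
    for r in reports:
        lines.append(
            f"{r.method}\t{r.n_match}\t{r.n_motu}\t{r.n_morph}\t{r.ratio_2dp:.2f}"
        )
    return "\n".join(lines) + "\n"


def classes_table(reports) -> str:
    """Long-format TSV of per-species agreement classes across methods."""
    lines = ["method\tspecies\tclass"]
    for r in reports:
        for sp in sorted(r.classes):
            lines.append(f"{r.method}\t{sp}\t{r.classes[sp]}")
    return "\n".join(lines) + "\n"
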