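"""Readers, writers and validated core containers.

The pipeline touches three plain-text formats: FASTA for the aligned
nucleotide matrix, TSV for specimen labels and partitions, and Newick for
trees.  Everything is validated on the way in, so downstream modules can
assume the invariants (equal-length rows, disjoint covering partitions,
finite non-negative branch lengths) without re-checking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC nucleotide codes plus gap and missing symbols.
IUPAC_NT = set("ACGTRYSWKMBDHVN-")
#: Unambiguous bases; everything else counts as missing for distances.
UNAMBIGUOUS = set("ACGT")


class ValidationError(ValueError):
    """An input file or container violates a structural invariant."""


@dataclass
class Alignment:
    """An aligned nucleotide matrix keyed by specimen id.

    Residues are stored uppercase; ``N`` and ``-`` (and any IUPAC
    ambiguity) are treated as missing data by the distance layer.
    """

    records: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("alignment has no records")
        lengths = {sid: len(s) for sid, s in self.records.items()}
        distinct = set(lengths.values())
        if len(distinct) > 1:
            ragged = sorted(lengths, key=lambda k: (lengths[k], k))
            raise ValidationError(
                "ragged alignment: records have unequal lengths: "
                + ", ".join(f"{sid}({lengths[sid]})" for sid in ragged)
            )
        if 0 in distinct:
            raise ValidationError("alignment rows are empty")
        up: Dict[str, str] = {}
        for sid, seq in self.records.items():
            if not sid:
                raise ValidationError("empty specimen id")
            s = seq.upper()
            for pos, ch in enumerate(s):
                if ch not in IUPAC_NT:
                    raise ValidationError(
                        f"illegal character {ch!r} in record {sid!r} at position {pos}"
                    )
            up[sid] = s
        self.records = up

    @property
    def ids(self) -> List[str]:
        return list(self.records)

    @property
    def length(self) -> int:
        return len(next(iter(self.records.values())))

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SpecimenTable:
    """Specimen -> morphospecies labels (the reference identifications)."""

    labels: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValidationError("specimen table is empty")
        for sid, sp in self.labels.items():
            if not sid or not sp:
                raise ValidationError(f"empty id or label in row {sid!r} -> {sp!r}")

    @property
    def species(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for sid, sp in self.labels.items():
            out.setdefault(sp, []).append(sid)
        return out

    @property
    def singletons(self) -> Set[str]:
        return {sp for sp, ids in self.species.items() if len(ids) == 1}

    def to_partition(self, method: str = "morphospecies") -> "Partition":
        return Partition(
            groups={sp: frozenset(ids) for sp, ids in self.species.items()},
            method=method,
        )


@dataclass
class Partition:
    """A disjoint, covering assignment of specimens to group labels."""

    groups: Dict[str, frozenset]
    method: str = ""

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("partition has no groups")
        seen: Set[str] = set()
        groups: Dict[str, frozenset] = {}
        for gid, members in self.groups.items():
            members = frozenset(members)
            if not members:
                raise ValidationError(f"group {gid!r} is empty")
            overlap = seen & members
            if overlap:
                raise ValidationError(
                    f"groups overlap: {sorted(overlap)} appear more than once"
                )
            seen |= members
            groups[gid] = members
        self.groups = groups

    @property
    def specimens(self) -> frozenset:
        out: Set[str] = set()
        for members in self.groups.values():
            out |= members
        return frozenset(out)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self) -> Dict[str, str]:
        return {sid: gid for gid, members in self.groups.items() for sid in members}

    def as_sets(self) -> Set[frozenset]:
        return set(self.groups.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.as_sets() == other.as_sets()

    def __hash__(self) -> int:  # partitions compare by their blocks
        return hash(frozenset(self.as_sets()))


def canonical_partition(blocks: Iterable[Iterable[str]], method: str = "") -> Partition:
    """Build a Partition with deterministic group ids (lowest member id)."""
    groups = {}
    for block in blocks:
        block = frozenset(block)
        groups[min(block)] = block
    return Partition(groups=groups, method=method)


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths in substitutions/site.

    Thin wrapper over a :class:`dendropy.Tree`; ``rooted`` records whether
    the source Newick had a bifurcating root (trees read from unrooted
    Newick are accepted and flagged so they can be midpoint rooted).
    """

    tree: dendropy.Tree
    rooted: bool = True

    def __post_init__(self) -> None:
        tips = self.tip_names()
        if len(tips) != len(set(tips)):
            raise ValidationError("duplicate tip names in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                raise ValidationError(
                    "missing branch length (tree-based delimitation needs lengths)"
                )
            if not (edge.length >= 0) or edge.length != edge.length:
                raise ValidationError(f"negative or non-finite branch length {edge.length}")

    def tip_names(self) -> List[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def clone(self) -> "PhyloTree":
        return PhyloTree(tree=self.tree.clone(depth=1), rooted=self.rooted)

    def as_newick(self) -> str:
        return (
            self.tree.as_string(schema="newick", suppress_rooting=True).strip()
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_alignment(path) -> Alignment:
    records: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValidationError(f"duplicate specimen id {rec.id!r} in FASTA")
        records[rec.id] = str(rec.seq)
    return Alignment(records=records)


def write_alignment(aln: Alignment, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_specimen_table(path) -> SpecimenTable:
    labels: Dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["specimen_id", "species"]:
            raise ValidationError(
                f"expected header 'specimen_id\\tspecies', got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValidationError(f"line {lineno}: expected 2 columns")
            sid, sp = parts[0], parts[1]
            if sid in labels:
                raise ValidationError(f"duplicate specimen id {sid!r} at line {lineno}")
            labels[sid] = sp
    return SpecimenTable(labels=labels)


def write_specimen_table(table: SpecimenTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("specimen_id\tspecies\n")
        for sid in sorted(table.labels):
            fh.write(f"{sid}\t{table.labels[sid]}\n")


def validate_against_alignment(table: SpecimenTable, aln: Alignment) -> None:
    """Cross-check that labels and alignment cover the same specimens."""
    missing = set(aln.ids) - set(table.labels)
    extra = set(table.labels) - set(aln.ids)
    if missing or extra:
        raise ValidationError(
            f"label/alignment mismatch: unlabeled={sorted(missing)}, "
            f"unsequenced={sorted(extra)}"
        )


def read_partition_table(path, method: Optional[str] = None) -> Partition:
    groups: Dict[str, Set[str]] = {}
    meth = method
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["specimen_id", "group_id"]:
            raise ValidationError(
                f"expected header starting 'specimen_id\\tgroup_id', got {header!r}"
            )
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            sid, gid = parts[0], parts[1]
            if meth is None and len(parts) >= 3:
                meth = parts[2]
            groups.setdefault(gid, set()).add(sid)
    return Partition(
        groups={g: frozenset(m) for g, m in groups.items()}, method=meth or ""
    )


def write_partition_table(p: Partition, path) -> None:
    rows = sorted((sid, gid) for gid, members in p.groups.items() for sid in members)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("specimen_id\tgroup_id\tmethod\n")
        for sid, gid in rows:
            fh.write(f"{sid}\t{gid}\t{p.method}\n")


def read_tree(path) -> PhyloTree:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read())


def parse_newick(newick: str) -> PhyloTree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    nchild = len(tree.seed_node.child_nodes())
    rooted = nchild <= 2
    return PhyloTree(tree=tree, rooted=rooted)


def write_tree(t: PhyloTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(t.as_newick() + "\n")
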