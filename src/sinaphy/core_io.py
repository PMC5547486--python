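"""Core domain types and FASTA/Newick input-output.

The whole pipeline passes three containers around:

* :class:`SequenceRecord` -- one protein sequence with a species name and a
  paralog group label (SINA / SIAH1 / SIAH2 / SIAH3 / unknown).
* :class:`Alignment` -- an ordered list of equal-length records plus a
  ``column_map`` that records, for every current column, its 1-based index in
  the originating (pre-trimming) alignment.  Trimming operations compose this
  map so any trimmed column can be traced back to the raw alignment.
* :class:`PhyloTree` -- a rooted or unrooted tree with branch lengths in
  substitutions/site and optional integer bootstrap supports on internal
  nodes.

All column and residue coordinates exposed by this package are 1-based and
inclusive, matching the residue-numbering style used in the protein-domain
literature (e.g. a core region written "#80-#324").
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("sinaphy")

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
AMBIGUOUS = "X"
#: letters accepted in sequence input; rare one-letter codes are mapped to X
ALPHABET = set(AMINO_ACIDS) | {AMBIGUOUS, GAP}
_RARE_CODES = {"U": AMBIGUOUS, "B": AMBIGUOUS, "Z": AMBIGUOUS, "J": AMBIGUOUS,
               "O": AMBIGUOUS, "*": AMBIGUOUS}

GROUP_LABELS = ("SINA", "SIAH1", "SIAH2", "SIAH3", "unknown")


class AlignmentFormatError(ValueError):
    """Aligned input whose sequences differ in length."""


class DuplicateIdError(ValueError):
    """Two records share an identifier."""


class AlphabetError(ValueError):
    """A residue outside the amino-acid alphabet (after rare-code mapping)."""


@dataclass
class SequenceRecord:
    id: str
    residues: str
    taxon: str = ""
    group_label: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be nonempty")
        if self.group_label not in GROUP_LABELS:
            raise ValueError(f"record {self.id!r}: unknown group label "
                             f"{self.group_label!r}")
        cleaned = []
        for pos, ch in enumerate(self.residues.upper(), start=1):
            if ch in _RARE_CODES:
                logger.warning("record %s: rare residue code %r at position %d "
                               "mapped to 'X'", self.id, ch, pos)
                ch = _RARE_CODES[ch]
            if ch not in ALPHABET:
                raise AlphabetError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}")
            cleaned.append(ch)
        self.residues = "".join(cleaned)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def ungapped_length(self) -> int:
        return len(self.ungapped)


@dataclass
class Alignment:
    """Ordered equal-length records with a map back to pre-trim columns."""

    records: list[SequenceRecord]
    column_map: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentFormatError("alignment must contain at least one record")
        n = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != n:
                raise AlignmentFormatError(
                    f"record {rec.id!r} has length {len(rec.residues)}, expected {n}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError(f"duplicate record ids: {dupes}")
        if self.column_map is None:
            self.column_map = np.arange(1, n + 1, dtype=np.int64)
        else:
            self.column_map = np.asarray(self.column_map, dtype=np.int64)
        if len(self.column_map) != n:
            raise ValueError("column_map length must equal alignment width")
        if n > 1 and not np.all(np.diff(self.column_map) > 0):
            raise ValueError("column_map must be strictly increasing")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def record(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(f"no record with id {rec_id!r}")

    def column(self, j: int) -> str:
        """Characters of 1-based column ``j``, in record order."""
        if not 1 <= j <= self.n_columns:
            raise IndexError(f"column {j} out of range 1..{self.n_columns}")
        return "".join(r.residues[j - 1] for r in self.records)

    def take_columns(self, keep: np.ndarray) -> "Alignment":
        """New alignment restricted to the given 0-based column indices
        (sorted), with ``column_map`` composed through the selection."""
        keep = np.asarray(sorted(set(int(k) for k in keep)), dtype=np.int64)
        if keep.size == 0:
            raise AlignmentFormatError("cannot produce an empty alignment")
        recs = [replace(r, residues="".join(r.residues[k] for k in keep))
                for r in self.records]
        return Alignment(recs, column_map=self.column_map[keep])

    def subset(self, ids: list[str]) -> "Alignment":
        order = {r.id: r for r in self.records}
        missing = [i for i in ids if i not in order]
        if missing:
            raise KeyError(f"records not in alignment: {missing}")
        return Alignment([order[i] for i in ids], column_map=self.column_map.copy())

    def to_matrix(self) -> np.ndarray:
        """(n_records, n_columns) array of single characters."""
        return np.array([list(r.residues) for r in self.records])


# ---------------------------------------------------------------------------
# FASTA

def _parse_fasta_records(handle) -> list[SequenceRecord]:
    out = []
    for rec in SeqIO.parse(handle, "fasta"):
        taxon, group = "", "unknown"
        # optional structured description: "id taxon=... group=..."
        for tok in rec.description.split()[1:]:
            if tok.startswith("taxon="):
                taxon = tok[6:].replace("_", " ")
            elif tok.startswith("group="):
                group = tok[6:]
        out.append(SequenceRecord(id=rec.id, residues=str(rec.seq),
                                  taxon=taxon, group_label=group))
    if not out:
        raise AlignmentFormatError("no FASTA records found")
    return out


def read_fasta(path, aligned: bool = False):
    """Read a FASTA file.

    With ``aligned=True`` returns an :class:`Alignment` (all sequences must
    share a length; the column map is the identity).  Otherwise returns a list
    of gap-free :class:`SequenceRecord`.
    """
    with open(path) as fh:
        records = _parse_fasta_records(fh)
    if aligned:
        return Alignment(records)
    for r in records:
        if GAP in r.residues:
            raise AlphabetError(f"record {r.id!r}: gap character in unaligned input")
    return records


def write_fasta(obj, path) -> None:
    """Write an Alignment or list of SequenceRecord as FASTA.

    Taxon and group metadata are stored in the description so that a
    read/write round-trip is lossless.
    """
    records = obj.records if isinstance(obj, Alignment) else list(obj)
    if not records:
        raise ValueError("refusing to write an empty sequence set")
    bio = []
    for r in records:
        desc = []
        if r.taxon:
            desc.append("taxon=" + r.taxon.replace(" ", "_"))
        if r.group_label != "unknown":
            desc.append("group=" + r.group_label)
        bio.append(_BioSeqRecord(Seq(r.residues), id=r.id, description=" ".join(desc)))
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# Trees

class Node:
    """Tree node.  ``length`` is the branch above the node (None at the root);
    ``support`` is an integer bootstrap percentage on internal nodes."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None,
                 support: int | None = None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "Node":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> frozenset:
        return frozenset(n.name for n in self.leaves())

    def copy(self) -> "Node":
        dup = Node(self.name, self.length, self.support)
        for c in self.children:
            dup.add(c.copy())
        return dup


@dataclass
class PhyloTree:
    """Phylogenetic tree; branch lengths in substitutions/site."""

    root: Node
    rooted: bool = False

    def __post_init__(self) -> None:
        names = [n.name for n in self.root.leaves()]
        if len(set(names)) != len(names):
            raise ValueError("leaf labels must be unique")
        for n in self.root.postorder():
            if n.length is not None:
                if not np.isfinite(n.length):
                    raise ValueError("branch lengths must be finite")
                if n.length < 0:
                    raise ValueError(f"negative branch length {n.length}")

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), rooted=self.rooted)

    def find_leaf(self, name: str) -> Node:
        for n in self.root.leaves():
            if n.name == name:
                return n
        raise KeyError(f"no leaf named {name!r}")

    def mrca(self, names) -> Node:
        target = frozenset(names)
        unknown = target - frozenset(self.leaf_names)
        if unknown:
            raise KeyError(f"unknown taxa: {sorted(unknown)}")
        for node in self.root.postorder():
            if target <= node.leaf_names():
                return node
        raise RuntimeError("unreachable: root contains all leaves")

    def bipartitions(self) -> dict[frozenset, Node]:
        """Map from the leaf-set below each internal (non-root) edge to the
        child node of that edge.  Used for splits/supports."""
        out = {}
        for node in self.root.postorder():
            if node is self.root or node.is_leaf:
                continue
            out[node.leaf_names()] = node
        return out

    def newick(self, include_supports: bool = True,
               support_cutoff: int | None = None) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if include_supports and node.support is not None:
                    if support_cutoff is None or node.support >= support_cutoff:
                        body += str(int(node.support))
            if node.length is not None:
                body += ":" + format(node.length, ".10g")
            return body

        return fmt(self.root) + ";"


def _from_dendropy(dtree: dendropy.Tree) -> Node:
    def build(dnode) -> Node:
        is_leaf = dnode.is_leaf()
        name = dnode.taxon.label if (is_leaf and dnode.taxon is not None) else None
        support = None
        if not is_leaf and dnode.label is not None:
            try:
                support = int(round(float(dnode.label)))
            except ValueError:
                pass
        node = Node(name=name, length=dnode.edge.length, support=support)
        for child in dnode.child_nodes():
            node.add(build(child))
        return node

    return build(dtree.seed_node)


def read_newick(path_or_string, rooted: bool | None = None) -> PhyloTree:
    """Parse Newick (file path or literal string).

    Internal node labels are interpreted as integer bootstrap supports, the
    convention used by common ML tree programs.  A tree whose root has two
    children is treated as rooted unless ``rooted`` says otherwise.
    """
    text = None
    if isinstance(path_or_string, str) and path_or_string.lstrip().startswith("("):
        text = path_or_string
    else:
        with open(path_or_string) as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
    except Exception as exc:
        raise ValueError(f"invalid Newick: {exc}") from exc
    root = _from_dendropy(dtree)
    tree = PhyloTree(root, rooted=False)
    if rooted is None:
        rooted = len(root.children) == 2
    tree.rooted = rooted
    return tree


def write_newick(tree: PhyloTree, path, include_supports: bool = True,
                 support_cutoff: int | None = None) -> None:
    """Write Newick; with ``support_cutoff`` set, supports below the cutoff
    are omitted from the output (display convention; topology unchanged)."""
    with open(path, "w") as fh:
        fh.write(tree.newick(include_supports=include_supports,
                             support_cutoff=support_cutoff) + "\n")
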