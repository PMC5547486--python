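"""Post-inference tree statistics: root-to-tip distances, rate ratios, and
monophyly queries.

The root-to-tip distance is the per-paralog substitution-rate proxy used for
comparing subfamilies: within a rooted tree, take the most recent common
ancestor of a named subtree's members, step to its child on the path toward
a designated focal tip (e.g. the human sequence), and sum branch lengths
from that child down to the tip.  The subtree root's own incoming edge and
the first edge inside the subtree are thereby excluded: the path *starts* at
the node adjacent to the subtree's root.  A focal tip that is itself a child
of the subtree root has distance 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_io import Node, PhyloTree


@dataclass
class SubtreeSpec:
    name: str
    members: list[str]
    focal_tip: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("subtree members must be nonempty")
        if self.focal_tip not in self.members:
            raise ValueError(f"focal tip {self.focal_tip!r} not among members")


def _path_to_tip(ancestor: Node, tip_name: str) -> list[Node]:
    """Nodes from ``ancestor`` (inclusive) down to the named tip."""
    path = []

    def descend(node: Node) -> bool:
        path.append(node)
        if node.is_leaf and node.name == tip_name:
            return True
        for c in node.children:
            if descend(c):
                return True
        path.pop()
        return False

    if not descend(ancestor):
        raise KeyError(f"tip {tip_name!r} not below the given ancestor")
    return path


def root_to_tip_distance(tree: PhyloTree, spec: SubtreeSpec) -> float:
    """Sum of branch lengths from the subtree root's focal-side child down
    to the focal tip (see module docstring for the path convention)."""
    if not tree.rooted:
        raise ValueError("root-to-tip distances require a rooted tree")
    mrca = tree.mrca(spec.members)
    clade = mrca.leaf_names()
    members = frozenset(spec.members)
    if clade != members:
        intruders = sorted(clade - members)
        raise ValueError(f"subtree {spec.name!r} is not monophyletic: "
                         f"clade also contains {intruders}")
    path = _path_to_tip(mrca, spec.focal_tip)
    # path[0] = mrca, path[1] = focal-side child; sum edges below that child
    return float(sum(n.length or 0.0 for n in path[2:]))


def rate_ratio(d_a: float, d_b: float) -> float:
    """Fold difference between two root-to-tip distances."""
    if d_b == 0:
        raise ZeroDivisionError("denominator distance is zero")
    return d_a / d_b


def is_monophyletic(tree: PhyloTree, taxa) -> tuple[bool, int | None]:
    """Whether the taxa form exactly one clade in the rooted tree, plus the
    bootstrap support of the defining edge when present."""
    taxa = frozenset(taxa)
    unknown = taxa - frozenset(tree.leaf_names)
    if unknown:
        raise KeyError(f"unknown taxa: {sorted(unknown)}")
    if len(taxa) == 1 or taxa == frozenset(tree.leaf_names):
        return True, None
    for node in tree.root.postorder():
        if node.leaf_names() == taxa:
            return True, node.support
    return False, None


def metrics_report(tree: PhyloTree, specs: list[SubtreeSpec]) -> pd.DataFrame:
    """Root-to-tip table plus all pairwise rate ratios."""
    rows = []
    dists = {}
    for spec in specs:
        d = root_to_tip_distance(tree, spec)
        dists[spec.name] = d
        mono, support = is_monophyletic(tree, spec.members)
        rows.append({"subtree": spec.name, "focal_tip": spec.focal_tip,
                     "root_to_tip": d, "monophyletic": mono,
                     "support": support})
    df = pd.DataFrame(rows)
    for a in dists:
        for b in dists:
            if a != b and dists[b] > 0:
                df.loc[df["subtree"] == a, f"ratio_vs_{b}"] = rate_ratio(
                    dists[a], dists[b])
    return df
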