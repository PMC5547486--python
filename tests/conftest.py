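"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sinaphy.core_io import AMINO_ACIDS, Alignment, Node, PhyloTree, SequenceRecord
from sinaphy.substitution import AA_INDEX

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# random structures

def random_unrooted_tree(rng: np.random.Generator, n_taxa: int,
                         min_len: float = 0.05, max_len: float = 1.0) -> PhyloTree:
    """Random unrooted binary tree built by sequential edge splitting."""
    root = Node()
    for name in ("t1", "t2", "t3"):
        root.add(Node(name=name, length=float(rng.uniform(min_len, max_len))))
    for k in range(4, n_taxa + 1):
        tree = PhyloTree(root, rooted=False)
        edges = [n for n in root.postorder() if n.parent is not None]
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        half = target.length / 2
        joint = Node(length=half)
        target.detach()
        target.length = half
        joint.add(target)
        joint.add(Node(name=f"t{k}", length=float(rng.uniform(min_len, max_len))))
        parent.add(joint)
    return PhyloTree(root, rooted=False)


def random_rooted_tree(rng: np.random.Generator, n_taxa: int) -> PhyloTree:
    unrooted = random_unrooted_tree(rng, max(n_taxa, 3))
    from sinaphy.phylo import root_at_outgroup
    return root_at_outgroup(unrooted, ["t1"])


def path_length_matrix(tree: PhyloTree) -> dict[tuple[str, str], float]:
    """All-pairs leaf path lengths by independent traversal (oracle)."""
    dists: dict[tuple[str, str], float] = {}

    def walk(node: Node, acc: dict[str, float]):
        if node.is_leaf:
            return {node.name: acc.get("_", 0.0)}
        below: dict[str, float] = {}
        groups = []
        for child in node.children:
            sub = walk(child, {"_": 0.0})
            sub = {k: v + child.length for k, v in sub.items()}
            groups.append(sub)
            below.update(sub)
        for g1, g2 in itertools.combinations(groups, 2):
            for a, da in g1.items():
                for b, db in g2.items():
                    dists[tuple(sorted((a, b)))] = da + db
        return below

    walk(tree.root, {})
    return dists


def random_alignment(rng: np.random.Generator, n_records: int, n_columns: int,
                     gap_prob: float = 0.2, x_prob: float = 0.02) -> Alignment:
    records = []
    for i in range(n_records):
        chars = []
        for _ in range(n_columns):
            u = rng.random()
            if u < gap_prob:
                chars.append("-")
            elif u < gap_prob + x_prob:
                chars.append("X")
            else:
                chars.append(AMINO_ACIDS[rng.integers(20)])
        records.append(SequenceRecord(id=f"r{i}", residues="".join(chars)))
    return Alignment(records)


# ---------------------------------------------------------------------------
# brute-force likelihood oracle (independent of the pruning engine)

def brute_force_loglik(tree: PhyloTree, aln: Alignment, model) -> float:
    """Sum over all internal-node state assignments; usable for <=5 taxa."""
    internals = [n for n in tree.root.postorder() if not n.is_leaf]
    n_int = len(internals)
    idx = {id(n): i for i, n in enumerate(internals)}
    rates = model.category_rates()
    pi = model.frequencies
    assignments = np.array(list(itertools.product(range(20), repeat=n_int)))
    codes = {r.id: [AA_INDEX.get(c, 20) for c in r.residues] for r in aln.records}
    n_sites = aln.n_columns
    site_liks = np.zeros(n_sites)
    for rate in rates:
        P = {}
        for node in tree.root.postorder():
            if node.parent is not None:
                P[id(node)] = model.transition_matrix(node.length * rate)
        for s in range(n_sites):
            probs = pi[assignments[:, idx[id(tree.root)]]].copy()
            for node in tree.root.postorder():
                if node.parent is None:
                    continue
                par_states = assignments[:, idx[id(node.parent)]]
                if node.is_leaf:
                    st = codes[node.name][s]
                    if st == 20:
                        continue  # fully ambiguous leaf: factor sums to 1
                    probs *= P[id(node)][par_states, st]
                else:
                    probs *= P[id(node)][par_states, assignments[:, idx[id(node)]]]
            site_liks[s] += probs.sum() / len(rates)
    return float(np.log(site_liks).sum())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240731)


@pytest.fixture()
def toy_alignment():
    return Alignment([
        SequenceRecord(id="ref", residues="ARNDCQEGHI"),
        SequenceRecord(id="same", residues="ARNDCQEGHI"),
        SequenceRecord(id="diff3gap1", residues="AWNDCQE-YL"),
    ])


@pytest.fixture(scope="session")
def small_family():
    """Default synthetic family (25 sequences, 3 paralog lineages)."""
    from sinaphy.simulate import SimulationConfig, simulate_family
    return simulate_family(SimulationConfig(seed=42))
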