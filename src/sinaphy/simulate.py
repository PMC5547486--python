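"""Synthetic gene-family simulator.

Generates protein families with the statistical structure the analysis
pipeline assumes, so every downstream stage can be exercised against known
truth:

* a species tree with an outgroup, onto which gene duplications are grafted
  (each duplication splits a lineage on a chosen species-tree edge into two
  paralog lineages);
* per-paralog global rate multipliers (the study family's pattern: a
  SIAH3-like paralog evolving an order of magnitude faster than a SIAH1-like
  one, with a SIAH2-like paralog in between);
* a domain architecture (N-terminal region, RING, SZF, SBS, DIMER) with
  per-domain rate multipliers (substrate-binding site most conserved,
  N-terminal region fast);
* amino-acid substitution under a general replacement matrix with discrete
  gamma site-rate heterogeneity;
* an insertion/deletion process restricted to the N-terminal region
  (Poisson events along branches, geometric lengths), reproducing the large
  N-terminal length variance seen in real families.

All randomness flows from a single seed; identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conservation import DomainMap, write_domain_maps
from .core_io import (AMINO_ACIDS, GAP, GROUP_LABELS, Alignment, Node,
                      PhyloTree, SequenceRecord, read_newick, write_fasta,
                      write_newick)
from .substitution import SubstitutionModel

DEFAULT_SPECIES_TREE = ("((((sp1:0.05,sp2:0.05):0.05,(sp3:0.05,sp4:0.05):0.05)"
                        ":0.05,((sp5:0.05,sp6:0.05):0.05,(sp7:0.05,sp8:0.05)"
                        ":0.05):0.05):0.15,out:0.5);")

DEFAULT_INGROUP = ("sp1", "sp2", "sp3", "sp4", "sp5", "sp6", "sp7", "sp8")

#: (clade below the duplication edge, source lineage label, daughter labels)
DEFAULT_DUPLICATIONS = (
    (DEFAULT_INGROUP, "SINA", ("SIAH12", "SIAH3")),
    (DEFAULT_INGROUP, "SIAH12", ("SIAH1", "SIAH2")),
)

DEFAULT_PARALOG_RATES = {"SINA": 1.0, "SIAH12": 1.0,
                         "SIAH1": 1.0, "SIAH2": 2.0, "SIAH3": 10.0}

#: architecture segments in N-to-C order; NTERM is the indel-prone region
DEFAULT_DOMAIN_LENGTHS = (("NTERM", 80), ("RING", 36), ("SZF", 60),
                          ("SBS", 25), ("DIMER", 48))
DEFAULT_DOMAIN_RATES = {"NTERM": 2.0, "RING": 0.5, "SZF": 0.8,
                        "SBS": 0.2, "DIMER": 0.6}


@dataclass
class SimulationConfig:
    species_tree: str = DEFAULT_SPECIES_TREE
    outgroup_taxa: tuple[str, ...] = ("out",)
    root_label: str = "SINA"
    duplications: tuple = DEFAULT_DUPLICATIONS
    paralog_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARALOG_RATES))
    domain_lengths: tuple = DEFAULT_DOMAIN_LENGTHS
    domain_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_RATES))
    matrix_name: str = "LG"
    gamma_shape: float = 0.5852
    n_categories: int = 4
    frequencies: np.ndarray | None = None
    insertion_rate: float = 0.25   # events per unit branch length, N-term only
    deletion_rate: float = 0.25
    mean_indel_length: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        for label, m in self.paralog_rates.items():
            if m <= 0:
                raise ValueError(f"paralog multiplier for {label!r} must be > 0")
        for name, g in self.domain_rates.items():
            if g < 0:
                raise ValueError(f"domain multiplier for {name!r} must be >= 0")
        for name, length in self.domain_lengths:
            if length < 1:
                raise ValueError(f"domain {name!r} must have positive length")
        if self.mean_indel_length < 1:
            raise ValueError("mean indel length must be >= 1")

    @property
    def root_length(self) -> int:
        return sum(length for _, length in self.domain_lengths)

    def model(self) -> SubstitutionModel:
        return SubstitutionModel(self.matrix_name, gamma_shape=self.gamma_shape,
                                 n_categories=self.n_categories,
                                 frequencies=self.frequencies)


@dataclass
class SimulationTruth:
    tree: PhyloTree
    alignment: Alignment
    root_sequence: str
    column_domains: list[str]
    domain_maps: dict[str, DomainMap]
    paralog_rates: dict[str, float]
    domain_rates: dict[str, float]
    config: SimulationConfig


# ---------------------------------------------------------------------------
# gene tree

def _find_clade_edges(species: PhyloTree, duplications):
    """Attach each duplication to the species-tree node whose clade it names."""
    by_node: dict[int, list] = {}
    for clade, source, daughters in duplications:
        target = species.mrca(clade)
        if target.leaf_names() != frozenset(clade):
            raise ValueError(f"duplication clade {sorted(clade)} is not a "
                             "clade of the species tree")
        if target.parent is None:
            raise ValueError("cannot place a duplication above the species root")
        by_node.setdefault(id(target), []).append((source, daughters))
    return by_node


def build_gene_tree(config: SimulationConfig) -> PhyloTree:
    """Graft duplications onto the species tree; each gene-tree edge's
    length is the species-edge segment times the lineage's rate multiplier.
    Successive duplications on one edge are spaced evenly along it."""
    species = read_newick(config.species_tree)
    dups = _find_clade_edges(species, config.duplications)
    rates = config.paralog_rates

    def rate(label: str) -> float:
        if label not in rates:
            raise ValueError(f"no rate multiplier for paralog label {label!r}")
        return rates[label]

    def grow(sp_node: Node, label: str, frac: float) -> Node:
        """Gene lineage traversing the species edge above ``sp_node``
        starting at ``frac`` of the way down; returns the gene subtree."""
        edge_len = sp_node.length or 0.0
        events = dups.get(id(sp_node), [])
        positions = [(i + 1) / (len(events) + 1) for i in range(len(events))]
        for pos, (source, daughters) in zip(positions, events):
            if pos > frac and source == label:
                seg = (pos - frac) * edge_len * rate(label)
                node = Node(length=seg)
                node.add(grow_at(sp_node, daughters[0], pos))
                node.add(grow_at(sp_node, daughters[1], pos))
                return node
        seg = (1.0 - frac) * edge_len * rate(label)
        if sp_node.is_leaf:
            return Node(name=f"{sp_node.name}_{label}", length=seg)
        node = Node(length=seg)
        for child in sp_node.children:
            node.add(grow(child, label, 0.0))
        return node

    def grow_at(sp_node: Node, label: str, frac: float) -> Node:
        return grow(sp_node, label, frac)

    root = Node()
    for child in species.root.children:
        root.add(grow(child, config.root_label, 0.0))
    return PhyloTree(root, rooted=True)


def leaf_paralog(leaf_name: str) -> tuple[str, str]:
    """Split a gene leaf name back into (species, paralog label)."""
    species, _, label = leaf_name.rpartition("_")
    return species, label


# ---------------------------------------------------------------------------
# sequence evolution

class _Evolver:
    """Evolves (column_id, state) sequences down the gene tree with
    substitutions everywhere and indels confined to the N-terminal region."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        self.model = config.model()
        self.rates = self.model.category_rates()
        self.lam, self.right, self.left = self.model.eigensystem()
        self.pi = self.model.frequencies
        self.col_domain: dict[int, str] = {}
        self.col_cat: dict[int, int] = {}
        self.master: list[int] = []      # global column order
        self._next_col = 0

    def _new_column(self, domain: str) -> int:
        cid = self._next_col
        self._next_col += 1
        self.col_domain[cid] = domain
        self.col_cat[cid] = int(self.rng.integers(0, len(self.rates)))
        return cid

    def root_sequence(self) -> list[tuple[int, int]]:
        seq = []
        for name, length in self.cfg.domain_lengths:
            for _ in range(length):
                cid = self._new_column(name)
                self.master.append(cid)
                state = int(self.rng.choice(20, p=self.pi))
                seq.append((cid, state))
        return seq

    def _transition(self, t_eff: float) -> np.ndarray:
        P = (self.right * np.exp(self.lam * t_eff)[None, :]) @ self.left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def substitute(self, seq, t: float):
        """Substitutions over one branch: per site, rate = gamma category
        rate times the domain multiplier."""
        out = []
        # group sites by (domain, category) to share transition matrices
        groups: dict[tuple[str, int], list[int]] = {}
        for idx, (cid, _) in enumerate(seq):
            groups.setdefault((self.col_domain[cid], self.col_cat[cid]),
                              []).append(idx)
        new_states = [s for _, s in seq]
        for (domain, cat), idxs in sorted(groups.items()):
            g = self.cfg.domain_rates.get(domain, 1.0)
            if g == 0 or t == 0:
                continue
            P = self._transition(t * g * self.rates[cat])
            cum = np.cumsum(P, axis=1)
            u = self.rng.random(len(idxs))
            for u_k, idx in zip(u, idxs):
                row = cum[seq[idx][1]]
                new_states[idx] = int(np.searchsorted(row, u_k, side="right"))
        for (cid, _), s in zip(seq, new_states):
            out.append((cid, min(s, 19)))
        return out

    def indels(self, seq, t: float):
        """Poisson insertions/deletions on a branch, N-terminal region only."""
        cfg = self.cfg
        n_ins = int(self.rng.poisson(cfg.insertion_rate * t))
        n_del = int(self.rng.poisson(cfg.deletion_rate * t))
        p_geo = 1.0 / cfg.mean_indel_length
        for _ in range(n_ins):
            nterm_idx = [i for i, (cid, _) in enumerate(seq)
                         if self.col_domain[cid] == "NTERM"]
            if not nterm_idx:
                break
            at = int(self.rng.choice(nterm_idx))
            length = int(self.rng.geometric(p_geo))
            anchor = seq[at][0]
            pos_master = self.master.index(anchor) + 1
            new_sites = []
            for _ in range(length):
                cid = self._new_column("NTERM")
                state = int(self.rng.choice(20, p=self.pi))
                new_sites.append((cid, state))
            self.master[pos_master:pos_master] = [c for c, _ in new_sites]
            seq = seq[:at + 1] + new_sites + seq[at + 1:]
        for _ in range(n_del):
            nterm_idx = [i for i, (cid, _) in enumerate(seq)
                         if self.col_domain[cid] == "NTERM"]
            if len(nterm_idx) <= 1:
                break
            start = int(self.rng.choice(len(nterm_idx)))
            length = int(self.rng.geometric(p_geo))
            doomed = set(nterm_idx[start:start + length])
            seq = [site for i, site in enumerate(seq) if i not in doomed]
        return seq


def simulate_family(config: SimulationConfig) -> SimulationTruth:
    """Simulate a gene family; see the module docstring for the model."""
    rng = np.random.default_rng(config.seed)
    tree = build_gene_tree(config)
    evo = _Evolver(config, rng)
    root_seq = evo.root_sequence()
    leaf_seqs: dict[str, list[tuple[int, int]]] = {}

    def descend(node: Node, seq) -> None:
        if node.length:
            seq = evo.substitute(seq, node.length)
            seq = evo.indels(seq, node.length)
        if node.is_leaf:
            leaf_seqs[node.name] = seq
            return
        for child in node.children:
            descend(child, list(seq))

    descend(tree.root, root_seq)

    master_pos = {cid: i for i, cid in enumerate(evo.master)}
    records = []
    domain_maps = {}
    for leaf in tree.root.leaves():
        seq = leaf_seqs[leaf.name]
        row = [GAP] * len(evo.master)
        for cid, state in seq:
            row[master_pos[cid]] = AMINO_ACIDS[state]
        species, label = leaf_paralog(leaf.name)
        group = label if label in GROUP_LABELS else "unknown"
        records.append(SequenceRecord(id=leaf.name, residues="".join(row),
                                      taxon=species, group_label=group))
        # ungapped domain spans for this sequence (indels stay inside NTERM,
        # so every segment is contiguous)
        spans: dict[str, tuple[int, int]] = {}
        pos = 0
        for cid, _ in seq:
            pos += 1
            dom = evo.col_domain[cid]
            if dom == "NTERM":
                continue
            if dom not in spans:
                spans[dom] = (pos, pos)
            else:
                spans[dom] = (spans[dom][0], pos)
        domain_maps[leaf.name] = DomainMap(reference_id=leaf.name, spans=spans)

    alignment = Alignment(records)
    column_domains = [evo.col_domain[cid] for cid in evo.master]
    root_sequence = "".join(AMINO_ACIDS[s] for _, s in root_seq)
    return SimulationTruth(tree=tree, alignment=alignment,
                           root_sequence=root_sequence,
                           column_domains=column_domains,
                           domain_maps=domain_maps,
                           paralog_rates=dict(config.paralog_rates),
                           domain_rates=dict(config.domain_rates),
                           config=config)


def write_truth(truth: SimulationTruth, outdir) -> dict[str, str]:
    """Write the true alignment, ungapped sequences, gene tree, domain maps,
    and a JSON truth record; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": str(outdir / "true_alignment.fasta"),
        "sequences": str(outdir / "sequences.fasta"),
        "tree": str(outdir / "true_tree.nwk"),
        "domains": str(outdir / "true_domains.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    write_fasta(truth.alignment, paths["alignment"])
    ungapped = [SequenceRecord(id=r.id, residues=r.ungapped, taxon=r.taxon,
                               group_label=r.group_label)
                for r in truth.alignment.records]
    write_fasta(ungapped, paths["sequences"])
    write_newick(truth.tree, paths["tree"])
    write_domain_maps(truth.domain_maps, paths["domains"])
    payload = {
        "seed": truth.config.seed,
        "paralog_rates": truth.paralog_rates,
        "domain_rates": truth.domain_rates,
        "root_sequence": truth.root_sequence,
        "column_domains": truth.column_domains,
        "n_columns": truth.alignment.n_columns,
        "n_records": truth.alignment.n_records,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# fixtures

def make_fixture_suite(size: str, seed: int, outdir) -> dict[str, str]:
    """Emit curated test fixtures.

    ``tiny``  -- 4 taxa x 12 sites, small enough for brute-force likelihood
    checks, plus a hand-countable gappy toy alignment and a 4-taxon additive
    distance matrix.
    ``small`` -- the default 3-paralog x 8-species family at 300 sites.
    ``medium`` -- the same family at 1000 sites.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    if size == "tiny":
        cfg = SimulationConfig(
            species_tree="((A:0.3,B:0.2):0.1,C:0.4,D:0.5);",
            outgroup_taxa=("D",), duplications=(),
            paralog_rates={"SINA": 1.0},
            domain_lengths=(("RING", 12),), domain_rates={"RING": 1.0},
            insertion_rate=0.0, deletion_rate=0.0, seed=seed)
        truth = simulate_family(cfg)
        paths.update(write_truth(truth, outdir / "tiny"))
        toy = Alignment([
            SequenceRecord(id="t1", residues="ACDEF-GHIK"),
            SequenceRecord(id="t2", residues="ACDEF-GH-K"),
            SequenceRecord(id="t3", residues="ACD---GHIK"),
        ])
        write_fasta(toy, outdir / "toy_gappy.fasta")
        paths["toy_gappy"] = str(outdir / "toy_gappy.fasta")
        with open(outdir / "additive_matrix.tsv", "w") as fh:
            fh.write("\tA\tB\tC\tD\n")
            # from tree ((A:1,B:2):1,(C:3,D:4):0);
            D = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
            for name, row in zip("ABCD", D):
                fh.write(name + "\t" + "\t".join(str(x) for x in row) + "\n")
        paths["additive_matrix"] = str(outdir / "additive_matrix.tsv")
    elif size in ("small", "medium"):
        scale = 1 if size == "small" else 3
        lengths = tuple((n, L * scale) for n, L in DEFAULT_DOMAIN_LENGTHS)
        cfg = SimulationConfig(domain_lengths=lengths, seed=seed)
        truth = simulate_family(cfg)
        paths.update(write_truth(truth, outdir / size))
    else:
        raise ValueError("size must be 'tiny', 'small', or 'medium'")
    return paths
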