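"""Maximum-likelihood protein phylogenetics.

The inference stack mirrors the common ML workflow for protein families:

1. pairwise ML distances under a one-parameter JTT model;
2. Neighbor-Joining and BioNJ starting topologies, keeping the one with the
   better likelihood;
3. Felsenstein pruning likelihood under {Dayhoff, JTT, WAG, LG} x (+G) x
   (+/-F), with site-pattern compression, per-node scaling, and gap/X columns
   treated as fully ambiguous;
4. iterative per-branch Brent optimization (with cached "outer" partial
   likelihoods so a branch update costs O(patterns x states), not a full
   tree pass) interleaved with gamma-shape optimization;
5. subtree-pruning-regrafting (SPR) search with a bounded regraft radius
   ("level"), accepting only likelihood-improving moves;
6. nonparametric bootstrap with bipartition supports;
7. AICc-based model selection over the replacement-matrix grid;
8. outgroup rooting of the final unrooted tree.

Likelihood is invariant to root placement for these reversible models, so
trees are handled unrooted (a trifurcating root node) until the final
outgroup rooting step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core_io import AMBIGUOUS, GAP, Alignment, Node, PhyloTree
from .substitution import AA_INDEX, N_STATES, SubstitutionModel

logger = logging.getLogger("sinaphy")

MISSING_STATE = N_STATES  # '-' and 'X' are fully ambiguous
MIN_BRANCH = 1e-8
MAX_BRANCH = 20.0
_LOG_TINY = 1e-300


# ---------------------------------------------------------------------------
# alignment encoding

def encode_alignment(aln: Alignment) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Compress an alignment into site patterns.

    Returns ``(codes, weights)`` where ``codes[record_id]`` is an int array
    of length n_patterns (0..19 for amino acids, 20 for '-'/'X') and
    ``weights`` counts how many columns realize each pattern.
    """
    cached = getattr(aln, "_pattern_cache", None)
    if cached is not None:
        return cached
    mat = np.full((aln.n_records, aln.n_columns), MISSING_STATE, dtype=np.int8)
    for i, rec in enumerate(aln.records):
        for j, ch in enumerate(rec.residues):
            mat[i, j] = AA_INDEX.get(ch, MISSING_STATE)
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    codes = {rec.id: patterns[i] for i, rec in enumerate(aln.records)}
    result = (codes, weights.astype(float))
    aln._pattern_cache = result  # alignments are treated as immutable
    return result


def _tip_partial(code: np.ndarray) -> np.ndarray:
    """(n_patterns, 20) indicator partials; ambiguous rows are all ones."""
    npat = code.shape[0]
    out = np.zeros((npat, N_STATES))
    obs = code < N_STATES
    out[np.arange(npat)[obs], code[obs]] = 1.0
    out[~obs] = 1.0
    return out


# ---------------------------------------------------------------------------
# pruning likelihood engine

class TreeLikelihood:
    """Felsenstein pruning over a (copy of a) tree with cached partials.

    The engine owns a private copy of the topology; optimized branch lengths
    are read back with :meth:`current_tree`.
    """

    def __init__(self, tree: PhyloTree, aln: Alignment, model: SubstitutionModel):
        leaf_set = set(tree.leaf_names)
        if leaf_set != set(aln.ids):
            raise ValueError("tree leaves and alignment records differ: "
                             f"{sorted(leaf_set ^ set(aln.ids))[:6]} ...")
        self.model = model
        self.root = tree.root.copy()
        self.rooted = tree.rooted
        self.codes, self.weights = encode_alignment(aln)
        self.npat = len(self.weights)
        self.n_sites = int(self.weights.sum())
        self.rates = model.category_rates()
        self.ncat = len(self.rates)
        self._lam, self._right, self._left = model.eigensystem()
        self.pi = model.frequencies
        self._down: dict[int, np.ndarray] = {}
        self._down_scale: dict[int, np.ndarray] = {}
        self._tips: dict[int, np.ndarray] = {}
        for leaf in self.root.leaves():
            self._tips[id(leaf)] = _tip_partial(self.codes[leaf.name])
        for node in self.root.postorder():
            if node is not self.root and node.length is None:
                node.length = MIN_BRANCH
        self.full_downpass()

    # -- transition matrices -------------------------------------------------
    def _P(self, t: float) -> np.ndarray:
        expo = np.exp(self._lam[None, :] * (self.rates[:, None] * t))
        P = np.matmul(self._right[None, :, :] * expo[:, None, :], self._left)
        np.clip(P, 0.0, None, out=P)
        return P

    # -- downward (subtree) partials -----------------------------------------
    def _compute_down(self, node: Node) -> None:
        if node.is_leaf:
            tip = self._tips[id(node)]
            self._down[id(node)] = np.broadcast_to(tip, (self.ncat,) + tip.shape)
            self._down_scale[id(node)] = np.zeros((self.ncat, self.npat))
            return
        prod = None
        scale = np.zeros((self.ncat, self.npat))
        for child in node.children:
            P = self._P(child.length)
            term = np.matmul(self._down[id(child)], P.transpose(0, 2, 1))
            prod = term if prod is None else prod * term
            scale += self._down_scale[id(child)]
        m = prod.max(axis=2)
        safe = np.where(m > 0, m, 1.0)
        prod = prod / safe[:, :, None]
        scale += np.log(np.where(m > 0, safe, _LOG_TINY))
        self._down[id(node)] = prod
        self._down_scale[id(node)] = scale

    def full_downpass(self) -> None:
        for node in self.root.postorder():
            self._compute_down(node)

    def log_likelihood(self) -> float:
        L = np.matmul(self._down[id(self.root)], self.pi)
        return self._combine(L, self._down_scale[id(self.root)])

    def _combine(self, L: np.ndarray, scale: np.ndarray) -> float:
        logL = np.log(np.maximum(L, _LOG_TINY)) + scale
        mx = logL.max(axis=0)
        site = mx + np.log(np.exp(logL - mx[None, :]).sum(axis=0) / self.ncat)
        return float(np.dot(self.weights, site))

    # -- per-branch optimization sweep ---------------------------------------
    def optimize_branches(self, optimize_nodes: set[int] | None = None) -> float:
        """One in-place smoothing sweep: visit every branch in preorder,
        Brent-optimize its length against fixed outer/inner partials, and
        refresh partials on the way.  Returns the post-sweep likelihood."""
        touched: dict[int, bool] | None = None
        if optimize_nodes is not None:
            # mark nodes whose subtree holds a target edge, so the sweep can
            # skip whole subtrees that need neither a Brent step nor a W pass
            touched = {}
            for n in self.root.postorder():
                touched[id(n)] = (id(n) in optimize_nodes
                                  or any(touched[id(c)] for c in n.children))
            if not touched[id(self.root)]:
                return self.log_likelihood()
        W0 = np.broadcast_to(self.pi, (self.ncat, self.npat, N_STATES)).copy()
        self._sweep(self.root, W0, np.zeros((self.ncat, self.npat)),
                    optimize_nodes, touched)
        self.full_downpass()
        return self.log_likelihood()

    def _sweep(self, node: Node, W: np.ndarray, w_scale: np.ndarray,
               optimize_nodes: set[int] | None,
               touched: dict[int, bool] | None) -> None:
        children = node.children
        # outer partial contribution of each child, for sibling products
        trans = {}
        for c in children:
            P = self._P(c.length)
            trans[id(c)] = np.matmul(self._down[id(c)], P.transpose(0, 2, 1))
        for c in children:
            if touched is not None and not touched[id(c)]:
                continue
            H = W.copy()
            h_scale = w_scale.copy()
            for b in children:
                if b is c:
                    continue
                H = H * trans[id(b)]
                h_scale = h_scale + self._down_scale[id(b)]
            m = H.max(axis=2)
            safe = np.where(m > 0, m, 1.0)
            H /= safe[:, :, None]
            h_scale = h_scale + np.log(np.where(m > 0, safe, _LOG_TINY))
            if optimize_nodes is None or id(c) in optimize_nodes:
                c.length = self._optimize_edge(H, h_scale, c)
            Pt = self._P(c.length)
            trans[id(c)] = np.matmul(self._down[id(c)], Pt.transpose(0, 2, 1))
            if not c.is_leaf:
                Wc = np.matmul(H, Pt)
                self._sweep(c, Wc, h_scale, optimize_nodes, touched)
                self._compute_down(c)
                trans[id(c)] = np.matmul(self._down[id(c)],
                                         self._P(c.length).transpose(0, 2, 1))

    def _optimize_edge(self, H: np.ndarray, h_scale: np.ndarray,
                       child: Node) -> float:
        # project into the eigenbasis: the edge likelihood is a 20-term
        # exponential sum per (category, pattern), so each Brent evaluation
        # is O(ncat * npat * 20)
        Hh = np.matmul(H, self._right)
        Dh = np.matmul(self._down[id(child)], self._left.T)
        G = Hh * Dh
        base_scale = h_scale + self._down_scale[id(child)]
        lam_c = self._lam[None, :] * self.rates[:, None]

        def negloglik(t: float) -> float:
            L = np.matmul(G, np.exp(lam_c * t)[:, :, None])[:, :, 0]
            return -self._combine(L, base_scale)

        f_old = negloglik(child.length)
        res = minimize_scalar(negloglik, bounds=(MIN_BRANCH, MAX_BRANCH),
                              method="bounded", options={"xatol": 1e-8})
        return float(res.x) if res.fun < f_old else child.length

    def current_tree(self) -> PhyloTree:
        return PhyloTree(self.root.copy(), rooted=self.rooted)


def log_likelihood(tree: PhyloTree, aln: Alignment,
                   model: SubstitutionModel) -> float:
    """Pruning log-likelihood of an alignment on a tree."""
    return TreeLikelihood(tree, aln, model).log_likelihood()


# ---------------------------------------------------------------------------
# fitting

@dataclass
class SearchResult:
    tree: PhyloTree
    log_likelihood: float
    model: SubstitutionModel
    trace: list[float] = field(default_factory=list)


def optimize_branch_lengths(tree: PhyloTree, aln: Alignment,
                            model: SubstitutionModel, max_rounds: int = 20,
                            tol: float = 1e-6) -> SearchResult:
    """Iterate per-branch Brent sweeps until the relative likelihood gain
    falls below ``tol``.  The likelihood never decreases between sweeps."""
    engine = TreeLikelihood(tree, aln, model)
    trace = [engine.log_likelihood()]
    for _ in range(max_rounds):
        lnl = engine.optimize_branches()
        trace.append(lnl)
        if abs(lnl - trace[-2]) < tol * max(1.0, abs(lnl)):
            break
    else:
        logger.warning("branch-length optimization: no convergence after "
                       "%d rounds (last gain %.3g)", max_rounds,
                       trace[-1] - trace[-2])
    return SearchResult(engine.current_tree(), trace[-1], model, trace)


def optimize_shape(tree: PhyloTree, aln: Alignment, model: SubstitutionModel,
                   bounds: tuple[float, float] = (0.02, 20.0)
                   ) -> tuple[SubstitutionModel, float]:
    """Brent-optimize the gamma shape on a fixed tree; returns the updated
    model and its likelihood."""
    def neg(log_shape: float) -> float:
        m = model.with_shape(float(np.exp(log_shape)))
        return -TreeLikelihood(tree, aln, m).log_likelihood()

    res = minimize_scalar(neg, bounds=(np.log(bounds[0]), np.log(bounds[1])),
                          method="bounded", options={"xatol": 1e-4})
    best = model.with_shape(float(np.exp(res.x)))
    return best, -float(res.fun)


def fit_model(tree: PhyloTree, aln: Alignment, model: SubstitutionModel,
              estimate_shape: bool = True, max_outer: int = 8,
              tol: float = 1e-6) -> SearchResult:
    """Alternate branch-length and gamma-shape optimization on a fixed
    topology until the joint likelihood converges."""
    current = optimize_branch_lengths(tree, aln, model, tol=tol)
    trace = list(current.trace)
    if not estimate_shape or model.gamma_shape is None:
        return SearchResult(current.tree, current.log_likelihood, model, trace)
    model_now = model
    for _ in range(max_outer):
        before = trace[-1]
        model_now, lnl = optimize_shape(current.tree, aln, model_now)
        current = optimize_branch_lengths(current.tree, aln, model_now, tol=tol)
        trace.append(current.log_likelihood)
        if abs(trace[-1] - before) < tol * max(1.0, abs(trace[-1])):
            break
    return SearchResult(current.tree, trace[-1], model_now, trace)


# ---------------------------------------------------------------------------
# pairwise distances

def pairwise_ml_distance(seq_a: str, seq_b: str, model: SubstitutionModel,
                         max_distance: float = 10.0) -> float:
    """ML distance (substitutions/site) between two aligned sequences.

    Columns where either sequence is '-' or 'X' are dropped.  The distance
    maximizes the two-sequence likelihood prod pi_a P_ab(t); it is symmetric
    because the model is reversible.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned (equal length)")
    counts = np.zeros((N_STATES, N_STATES))
    for ca, cb in zip(seq_a, seq_b):
        ia, ib = AA_INDEX.get(ca), AA_INDEX.get(cb)
        if ia is not None and ib is not None:
            counts[ia, ib] += 1
    if counts.sum() == 0:
        raise ValueError("no comparable (unambiguous) columns")
    if np.trace(counts) == counts.sum():
        return 0.0
    lam, right, left = model.eigensystem()
    log_pi = np.log(model.frequencies)

    def neg(t: float) -> float:
        P = (right * np.exp(lam * t)[None, :]) @ left
        np.clip(P, _LOG_TINY, None, out=P)
        return -float((counts * (log_pi[:, None] + np.log(P))).sum())

    res = minimize_scalar(neg, bounds=(MIN_BRANCH, max_distance),
                          method="bounded", options={"xatol": 1e-8})
    return float(res.x)


def distance_matrix(aln: Alignment, model: SubstitutionModel | None = None,
                    max_distance: float = 10.0) -> tuple[list[str], np.ndarray]:
    """All-pairs ML distance matrix (default model: JTT without gamma, the
    usual choice for a starting tree)."""
    if model is None:
        model = SubstitutionModel("JTT", gamma_shape=None)
    n = aln.n_records
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_ml_distance(aln.records[i].residues,
                                     aln.records[j].residues, model,
                                     max_distance=max_distance)
            D[i, j] = D[j, i] = d
    return aln.ids, D


# ---------------------------------------------------------------------------
# distance-based starting trees

def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if D.shape[0] < 3:
        raise ValueError("need at least three taxa")
    return D


def _agglomerate(D: np.ndarray, labels: list[str], bionj_update: bool) -> Node:
    """Shared NJ/BioNJ agglomeration; BioNJ adds variance-weighted updates."""
    D = D.copy()
    V = D.copy()  # BioNJ variance estimates
    nodes = [Node(name=lbl) for lbl in labels]
    active = list(range(len(labels)))
    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        bi = 0.5 * dij + (r[ai] - r[aj]) / (2 * (n - 2))
        bj = dij - bi
        parent = Node()
        nodes[i].length = max(bi, 0.0)
        nodes[j].length = max(bj, 0.0)
        parent.add(nodes[i])
        parent.add(nodes[j])
        if bionj_update and V[i, j] > 0:
            others = [k for k in active if k not in (i, j)]
            lam = 0.5 + (sum(V[j, k] - V[i, k] for k in others)
                         / (2 * (n - 2) * V[i, j]))
            lam = min(max(lam, 0.0), 1.0)
        else:
            lam = 0.5
        new = len(nodes)
        nodes.append(parent)
        D = np.pad(D, ((0, 1), (0, 1)))
        V = np.pad(V, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            duk = lam * (D[i, k] - bi) + (1 - lam) * (D[j, k] - bj)
            D[new, k] = D[k, new] = duk
            V[new, k] = V[k, new] = (lam * V[i, k] + (1 - lam) * V[j, k]
                                     - lam * (1 - lam) * V[i, j])
        active = [k for k in active if k not in (i, j)] + [new]
    # resolve the final three branches with the three-point formulas
    a, b, c = active
    root = Node()
    nodes[a].length = max(0.5 * (D[a, b] + D[a, c] - D[b, c]), 0.0)
    nodes[b].length = max(0.5 * (D[a, b] + D[b, c] - D[a, c]), 0.0)
    nodes[c].length = max(0.5 * (D[a, c] + D[b, c] - D[a, b]), 0.0)
    for k in (a, b, c):
        root.add(nodes[k])
    return root


def neighbor_joining(D: np.ndarray, labels: list[str]) -> PhyloTree:
    """Classic Neighbor-Joining; exact on additive matrices."""
    D = _check_distance_matrix(D)
    return PhyloTree(_agglomerate(D, labels, bionj_update=False), rooted=False)


def bionj(D: np.ndarray, labels: list[str]) -> PhyloTree:
    """BioNJ: Neighbor-Joining with variance-weighted distance updates."""
    D = _check_distance_matrix(D)
    return PhyloTree(_agglomerate(D, labels, bionj_update=True), rooted=False)


# ---------------------------------------------------------------------------
# tree manipulation helpers

def unroot(tree: PhyloTree) -> PhyloTree:
    """Collapse a two-child root into a trifurcation (no-op otherwise)."""
    root = tree.root.copy()
    if len(root.children) == 2:
        a, b = root.children
        inner = b if not b.is_leaf else (a if not a.is_leaf else None)
        if inner is not None:
            other = a if inner is b else b
            new_root = Node()
            for c in list(inner.children):
                new_root.add(c)
            other.length = (other.length or 0.0) + (inner.length or 0.0)
            if other.support is None:
                other.support = inner.support
            new_root.add(other)
            root = new_root
    return PhyloTree(root, rooted=False)


def tree_splits(tree: PhyloTree, min_length: float = 0.0) -> set[frozenset]:
    """Unrooted bipartitions, each normalized to the side *not* containing
    the lexicographically smallest leaf.  ``min_length`` treats shorter
    internal edges as unresolved (used by the bootstrap, where a zero-length
    edge carries no signal for its bipartition)."""
    all_leaves = frozenset(tree.leaf_names)
    anchor = min(all_leaves)
    splits = set()
    for node in tree.root.postorder():
        if node is tree.root or node.is_leaf:
            continue
        if min_length > 0 and (node.length or 0.0) < min_length:
            continue
        side = node.leaf_names()
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(side)
    return splits


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference (RF) distance between unrooted topologies."""
    return len(tree_splits(unroot(t1)) ^ tree_splits(unroot(t2)))


def root_at_outgroup(tree: PhyloTree, outgroup_taxa) -> PhyloTree:
    """Root on the edge separating the outgroup from the ingroup.

    If the outgroup is not separable (non-monophyletic in the unrooted
    sense), the root goes on the edge maximizing outgroup-side purity, with
    a warning.  The unrooted topology is unchanged.
    """
    out = frozenset(outgroup_taxa)
    work = unroot(tree)
    all_leaves = frozenset(work.leaf_names)
    unknown = out - all_leaves
    if unknown:
        raise KeyError(f"outgroup taxa not in tree: {sorted(unknown)}")
    if out == all_leaves:
        raise ValueError("outgroup cannot contain every leaf")
    best, best_score = None, -1
    for node in work.root.postorder():
        if node is work.root:
            continue
        below = node.leaf_names()
        for side in (below, all_leaves - below):
            score = len(out & side) + len((all_leaves - out) - side)
            if score > best_score:
                best, best_score = node, score
        if below == out or below == all_leaves - out:
            best, best_score = node, len(all_leaves) + 1
            break
    if best_score <= len(all_leaves):
        logger.warning("outgroup %s is not separable; rooting at the edge "
                       "with maximal outgroup purity", sorted(out))
    return _root_on_edge(work, best)


def _root_on_edge(tree: PhyloTree, child: Node, fraction: float = 0.5) -> PhyloTree:
    """Place the root on the edge above ``child``, splitting its length."""
    work = tree.root.copy()
    # re-locate child in the copy by preorder index
    index = next(i for i, n in enumerate(tree.root.preorder()) if n is child)
    child = list(work.preorder())[index]
    length = child.length or 0.0
    split_support = child.support
    path = []
    cur = child.parent
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    child.detach()
    new_root = Node()
    child.length = length * fraction
    new_root.add(child)
    prev, carry_len, carry_sup = new_root, length * (1 - fraction), split_support
    for node in path:
        if node.parent is not None:
            node.detach()
        next_len, next_sup = node.length, node.support
        node.length, node.support = carry_len, carry_sup
        prev.add(node)
        prev, carry_len, carry_sup = node, next_len, next_sup
    # suppress a degree-2 node left where the old root sat
    old_root = prev
    if len(old_root.children) == 1 and old_root.parent is not None:
        only = old_root.children[0]
        only.length = (only.length or 0.0) + (old_root.length or 0.0)
        parent = old_root.parent
        old_root.detach()
        only.parent = None
        parent.add(only)
    return PhyloTree(new_root, rooted=True)


# ---------------------------------------------------------------------------
# SPR search

def _spr_candidates(tree: PhyloTree, level: int):
    """Yield (tree_copy, regraft_node_preorder_index) for every SPR move
    whose regraft edge lies within ``level`` edges of the pruning point."""
    base = tree.root
    preorder = list(base.preorder())
    n_nodes = len(preorder)
    for prune_idx in range(1, n_nodes):  # skip the root
        work = base.copy()
        nodes = list(work.preorder())
        v = nodes[prune_idx]
        u = v.parent
        if u is None:
            continue
        v.detach()
        # suppress u if it became degree-2 (internal) or trivial (root)
        seam_nodes = []
        if u.parent is None:
            if len(u.children) == 1 and not u.children[0].is_leaf:
                # root with a single child: descend the root
                only = u.children[0]
                only.detach()
                only.length = None
                work = only
                seam_nodes = list(only.children)
            else:
                seam_nodes = list(u.children)
                work = u
        else:
            if len(u.children) == 1:
                only = u.children[0]
                only.length = (only.length or 0.0) + (u.length or 0.0)
                parent = u.parent
                u.detach()
                only.parent = None
                parent.add(only)
                seam_nodes = [only, parent]
            else:
                seam_nodes = [u]
        remaining = PhyloTree(work, rooted=False)
        # BFS node distances from the seam
        dist = {}
        frontier = [(s, 0) for s in seam_nodes]
        while frontier:
            node, d = frontier.pop(0)
            if id(node) in dist and dist[id(node)] <= d:
                continue
            dist[id(node)] = d
            neigh = list(node.children)
            if node.parent is not None:
                neigh.append(node.parent)
            for nb in neigh:
                if id(nb) not in dist:
                    frontier.append((nb, d + 1))
        rem_pre = list(remaining.root.preorder())
        for ridx, target in enumerate(rem_pre):
            if target.parent is None:
                continue
            d_edge = min(dist.get(id(target), np.inf),
                         dist.get(id(target.parent), np.inf))
            if d_edge >= level:
                continue
            if target in seam_nodes and len(seam_nodes) <= 2 and d_edge == 0 \
                    and target.parent in seam_nodes:
                continue  # regrafting on the seam edge restores the original
            cand_root = remaining.root.copy()
            cand_nodes = list(cand_root.preorder())
            tgt = cand_nodes[ridx]
            parent = tgt.parent
            half = (tgt.length or 0.0) / 2.0
            joint = Node(length=half)
            tgt.detach()
            tgt.length = half
            joint.add(tgt)
            graft = v.copy()
            if graft.length is None:
                graft.length = MIN_BRANCH
            joint.add(graft)
            parent.add(joint)
            cand = PhyloTree(cand_root, rooted=False)
            yield cand, joint


def spr_search(start_tree: PhyloTree, aln: Alignment, model: SubstitutionModel,
               level: int = 5, max_iterations: int = 50,
               tol: float = 1e-4) -> SearchResult:
    """Greedy SPR hill-climb.

    Each candidate move (regraft within ``level`` edges of the prune point)
    is scored after Brent-optimizing only the branches at the new junction;
    the first improving move is accepted, branch lengths are re-optimized
    globally, and the scan restarts.  The search stops when a full scan
    finds no improving move; the accepted-move likelihood sequence is
    strictly increasing.
    """
    current = optimize_branch_lengths(unroot(start_tree), aln, model,
                                      max_rounds=10, tol=1e-5)
    trace = [current.log_likelihood]
    for _ in range(max_iterations):
        accepted = None
        current_splits = tree_splits(current.tree)
        for cand, joint in _spr_candidates(current.tree, level):
            if tree_splits(cand) == current_splits:
                continue  # regraft reproduces the current topology
            engine = TreeLikelihood(cand, aln, model)
            local = {id(n) for n in list(joint.children) + [joint]}
            # map ids into the engine's private copy via preorder positions
            cand_pre = list(cand.root.preorder())
            eng_pre = list(engine.root.preorder())
            local_idx = {id(eng_pre[i]) for i, n in enumerate(cand_pre)
                         if id(n) in local}
            lnl = engine.optimize_branches(optimize_nodes=local_idx)
            if lnl > trace[-1] + tol:
                accepted = engine.current_tree()
                break
        if accepted is None:
            break
        current = optimize_branch_lengths(accepted, aln, model,
                                          max_rounds=4, tol=1e-5)
        trace.append(current.log_likelihood)
    return SearchResult(current.tree, trace[-1], model, trace)


# ---------------------------------------------------------------------------
# full inference and bootstrap

def infer_ml_tree(aln: Alignment, model: SubstitutionModel,
                  spr_level: int = 5, estimate_shape: bool = False,
                  do_spr: bool = True) -> SearchResult:
    """NJ/BioNJ starting trees from JTT distances, keep the better one,
    optimize, then SPR-refine."""
    labels, D = distance_matrix(aln)
    starts = [neighbor_joining(D, labels), bionj(D, labels)]
    scored = [(log_likelihood(t, aln, model), t) for t in starts]
    scored.sort(key=lambda x: -x[0])
    best = fit_model(scored[0][1], aln, model, estimate_shape=estimate_shape)
    if do_spr:
        refined = spr_search(best.tree, aln, best.model, level=spr_level)
        if estimate_shape:
            final = fit_model(refined.tree, aln, best.model,
                              estimate_shape=True)
        else:
            final = refined
        trace = best.trace + refined.trace + final.trace
        return SearchResult(final.tree, final.log_likelihood, final.model, trace)
    return best


def bootstrap(aln: Alignment, model: SubstitutionModel,
              n_replicates: int = 100, seed: int | None = None,
              search: str = "nj", spr_level: int = 1,
              main_tree: PhyloTree | None = None) -> PhyloTree:
    """Nonparametric bootstrap: resample columns with replacement, infer a
    tree per replicate, and annotate each internal edge of the main tree
    with the percentage of replicates containing its bipartition.

    ``search`` chooses the per-replicate effort: ``"nj"`` (distance tree
    only), ``"spr"`` (NJ start + SPR at ``spr_level``), or ``"full"``
    (NJ/BioNJ + SPR, mirroring the main search).
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    if main_tree is None:
        main_tree = infer_ml_tree(aln, model, spr_level=spr_level,
                                  do_spr=(search != "nj")).tree
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, aln.n_columns, size=aln.n_columns)
        recs = [type(r)(id=r.id, taxon=r.taxon, group_label=r.group_label,
                        residues="".join(r.residues[c] for c in cols))
                for r in aln.records]
        rep = Alignment(recs)
        labels, D = distance_matrix(rep)
        rep_tree = neighbor_joining(D, labels)
        if search in ("spr", "full"):
            rep_tree = spr_search(rep_tree, rep, model, level=spr_level).tree
        for split in tree_splits(rep_tree, min_length=1e-7):
            counts[split] = counts.get(split, 0) + 1
    annotated = unroot(main_tree)
    all_leaves = frozenset(annotated.leaf_names)
    anchor = min(all_leaves)
    for node in annotated.root.postorder():
        if node is annotated.root or node.is_leaf:
            continue
        if (node.length or 0.0) < 1e-7:
            continue  # unresolved: support stays absent
        side = node.leaf_names()
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            node.support = int(round(100.0 * counts.get(side, 0) / n_replicates))
    return annotated


# ---------------------------------------------------------------------------
# model selection

@dataclass
class ModelSelectionRecord:
    model_name: str
    k: int
    lnL: float
    aicc: float
    gamma_shape: float | None
    computable: bool = True


def aicc(k: int, lnl: float, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        return np.inf
    return 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)


def select_model(aln: Alignment, tree: PhyloTree,
                 matrices=("Dayhoff", "JTT", "WAG", "LG"),
                 plus_f_options=(False, True), n_categories: int = 4,
                 estimate_shape: bool = True) -> tuple[pd.DataFrame, list[ModelSelectionRecord]]:
    """Fit every candidate on the fixed topology and rank by AICc.

    The sample size is the number of alignment columns; the parameter count
    is branch lengths + gamma shape (+19 free frequencies under +F).
    """
    candidates = [(m, f) for m in matrices for f in plus_f_options]
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    n = aln.n_columns
    n_branches = sum(1 for node in unroot(tree).root.postorder()
                     if node.parent is not None)
    records = []
    for matrix, plus_f in candidates:
        model = SubstitutionModel(matrix, gamma_shape=1.0,
                                  n_categories=n_categories)
        if plus_f:
            model = model.with_empirical_frequencies(aln)
        fit = fit_model(tree, aln, model, estimate_shape=estimate_shape)
        k = fit.model.n_free_parameters(n_branches)
        score = aicc(k, fit.log_likelihood, n)
        records.append(ModelSelectionRecord(
            model_name=fit.model.name, k=k, lnL=fit.log_likelihood,
            aicc=score, gamma_shape=fit.model.gamma_shape,
            computable=np.isfinite(score)))
    records.sort(key=lambda r: r.aicc)
    df = pd.DataFrame([{"model": r.model_name, "k": r.k, "lnL": r.lnL,
                        "AICc": r.aicc, "gamma_shape": r.gamma_shape,
                        "computable": r.computable, "rank": i + 1}
                       for i, r in enumerate(records)])
    return df, records
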