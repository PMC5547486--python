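"""Amino-acid substitution models with discrete-gamma rate heterogeneity.

The four general replacement matrices used in model selection (Dayhoff, JTT,
WAG, LG) ship as plain-text data assets holding the published lower-triangle
exchangeabilities and equilibrium frequencies, in the conventional
ARNDCQEGHILKMFPSTWYV state order.  A model is the combination of

* a symmetric exchangeability table ``S``,
* equilibrium frequencies ``pi`` (the matrix authors' values, or empirical
  "+F" frequencies counted from the analyzed alignment),
* a gamma shape ``alpha`` discretized into ``k`` equal-probability categories
  whose rates are the category means (mean rate exactly 1).

The instantaneous rate matrix is Q[i,j] = S[i,j] * pi[j] (i != j), with the
diagonal set so rows sum to zero, rescaled so the expected number of
substitutions per site per unit time is one: -sum_i pi_i Q_ii = 1.
Transition matrices P(t) come from the symmetric eigendecomposition of
D^1/2 Q D^-1/2 (D = diag(pi)), which is exact for reversible models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .core_io import AMINO_ACIDS, Alignment

N_STATES = 20
MATRIX_NAMES = ("Dayhoff", "JTT", "WAG", "LG")
#: index of each amino acid in the canonical state order
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _load_matrix_file(name: str) -> tuple[np.ndarray, np.ndarray]:
    text = (resources.files("sinaphy.data") / f"{name.lower()}.dat").read_text()
    rows = [line.split() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]
    S = np.zeros((N_STATES, N_STATES))
    for i in range(1, N_STATES):
        vals = [float(x) for x in rows[i - 1]]
        if len(vals) != i:
            raise ValueError(f"malformed matrix file for {name}: row {i}")
        S[i, :i] = vals
        S[:i, i] = vals
    freqs = np.array([float(x) for x in rows[N_STATES - 1]])
    if len(freqs) != N_STATES:
        raise ValueError(f"malformed frequency row for {name}")
    return S, freqs / freqs.sum()


_MATRIX_CACHE: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def load_exchangeabilities(matrix_name: str) -> tuple[np.ndarray, np.ndarray]:
    """Published exchangeabilities and frequencies for a named matrix."""
    key = matrix_name.strip()
    canonical = {m.lower(): m for m in MATRIX_NAMES}.get(key.lower())
    if canonical is None:
        raise KeyError(f"unknown replacement matrix {matrix_name!r}; "
                       f"choose from {MATRIX_NAMES}")
    if canonical not in _MATRIX_CACHE:
        _MATRIX_CACHE[canonical] = _load_matrix_file(canonical)
    S, freqs = _MATRIX_CACHE[canonical]
    return S.copy(), freqs.copy()


def empirical_frequencies(aln: Alignment, pseudocount: float = 0.0) -> np.ndarray:
    """"+F" frequencies counted from an alignment; gaps and X excluded."""
    counts = np.full(N_STATES, pseudocount, dtype=float)
    for rec in aln.records:
        for ch in rec.residues:
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("alignment contains no unambiguous residues")
    return counts / total


def discretize_gamma(shape: float, k: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Equal-probability discrete gamma with category-mean rates.

    Returns ``(rates, probs)`` with ``probs`` all 1/k and the rates the exact
    conditional means of a Gamma(shape, mean 1) within each probability
    quantile, so that sum(p_i * r_i) == 1.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if k < 1:
        raise ValueError("need at least one rate category")
    if k == 1:
        return np.array([1.0]), np.array([1.0])
    # quantile boundaries of Gamma(alpha, rate alpha) (mean 1)
    qs = np.arange(1, k) / k
    bounds = gamma_dist.ppf(qs, a=shape, scale=1.0 / shape)
    edges = np.concatenate(([0.0], bounds, [np.inf]))
    # E[X | a < X <= b] * P(a < X <= b) = gammainc(alpha+1, b*alpha) - gammainc(alpha+1, a*alpha)
    upper = np.where(np.isinf(edges[1:]), 1.0, gammainc(shape + 1, edges[1:] * shape))
    lower = gammainc(shape + 1, edges[:-1] * shape)
    rates = k * (upper - lower)
    rates = rates / (rates.mean())  # guard against last-digit drift
    probs = np.full(k, 1.0 / k)
    return rates, probs


@dataclass
class SubstitutionModel:
    """A replacement matrix + frequencies + discrete-gamma configuration."""

    matrix_name: str = "LG"
    plus_F: bool = False
    gamma_shape: float | None = 1.0
    n_categories: int = 4
    frequencies: np.ndarray | None = None
    exchangeabilities: np.ndarray = field(init=False, repr=False)
    _eigen: tuple | None = field(default=None, init=False, repr=False)

    def __post_init__(self) -> None:
        S, model_freqs = load_exchangeabilities(self.matrix_name)
        self.exchangeabilities = S
        if self.frequencies is None:
            self.frequencies = model_freqs
        else:
            self.frequencies = np.asarray(self.frequencies, dtype=float)
            self.frequencies = self.frequencies / self.frequencies.sum()
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    # -- construction helpers ------------------------------------------------
    def with_empirical_frequencies(self, aln: Alignment) -> "SubstitutionModel":
        return SubstitutionModel(self.matrix_name, plus_F=True,
                                 gamma_shape=self.gamma_shape,
                                 n_categories=self.n_categories,
                                 frequencies=empirical_frequencies(aln))

    def with_shape(self, shape: float) -> "SubstitutionModel":
        return SubstitutionModel(self.matrix_name, plus_F=self.plus_F,
                                 gamma_shape=shape,
                                 n_categories=self.n_categories,
                                 frequencies=self.frequencies.copy())

    @property
    def name(self) -> str:
        parts = [self.matrix_name]
        if self.gamma_shape is not None:
            parts.append("G" if self.n_categories > 1 else "G1")
        if self.plus_F:
            parts.append("F")
        return "+".join(parts)

    # -- rate matrix ---------------------------------------------------------
    def rate_matrix(self) -> np.ndarray:
        """Reversible Q scaled to one expected substitution per site per unit
        branch length at rate 1."""
        pi = self.frequencies
        Q = self.exchangeabilities * pi[np.newaxis, :]
        np.fill_diagonal(Q, 0.0)
        Q[np.diag_indices(N_STATES)] = -Q.sum(axis=1)
        scale = -np.dot(pi, np.diag(Q))
        return Q / scale

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eigenvalues, right-transform, left-transform) with
        P(t) = right @ diag(exp(lam t)) @ left."""
        if self._eigen is None:
            pi = self.frequencies
            Q = self.rate_matrix()
            d = np.sqrt(pi)
            B = (Q * d[:, None]) / d[None, :]
            B = (B + B.T) / 2.0
            lam, V = np.linalg.eigh(B)
            right = V / d[:, None]
            left = V.T * d[None, :]
            self._eigen = (lam, right, left)
        return self._eigen

    def transition_matrix(self, t: float) -> np.ndarray:
        lam, right, left = self.eigensystem()
        P = (right * np.exp(lam * t)[None, :]) @ left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition_matrices(self, t: float,
                            rates: np.ndarray | None = None) -> np.ndarray:
        """(n_cat, 20, 20) stack of P(rate_c * t)."""
        if rates is None:
            rates = self.category_rates()
        lam, right, left = self.eigensystem()
        expo = np.exp(lam[None, :] * (np.asarray(rates)[:, None] * t))
        P = np.einsum("il,cl,lj->cij", right, expo, left)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.array([1.0])
        rates, _ = discretize_gamma(self.gamma_shape, self.n_categories)
        return rates

    def n_free_parameters(self, n_branches: int) -> int:
        """Free parameters for information criteria: branch lengths, gamma
        shape, and 19 frequencies when they were estimated from the data."""
        k = n_branches
        if self.gamma_shape is not None:
            k += 1
        if self.plus_F:
            k += N_STATES - 1
        return k
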