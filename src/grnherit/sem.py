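"""Linear structural-equation model of expression on a signed GRN.

Each gene's expression is the sum of an aggregate cis-genetic input
(normalized to unit variance), the expression of its regulators scaled
by a signed effect of common magnitude ``gamma``, and independent
non-genetic noise. Writing ``G`` for the weighted adjacency matrix
(``G[j, i]`` = direct effect of gene j on gene i), the total-effect
matrix is

    L = (I - G)^{-1} = sum_t G^t        (finite: G is nilpotent on a DAG)

so ``L[j, i]`` is the signed sum over all directed paths j -> i of the
product of edge weights. Because every gene's cis input has unit
variance, gene i's genetic variance is ``(L^T L)_ii`` and its cis
fraction is ``L_ii^2 / (L^T L)_ii = 1 / (L^T L)_ii``. Per-regulator
trans contributions are the squared off-diagonal entries of ``L``
normalized the same way, and grouping them by unweighted shortest-path
distance gives the distance-resolved decomposition.

Fraction-of-genetic-variance quantities are noise-free; the noise
variance only rescales total heritability as ``h^2 = 1/(1 + sigma2)``,
identically for all genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import shortest_path

from .dag import GRNTopology

__all__ = [
    "SignedGRN",
    "TotalEffects",
    "VarianceDecomposition",
    "DistanceDecomposition",
    "IndividualSample",
    "assign_signs",
    "total_effects",
    "variance_decomposition",
    "distance_decomposition",
    "simulate_individuals",
    "heritability_scaling",
]


@dataclass
class SignedGRN:
    """A topology plus per-gene regulator signs and a common effect size.

    Each gene acts consistently as an activator (+1) or repressor (-1)
    on all of its targets; the weight of edge j -> i is
    ``sign[j] * gamma``.
    """

    topology: GRNTopology
    signs: np.ndarray
    gamma: float

    def __post_init__(self) -> None:
        self.signs = np.asarray(self.signs, dtype=np.int64)
        if self.signs.shape != (self.topology.n,):
            raise ValueError("one sign per gene required")
        if not np.all(np.isin(self.signs, (-1, 1))):
            raise ValueError("signs must be +1 or -1")

    def weighted_adjacency(self) -> sparse.csr_matrix:
        """G[src, dst] = sign(src) * gamma on edges, 0 elsewhere."""
        topo = self.topology
        if topo.n_edges == 0:
            return sparse.csr_matrix((topo.n, topo.n), dtype=np.float64)
        src, dst = topo.edges[:, 0], topo.edges[:, 1]
        data = self.signs[src].astype(np.float64) * self.gamma
        return sparse.csr_matrix((data, (src, dst)), shape=(topo.n, topo.n))


def assign_signs(
    topology: GRNTopology, p_plus: float, gamma: float, seed: int
) -> SignedGRN:
    """Independently assign each gene +1 with probability ``p_plus``, else -1."""
    if not 0.0 <= p_plus <= 1.0:
        raise ValueError("p_plus must be in [0, 1]")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    rng = np.random.default_rng(seed)
    signs = np.where(rng.random(topology.n) < p_plus, 1, -1)
    return SignedGRN(topology=topology, signs=signs, gamma=gamma)


@dataclass
class TotalEffects:
    """Total-effect matrix L (dense, gene-id indexed): L[j, i] is the
    effect of gene j's unit cis input on gene i."""

    L: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.L.shape[0]


def total_effects(grn: SignedGRN) -> TotalEffects:
    """Accumulate L = (I - G)^{-1} by triangular substitution in
    topological order (no dense matrix inversion).

    Column i of L is ``e_i + sum_{j in parents(i)} w_ji * column j``;
    processing genes in topological order makes each column available
    before it is needed.
    """
    topo = grn.topology
    n = topo.n
    order = topo.topo_order
    pos = topo.topo_index
    # parent lists in position space
    par: list[list[int]] = [[] for _ in range(n)]
    if topo.n_edges:
        src_pos = pos[topo.edges[:, 0]]
        dst_pos = pos[topo.edges[:, 1]]
        for s, t in zip(src_pos.tolist(), dst_pos.tolist()):
            par[t].append(s)
    w_of = grn.signs[order].astype(np.float64) * grn.gamma  # weight by source position

    Lp = np.zeros((n, n))  # position space
    for j in range(n):
        pj = par[j]
        if pj:
            idx = np.asarray(pj, dtype=np.int64)
            Lp[:, j] = Lp[:, idx] @ w_of[idx]
        Lp[j, j] = 1.0
    # back to gene-id space
    L = np.empty_like(Lp)
    L[np.ix_(order, order)] = Lp
    return TotalEffects(L=L)


@dataclass
class VarianceDecomposition:
    """Per-gene decomposition of genetic variance under unit cis inputs.

    ``genetic_variance[i]`` is ``(L^T L)_ii``; ``cis_fraction`` is its
    reciprocal (the cis term is exactly 1); ``lead_trans_fraction`` is
    the largest single-regulator variance contribution
    ``max_{j != i} L_ji^2 / (L^T L)_ii``; ``lead_ratio`` is the
    amplitude version ``max_{j != i} |L_ji| / |L_ii|``, the model's
    proxy for the lead trans/cis eQTL effect-size ratio (its square,
    ``lead_ratio_sq``, is the variance-contribution ratio).
    """

    genetic_variance: np.ndarray
    cis_fraction: np.ndarray
    lead_trans_fraction: np.ndarray
    lead_ratio: np.ndarray
    effects: TotalEffects = field(repr=False)

    @property
    def lead_ratio_sq(self) -> np.ndarray:
        return self.lead_ratio**2

    def trans_contributions(self, gene: int) -> np.ndarray:
        """B_ji^2 for all regulators j of ``gene`` (own entry set to 0)."""
        L = self.effects.L
        b2 = L[:, gene] ** 2 / self.genetic_variance[gene]
        b2[gene] = 0.0
        return b2

    def to_frame(self, n_ancestors: Optional[np.ndarray] = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene": np.arange(self.cis_fraction.size),
                "cis_fraction": self.cis_fraction,
                "lead_trans_fraction": self.lead_trans_fraction,
                "lead_ratio": self.lead_ratio,
            }
        )
        if n_ancestors is not None:
            df["n_ancestors"] = n_ancestors
        return df


def variance_decomposition(effects: TotalEffects) -> VarianceDecomposition:
    L = effects.L
    vg = np.einsum("ji,ji->i", L, L)  # column squared norms = (L^T L)_ii
    off = L**2
    np.fill_diagonal(off, 0.0)
    lead2 = off.max(axis=0)
    return VarianceDecomposition(
        genetic_variance=vg,
        cis_fraction=1.0 / vg,
        lead_trans_fraction=lead2 / vg,
        lead_ratio=np.sqrt(lead2),
        effects=effects,
    )


@dataclass
class DistanceDecomposition:
    """Fraction of genetic variance from regulators at each graph distance.

    ``fractions[i, d]`` is gene i's fraction of genetic variance due to
    regulators at unweighted shortest-path distance ``d`` (d = 0 is the
    cis term). Rows sum to 1.
    """

    fractions: np.ndarray  # (n, max_distance + 1)

    @property
    def max_distance(self) -> int:
        return self.fractions.shape[1] - 1

    def cumulative(self, max_distance: int) -> np.ndarray:
        """Per-gene cumulative fraction within ``max_distance`` hops."""
        d = min(max_distance, self.max_distance)
        return self.fractions[:, : d + 1].sum(axis=1)

    def to_long_frame(self) -> pd.DataFrame:
        n, m = self.fractions.shape
        return pd.DataFrame(
            {
                "gene": np.repeat(np.arange(n), m),
                "distance": np.tile(np.arange(m), n),
                "fraction": self.fractions.ravel(),
            }
        )


def pairwise_distances(topology: GRNTopology) -> np.ndarray:
    """Unweighted directed shortest-path distances D[j, i] (inf if no path)."""
    adj = topology.adjacency(dtype=np.float64)
    return shortest_path(adj, method="D", directed=True, unweighted=True)


def distance_decomposition(
    effects: TotalEffects,
    topology: GRNTopology,
    distances: Optional[np.ndarray] = None,
) -> DistanceDecomposition:
    """Group squared total effects by regulator-target graph distance.

    Regulators with no directed path contribute nothing (their entry of
    L is zero); unreachable pairs are simply skipped.
    """
    if distances is None:
        distances = pairwise_distances(topology)
    L2 = effects.L**2
    vg = np.einsum("ji,ji->i", effects.L, effects.L)
    finite = np.isfinite(distances)
    dmax = int(distances[finite].max()) if finite.any() else 0
    n = topology.n
    frac = np.zeros((n, dmax + 1))
    dist_int = np.where(finite, distances, -1).astype(np.int64)
    for d in range(dmax + 1):
        mask = dist_int == d
        frac[:, d] = (L2 * mask).sum(axis=0)
    frac /= vg[np.newaxis, :].T
    return DistanceDecomposition(fractions=frac)


@dataclass
class IndividualSample:
    """Monte-Carlo sample of individual-level genotypes and expression.

    ``expression[ind, gene]`` follows the SEM gene-by-gene in
    topological order; ``cis_score[ind, gene]`` is the aggregate cis
    input (unit variance in expectation), kept for attribution checks.
    """

    expression: np.ndarray = field(repr=False)
    cis_score: np.ndarray = field(repr=False)
    sigma2: float = 0.0

    @property
    def n_individuals(self) -> int:
        return self.expression.shape[0]


def simulate_individuals(
    grn: SignedGRN,
    n_individuals: int,
    q_per_gene: int = 3,
    sigma2: float = 0.0,
    seed: int = 0,
) -> IndividualSample:
    """Simulate individual-level expression as an oracle for the analytic
    decomposition.

    Each gene carries ``q_per_gene`` independent cis variants with
    standardized Binomial(2, 1/2) allele counts and equal effects
    ``1/sqrt(q)``, so the aggregate cis variance is 1 in expectation.
    Expression is then built in topological order from the cis score,
    the regulator terms, and Gaussian noise of variance ``sigma2``.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if q_per_gene < 1:
        raise ValueError("need at least one cis variant per gene")
    topo = grn.topology
    n = topo.n
    rng = np.random.default_rng(seed)

    counts = rng.binomial(2, 0.5, size=(n_individuals, n, q_per_gene))
    x = (counts - 1.0) / np.sqrt(0.5)  # standardized genotypes
    beta = 1.0 / np.sqrt(q_per_gene)
    cis = x.sum(axis=2) * beta

    y = np.empty((n_individuals, n))
    order = topo.topo_order
    par: list[list[int]] = [[] for _ in range(n)]
    for s, t in zip(topo.edges[:, 0].tolist(), topo.edges[:, 1].tolist()):
        par[t].append(s)
    noise = (
        rng.normal(0.0, np.sqrt(sigma2), size=(n_individuals, n))
        if sigma2 > 0
        else np.zeros((n_individuals, n))
    )
    for g in order.tolist():
        acc = cis[:, g] + noise[:, g]
        for j in par[g]:
            acc = acc + (grn.signs[j] * grn.gamma) * y[:, j]
        y[:, g] = acc
    return IndividualSample(expression=y, cis_score=cis, sigma2=sigma2)


def heritability_scaling(sigma2: float) -> float:
    """Network-wide heritability ``h^2 = 1/(1 + sigma2)``.

    The ratio of incoming genetic to noise variance is the same for
    every gene, so a single noise variance sets a common heritability.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    return 1.0 / (1.0 + sigma2)
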