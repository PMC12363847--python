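"""Random directed-acyclic regulatory topologies.

Two generators are provided. The planted partition model (PPM) assigns
genes to ``k`` groups and draws each unordered pair as an edge with
probability ``p`` within a group and ``q`` between groups; edges are then
oriented along a random topological ordering, which makes acyclicity
structural. The model is reparameterized in terms of the expected number
of regulators per gene ``r`` and the expected within-group edge fraction
``m``::

    p = 2 k r m / (n - 1)
    q = 2 k r (1 - m) / ((k - 1)(n - 1))

with the inverse map ``r = (n-1)(p + q(k-1)) / (2k)`` and
``m = p / (p + q(k-1))``. With ``k = 1`` the PPM degenerates to the
Erdos--Renyi model and ``m`` is meaningless.

The second generator produces modular acyclic scale-free graphs: genes
are created in topological order and choose parents among earlier genes
preferentially by current out-degree, softened by a uniformity parameter
``d``. Small ``d`` concentrates outgoing regulation in hub genes
(heavy-tailed out-degree); large ``d`` approaches the uniform (PPM-like)
behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse

__all__ = [
    "GRNParams",
    "PPMEdgeProbs",
    "GRNTopology",
    "ppm_edge_probs",
    "er_edge_prob",
    "generate_ppm_dag",
    "generate_scalefree_dag",
    "topology_stats",
    "write_edgelist",
    "read_edgelist",
]


@dataclass(frozen=True)
class GRNParams:
    """Generative parameters for one gene regulatory network.

    Parameters
    ----------
    n : int
        Number of genes (>= 2).
    k : int
        Number of groups (1 <= k <= n). ``k = 1`` gives an ER graph and
        disables ``m``.
    m : float, optional
        Expected fraction of edges within groups, in ``(1/k, 1]``.
        Ignored (and may be None) when ``k = 1``.
    r : float
        Expected number of regulators (in-edges) per gene.
    gamma : float
        Magnitude of each regulatory effect.
    p_plus : float
        Probability that a gene acts as an activator on all its targets.
    d : float, optional
        Out-degree uniformity; ``None`` selects the PPM generator.
    sigma2 : float
        Non-genetic noise variance (sets heritability ``1/(1+sigma2)``).
    """

    n: int
    k: int = 1
    m: Optional[float] = None
    r: float = 0.0
    gamma: float = 0.2
    p_plus: float = 0.5
    d: Optional[float] = None
    sigma2: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need n >= 2, got {self.n}")
        if not 1 <= self.k <= self.n:
            raise ValueError(f"need 1 <= k <= n, got k={self.k}")
        if self.r < 0:
            raise ValueError("r must be non-negative")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if not 0.0 <= self.p_plus <= 1.0:
            raise ValueError("p_plus must be in [0, 1]")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if self.d is not None and self.d <= 0:
            raise ValueError("d must be positive")
        if self.k > 1:
            if self.m is None:
                raise ValueError("m is required when k > 1")
            if not (1.0 / self.k < self.m <= 1.0):
                raise ValueError(
                    f"need m in (1/k, 1]: m={self.m}, k={self.k} "
                    "(dissociative regime m <= 1/k is excluded)"
                )


@dataclass(frozen=True)
class PPMEdgeProbs:
    """Within- and between-group edge probabilities of the PPM."""

    p: float
    q: float


@dataclass
class GRNTopology:
    """A labeled regulatory DAG.

    ``topo_index[g]`` gives the topological position (0..n-1) of gene
    ``g``; every edge runs from a lower to a higher position, so
    acyclicity is guaranteed by construction. ``groups`` holds 0-based
    group labels.
    """

    n: int
    topo_index: np.ndarray
    edges: np.ndarray  # shape (E, 2), columns (source gene, target gene)
    groups: np.ndarray
    k: int = 1

    def __post_init__(self) -> None:
        self.topo_index = np.asarray(self.topo_index, dtype=np.int64)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.groups = np.asarray(self.groups, dtype=np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    @property
    def topo_order(self) -> np.ndarray:
        """Genes listed in topological order (inverse of ``topo_index``)."""
        return np.argsort(self.topo_index, kind="stable")

    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        if sorted(self.topo_index.tolist()) != list(range(self.n)):
            raise ValueError("topo_index is not a permutation of 0..n-1")
        if self.edges.size:
            src, dst = self.edges[:, 0], self.edges[:, 1]
            if np.any(src == dst):
                raise ValueError("self-edge found")
            if not np.all(self.topo_index[src] < self.topo_index[dst]):
                raise ValueError("edge violates the topological order")
            pairs = set(map(tuple, self.edges.tolist()))
            if len(pairs) != self.n_edges:
                raise ValueError("duplicate edges found")
        if self.groups.shape != (self.n,):
            raise ValueError("groups must have one label per gene")

    def adjacency(self, dtype=np.int8) -> sparse.csr_matrix:
        """Unweighted adjacency matrix A[src, dst] = 1."""
        if self.n_edges == 0:
            return sparse.csr_matrix((self.n, self.n), dtype=dtype)
        data = np.ones(self.n_edges, dtype=dtype)
        return sparse.csr_matrix(
            (data, (self.edges[:, 0], self.edges[:, 1])), shape=(self.n, self.n)
        )


def ppm_edge_probs(params: GRNParams) -> PPMEdgeProbs:
    """Within/between edge probabilities from the (r, k, m) parameterization.

    Only defined for ``k >= 2``; the single-group case degenerates to the
    ER model (use :func:`er_edge_prob`).
    """
    n, k, r, m = params.n, params.k, params.r, params.m
    if k < 2:
        raise ValueError("ppm_edge_probs requires k >= 2; use er_edge_prob for k = 1")
    p = 2.0 * k * r * m / (n - 1)
    q = 2.0 * k * r * (1.0 - m) / ((k - 1) * (n - 1))
    if p > 1.0 or q > 1.0:
        raise ValueError(
            f"parameters imply an edge probability above 1 (p={p:.4g}, q={q:.4g})"
        )
    return PPMEdgeProbs(p=p, q=q)


def ppm_rm_from_probs(n: int, k: int, probs: PPMEdgeProbs) -> tuple[float, float]:
    """Inverse reparameterization: recover (r, m) from (p, q)."""
    p, q = probs.p, probs.q
    r = (n - 1) * (p + q * (k - 1)) / (2.0 * k)
    m = p / (p + q * (k - 1))
    return r, m


def er_edge_prob(n: int, r: float) -> float:
    """ER edge probability giving expected in-degree ``r`` on the oriented DAG."""
    p = 2.0 * r / (n - 1)
    if p > 1.0:
        raise ValueError(f"r={r} is infeasible at n={n} (edge probability {p:.4g} > 1)")
    return p


def _streams(seed: int, n_streams: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n_streams)]


def _groups_and_order(
    params: GRNParams, rg_group: np.random.Generator, rg_order: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    groups = rg_group.integers(params.k, size=params.n)
    topo_order = rg_order.permutation(params.n)  # position -> gene
    topo_index = np.empty(params.n, dtype=np.int64)
    topo_index[topo_order] = np.arange(params.n)
    return groups, topo_order, topo_index


def generate_ppm_dag(params: GRNParams, seed: int) -> GRNTopology:
    """Draw one planted-partition (or ER, if k=1) DAG.

    Genes are assigned to groups uniformly at random, a random
    topological ordering is drawn, and each unordered pair becomes an
    edge independently with probability ``p`` (same group) or ``q``
    (different groups), oriented from the earlier to the later gene in
    the ordering. Deterministic given ``(params, seed)``.
    """
    if params.k == 1:
        p = q = er_edge_prob(params.n, params.r)
    else:
        probs = ppm_edge_probs(params)
        p, q = probs.p, probs.q

    rg_group, rg_order, rg_edges = _streams(seed, 3)
    groups, topo_order, topo_index = _groups_and_order(params, rg_group, rg_order)

    src_list: list[np.ndarray] = []
    dst_list: list[np.ndarray] = []
    ordered_groups = groups[topo_order]
    for j in range(1, params.n):
        u = rg_edges.random(j)
        if p == q:
            hit = u < p
        else:
            same = ordered_groups[:j] == ordered_groups[j]
            hit = u < np.where(same, p, q)
        parents = np.nonzero(hit)[0]
        if parents.size:
            src_list.append(topo_order[parents])
            dst_list.append(np.full(parents.size, topo_order[j], dtype=np.int64))

    if src_list:
        edges = np.column_stack([np.concatenate(src_list), np.concatenate(dst_list)])
    else:
        edges = np.empty((0, 2), dtype=np.int64)
    return GRNTopology(
        n=params.n, topo_index=topo_index, edges=edges, groups=groups, k=params.k
    )


def generate_scalefree_dag(params: GRNParams, seed: int) -> GRNTopology:
    """Draw one modular acyclic scale-free DAG.

    Sequential construction: the gene at topological position ``i``
    draws its parent count from Binomial(i, 2r/(n-1)) — the same
    expected in-degree profile as the oriented PPM, so the network-wide
    expected in-degree is exactly ``r`` — and samples that many distinct
    parents among earlier genes with probability proportional to
    ``(out-degree + d)``, boosted for same-group candidates so that the
    conditional within-group pick probability equals ``m``. Small ``d``
    yields hub regulators; in the large-``d`` limit parent choice is
    uniform and the out-degree distribution matches the PPM at equal
    ``r``.
    """
    if params.d is None:
        raise ValueError("scale-free generation requires the uniformity parameter d")
    d = float(params.d)
    p_in = er_edge_prob(params.n, params.r)  # also validates feasibility

    rg_group, rg_order, rg_edges = _streams(seed, 3)
    groups, topo_order, topo_index = _groups_and_order(params, rg_group, rg_order)
    ordered_groups = groups[topo_order]

    n, k, m = params.n, params.k, params.m
    outdeg = np.zeros(n, dtype=np.float64)  # indexed by topological position
    src_list: list[np.ndarray] = []
    dst_list: list[np.ndarray] = []

    for j in range(1, n):
        cnt = int(rg_edges.binomial(j, p_in))
        if cnt == 0:
            continue
        w = outdeg[:j] + d
        if k > 1:
            same = ordered_groups[:j] == ordered_groups[j]
            w_same = w[same].sum()
            w_diff = w.sum() - w_same
            if m is not None and w_same > 0 and w_diff > 0:
                if m >= 1.0:
                    w = np.where(same, w, 0.0)
                    cnt = min(cnt, int(same.sum()))
                else:
                    # boost so the conditional within-group pick prob is m
                    g = (m * w_diff) / ((1.0 - m) * w_same)
                    w = np.where(same, w * g, w)
        if cnt == 0:
            continue
        # Gumbel top-k: without-replacement sampling proportional to w
        with np.errstate(divide="ignore"):
            keys = np.log(w) + rg_edges.gumbel(size=j)
        if cnt < j:
            sel = np.argpartition(-keys, cnt - 1)[:cnt]
        else:
            sel = np.nonzero(w > 0)[0]
        sel = sel[w[sel] > 0]
        if sel.size == 0:
            continue
        sel = np.sort(sel)
        outdeg[sel] += 1.0
        src_list.append(topo_order[sel])
        dst_list.append(np.full(sel.size, topo_order[j], dtype=np.int64))

    if src_list:
        edges = np.column_stack([np.concatenate(src_list), np.concatenate(dst_list)])
    else:
        edges = np.empty((0, 2), dtype=np.int64)
    return GRNTopology(n=n, topo_index=topo_index, edges=edges, groups=groups, k=k)


def generate_topology(params: GRNParams, seed: int) -> GRNTopology:
    """Dispatch to the PPM or scale-free generator based on ``params.d``."""
    if params.d is None:
        return generate_ppm_dag(params, seed)
    return generate_scalefree_dag(params, seed)


@dataclass
class TopologyStats:
    n: int
    n_edges: int
    mean_in_degree: float
    within_group_fraction: float  # nan when there are no edges or k == 1
    out_degree_hist: np.ndarray = field(repr=False)

    @property
    def out_degree_variance(self) -> float:
        degs = np.repeat(np.arange(self.out_degree_hist.size), self.out_degree_hist)
        return float(np.var(degs))


def topology_stats(topology: GRNTopology) -> TopologyStats:
    """Realized diagnostics for a generated topology."""
    n, e = topology.n, topology.n_edges
    if e:
        src, dst = topology.edges[:, 0], topology.edges[:, 1]
        outdeg = np.bincount(src, minlength=n)
        if topology.k > 1:
            within = float(np.mean(topology.groups[src] == topology.groups[dst]))
        else:
            within = float("nan")
    else:
        outdeg = np.zeros(n, dtype=np.int64)
        within = float("nan")
    hist = np.bincount(outdeg)
    return TopologyStats(
        n=n,
        n_edges=e,
        mean_in_degree=e / n,
        within_group_fraction=within,
        out_degree_hist=hist,
    )


def write_edgelist(topology: GRNTopology, edge_path, node_path=None, signs=None) -> None:
    """Write the topology as TSV edge and node-attribute tables.

    The edge table has header ``source\\ttarget`` with gene ids; rows are
    sorted by topological position. The optional node table has columns
    ``gene``, ``topo_index``, ``group`` and, if ``signs`` is given,
    ``sign``.
    """
    order = np.lexsort(
        (topology.topo_index[topology.edges[:, 0]], topology.topo_index[topology.edges[:, 1]])
    ) if topology.n_edges else np.empty(0, dtype=np.int64)
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\n")
        for i in order:
            fh.write(f"{topology.edges[i, 0]}\t{topology.edges[i, 1]}\n")
    if node_path is not None:
        with open(node_path, "w", encoding="utf-8") as fh:
            cols = "gene\ttopo_index\tgroup"
            if signs is not None:
                cols += "\tsign"
            fh.write(cols + "\n")
            for g in range(topology.n):
                row = f"{g}\t{topology.topo_index[g]}\t{topology.groups[g]}"
                if signs is not None:
                    row += f"\t{int(signs[g])}"
                fh.write(row + "\n")


def read_edgelist(edge_path, node_path) -> tuple[GRNTopology, Optional[np.ndarray]]:
    """Read a topology (and per-gene signs, if present) written by
    :func:`write_edgelist`."""
    import pandas as pd

    nodes = pd.read_csv(node_path, sep="\t")
    edges = pd.read_csv(edge_path, sep="\t")
    n = len(nodes)
    topo_index = np.empty(n, dtype=np.int64)
    groups = np.empty(n, dtype=np.int64)
    topo_index[nodes["gene"].to_numpy()] = nodes["topo_index"].to_numpy()
    groups[nodes["gene"].to_numpy()] = nodes["group"].to_numpy()
    k = int(groups.max()) + 1 if n else 1
    edge_arr = edges[["source", "target"]].to_numpy(dtype=np.int64)
    topo = GRNTopology(n=n, topo_index=topo_index, edges=edge_arr, groups=groups, k=k)
    signs = None
    if "sign" in nodes.columns:
        signs = np.empty(n, dtype=np.int64)
        signs[nodes["gene"].to_numpy()] = nodes["sign"].to_numpy()
    return topo, signs
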