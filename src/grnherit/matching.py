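"""Per-network summaries and distribution matching.

A simulated network is summarized by medians over its genes (cis
fraction, lead trans/cis ratio, ancestor count, cumulative heritability
within two hops) plus motif counts and realized generator diagnostics.
Networks are compared to a reference cis-fraction distribution with the
two-sample Kolmogorov-Smirnov statistic, used purely as a distance (no
p-values), and the best-matching tail is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import stats

from .dag import GRNTopology, GRNParams, topology_stats
from .motifs import MotifCounts
from .sem import VarianceDecomposition, DistanceDecomposition

__all__ = [
    "GRNSummary",
    "ks_distance",
    "select_matched",
    "summarize_grn",
    "ancestor_counts",
    "cumulative_by_distance",
]


def ks_distance(sample_a, sample_b) -> float:
    """Two-sample K-S statistic D = sup |F_a - F_b|, symmetric, in [0, 1]."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_distance requires non-empty samples")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def select_matched(ks_stats, tail_fraction: float) -> np.ndarray:
    """Indices of the round(tail_fraction * N) smallest statistics.

    Ties are broken by index order (stable sort), so the selection is
    invariant to adding a constant to every statistic.
    """
    if not 0.0 < tail_fraction < 1.0:
        raise ValueError("tail_fraction must be in (0, 1)")
    ks = np.asarray(ks_stats, dtype=float)
    n_sel = int(np.floor(tail_fraction * ks.size + 0.5))
    order = np.argsort(ks, kind="stable")
    return np.sort(order[:n_sel])


def ancestor_counts(topology: GRNTopology) -> np.ndarray:
    """Number of direct and indirect regulators per gene (reachability
    closure on the DAG)."""
    n = topology.n
    reach = np.zeros((n, n), dtype=bool)  # reach[j, i]: path j -> i
    par: list[list[int]] = [[] for _ in range(n)]
    for s, t in zip(topology.edges[:, 0].tolist(), topology.edges[:, 1].tolist()):
        par[t].append(s)
    for g in topology.topo_order.tolist():
        for j in par[g]:
            reach[:, g] |= reach[:, j]
            reach[j, g] = True
    return reach.sum(axis=0).astype(np.int64)


def cumulative_by_distance(
    distance_fractions: DistanceDecomposition, max_distance: int
) -> tuple[np.ndarray, float]:
    """Per-gene cumulative variance fraction within ``max_distance`` hops,
    and its median over genes."""
    per_gene = distance_fractions.cumulative(max_distance)
    return per_gene, float(np.median(per_gene))


@dataclass
class GRNSummary:
    """One network's summary row."""

    median_cis_fraction: float
    median_lead_ratio: float
    median_ancestors: float
    median_cum_within_2: float
    n_ffl: int
    n_biparallel: int
    n_edges: int
    mean_in_degree: float
    within_group_fraction: float
    params: Optional[GRNParams] = None

    def to_row(self) -> dict:
        row = asdict(self)
        params = row.pop("params")
        if params is not None:
            row.update(params)
        return row


def summarize_grn(
    decomp: VarianceDecomposition,
    topology: GRNTopology,
    motifs: MotifCounts,
    distance_fractions: Optional[DistanceDecomposition] = None,
    params: Optional[GRNParams] = None,
) -> GRNSummary:
    """Medians over all genes plus motif and topology diagnostics."""
    stats_ = topology_stats(topology)
    anc = ancestor_counts(topology)
    if distance_fractions is not None:
        _, med_cum2 = cumulative_by_distance(distance_fractions, 2)
    else:
        med_cum2 = float("nan")
    return GRNSummary(
        median_cis_fraction=float(np.median(decomp.cis_fraction)),
        median_lead_ratio=float(np.median(decomp.lead_ratio)),
        median_ancestors=float(np.median(anc)),
        median_cum_within_2=med_cum2,
        n_ffl=motifs.ffl,
        n_biparallel=motifs.biparallel,
        n_edges=topology.n_edges,
        mean_in_degree=stats_.mean_in_degree,
        within_group_fraction=stats_.within_group_fraction,
        params=params,
    )
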