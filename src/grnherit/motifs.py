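"""Motif theory: closed-form expected cis fractions and network counts.

Three local architectures around a focal gene are considered, each with
``r`` baseline regulators of strength ``gamma`` plus one additional
gene:

* V motif — the extra gene is simply an (r+1)-th independent regulator;
* diamond (bi-parallel) — the extra gene is a peripheral master
  regulator feeding every one of the r direct regulators but not the
  focal gene;
* triangle (feed-forward) — the master also regulates the focal gene
  directly.

Averaging the exact variance decomposition over random activator /
repressor assignments (each gene an activator with probability
``p_plus``) gives closed forms for the ratio of the expected cis
variance to the expected total genetic variance:

    V:        1 / (1 + (r+1) g^2)
    diamond:  1 / (1 + r g^2 + r g^4 + 2 C(r,2) (2p-1)^2 g^4)
    triangle: 1 / (1 + (r+1) g^2 + r g^4 + 2 C(r,2) (2p-1)^2 g^4
                     + 2 r (2p-1) g^3)

The covariance terms scale with powers of ``2 p_plus - 1``: master
regulators only shift expected variance when activators and repressors
are unbalanced, and the feed-forward motif additionally carries a
sign-sensitive g^3 interaction between its direct and indirect paths
(coherent motifs add variance, incoherent ones cancel it).
"""

from __future__ import annotations

from itertools import product
from math import comb

import numpy as np

from .dag import GRNTopology

__all__ = [
    "MotifCounts",
    "expected_cis_fraction_v",
    "expected_cis_fraction_diamond",
    "expected_cis_fraction_triangle",
    "sign_enumeration_oracle",
    "count_motifs",
]


def expected_cis_fraction_v(r: int, gamma: float) -> float:
    """Expected cis fraction with r+1 independent regulators."""
    if r < 0:
        raise ValueError("r must be a non-negative integer")
    return 1.0 / (1.0 + (r + 1) * gamma**2)


def expected_cis_fraction_diamond(r: int, gamma: float, p_plus: float) -> float:
    """Expected cis fraction with a peripheral master over r regulators."""
    if r < 1:
        raise ValueError("the diamond motif needs at least one direct regulator")
    g2, g4 = gamma**2, gamma**4
    s = 2.0 * p_plus - 1.0
    return 1.0 / (1.0 + r * g2 + r * g4 + 2.0 * comb(r, 2) * s**2 * g4)


def expected_cis_fraction_triangle(r: int, gamma: float, p_plus: float) -> float:
    """Expected cis fraction with a master regulating both the r direct
    regulators and the focal gene."""
    if r < 0:
        raise ValueError("r must be a non-negative integer")
    g2, g3, g4 = gamma**2, gamma**3, gamma**4
    s = 2.0 * p_plus - 1.0
    return 1.0 / (
        1.0
        + (r + 1) * g2
        + r * g4
        + 2.0 * comb(r, 2) * s**2 * g4
        + 2.0 * r * s * g3
    )


def _motif_adjacency(motif: str, r: int) -> tuple[np.ndarray, int, int]:
    """Explicit DAG for a motif: returns (edge matrix over signed genes +
    focal, focal index, number of signed genes).

    Gene layout: 0..n_signed-1 are the genes whose signs matter (master
    first when present, then the r direct regulators); the focal gene is
    last. The focal gene's own sign never affects its variance, so it is
    excluded from enumeration.
    """
    if motif == "v":
        n_signed = r + 1  # r+1 independent regulators
        n = n_signed + 1
        A = np.zeros((n, n), dtype=bool)
        A[:n_signed, n_signed] = True
        return A, n_signed, n_signed
    if motif in ("diamond", "triangle"):
        n_signed = r + 1  # master + r regulators
        n = n_signed + 1
        focal = n_signed
        A = np.zeros((n, n), dtype=bool)
        A[0, 1 : r + 1] = True  # master -> each regulator
        A[1 : r + 1, focal] = True  # regulators -> focal
        if motif == "triangle":
            A[0, focal] = True
        return A, focal, n_signed
    raise ValueError(f"unknown motif {motif!r}")


def sign_enumeration_oracle(
    motif: str, r: int, gamma: float, p_plus: float
) -> float:
    """Brute-force expected cis fraction by enumerating all sign
    assignments of the motif's regulators.

    Builds the explicit motif DAG, computes the exact variance
    decomposition for each of the ``2^(r+1)`` activator/repressor
    assignments, and returns E[V_cis] / E[V_G] with assignment
    probabilities from ``p_plus`` (the ratio of expectations, not the
    expectation of the ratio).
    """
    if r > 12:
        raise ValueError("enumeration limited to r <= 12")
    A, focal, n_signed = _motif_adjacency(motif, r)
    n = A.shape[0]
    e_vg = 0.0
    e_vcis = 0.0
    for signs in product((1.0, -1.0), repeat=n_signed):
        w = np.zeros(n)
        w[:n_signed] = signs
        G = A * (w[:, None] * gamma)
        L = np.linalg.inv(np.eye(n) - G)
        prob = 1.0
        for s in signs:
            prob *= p_plus if s > 0 else 1.0 - p_plus
        e_vg += prob * float(L[:, focal] @ L[:, focal])
        e_vcis += prob * float(L[focal, focal] ** 2)
    return e_vcis / e_vg


class MotifCounts:
    """Feed-forward and bi-parallel motif counts for a whole network."""

    __slots__ = ("ffl", "biparallel")

    def __init__(self, ffl: int, biparallel: int):
        self.ffl = int(ffl)
        self.biparallel = int(biparallel)

    def __repr__(self) -> str:  # pragma: no cover
        return f"MotifCounts(ffl={self.ffl}, biparallel={self.biparallel})"

    def __eq__(self, other) -> bool:
        return (self.ffl, self.biparallel) == (other.ffl, other.biparallel)


def count_motifs(topology: GRNTopology, exclude_direct: bool = False) -> MotifCounts:
    """Count feed-forward triples and bi-parallel quadruples.

    A feed-forward loop is an ordered triple (a, b, c) with edges a->b,
    b->c and a->c. A bi-parallel motif is a source-target pair (a, c)
    together with an unordered pair of distinct intermediates {b1, b2},
    each on a 2-path a->bi->c; by default the presence of a direct a->c
    edge does not disqualify the pair (set ``exclude_direct`` for the
    stricter convention).
    """
    A = topology.adjacency(dtype=np.int64)
    if topology.n_edges == 0:
        return MotifCounts(0, 0)
    P2 = (A @ A).tocsr()  # number of 2-paths per (a, c)
    ffl = int(P2.multiply(A).sum())
    if exclude_direct:
        P2 = P2 - P2.multiply(A > 0)
        P2.eliminate_zeros()
    t = P2.data.astype(np.int64)
    biparallel = int((t * (t - 1) // 2).sum())
    return MotifCounts(ffl=ffl, biparallel=biparallel)
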