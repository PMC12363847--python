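import dataclasses

import numpy as np
import pytest

from grnherit.dag import GRNTopology
from grnherit.pipeline import PRESETS, run_sweep
from grnherit.sem import SignedGRN
from grnherit.tables import filter_eqtl_genes, generate_synthetic_table


def make_topology(n, edges, groups=None, k=1, topo_index=None):
    """Topology with identity topological order unless overridden."""
    if topo_index is None:
        topo_index = np.arange(n)
    if groups is None:
        groups = np.zeros(n, dtype=np.int64)
    topo = GRNTopology(
        n=n,
        topo_index=topo_index,
        edges=np.asarray(edges, dtype=np.int64).reshape(-1, 2),
        groups=np.asarray(groups),
        k=k,
    )
    topo.validate()
    return topo


def signed(topo, signs, gamma):
    return SignedGRN(topology=topo, signs=np.asarray(signs), gamma=gamma)


@pytest.fixture
def chain3():
    """A -> B -> C."""
    return make_topology(3, [[0, 1], [1, 2]])


@pytest.fixture
def ffl3():
    """Feed-forward triple: A -> B, B -> C, A -> C."""
    return make_topology(3, [[0, 1], [1, 2], [0, 2]])


@pytest.fixture(scope="session")
def ppm_desk_sweep():
    cfg = dataclasses.replace(PRESETS["ppm-desk"], seed=20260928)
    return run_sweep(cfg)


@pytest.fixture(scope="session")
def scalefree_desk_sweep():
    cfg = dataclasses.replace(PRESETS["scalefree-desk"], seed=20260929)
    return run_sweep(cfg)


@pytest.fixture(scope="session")
def reference_table():
    return filter_eqtl_genes(generate_synthetic_table(11409, 0.28, seed=42))
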