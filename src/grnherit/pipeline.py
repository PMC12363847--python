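"""Sweep, matching, and report orchestration.

A sweep draws generator parameters per network from configured
distributions, builds each network, runs the variance decomposition and
motif counts, and collects one summary row per network together with
the per-gene cis-fraction sample needed for distribution matching.
Everything is reproducible from a single root seed: each network gets a
recorded integer sub-seed that drives parameter draws, topology,
and sign assignment.

Shipped presets follow the two published sweep schemes (ER illustration
and the planted-partition / scale-free parameter sweeps) at full scale,
plus reduced "desk" variants (n = 500 genes, 500 networks, group counts
shrunk proportionally so edge probabilities stay feasible) sized to run
in minutes on a laptop.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .dag import GRNParams, generate_topology
from .matching import ks_distance, select_matched, summarize_grn, ancestor_counts
from .motifs import count_motifs
from .sem import (
    assign_signs,
    distance_decomposition,
    total_effects,
    variance_decomposition,
)
from .tables import HeritabilityTable

logger = logging.getLogger("grnherit")

__all__ = [
    "SweepConfig",
    "SweepResult",
    "MatchResult",
    "run_sweep",
    "run_matching",
    "run_exemplar_report",
    "PRESETS",
    "load_config",
]


# Parameter distribution specs: {"dist": "fixed"|"uniform"|"loguniform"|
# "randint"|"uniform_m", ...}. "uniform_m" draws m ~ U(1/k, 1) given the
# current k draw.
ParamSpec = dict


@dataclass
class SweepConfig:
    generator: str  # "ppm" or "scalefree"
    n_grns: int
    n_genes: int
    params: dict[str, ParamSpec] = field(default_factory=dict)
    seed: int = 0
    tail_fraction: float = 0.025
    name: str = "sweep"

    def __post_init__(self) -> None:
        if self.generator not in ("ppm", "scalefree"):
            raise ValueError("generator must be 'ppm' or 'scalefree'")
        if self.n_grns < 1:
            raise ValueError("n_grns must be >= 1")
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        for name, spec in self.params.items():
            lo, hi = spec.get("low"), spec.get("high")
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"invalid range for {name}: {lo} > {hi}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> SweepConfig:
    """Read a sweep configuration from YAML or JSON."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return SweepConfig(**raw)


def _draw(spec: ParamSpec, rng: np.random.Generator, drawn: dict) -> float:
    kind = spec.get("dist", "fixed")
    if kind == "fixed":
        return spec["value"]
    if kind == "uniform":
        return float(rng.uniform(spec["low"], spec["high"]))
    if kind == "loguniform":
        return float(np.exp(rng.uniform(np.log(spec["low"]), np.log(spec["high"]))))
    if kind == "randint":
        return int(rng.integers(spec["low"], spec["high"] + 1))
    if kind == "uniform_m":
        k = drawn["k"]
        return float(rng.uniform(1.0 / k, 1.0)) if k > 1 else None
    raise ValueError(f"unknown distribution {kind!r}")


def draw_params(config: SweepConfig, rng: np.random.Generator) -> GRNParams:
    drawn: dict = {}
    for name in ("k", "m", "r", "gamma", "p_plus", "d", "sigma2"):
        if name in config.params:
            drawn[name] = _draw(config.params[name], rng, drawn)
    drawn.setdefault("k", 1)
    if drawn["k"] == 1:
        drawn["m"] = None
    if config.generator == "ppm":
        drawn["d"] = None
    elif "d" not in drawn:
        raise ValueError("scale-free sweeps need a spec for d")
    return GRNParams(n=config.n_genes, **drawn)


@dataclass
class SweepResult:
    config: SweepConfig
    table: pd.DataFrame
    cis_fraction_samples: list[np.ndarray]
    lead_ratio_samples: list[np.ndarray]
    sub_seeds: np.ndarray
    n_failed: int = 0

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def run_sweep(
    config: SweepConfig,
    keep_networks: bool = False,
    with_distances: bool = True,
) -> SweepResult:
    """Run one parameter sweep; one summary row per network.

    ``keep_networks`` additionally retains the signed networks (for
    exemplar reports); ``with_distances`` controls whether the
    (quadratic-cost) distance decomposition and two-hop summary are
    computed.
    """
    root = np.random.default_rng(config.seed)
    sub_seeds = root.integers(2**31 - 1, size=config.n_grns)
    rows: list[dict] = []
    cis_samples: list[np.ndarray] = []
    lead_samples: list[np.ndarray] = []
    networks: list = []
    n_failed = 0
    for i, sub in enumerate(sub_seeds.tolist()):
        rng = np.random.default_rng(sub)
        try:
            params = draw_params(config, rng)
            topo = generate_topology(params, seed=int(rng.integers(2**31 - 1)))
            grn = assign_signs(
                topo, params.p_plus, params.gamma, seed=int(rng.integers(2**31 - 1))
            )
            eff = total_effects(grn)
            decomp = variance_decomposition(eff)
            motifs = count_motifs(topo)
            dist = distance_decomposition(eff, topo) if with_distances else None
            summary = summarize_grn(decomp, topo, motifs, dist, params=params)
        except Exception as exc:
            logger.error("GRN %d (sub-seed %d) failed: %s", i, sub, exc)
            n_failed += 1
            continue
        row = summary.to_row()
        row["grn"] = i
        row["sub_seed"] = sub
        rows.append(row)
        cis_samples.append(decomp.cis_fraction)
        lead_samples.append(decomp.lead_ratio)
        if keep_networks:
            networks.append((grn, eff, decomp, dist))
        logger.debug("GRN %d sub-seed %d params %s", i, sub, params)
    table = pd.DataFrame(rows)
    result = SweepResult(
        config=config,
        table=table,
        cis_fraction_samples=cis_samples,
        lead_ratio_samples=lead_samples,
        sub_seeds=sub_seeds,
        n_failed=n_failed,
    )
    if keep_networks:
        result.networks = networks  # type: ignore[attr-defined]
    return result


@dataclass
class MatchResult:
    ks_stats: np.ndarray
    matched: np.ndarray  # boolean flag per network
    matched_indices: np.ndarray
    report: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ks_stat": self.ks_stats, "matched": self.matched})


def run_matching(
    sweep: SweepResult,
    reference: HeritabilityTable | np.ndarray,
    tail_fraction: Optional[float] = None,
) -> MatchResult:
    """K-S match every swept network against a reference cis-fraction
    distribution and select the closest tail.

    The report compares generator-parameter medians among matched
    networks with the background, and gives the matched-set median of
    the per-network median lead trans/cis ratio.
    """
    if isinstance(reference, HeritabilityTable):
        ref = reference.cis_fractions()
    else:
        ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference distribution")
    tail = tail_fraction if tail_fraction is not None else sweep.config.tail_fraction
    ks = np.array([ks_distance(s, ref) for s in sweep.cis_fraction_samples])
    idx = select_matched(ks, tail)
    matched = np.zeros(ks.size, dtype=bool)
    matched[idx] = True

    tbl = sweep.table
    param_cols = [
        c for c in ("r", "gamma", "p_plus", "k", "m", "d")
        if c in tbl and tbl[c].notna().any()
    ]
    report: dict = {
        "n_grns": int(ks.size),
        "n_matched": int(idx.size),
        "median_ks_matched": float(np.median(ks[idx])) if idx.size else float("nan"),
        "median_ks_background": float(np.median(ks[~matched])) if (~matched).any() else float("nan"),
        "params_matched": {c: float(tbl.loc[matched, c].median()) for c in param_cols},
        "params_background": {c: float(tbl.loc[~matched, c].median()) for c in param_cols},
        "matched_median_lead_ratio": float(
            tbl.loc[matched, "median_lead_ratio"].median()
        )
        if idx.size
        else float("nan"),
        "matched_median_cis_fraction": float(
            tbl.loc[matched, "median_cis_fraction"].median()
        )
        if idx.size
        else float("nan"),
    }
    return MatchResult(ks_stats=ks, matched=matched, matched_indices=idx, report=report)


def run_exemplar_report(sweep: SweepResult, indices: Sequence[int]) -> dict:
    """Per-gene tables for selected networks.

    For each selected network: ancestor counts and lead trans effects
    by topological index, and the median cumulative heritability as a
    function of network distance. Requires a sweep run with
    ``keep_networks=True``.
    """
    networks = getattr(sweep, "networks", None)
    if networks is None:
        raise ValueError("sweep was not run with keep_networks=True")
    out: dict = {}
    for i in indices:
        if not 0 <= i < len(networks):
            raise KeyError(f"network {i} not found in sweep")
        grn, eff, decomp, dist = networks[i]
        topo = grn.topology
        anc = ancestor_counts(topo)
        per_gene = decomp.to_frame(n_ancestors=anc)
        per_gene["topo_index"] = topo.topo_index
        if dist is None:
            dist = distance_decomposition(eff, topo)
        med_cum = [
            float(np.median(dist.cumulative(dmax)))
            for dmax in range(dist.max_distance + 1)
        ]
        out[int(i)] = {
            "per_gene": per_gene,
            "median_cumulative_by_distance": med_cum,
            "median_ancestors": float(np.median(anc)),
            "median_cum_within_2": float(np.median(dist.cumulative(2))),
        }
    return out


def _uniform(lo, hi) -> ParamSpec:
    return {"dist": "uniform", "low": lo, "high": hi}


def _fixed(v) -> ParamSpec:
    return {"dist": "fixed", "value": v}


PRESETS: dict[str, SweepConfig] = {
    # illustration scheme: 50 ER networks
    "fig-er": SweepConfig(
        generator="ppm",
        n_grns=50,
        n_genes=1000,
        params={
            "k": _fixed(1),
            "r": _uniform(4, 8),
            "gamma": _uniform(0.1, 0.5),
            "p_plus": _fixed(0.5),
        },
        name="fig-er",
    ),
    "ppm-full": SweepConfig(
        generator="ppm",
        n_grns=10_000,
        n_genes=5000,
        params={
            "k": {"dist": "randint", "low": 2, "high": 100},
            "m": {"dist": "uniform_m"},
            "r": _uniform(2, 10),
            "gamma": _uniform(0.2, 0.5),
            "p_plus": _uniform(0, 1),
        },
        name="ppm-full",
    ),
    "scalefree-full": SweepConfig(
        generator="scalefree",
        n_grns=10_000,
        n_genes=5000,
        params={
            "k": {"dist": "randint", "low": 2, "high": 100},
            "m": {"dist": "uniform_m"},
            "r": _uniform(2, 10),
            "gamma": _uniform(0.2, 0.5),
            "p_plus": _uniform(0, 1),
            "d": {"dist": "loguniform", "low": 1.0, "high": 30.0},
        },
        name="scalefree-full",
    ),
}

# Desk-scale variants: 500 networks of 500 genes; the group-count range
# shrinks with n so the implied edge probabilities stay below 1.
for _name, _full, _khigh in (("ppm-desk", "ppm-full", 10), ("scalefree-desk", "scalefree-full", 10)):
    _cfg = PRESETS[_full]
    _params = dict(_cfg.params)
    _params["k"] = {"dist": "randint", "low": 2, "high": _khigh}
    PRESETS[_name] = SweepConfig(
        generator=_cfg.generator,
        n_grns=500,
        n_genes=500,
        params=_params,
        name=_name,
    )


def write_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
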