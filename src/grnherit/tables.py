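"""Per-gene cis/trans heritability tables.

The matching pipeline needs a reference distribution of per-gene cis
fractions, ``h2_cis / (h2_cis + h2_trans)``. Tables can be read from a
TSV with columns ``gene``, ``h2_cis``, ``h2_trans``, ``has_cis_eqtl``,
``has_trans_eqtl`` (flags 0/1, empty field = NA), or generated
synthetically with the statistical shape of published twin-study
estimates: cis fractions Beta-distributed with a chosen population
median (default 0.28), total genetic variance Beta-distributed on
(0, 1), and eQTL-detection flags drawn with probability increasing in
the respective heritability component so that subsetting to genes with
both a cis- and a trans-eQTL shifts the cis-fraction distribution
(weakly) upward, as observed in real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "HeritabilityTable",
    "read_heritability_table",
    "generate_synthetic_table",
    "filter_eqtl_genes",
]

REQUIRED_COLUMNS = ("gene", "h2_cis", "h2_trans", "has_cis_eqtl", "has_trans_eqtl")


@dataclass
class HeritabilityTable:
    """Wrapper around a per-gene heritability DataFrame.

    ``cis_fraction`` is derived where the total genetic variance is
    positive and NaN otherwise (such genes are retained in the table
    but excluded from distribution summaries).
    """

    data: pd.DataFrame
    median_shift: Optional[float] = None  # set by filter_eqtl_genes

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if (df["h2_cis"] < 0).any() or (df["h2_trans"] < 0).any():
            bad = df.index[(df["h2_cis"] < 0) | (df["h2_trans"] < 0)].tolist()
            raise ValueError(f"negative heritability in rows {bad}")
        total = df["h2_cis"] + df["h2_trans"]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, df["h2_cis"] / total, np.nan)
        self.data = df.assign(cis_fraction=frac)

    def __len__(self) -> int:
        return len(self.data)

    def cis_fractions(self) -> np.ndarray:
        """Defined cis fractions only (genes with positive total variance)."""
        vals = self.data["cis_fraction"].to_numpy(dtype=float)
        return vals[np.isfinite(vals)]

    def median_cis_fraction(self) -> float:
        return float(np.median(self.cis_fractions()))

    def write(self, path) -> None:
        cols = list(REQUIRED_COLUMNS)
        out = self.data[cols].copy()
        out["has_cis_eqtl"] = out["has_cis_eqtl"].astype(int)
        out["has_trans_eqtl"] = out["has_trans_eqtl"].astype(int)
        out.to_csv(path, sep="\t", index=False, na_rep="")


def read_heritability_table(path) -> HeritabilityTable:
    """Parse a heritability TSV, reporting unparseable rows by line number."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise ValueError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("h2_cis", "h2_trans"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad]  # 1-based, after header
            raise ValueError(f"{path}: unparseable {col} at lines {lines}")
        df[col] = coerced
    return HeritabilityTable(data=df)


def filter_eqtl_genes(table: HeritabilityTable) -> HeritabilityTable:
    """Keep genes with at least one cis- and one trans-eQTL.

    Records the shift in the median cis fraction induced by filtering on
    the returned table (``median_shift``); an empty result is allowed.
    """
    df = table.data
    mask = (df["has_cis_eqtl"].astype(bool)) & (df["has_trans_eqtl"].astype(bool))
    sub = df.loc[mask].drop(columns=["cis_fraction"]).reset_index(drop=True)
    out = HeritabilityTable(data=sub)
    if len(out) and len(table.cis_fractions()):
        shift = out.median_cis_fraction() - table.median_cis_fraction()
    else:
        shift = float("nan")
    out.median_shift = shift
    return out


def _beta_params_for_median(target: float, concentration: float) -> tuple[float, float]:
    """Solve for Beta(a, concentration - a) with the requested median."""

    def f(a: float) -> float:
        return stats.beta.median(a, concentration - a) - target

    eps = 1e-6 * concentration
    a = optimize.brentq(f, eps, concentration - eps, xtol=1e-12)
    return a, concentration - a


def generate_synthetic_table(
    n_genes: int,
    target_median_cis_fraction: float = 0.28,
    seed: int = 0,
    concentration: float = 2.0,
    total_beta: tuple[float, float] = (2.0, 2.0),
    cis_flag_logit: tuple[float, float] = (-1.0, 15.0),
    trans_flag_logit: tuple[float, float] = (2.0, 5.0),
) -> HeritabilityTable:
    """Draw a synthetic per-gene heritability table.

    Cis fractions come from a Beta whose parameters are solved
    numerically so the population median equals the target; total
    genetic variance from ``Beta(*total_beta)``; detection flags from
    logistic models on the respective component (intercept, slope).
    Deterministic given ``seed``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    if not 0.0 < target_median_cis_fraction < 1.0:
        raise ValueError("target median must be in (0, 1)")
    a, b = _beta_params_for_median(target_median_cis_fraction, concentration)
    rng = np.random.default_rng(seed)
    frac = rng.beta(a, b, size=n_genes)
    total = rng.beta(*total_beta, size=n_genes)
    h2_cis = frac * total
    h2_trans = (1.0 - frac) * total
    p_cis = expit(cis_flag_logit[0] + cis_flag_logit[1] * h2_cis)
    p_trans = expit(trans_flag_logit[0] + trans_flag_logit[1] * h2_trans)
    df = pd.DataFrame(
        {
            "gene": [f"gene_{i:05d}" for i in range(n_genes)],
            "h2_cis": h2_cis,
            "h2_trans": h2_trans,
            "has_cis_eqtl": (rng.random(n_genes) < p_cis).astype(int),
            "has_trans_eqtl": (rng.random(n_genes) < p_trans).astype(int),
        }
    )
    return HeritabilityTable(data=df)
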