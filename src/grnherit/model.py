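"""Model/results interface for fitting network architecture to data.

`GRNArchitectureModel` wraps the whole inference loop in a familiar
fit/results shape: construct it from a per-gene heritability table (the
observed cis-fraction distribution) and a sweep configuration, call
``fit()`` to simulate the sweep and match each network to the data by
K-S distance, and read estimates off the returned
:class:`GRNArchitectureResults` — the matched-set medians of the
generator parameters are the point estimates, with their matched-set
interquartile ranges as spread, plus diagnostics (K-S distances, the
matched trans/cis effect-size ratio) and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .pipeline import PRESETS, MatchResult, SweepConfig, SweepResult, run_matching, run_sweep
from .tables import HeritabilityTable

__all__ = ["GRNArchitectureModel", "GRNArchitectureResults"]


class GRNArchitectureModel:
    """Fit generative network parameters to an observed cis-fraction
    distribution by simulation and distribution matching."""

    def __init__(
        self,
        reference: HeritabilityTable | np.ndarray,
        config: SweepConfig | str = "scalefree-desk",
        tail_fraction: Optional[float] = None,
    ):
        if isinstance(config, str):
            config = PRESETS[config]
        self.config = config
        self.reference = reference
        self.tail_fraction = (
            tail_fraction if tail_fraction is not None else config.tail_fraction
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "GRNArchitectureModel":
        """Build from a DataFrame with the heritability-table schema."""
        return cls(HeritabilityTable(data=df.copy()), **kwargs)

    def fit(self, keep_networks: bool = False) -> "GRNArchitectureResults":
        sweep = run_sweep(self.config, keep_networks=keep_networks)
        match = run_matching(sweep, self.reference, self.tail_fraction)
        return GRNArchitectureResults(self, sweep, match)


class GRNArchitectureResults:
    """Matched-network estimates of regulatory-architecture parameters."""

    def __init__(
        self, model: GRNArchitectureModel, sweep: SweepResult, match: MatchResult
    ):
        self.model = model
        self.sweep = sweep
        self.match = match
        tbl = sweep.table
        self._param_cols = [
            c for c in ("r", "gamma", "p_plus", "k", "m", "d") if c in tbl and tbl[c].notna().any()
        ]

    @property
    def ks_stats(self) -> np.ndarray:
        return self.match.ks_stats

    @property
    def matched(self) -> np.ndarray:
        return self.match.matched

    @property
    def params(self) -> pd.Series:
        """Matched-set medians of the generator parameters."""
        tbl = self.sweep.table
        return tbl.loc[self.matched, self._param_cols].median()

    @property
    def params_iqr(self) -> pd.DataFrame:
        tbl = self.sweep.table.loc[self.matched, self._param_cols]
        return tbl.quantile([0.25, 0.75]).T.rename(columns={0.25: "q25", 0.75: "q75"})

    @property
    def trans_cis_ratio(self) -> float:
        """Matched-set median of the per-network median lead trans/cis
        effect-size ratio."""
        return self.match.report["matched_median_lead_ratio"]

    def summary(self) -> str:
        tbl = self.sweep.table
        rep = self.match.report
        lines = [
            "GRN architecture matching results",
            "=" * 46,
            f"generator:          {self.model.config.generator}",
            f"networks simulated: {rep['n_grns']}  (genes per network: {self.model.config.n_genes})",
            f"networks matched:   {rep['n_matched']}  (tail {self.model.tail_fraction:.3f})",
            f"median K-S matched: {rep['median_ks_matched']:.4f}",
            f"median K-S backgnd: {rep['median_ks_background']:.4f}",
            "",
            f"{'param':>8} {'matched':>10} {'q25':>8} {'q75':>8} {'background':>11}",
        ]
        iqr = self.params_iqr
        for c in self._param_cols:
            lines.append(
                f"{c:>8} {self.params[c]:>10.3f} {iqr.loc[c, 'q25']:>8.3f} "
                f"{iqr.loc[c, 'q75']:>8.3f} {tbl.loc[~self.matched, c].median():>11.3f}"
            )
        lines += [
            "",
            f"matched median cis fraction:      {rep['matched_median_cis_fraction']:.4f}",
            f"matched lead trans/cis ratio:     {rep['matched_median_lead_ratio']:.4f}",
            f"reference median cis fraction:    {self._reference_median():.4f}",
        ]
        return "\n".join(lines)

    def _reference_median(self) -> float:
        ref = self.model.reference
        if isinstance(ref, HeritabilityTable):
            return ref.median_cis_fraction()
        return float(np.median(np.asarray(ref, dtype=float)))
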