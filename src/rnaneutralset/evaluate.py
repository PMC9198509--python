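"""Batch comparison of set-size predictors and the log-scale accuracy metrics.

All comparisons are done on log10 set sizes: Pearson correlation of the logs,
the r^2 of an ordinary least-squares linear fit of predicted on reference
log10 values, and the RMSD of the log10 values.  Rows with zero (or failed)
reference or prediction are excluded from the metrics but counted and reported
as percentages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["loglog_metrics", "ComparisonTable", "zero_rate", "MetricsError"]


class MetricsError(ValueError):
    """Not enough valid rows, or degenerate data, for the requested metric."""


def loglog_metrics(
    reference_log10: Sequence[float], predicted_log10: Sequence[float]
) -> dict[str, float]:
    """Pearson-on-logs, r^2 of the log-log OLS fit, and RMSD of log10 values.

    Inputs are log10 set sizes with non-finite entries (zero or failed set
    sizes) already removed or marked NaN; NaN rows are dropped pairwise.
    The OLS fit regresses prediction on reference; r^2 is symmetric under
    exchanging the roles and invariant under affine maps of either column.
    """
    ref = np.asarray(reference_log10, dtype=float)
    pred = np.asarray(predicted_log10, dtype=float)
    if ref.shape != pred.shape:
        raise ValueError("reference and prediction lengths differ")
    keep = np.isfinite(ref) & np.isfinite(pred)
    ref, pred = ref[keep], pred[keep]
    if ref.size < 3:
        raise MetricsError(f"only {ref.size} valid rows; need at least 3")
    if np.ptp(ref) == 0 or np.ptp(pred) == 0:
        raise MetricsError("zero variance in reference or prediction")
    pearson = stats.pearsonr(ref, pred).statistic
    fit = stats.linregress(ref, pred)
    rmsd = float(np.sqrt(np.mean((pred - ref) ** 2)))
    return {
        "pearson_log": float(pearson),
        "r2_loglog": float(fit.rvalue**2),
        "rmsd_log10": rmsd,
        "n": int(ref.size),
    }


def zero_rate(log10_values: Sequence[float]) -> float:
    """Percentage of entries that are zero/failed (non-finite log10 size)."""
    vals = np.asarray(log10_values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty column")
    return float(100.0 * np.mean(~np.isfinite(vals)))


@dataclass
class ComparisonTable:
    """Reference vs per-method predicted log10 set sizes, keyed by structure.

    ``table`` has one row per structure with a ``reference`` column, one
    column per method, and feature columns (n_bp, n_stack_regions, n_eos).
    Metrics are computed only over rows where both reference and prediction
    are finite (structures with zero set size are excluded).
    """

    table: pd.DataFrame
    config: dict

    REQUIRED = ("structure", "reference")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"comparison table lacks column {col!r}")

    @property
    def methods(self) -> list[str]:
        skip = set(self.REQUIRED) | {"n_bp", "n_stack_regions", "n_eos", "L"}
        return [
            c for c in self.table.columns
            if c not in skip and pd.api.types.is_numeric_dtype(self.table[c])
        ]

    def metrics(self, method: str) -> dict[str, float]:
        if method not in self.table.columns:
            raise KeyError(f"no prediction column {method!r}")
        return loglog_metrics(self.table["reference"], self.table[method])

    def metrics_block(self) -> dict[str, dict]:
        out: dict[str, dict] = {}
        for m in self.methods:
            try:
                out[m] = self.metrics(m)
            except MetricsError as err:
                out[m] = {"error": str(err)}
        return out

    def write(self, path, sidecar: Optional[dict] = None) -> None:
        """Write the table as TSV plus a JSON sidecar with configuration."""
        self.table.to_csv(path, sep="\t", index=False)
        meta = dict(self.config)
        if sidecar:
            meta.update(sidecar)
        meta["metrics"] = self.metrics_block()
        meta["zero_rate_pct"] = {
            c: zero_rate(self.table[c])
            for c in ["reference"] + self.methods
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2, default=str)

    @classmethod
    def from_frames(cls, reference: pd.DataFrame, predictions: pd.DataFrame,
                    config: Optional[dict] = None) -> "ComparisonTable":
        """Join a reference table and prediction table on the structure column."""
        merged = reference.merge(predictions, on="structure", how="inner")
        if len(merged) != len(reference):
            raise ValueError("structure sets of reference and predictions differ")
        return cls(table=merged, config=config or {})
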