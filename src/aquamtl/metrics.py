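"""Forecast-error metrics, reports, and improvement arithmetic.

Per indicator the root mean square error (RMSE), mean absolute error
(MAE) and mean absolute percentage error (MAPE) are computed on the
original measurement scale, after inverting the training scaler.  The
multi-indicator aggregate is the SUM of the per-indicator values —
the convention under which the reference multi-indicator comparison
rows equal the row sums of the per-indicator table — with the mean
available as an option.

MAPE is kept as a fraction internally and multiplied by 100 only at
reporting interfaces.  It is undefined at zero targets, so any target
within an epsilon of zero raises a structured error naming the
offending indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import DataError

MAPE_EPSILON = 1e-8


def _check_pair(y, yhat):
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if y.size == 0:
        raise DataError("metric input is empty")
    if y.shape != yhat.shape:
        raise DataError(f"length mismatch: {y.shape} vs {yhat.shape}")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root mean square error: sqrt of the mean squared residual."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mae(y, yhat) -> float:
    """Mean absolute error."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def mape(y, yhat, epsilon: float = MAPE_EPSILON) -> float:
    """Mean absolute percentage error, returned as a fraction.

    Raises on targets within ``epsilon`` of zero, where the relative
    error is undefined.
    """
    y, yhat = _check_pair(y, yhat)
    bad = np.nonzero(np.abs(y) <= epsilon)[0]
    if bad.size:
        raise DataError(
            f"MAPE undefined: {bad.size} target(s) within {epsilon} of zero "
            f"at indices {bad[:10].tolist()}"
        )
    return float(np.mean(np.abs((y - yhat) / y)))


def aggregate_multi(per_indicator_values, convention: str = "sum") -> float:
    """Cross-indicator aggregate of one metric.

    ``sum`` (default) matches the reference multi-indicator tables,
    whose aggregate cells equal the sums of the per-indicator cells;
    ``mean`` divides by the number of indicators.
    """
    vals = [float(v) for v in per_indicator_values]
    if convention == "sum":
        return float(sum(vals))
    if convention == "mean":
        return float(sum(vals) / len(vals))
    raise DataError(f"unknown aggregation convention {convention!r}")


def relative_improvement(reference: float, candidate: float) -> float:
    """Percentage improvement of candidate over reference, 1 decimal.

    Defined as 100 * (reference - candidate) / reference, rounded half
    away from zero, matching the reference improvement-row arithmetic
    (computed against the second-best model in the same column).
    """
    if reference <= 0:
        raise DataError(f"reference must be > 0, got {reference}")
    pct = 100.0 * (reference - candidate) / reference
    return float(
        Decimal(repr(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


@dataclass
class MetricsReport:
    """Per-indicator and aggregate RMSE/MAE/MAPE on the original scale."""

    per_indicator: dict          # indicator -> {"rmse","mae","mape"}
    aggregate: dict              # metric -> aggregate value
    n: int                       # evaluated values per indicator (samples*stations)
    convention: str = "sum"
    notices: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "per_indicator": {
                ind: {k: float(v) for k, v in m.items()}
                for ind, m in self.per_indicator.items()
            },
            "aggregate": {k: float(v) for k, v in self.aggregate.items()},
            "n": self.n,
            "convention": self.convention,
        }
        if self.notices:
            out["notices"] = list(self.notices)
        return out

    def metric_row(self, metric: str, percent_mape: bool = False) -> dict:
        scale = 100.0 if (percent_mape and metric == "mape") else 1.0
        row = {ind: m[metric] * scale for ind, m in self.per_indicator.items()}
        row["aggregate"] = self.aggregate[metric] * scale
        return row


def metrics_from_arrays(targets: dict, predictions: dict, convention: str = "sum",
                        notices: list | None = None) -> MetricsReport:
    """Compute the three metrics per indicator plus the aggregate."""
    per = {}
    n = 0
    for ind, y in targets.items():
        yhat = predictions[ind]
        per[ind] = {"rmse": rmse(y, yhat), "mae": mae(y, yhat), "mape": mape(y, yhat)}
        n = int(np.size(y))
    agg = {
        m: aggregate_multi([per[i][m] for i in per], convention)
        for m in ("rmse", "mae", "mape")
    }
    return MetricsReport(per_indicator=per, aggregate=agg, n=n,
                         convention=convention, notices=notices or [])
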