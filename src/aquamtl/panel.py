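"""Multi-station indicator panels, sliding windows, splits, and scaling.

A panel holds weekly measurements of several water-quality indicators
(by default pH, dissolved oxygen, permanganate index and ammonia
nitrogen) at a set of monitoring stations.  Supervised learning
examples are built by sliding a lookback window over the panel: the
model sees all stations' values of one indicator over the previous
``lookback`` weeks (flattened to one vector per indicator) and predicts
every station's value ``horizon`` steps ahead.

Splitting is strictly chronological — the earliest samples train, the
middle validate, the latest test — so no future information leaks into
fitting.  Scaling is per-indicator min–max to [0, 1], fit on the
training subset only, and always inverted before metrics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError

#: Canonical indicator order used throughout the package.
DEFAULT_INDICATORS = ("pH", "DO", "CODMn", "NH3N")

#: Physical lower bounds (pH strictly positive, concentrations non-negative).
INDICATOR_FLOORS = {"pH": 1e-3, "DO": 0.0, "CODMn": 0.0, "NH3N": 0.0}


@dataclass
class IndicatorPanel:
    """Measurement cube indexed (station, time, indicator).

    ``values`` may contain NaN for missing observations until
    :func:`impute_missing` has been applied.  Timestamps must be
    strictly increasing with uniform weekly spacing.
    """

    values: np.ndarray  # (n_stations, n_times, n_indicators), float64
    timestamps: pd.DatetimeIndex
    station_ids: tuple[str, ...]
    indicator_names: tuple[str, ...] = DEFAULT_INDICATORS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.station_ids = tuple(str(s) for s in self.station_ids)
        self.indicator_names = tuple(self.indicator_names)
        if self.values.ndim != 3:
            raise DataError("panel values must be 3-D (station, time, indicator)")
        ns, nt, ni = self.values.shape
        if ns != len(self.station_ids):
            raise DataError(
                f"{len(self.station_ids)} station ids but {ns} station rows"
            )
        if nt != len(self.timestamps):
            raise DataError(f"{len(self.timestamps)} timestamps but {nt} time steps")
        if ni != len(self.indicator_names):
            raise DataError(
                f"{len(self.indicator_names)} indicator names but {ni} columns"
            )
        if len(set(self.indicator_names)) != ni:
            raise DataError("indicator names must be unique")
        if len(set(self.station_ids)) != ns:
            raise DataError("station ids must be unique")
        if nt > 1:
            deltas = np.diff(self.timestamps.asi8)
            if not (deltas > 0).all():
                raise DataError("timestamps must be strictly increasing")
            if len(set(deltas.tolist())) != 1:
                raise DataError("timestamps must be uniformly spaced")

    @property
    def n_stations(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def n_indicators(self) -> int:
        return self.values.shape[2]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def missing_fraction(self) -> pd.DataFrame:
        """Per (station, indicator) fraction of missing observations."""
        frac = np.isnan(self.values).mean(axis=1)
        return pd.DataFrame(
            frac, index=list(self.station_ids), columns=list(self.indicator_names)
        )


@dataclass
class SupervisedWindows:
    """Lookback windows paired with next-step targets.

    ``X`` has shape (sample, lookback, station, indicator); ``Y`` has
    shape (sample, station, indicator).  ``target_times`` carries the
    timestamp each target row refers to.
    """

    X: np.ndarray
    Y: np.ndarray
    lookback: int
    horizon: int
    indicator_names: tuple[str, ...]
    target_times: pd.DatetimeIndex = field(default=None)  # type: ignore[assignment]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_stations(self) -> int:
        return self.X.shape[2]

    def task_inputs(self, tasks: tuple[str, ...] | None = None) -> dict[str, np.ndarray]:
        """Flatten windows to one (sample, lookback*station) matrix per indicator.

        Flattening order is time-major: all stations at the oldest lag
        first, the newest lag last.
        """
        tasks = tuple(tasks) if tasks is not None else self.indicator_names
        out = {}
        for name in tasks:
            j = self.indicator_names.index(name)
            x = self.X[:, :, :, j]  # (n, lookback, stations)
            out[name] = x.reshape(x.shape[0], -1)
        return out

    def task_targets(self, tasks: tuple[str, ...] | None = None) -> dict[str, np.ndarray]:
        tasks = tuple(tasks) if tasks is not None else self.indicator_names
        return {
            name: self.Y[:, :, self.indicator_names.index(name)] for name in tasks
        }

    def subset(self, idx: np.ndarray | slice) -> "SupervisedWindows":
        tt = self.target_times[idx] if self.target_times is not None else None
        return SupervisedWindows(
            X=self.X[idx],
            Y=self.Y[idx],
            lookback=self.lookback,
            horizon=self.horizon,
            indicator_names=self.indicator_names,
            target_times=tt,
        )


@dataclass(frozen=True)
class SplitSpec:
    """Chronological train/validation/test fractions (must sum to 1)."""

    train_fraction: float = 0.6
    val_fraction: float = 0.2
    test_fraction: float = 0.2

    def __post_init__(self) -> None:
        fr = (self.train_fraction, self.val_fraction, self.test_fraction)
        if any(f < 0 for f in fr):
            raise DataError(f"split fractions must be non-negative, got {fr}")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise DataError(f"split fractions must sum to 1, got {sum(fr)!r}")


@dataclass
class ScalerParams:
    """Per-indicator min–max parameters fit on the training subset only."""

    minimum: np.ndarray  # (n_indicators,)
    maximum: np.ndarray
    indicator_names: tuple[str, ...]
    method: str = "minmax"

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=np.float64)
        self.maximum = np.asarray(self.maximum, dtype=np.float64)
        if not (self.maximum > self.minimum).all():
            bad = [
                self.indicator_names[i]
                for i in np.nonzero(self.maximum <= self.minimum)[0]
            ]
            raise DataError(f"constant indicator(s) {bad}: max must exceed min")


def make_windows(panel: IndicatorPanel, lookback: int, horizon: int = 1) -> SupervisedWindows:
    """Slide a lookback window over the panel and pair it with targets.

    With T time steps the number of samples is ``T - lookback - horizon + 1``
    (zero if that is negative, which is not an error).
    """
    if lookback < 1 or horizon < 1:
        raise DataError("lookback and horizon must be >= 1")
    if panel.n_times == 0 or panel.n_stations == 0:
        raise DataError("cannot window an empty panel")
    if panel.has_missing:
        raise DataError("panel contains missing values; run impute_missing first")

    T = panel.n_times
    n = max(0, T - lookback - horizon + 1)
    S, I = panel.n_stations, panel.n_indicators
    X = np.empty((n, lookback, S, I))
    Y = np.empty((n, S, I))
    for k in range(n):
        X[k] = panel.values[:, k : k + lookback, :].transpose(1, 0, 2)
        Y[k] = panel.values[:, k + lookback + horizon - 1, :]
    tt = panel.timestamps[lookback + horizon - 1 :][:n] if n else panel.timestamps[:0]
    return SupervisedWindows(
        X=X,
        Y=Y,
        lookback=lookback,
        horizon=horizon,
        indicator_names=panel.indicator_names,
        target_times=tt,
    )


def chronological_split(
    windows: SupervisedWindows, spec: SplitSpec = SplitSpec()
) -> tuple[SupervisedWindows, SupervisedWindows, SupervisedWindows]:
    """Split windows by target time: earliest train, middle val, latest test.

    Train and validation take the floor of their fractions; remainder
    samples go to the test subset.
    """
    n = windows.n_samples
    n_train = int(np.floor(spec.train_fraction * n))
    n_val = int(np.floor(spec.val_fraction * n))
    return (
        windows.subset(slice(0, n_train)),
        windows.subset(slice(n_train, n_train + n_val)),
        windows.subset(slice(n_train + n_val, n)),
    )


def impute_missing(
    panel: IndicatorPanel, max_missing_fraction: float = 0.2
) -> IndicatorPanel:
    """Drop overly incomplete stations, then interpolate remaining gaps.

    A station is dropped when any of its indicators is missing in more
    than ``max_missing_fraction`` of weeks.  Interior gaps are filled by
    linear interpolation in time; gaps at the series edges take the
    nearest observed value.
    """
    if not panel.has_missing:
        return panel
    frac = np.isnan(panel.values).mean(axis=1)  # (station, indicator)
    keep = (frac <= max_missing_fraction).all(axis=1)
    if not keep.any():
        raise DataError(
            f"all {panel.n_stations} stations exceed the "
            f"{max_missing_fraction:.0%} missing-data threshold"
        )
    values = panel.values[keep].copy()
    for s in range(values.shape[0]):
        for j in range(values.shape[2]):
            series = pd.Series(values[s, :, j])
            if series.isna().any():
                if series.isna().all():
                    raise DataError("a retained series is entirely missing")
                series = series.interpolate(method="linear", limit_direction="both")
                values[s, :, j] = series.to_numpy()
    return IndicatorPanel(
        values=values,
        timestamps=panel.timestamps,
        station_ids=tuple(np.array(panel.station_ids)[keep]),
        indicator_names=panel.indicator_names,
    )


def fit_scaler(train_windows: SupervisedWindows) -> ScalerParams:
    """Fit per-indicator min/max over the training windows (inputs and targets)."""
    if train_windows.n_samples == 0:
        raise DataError("cannot fit a scaler on zero training samples")
    lo = np.minimum(
        train_windows.X.min(axis=(0, 1, 2)), train_windows.Y.min(axis=(0, 1))
    )
    hi = np.maximum(
        train_windows.X.max(axis=(0, 1, 2)), train_windows.Y.max(axis=(0, 1))
    )
    return ScalerParams(
        minimum=lo, maximum=hi, indicator_names=train_windows.indicator_names
    )


def apply_scaler(windows: SupervisedWindows, params: ScalerParams) -> SupervisedWindows:
    """Map each indicator affinely onto [0,1] over its training range.

    Values outside the training range map outside [0,1]; no clipping,
    so the transform stays exactly invertible.
    """
    span = params.maximum - params.minimum
    return replace(
        windows,
        X=(windows.X - params.minimum) / span,
        Y=(windows.Y - params.minimum) / span,
    )


def invert_scaler(data: np.ndarray, params: ScalerParams, indicator: str) -> np.ndarray:
    """Undo min–max scaling for one indicator's array of any shape."""
    j = params.indicator_names.index(indicator)
    return np.asarray(data) * (params.maximum[j] - params.minimum[j]) + params.minimum[j]


def scale_value(data: np.ndarray, params: ScalerParams, indicator: str) -> np.ndarray:
    """Apply min–max scaling to one indicator's array of any shape."""
    j = params.indicator_names.index(indicator)
    return (np.asarray(data) - params.minimum[j]) / (params.maximum[j] - params.minimum[j])
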