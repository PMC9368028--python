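import numpy as np
import pandas as pd
import pytest

from aquamtl.panel import DEFAULT_INDICATORS, IndicatorPanel


def build_panel(n_stations=2, n_times=30, seed=0, indicators=DEFAULT_INDICATORS):
    """Small random panel with positive values and weekly timestamps."""
    rng = np.random.default_rng(seed)
    values = rng.uniform(1.0, 9.0, size=(n_stations, n_times, len(indicators)))
    return IndicatorPanel(
        values=values,
        timestamps=pd.date_range("2013-01-06", periods=n_times, freq="7D"),
        station_ids=tuple(f"S{i}" for i in range(n_stations)),
        indicator_names=tuple(indicators),
    )


@pytest.fixture
def small_panel():
    return build_panel()


@pytest.fixture
def tiny_scaled_windows():
    """Four scaled supervised windows on a 2-station panel, lookback 3."""
    from aquamtl.panel import apply_scaler, fit_scaler, make_windows

    panel = build_panel(n_stations=2, n_times=20, seed=3)
    w = make_windows(panel, lookback=3, horizon=1)
    scaler = fit_scaler(w)
    return apply_scaler(w, scaler).subset(slice(0, 4))
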