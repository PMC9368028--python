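"""Synthetic multi-station water-quality panel generator.

Each station carries one latent AR(1) factor shared by all of its
indicators — the mechanism by which pH, dissolved oxygen, permanganate
index and ammonia nitrogen of the same water body co-move.  Indicator
``i`` at station ``s`` is

    value_t = mu_i + a_i * z_t + u_t^(i) + A_i * sin(2*pi*t/period + phase_i) + e_t

with ``z`` the shared AR(1) factor (stationary std ``shared_std``),
``u`` an indicator-specific AR(1), and ``e`` white observation noise.
Raising the loadings ``a_i`` relative to the idiosyncratic terms raises
the cross-indicator correlation, which is exactly the structure the
multi-task models are designed to exploit.

Randomness comes from one splittable seed sequence with sub-streams
per station and per indicator, so adding stations never perturbs the
series of existing ones, and a fixed seed reproduces the panel bit for
bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .panel import DEFAULT_INDICATORS, INDICATOR_FLOORS, IndicatorPanel

#: AR warm-up steps discarded so series start at stationarity.
BURN_IN = 100


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults give a plausible surface-water panel."""

    n_stations: int = 8
    n_weeks: int = 400
    phi_shared: float = 0.8
    phi_idio: float = 0.5
    shared_std: float = 1.0
    loadings: tuple[float, ...] = (0.3, 0.8, 0.6, 0.15)
    means: tuple[float, ...] = (7.5, 8.0, 4.0, 0.5)
    idio_stds: tuple[float, ...] = (0.15, 0.4, 0.3, 0.08)
    noise_stds: tuple[float, ...] = (0.05, 0.2, 0.15, 0.03)
    seasonal_amplitudes: tuple[float, ...] = (0.1, 1.5, 0.5, 0.05)
    seasonal_period: float = 52.0
    indicator_names: tuple[str, ...] = DEFAULT_INDICATORS
    start_date: str = "2013-01-06"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 1 or self.n_weeks < 1:
            raise ConfigError("n_stations and n_weeks must be positive")
        if not abs(self.phi_shared) < 1:
            raise ConfigError(f"phi_shared={self.phi_shared} violates |phi| < 1")
        if not abs(self.phi_idio) < 1:
            raise ConfigError(f"phi_idio={self.phi_idio} violates |phi| < 1")
        ni = len(self.indicator_names)
        for name in ("loadings", "means", "idio_stds", "noise_stds", "seasonal_amplitudes"):
            vec = getattr(self, name)
            if len(vec) != ni:
                raise ConfigError(f"{name} must have {ni} entries, got {len(vec)}")
        if self.shared_std < 0 or any(s < 0 for s in self.idio_stds + self.noise_stds):
            raise ConfigError("standard deviations must be non-negative")
        if self.seasonal_period <= 0:
            raise ConfigError("seasonal_period must be positive")


def default_water_config(**overrides) -> SyntheticConfig:
    """Documented default panel: 8 stations, 400 weeks, moderate sharing.

    Means of roughly pH 7.5, DO 8 mg/L, CODMn 4 mg/L and NH3-N 0.5 mg/L
    with amplitudes keeping every series positive.  These are plausible
    surface-water conventions, not estimates from any dataset.
    """
    return SyntheticConfig(**overrides)


def strong_shared_config(seed: int = 0, n_stations: int = 8, n_weeks: int = 400,
                         loading_scale: float = 1.0) -> SyntheticConfig:
    """Panel dominated by the per-station shared factor.

    All loadings equal ``loading_scale`` (1 = strong sharing, 0 = fully
    independent indicators); both idiosyncratic terms have std 0.3 times
    the shared factor's stationary std; seasonality off.  Means are
    shifted up so indicator floors never clip the Gaussian structure.

    The factor is slow (phi 0.95, half-life ~13 weeks, as for seasonal
    hydrological drivers) while the indicator-specific residual is
    nearly white (phi 0.2): pooling the four indicators then genuinely
    sharpens the estimate of the factor's current state, which is the
    mechanism multi-task sharing is meant to exploit.  Under these
    settings the population-optimal one-step RMSE of a multi-indicator
    predictor is ~6% below the single-indicator optimum.
    """
    return SyntheticConfig(
        n_stations=n_stations,
        n_weeks=n_weeks,
        phi_shared=0.95,
        phi_idio=0.2,
        shared_std=1.0,
        loadings=(loading_scale,) * 4,
        means=(7.5, 8.0, 6.0, 5.0),
        idio_stds=(0.3,) * 4,
        noise_stds=(0.3,) * 4,
        seasonal_amplitudes=(0.0,) * 4,
        seed=seed,
    )


def _ar1(rng: np.random.Generator, n: int, phi: float, stationary_std: float) -> np.ndarray:
    """Stationary-std-parameterized AR(1) path of length n (after burn-in)."""
    if stationary_std == 0.0:
        return np.zeros(n)
    innov_std = stationary_std * np.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_std, size=n + BURN_IN)
    x = np.empty(n + BURN_IN)
    x[0] = rng.normal(0.0, stationary_std)
    for t in range(1, n + BURN_IN):
        x[t] = phi * x[t - 1] + eps[t]
    return x[BURN_IN:]


def generate_panel(config: SyntheticConfig) -> IndicatorPanel:
    """Generate a seeded panel; identical config and seed give identical output."""
    if config.n_weeks <= 0:
        raise ConfigError("n_weeks must be positive")
    ni = len(config.indicator_names)
    T = config.n_weeks
    root = np.random.SeedSequence(config.seed)
    station_seeds = root.spawn(config.n_stations)

    t_idx = np.arange(T)
    season = np.stack(
        [
            a * np.sin(2.0 * np.pi * t_idx / config.seasonal_period + j * np.pi / 4.0)
            for j, a in enumerate(config.seasonal_amplitudes)
        ],
        axis=1,
    )  # (T, ni)

    values = np.empty((config.n_stations, T, ni))
    for s, sseed in enumerate(station_seeds):
        # one stream for the shared factor, then one per indicator AR and noise
        streams = sseed.spawn(1 + 2 * ni)
        z = _ar1(np.random.Generator(np.random.PCG64(streams[0])), T,
                 config.phi_shared, config.shared_std)
        for j in range(ni):
            u = _ar1(np.random.Generator(np.random.PCG64(streams[1 + j])), T,
                     config.phi_idio, config.idio_stds[j])
            noise_rng = np.random.Generator(np.random.PCG64(streams[1 + ni + j]))
            e = (noise_rng.normal(0.0, config.noise_stds[j], size=T)
                 if config.noise_stds[j] > 0 else np.zeros(T))
            values[s, :, j] = (
                config.means[j] + config.loadings[j] * z + u + season[:, j] + e
            )

    floors = np.array([INDICATOR_FLOORS.get(n, 0.0) for n in config.indicator_names])
    values = np.maximum(values, floors)

    timestamps = pd.date_range(config.start_date, periods=T, freq="7D")
    return IndicatorPanel(
        values=values,
        timestamps=timestamps,
        station_ids=tuple(f"S{s:03d}" for s in range(config.n_stations)),
        indicator_names=config.indicator_names,
    )


def config_to_dict(config: SyntheticConfig) -> dict:
    """JSON-serializable form of the generator configuration."""
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def config_from_dict(d: dict) -> SyntheticConfig:
    known = {f for f in SyntheticConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown synthetic config keys: {sorted(unknown)}")
    d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
    return SyntheticConfig(**d)
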