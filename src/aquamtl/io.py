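"""Panel CSV readers/writers, run configuration, and run manifests.

The on-disk panel format is long CSV with header
``station_id,date,indicator,value`` (ISO-8601 dates, weekly).  Missing
cells are simply absent rows.  Indicator spellings found in the wild
("NH3-N", "COD_Mn", ...) are mapped onto the canonical names through
a configurable alias table.

Run configuration is a flat YAML/JSON tree with sections ``synthetic``
/ ``data``, ``structure``, ``train``, ``split`` and ``benchmark``.
Unknown keys are rejected by name; value violations are reported with
dotted paths.  Defaults follow the reference protocol: lookback 10,
horizon 1, 60/20/20 chronological split, Adam with learning rate
0.001, 100 epochs, batch size 5.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError
from .models import StructureConfig
from .panel import DEFAULT_INDICATORS, IndicatorPanel, SplitSpec
from .synthetic import SyntheticConfig, config_from_dict
from .training import TrainConfig

#: Common alternative indicator spellings accepted on input.
DEFAULT_ALIASES = {
    "COD_Mn": "CODMn", "CODmn": "CODMn", "codmn": "CODMn",
    "NH3-N": "NH3N", "NH3_N": "NH3N", "NHN": "NH3N", "nh3n": "NH3N",
    "ph": "pH", "PH": "pH", "do": "DO", "Do": "DO",
}

PANEL_COLUMNS = ["station_id", "date", "indicator", "value"]


def read_panel_csv(path, aliases: dict | None = None,
                   indicator_names=DEFAULT_INDICATORS) -> IndicatorPanel:
    """Read a long-format panel CSV into an (station, time, indicator) cube.

    Missing (station, date, indicator) combinations become NaN.
    Duplicate rows and un-aliased indicator names are structured errors.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"panel file not found: {path}")
    df = pd.read_csv(path)
    missing_cols = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataError(f"panel CSV missing column(s) {missing_cols}; "
                        f"expected header {PANEL_COLUMNS}")
    alias_map = dict(DEFAULT_ALIASES)
    alias_map.update(aliases or {})
    df["indicator"] = df["indicator"].map(lambda x: alias_map.get(str(x), str(x)))
    unknown = sorted(set(df["indicator"]) - set(indicator_names))
    if unknown:
        raise DataError(f"unknown indicator name(s) {unknown}; "
                        f"known: {list(indicator_names)} (add aliases to map others)")
    dup = df.duplicated(subset=["station_id", "date", "indicator"], keep=False)
    if dup.any():
        rows = df.loc[dup, ["station_id", "date", "indicator"]].drop_duplicates()
        raise DataError(
            "duplicate (station, date, indicator) rows: "
            + "; ".join(f"{r.station_id}/{r.date}/{r.indicator}"
                        for r in rows.head(10).itertuples())
        )
    df["date"] = pd.to_datetime(df["date"])
    stations = tuple(sorted(df["station_id"].astype(str).unique()))
    times = pd.DatetimeIndex(sorted(df["date"].unique()))
    present = [i for i in indicator_names if i in set(df["indicator"])]

    cube = np.full((len(stations), len(times), len(present)), np.nan)
    s_idx = {s: i for i, s in enumerate(stations)}
    t_idx = {t: i for i, t in enumerate(times)}
    i_idx = {ind: i for i, ind in enumerate(present)}
    for r in df.itertuples():
        cube[s_idx[str(r.station_id)], t_idx[r.date], i_idx[r.indicator]] = r.value
    return IndicatorPanel(values=cube, timestamps=times, station_ids=stations,
                          indicator_names=tuple(present))


def write_panel_csv(panel: IndicatorPanel, path) -> None:
    """Write the long CSV format; missing cells are omitted."""
    rows = []
    for s, sid in enumerate(panel.station_ids):
        for t, ts in enumerate(panel.timestamps):
            for j, ind in enumerate(panel.indicator_names):
                v = panel.values[s, t, j]
                if not np.isnan(v):
                    rows.append((sid, ts.date().isoformat(), ind, repr(float(v))))
    with open(path, "w") as fh:
        fh.write(",".join(PANEL_COLUMNS) + "\n")
        for r in rows:
            fh.write(",".join(map(str, r)) + "\n")


def write_wide_csv(panel: IndicatorPanel, path) -> None:
    """One row per (station, date), one column per indicator."""
    rows = []
    for s, sid in enumerate(panel.station_ids):
        for t, ts in enumerate(panel.timestamps):
            row = {"station_id": sid, "date": ts.date().isoformat()}
            row.update({ind: panel.values[s, t, j]
                        for j, ind in enumerate(panel.indicator_names)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_TOP_KEYS = {"schema_version", "seed", "lookback", "horizon", "data", "synthetic",
             "split", "structure", "train", "benchmark", "output_dir"}
_SECTION_KEYS = {
    "split": {"train_fraction", "val_fraction", "test_fraction"},
    "structure": {"structure", "tower_type", "tasks", "hidden_width",
                  "tower_depths", "gh_literal_fusion", "tower_seq_len"},
    "train": {"learning_rate", "epochs", "batch_size", "checkpoint_best",
              "beta1", "beta2", "eps"},
    "synthetic": set(SyntheticConfig.__dataclass_fields__),
    "benchmark": {"structures", "seeds", "tower_types", "task_ablation",
                  "hidden_width", "tower_type"},
}


@dataclass
class RunConfig:
    """Parsed but not yet deeply validated run configuration."""

    schema_version: int = 1
    seed: int = 0
    lookback: int = 10
    horizon: int = 1
    data: str | None = None
    synthetic: dict = field(default_factory=dict)
    split: dict = field(default_factory=dict)
    structure: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    benchmark: dict = field(default_factory=dict)
    output_dir: str = "out"

    # -- section constructors (raise ConfigError on invalid values) --
    def split_spec(self) -> SplitSpec:
        return SplitSpec(**self.split)

    def structure_config(self) -> StructureConfig:
        d = dict(self.structure)
        if "tasks" in d:
            d["tasks"] = tuple(d["tasks"])
        return StructureConfig(**d)

    def train_config(self) -> TrainConfig:
        return TrainConfig(seed=self.seed, **self.train)

    def synthetic_config(self) -> SyntheticConfig:
        d = dict(self.synthetic)
        d.setdefault("seed", self.seed)
        return config_from_dict(d)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Parse a YAML/JSON run config, rejecting unknown keys by name."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"unreadable config {path}: {exc}") from exc
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    for section, allowed in _SECTION_KEYS.items():
        sec = raw.get(section) or {}
        if not isinstance(sec, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        bad = set(sec) - allowed
        if bad:
            raise ConfigError(
                f"unknown key(s) in section {section!r}: {sorted(bad)}"
            )
    return RunConfig(**raw)


def validate_config(config: RunConfig) -> list[str]:
    """Collect value violations as dotted-path messages (empty = valid)."""
    violations = []
    if config.lookback < 1:
        violations.append("lookback must be >= 1")
    if config.horizon < 1:
        violations.append("horizon must be >= 1")
    if config.data is None and not config.synthetic:
        violations.append("either data (path) or synthetic (section) is required")

    tr = config.train
    if tr.get("learning_rate", 0.001) <= 0:
        violations.append("train.learning_rate must be > 0")
    if tr.get("epochs", 100) < 1:
        violations.append("train.epochs must be >= 1")
    if tr.get("batch_size", 5) < 1:
        violations.append("train.batch_size must be >= 1")

    sp = config.split
    fracs = (sp.get("train_fraction", 0.6), sp.get("val_fraction", 0.2),
             sp.get("test_fraction", 0.2))
    if any(f < 0 for f in fracs):
        violations.append("split fractions must be non-negative")
    elif abs(sum(fracs) - 1.0) > 1e-9:
        violations.append(f"split fractions must sum to 1 (got {sum(fracs)})")

    for maker, label in ((config.structure_config, "structure"),
                         (config.synthetic_config, "synthetic")):
        if label == "synthetic" and not config.synthetic:
            continue
        try:
            maker()
        except ConfigError as exc:
            violations.append(f"{label}: {exc}")
    return violations


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(config: RunConfig, inputs=(), outputs=()) -> dict:
    """Assemble the reproducibility manifest for one run."""
    cfg = config.to_dict()
    return {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "created": datetime.now(timezone.utc).isoformat(),
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
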