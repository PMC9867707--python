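"""The BirdYear container: one individual's fixes from June 1 to May 31.

The fix table is a pandas DataFrame with one row per GPS+acceleration fix:

======== =====================================================================
column   meaning
======== =====================================================================
t        UTC timestamp (datetime64[ns])
lat, lon WGS84 degrees
mode     behavior mode: flap / soar / walk / stationary
floating True for on-water stationary fixes
dba      dynamic body acceleration of the burst, g
t_air    2-m air temperature, °C
wind     10-m wind speed, m s⁻¹
solar    surface solar radiation, W m⁻²
simulated True for gap-filled fixes
======== =====================================================================

CSV round-trips carry a YAML sidecar with the metadata (colony, interval,
strategy template parameters, injected gaps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["BirdYear", "FIX_COLUMNS"]

FIX_COLUMNS = [
    "t", "lat", "lon", "mode", "floating", "dba",
    "t_air", "wind", "solar", "simulated",
]


@dataclass
class BirdYear:
    """Ordered fixes for one bird-year plus colony location and metadata."""

    fixes: pd.DataFrame
    colony: tuple[float, float]  # (lat, lon)
    start: pd.Timestamp  # June 1, 00:00 UTC
    bird_id: str = "bird"
    interval_min: float = 20.0
    strategy: str | None = None
    #: generator ground truth (stage boundaries, budgets, ...) when synthetic
    truth: dict = field(default_factory=dict)
    #: injected data-gap windows as (start, end) timestamps, inclusive
    gaps: list = field(default_factory=list)
    #: entropy for the deterministic synthetic weather field, if any
    weather_seed: int | None = None

    def __post_init__(self) -> None:
        df = self.fixes
        missing = [c for c in FIX_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"fix table missing columns: {missing}")
        if not df["t"].is_monotonic_increasing:
            self.fixes = df.sort_values("t", ignore_index=True)
        self.start = pd.Timestamp(self.start).normalize()

    @property
    def end(self) -> pd.Timestamp:
        """First day of the next bird-year (exclusive bound)."""
        return self.start + pd.DateOffset(years=1)

    @property
    def n_days(self) -> int:
        return int((self.end - self.start).days)

    def year_days(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end - pd.Timedelta(days=1), freq="D")

    def copy(self) -> "BirdYear":
        return BirdYear(
            self.fixes.copy(), self.colony, self.start, self.bird_id,
            self.interval_min, self.strategy, dict(self.truth),
            list(self.gaps), self.weather_seed,
        )

    def with_fixes(self, fixes: pd.DataFrame) -> "BirdYear":
        out = self.copy()
        out.fixes = fixes.reset_index(drop=True)
        return out

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path) -> None:
        """Write the fix table as CSV plus a ``.yaml`` metadata sidecar."""
        path = Path(path)
        df = self.fixes.copy()
        df["t"] = df["t"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        df.to_csv(path, index=False)
        meta = {
            "bird_id": self.bird_id,
            "colony": {"lat": float(self.colony[0]), "lon": float(self.colony[1])},
            "start": str(self.start.date()),
            "interval_min": float(self.interval_min),
            "strategy": self.strategy,
            "weather_seed": self.weather_seed,
            "gaps": [[str(a), str(b)] for a, b in self.gaps],
            "truth": _yaml_safe(self.truth),
        }
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))

    @classmethod
    def from_csv(cls, path) -> "BirdYear":
        path = Path(path)
        df = pd.read_csv(path, parse_dates=["t"])
        df["floating"] = df["floating"].astype(bool)
        df["simulated"] = df["simulated"].astype(bool)
        meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
        return cls(
            df,
            (meta["colony"]["lat"], meta["colony"]["lon"]),
            pd.Timestamp(meta["start"]),
            bird_id=meta.get("bird_id", path.stem),
            interval_min=meta.get("interval_min", 20.0),
            strategy=meta.get("strategy"),
            truth=meta.get("truth") or {},
            gaps=[(pd.Timestamp(a), pd.Timestamp(b)) for a, b in meta.get("gaps", [])],
            weather_seed=meta.get("weather_seed"),
        )


def _yaml_safe(obj):
    """Recursively convert numpy/pandas scalars so yaml.safe_dump accepts them."""
    if isinstance(obj, dict):
        return {str(k): _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Timestamp):
        return str(obj)
    return obj
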