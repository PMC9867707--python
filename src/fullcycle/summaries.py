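"""Bird-year and cohort summary statistics.

Annual energy expenditure (AEE) is the mean of daily energy expenditure (DEE)
over a filled bird-year. How *concentrated* expenditure is in time is
quantified by the sum of deviance Σ_t |DEE̅_w(t) − AEE| where DEE̅_w is a
centered w-day moving mean (w ∈ {1, 7, 30}): a bird spending evenly scores
near zero, one with intense migration weeks balanced by quiet winters scores
high. Extreme weeks are picked greedily from the 7-day moving mean — most
extreme first, each chosen week excluding its days from later picks — and
reported with the annual-cycle stage of their central day. Migration-day
tables aggregate DEE and flight time on >70-km days per strategy and season.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accelerometry import MODES

__all__ = [
    "annual_summary",
    "moving_mean",
    "sum_of_deviance",
    "ExtremeWeek",
    "extreme_weeks",
    "migration_table",
    "export_model_tables",
]


def annual_summary(daily: pd.DataFrame, require_full_year: bool = True) -> dict:
    """Annual summary of one bird-year's per-day energy table.

    AEE is the arithmetic mean of DEE over all days. Mean daily hours per mode
    use the observed (non-simulated) time columns — gap-filled time budgets
    are excluded from time-allocation statistics — while energy fractions
    include simulated fixes (thermoregulation during gaps is real cost).
    """
    n = len(daily)
    if require_full_year and n < 365:
        raise ValueError(f"incomplete year: {n} days (need >= 365)")
    out = {"aee": float(daily["dee"].mean()), "n_days": n}
    for m in MODES:
        out[f"hours_{m}"] = float(daily[f"obs_time_{m}"].mean(skipna=True))
        out[f"efrac_{m}"] = float(daily[f"efrac_{m}"].mean())
    return out


def moving_mean(series, window: int) -> np.ndarray:
    """Centered moving mean; ends are truncated to the available days.

    ``window=1`` is the identity. Even windows place the extra day before the
    center (pandas convention).
    """
    x = pd.Series(np.asarray(series, dtype=float))
    if window > len(x):
        raise ValueError(f"window {window} exceeds series length {len(x)}")
    if window < 1:
        raise ValueError("window must be >= 1")
    return x.rolling(window, center=True, min_periods=1).mean().to_numpy()


def sum_of_deviance(series, window: int = 1, edges: str = "full") -> float:
    """Σ_t |moving_mean(DEE, window)_t − AEE| in kJ.

    AEE is always the mean of the raw series. With ``edges='full'`` (default)
    only full windows contribute for window > 1, avoiding edge inflation from
    truncated means; ``edges='truncated'`` keeps every day.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    aee = x.mean()
    sm = moving_mean(x, window)
    if window > 1 and edges == "full":
        half = (window - 1) // 2
        lo = half
        hi = x.size - (window - 1 - half)
        sm = sm[lo:hi]
    return float(np.abs(sm - aee).sum())


@dataclass(frozen=True)
class ExtremeWeek:
    kind: str  # "high" or "low"
    rank: int  # 1 = most extreme
    center_date: pd.Timestamp
    mean_dee: float
    stage: str | None


def extreme_weeks(
    series,
    dates=None,
    stages=None,
    n_weeks: int = 3,
    window: int = 7,
) -> list[ExtremeWeek]:
    """The three highest and three lowest non-overlapping weeks of a DEE series.

    Weeks are 7-day windows of the moving mean (full windows only). Selection
    is sequential from most to least extreme: the best remaining window is
    chosen, its days are excluded, and the search repeats, so no day
    contributes to two weeks within the high (or low) set. Highest weeks are
    ranked by largest window mean, lowest by smallest. Ties break to the
    earliest center date. When fewer than ``n_weeks`` disjoint windows remain,
    as many as fit are returned with a warning.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3 * window:
        raise ValueError(f"need at least {3 * window} days, got {x.size}")
    if dates is None:
        dates = pd.RangeIndex(x.size)
    else:
        dates = pd.Index(dates)
    half = window // 2
    centers = np.arange(half, x.size - (window - 1 - half))
    win_means = np.convolve(x, np.ones(window) / window, mode="valid")

    out: list[ExtremeWeek] = []
    for kind in ("high", "low"):
        blocked = np.zeros(x.size, dtype=bool)
        picked = 0
        for rank in range(1, n_weeks + 1):
            ok = np.array([
                not blocked[c - half: c - half + window].any() for c in centers
            ])
            if not ok.any():
                warnings.warn(
                    f"only {picked} disjoint {kind} weeks available (wanted {n_weeks})"
                )
                break
            vals = win_means[ok]
            cands = centers[ok]
            best = np.argmax(vals) if kind == "high" else np.argmin(vals)
            # np.argmax/argmin take the first occurrence: earliest-date tie-break
            c = int(cands[best])
            blocked[c - half: c - half + window] = True
            stage = stages[c] if stages is not None else None
            out.append(ExtremeWeek(kind, rank, dates[c], float(vals[best]), stage))
            picked += 1
    return out


def migration_table(processed_years) -> pd.DataFrame:
    """Table of migration-day statistics per strategy and season.

    ``processed_years`` is an iterable of objects with ``daily`` (per-day
    energy table joined to stage labels) and ``segmentation`` attributes (see
    :class:`fullcycle.pipeline.ProcessedBirdYear`). Reports, as mean ± SD
    across bird-years: migratory-period length (days between departure and
    arrival, stopovers included), number of migration days, mean and max DEE
    and daily flight hours on migration days. Bird-years with zero migration
    days in a season are flagged and contribute zeros to the day counts.
    """
    season_of = {"autumn_migration": "autumn", "spring_migration": "spring"}
    rows = []
    for py in processed_years:
        daily = py.daily
        for stage, season in season_of.items():
            sel = daily[daily["stage"] == stage]
            if sel.empty:
                continue
            mig = sel[sel["day_subtype"] == "migration_day"]
            flight = mig["time_flap"] + mig["time_soar"] if len(mig) else pd.Series(dtype=float)
            rows.append({
                "strategy": py.segmentation.strategy,
                "season": season,
                "bird_id": py.bird_year.bird_id,
                "period_days": len(sel),
                "n_migration_days": len(mig),
                "mean_dee": mig["dee"].mean() if len(mig) else np.nan,
                "max_dee": mig["dee"].max() if len(mig) else np.nan,
                "mean_flight_h": flight.mean() if len(mig) else np.nan,
                "max_flight_h": flight.max() if len(mig) else np.nan,
                "no_migration_days": len(mig) == 0,
            })
    per_year = pd.DataFrame(rows)
    if per_year.empty:
        return per_year
    agg = per_year.groupby(["strategy", "season"]).agg(
        n_bird_years=("bird_id", "count"),
        period_days_mean=("period_days", "mean"),
        period_days_sd=("period_days", "std"),
        n_migration_days_mean=("n_migration_days", "mean"),
        n_migration_days_sd=("n_migration_days", "std"),
        mean_dee=("mean_dee", "mean"),
        mean_dee_sd=("mean_dee", "std"),
        max_dee=("max_dee", "mean"),
        max_dee_sd=("max_dee", "std"),
        mean_flight_h=("mean_flight_h", "mean"),
        mean_flight_h_sd=("mean_flight_h", "std"),
        max_flight_h=("max_flight_h", "mean"),
        max_flight_h_sd=("max_flight_h", "std"),
    ).reset_index()
    return agg


def export_model_tables(processed_years) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy tables for external mixed-model fitting (LMM / GAMM in R).

    Returns ``(annual, daily)``: one row per bird-year with AEE, mean budgets
    and deviance sums; one row per bird-day with DEE, per-mode hours
    (simulated fixes excluded from the hour columns), flight and stationary
    metabolic rates, weather, stage and the simulated-data fraction.
    """
    annual_rows = []
    daily_frames = []
    for py in processed_years:
        daily = py.daily.copy()
        s = annual_summary(daily, require_full_year=False)
        dee = daily["dee"].to_numpy()
        rec = {
            "bird_id": py.bird_year.bird_id,
            "strategy": py.segmentation.strategy,
            "year_start": py.bird_year.start,
            "aee": s["aee"],
            "deviance_daily": sum_of_deviance(dee, 1),
            "deviance_7day": sum_of_deviance(dee, 7),
            "deviance_30day": sum_of_deviance(dee, 30),
        }
        for m in MODES:
            rec[f"hours_{m}"] = s[f"hours_{m}"]
            rec[f"efrac_{m}"] = s[f"efrac_{m}"]
        annual_rows.append(rec)

        d = daily.copy()
        d.insert(0, "bird_id", py.bird_year.bird_id)
        d.insert(1, "strategy", py.segmentation.strategy)
        keep = ["bird_id", "strategy", "date", "stage", "day_subtype", "dee",
                "flight_mr", "stationary_mr", "frac_simulated"] + \
               [f"obs_time_{m}" for m in MODES] + \
               [c for c in ("t_air", "solar") if c in d.columns]
        daily_frames.append(d[keep])
    return pd.DataFrame(annual_rows), pd.concat(daily_frames, ignore_index=True)
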