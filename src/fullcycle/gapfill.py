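"""Interval harmonisation, coverage filtering and gap filling.

Tags sample adaptively (2.5–60 min depending on battery), so each day is first
subsampled to a common interval between 20 and 60 min chosen from the day's
own worst gap. Bird-years keep at least 75% of the year covered or are
dropped. Data gaps — typical at high latitudes in autumn/winter when solar
tags cannot charge — are filled by resampling fixes from the same stationary
period (run of consecutive stationary days) at ±1 h time-of-day, so the filled
record carries realistic behavior and acceleration while thermoregulatory
costs are evaluated at the missing fix's own date and time. A bird-year that
relocated during a gap cannot be filled this way and is discarded.
"""

from __future__ import annotations

import warnings
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

from .annual_cycle import classify_day, daily_displacement, great_circle_km
from .energetics import annotate_energy, daily_energy_table

__all__ = [
    "subsample_day",
    "subsample_bird_year",
    "subsample_fixed",
    "Coverage",
    "coverage",
    "RelocationDuringGap",
    "fill_gaps",
    "interval_sensitivity",
]


class RelocationDuringGap(ValueError):
    """The bird relocated (>70 km) across a data gap; the bird-year must be
    discarded rather than gap-filled."""


def _day_target_interval(times: pd.Series, lo: float, hi: float) -> float:
    """Common interval for one day: the smallest interval in [lo, hi] no
    shorter than the day's largest observed gap between fixes."""
    if len(times) < 2:
        return lo
    gaps_min = times.diff().dropna().dt.total_seconds().to_numpy() / 60.0
    largest = float(np.round(gaps_min.max(), 6))
    return min(hi, max(lo, largest))


def subsample_day(day_fixes: pd.DataFrame, lo: float = 20.0, hi: float = 60.0) -> pd.DataFrame:
    """Subsample one day of fixes to its target interval.

    The day is split into target-interval bins from its first midnight and the
    earliest fix per bin is retained.
    """
    if len(day_fixes) == 0:
        raise ValueError("empty day")
    t = day_fixes["t"]
    target = _day_target_interval(t, lo, hi)
    day_start = t.iloc[0].normalize()
    bins = ((t - day_start).dt.total_seconds() // (target * 60.0)).astype(int)
    keep = ~bins.duplicated()
    return day_fixes.loc[keep]


def subsample_bird_year(bird_year, lo: float = 20.0, hi: float = 60.0):
    """Apply :func:`subsample_day` to every day of a bird-year."""
    fixes = bird_year.fixes
    date = fixes["t"].dt.normalize()
    out = fixes.groupby(date, group_keys=False).apply(
        lambda d: subsample_day(d, lo, hi)
    )
    return bird_year.with_fixes(out.reset_index(drop=True))


def subsample_fixed(fixes: pd.DataFrame, minutes: float) -> pd.DataFrame:
    """Subsample to a fixed interval (first fix per bin); used by the
    interval-sensitivity analysis."""
    t = fixes["t"]
    day_start = t.dt.normalize()
    bins = ((t - day_start).dt.total_seconds() // (minutes * 60.0)).astype(int)
    key = pd.MultiIndex.from_arrays([day_start, bins])
    keep = ~pd.Series(range(len(fixes)), index=key).index.duplicated()
    return fixes.loc[keep]


class Coverage(NamedTuple):
    fraction: float
    passes: bool


def coverage(bird_year, min_fraction: float = 0.75) -> Coverage:
    """Fraction of the bird-year's days with at least one fix, and whether it
    clears the selection threshold (75% of the year by default)."""
    days_with_data = bird_year.fixes["t"].dt.normalize().nunique()
    frac = days_with_data / bird_year.n_days
    return Coverage(float(frac), bool(frac >= min_fraction))


# ------------------------------------------------------------------ gap fill


def _detect_gaps(bird_year, factor: float = 3.0):
    """Intervals between consecutive fixes longer than ``factor`` times the
    nominal sampling interval, as (last fix before, first fix after) rows."""
    t = bird_year.fixes["t"]
    dt_min = t.diff().dt.total_seconds() / 60.0
    idx = np.where(dt_min > factor * bird_year.interval_min)[0]
    return [(int(i) - 1, int(i)) for i in idx]


def fill_gaps(
    bird_year,
    seed: int,
    weather_fn: Callable | None = None,
    threshold_km: float = 70.0,
    max_widen_h: int = 3,
):
    """Fill data gaps by resampling fixes from the same stationary period.

    Each missing slot (nominal sampling grid inside a gap) receives a donor
    fix drawn uniformly from the surrounding stationary period whose
    time-of-day lies within ±1 h of the slot; if no donor is found the window
    widens stepwise to ±2 h then ±3 h with a warning. The filled fix carries
    the donor's behavior, DBA and location but the slot's own timestamp;
    ``weather_fn(lat, lon, timestamp) -> (t_air, wind, solar)``, when given,
    re-evaluates weather at the donor location and the missing time.

    Returns ``(filled_bird_year, report)``. Raises :class:`RelocationDuringGap`
    when the bird moved more than ``threshold_km`` across any gap.
    """
    rng = np.random.default_rng(seed)
    fixes = bird_year.fixes.reset_index(drop=True)
    gaps = _detect_gaps(bird_year)
    report = {"gaps": [], "n_filled": 0, "fraction_simulated": 0.0}
    if not gaps:
        return bird_year.with_fixes(fixes), report

    daily = daily_displacement(bird_year)
    daily["day_type"] = classify_day(daily["displacement_km"].to_numpy(), threshold_km)
    dtypes = pd.Series(daily["day_type"].to_numpy(), index=daily["date"])

    fix_date = fixes["t"].dt.normalize()
    new_rows = []
    interval = pd.Timedelta(minutes=bird_year.interval_min)

    for i_prev, i_next in gaps:
        prev, nxt = fixes.iloc[i_prev], fixes.iloc[i_next]
        moved = great_circle_km((prev["lat"], prev["lon"]), (nxt["lat"], nxt["lon"]))
        if moved > threshold_km:
            raise RelocationDuringGap(
                f"bird moved {moved:.0f} km across the gap "
                f"{prev['t']} – {nxt['t']}; bird-year discarded"
            )

        # stationary period: expand day-wise from the gap over stationary
        # (or bounding missing) days until a relocation day bounds the run
        d0 = prev["t"].normalize()
        d1 = nxt["t"].normalize()
        lo = d0
        while True:
            prev_day = lo - pd.Timedelta(days=1)
            if prev_day in dtypes.index and dtypes[prev_day] in ("stationary", "missing"):
                lo = prev_day
            else:
                break
        hi = d1
        while True:
            next_day = hi + pd.Timedelta(days=1)
            if next_day in dtypes.index and dtypes[next_day] in ("stationary", "missing"):
                hi = next_day
            else:
                break
        pool = fixes[(fix_date >= lo) & (fix_date <= hi) & ~fixes["simulated"]]
        pool_tod = (pool["t"] - pool["t"].dt.normalize()).dt.total_seconds()

        slots = pd.date_range(prev["t"] + interval, nxt["t"] - interval, freq=interval)
        used: set[int] = set()
        widened = 0
        for slot in slots:
            tod = (slot - slot.normalize()).total_seconds()
            cand = np.array([], dtype=int)
            for widen in range(1, max_widen_h + 1):
                diff = np.abs(pool_tod.to_numpy() - tod)
                diff = np.minimum(diff, 86400 - diff)  # wrap across midnight
                cand = pool.index.to_numpy()[diff <= widen * 3600]
                if cand.size:
                    if widen > 1:
                        widened += 1
                        warnings.warn(
                            f"no donor within ±{widen - 1} h of {slot}; "
                            f"widened to ±{widen} h"
                        )
                    break
            if cand.size == 0:
                warnings.warn(f"no donor found for slot {slot}; left unfilled")
                continue
            fresh = np.array([c for c in cand if c not in used])
            donor_idx = int(rng.choice(fresh if fresh.size else cand))
            used.add(donor_idx)
            donor = fixes.loc[donor_idx]
            row = donor.copy()
            row["t"] = slot
            row["simulated"] = True
            if weather_fn is not None:
                row["t_air"], row["wind"], row["solar"] = weather_fn(
                    donor["lat"], donor["lon"], slot
                )
            new_rows.append(row)
        report["gaps"].append({
            "start": str(prev["t"]), "end": str(nxt["t"]),
            "n_slots": len(slots), "widened_windows": widened,
        })

    if new_rows:
        fixes = pd.concat([fixes, pd.DataFrame(new_rows)], ignore_index=True)
        fixes = fixes.sort_values("t", ignore_index=True)
    report["n_filled"] = len(new_rows)
    report["fraction_simulated"] = float(fixes["simulated"].mean())
    return bird_year.with_fixes(fixes), report


# -------------------------------------------------- interval sensitivity


def interval_sensitivity(
    bird_year,
    intervals=(20.0, 60.0),
    energy_config=None,
    thermo_config=None,
) -> pd.DataFrame:
    """How DEE estimated from coarse sampling compares to high-resolution DEE.

    The bird-year should be sampled at high resolution (e.g. 2.5 min). Per-day
    DEE is computed at native resolution and after fixed-interval subsampling;
    each coarse series is regressed on the native one. Returns one row per
    interval with slope, intercept, r, and the median |error| as a percentage
    of DEE.
    """
    from scipy.stats import linregress

    ref = daily_energy_table(
        annotate_energy(bird_year.fixes, energy_config, thermo_config)
    )[["date", "dee"]].rename(columns={"dee": "dee_ref"})

    rows = []
    for minutes in intervals:
        sub = subsample_fixed(bird_year.fixes, minutes)
        dee = daily_energy_table(
            annotate_energy(sub, energy_config, thermo_config)
        )[["date", "dee"]]
        merged = ref.merge(dee, on="date")
        fit = linregress(merged["dee_ref"], merged["dee"])
        err_pct = 100.0 * np.abs(merged["dee"] - merged["dee_ref"]) / merged["dee_ref"]
        rows.append({
            "interval_min": minutes,
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r": fit.rvalue,
            "median_abs_error_pct": float(err_pct.median()),
            "n_days": len(merged),
        })
    return pd.DataFrame(rows)
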