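"""End-to-end processing of bird-years: subsample → coverage filter → gap
fill → energetics → daily table → stage segmentation → annual summary.

This is the glue the individual modules are designed around; cohort helpers
simulate and process many bird-years for strategy-level comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annual_cycle import StageSegmentation, segment_stages
from .birdyear import BirdYear
from .energetics import EnergyModelConfig, ThermoConfig, annotate_energy, daily_energy_table
from .gapfill import Coverage, coverage, fill_gaps, subsample_bird_year
from .summaries import annual_summary
from .synthetic_tracks import TEMPLATES, generate_bird_year, weather_field

__all__ = ["ProcessedBirdYear", "process_bird_year", "simulate_cohort", "process_cohort"]


class CoverageError(ValueError):
    """Bird-year fails the minimum annual data-coverage requirement."""


@dataclass
class ProcessedBirdYear:
    """A fully processed bird-year."""

    bird_year: BirdYear  # subsampled and gap-filled
    daily: pd.DataFrame  # per-day energy + stage table
    segmentation: StageSegmentation
    coverage: Coverage
    annual: dict
    gap_report: dict


def process_bird_year(
    bird_year: BirdYear,
    energy_config: EnergyModelConfig | None = None,
    thermo_config: ThermoConfig | None = None,
    *,
    seed: int = 0,
    weather_fn=None,
    use_thermo: bool = True,
    do_subsample: bool = True,
    min_coverage: float = 0.75,
) -> ProcessedBirdYear:
    """Run the full pipeline on one bird-year.

    Coverage is evaluated before gap filling; bird-years under ``min_coverage``
    raise :class:`CoverageError`. For synthetic bird-years the weather lookup
    used during gap filling defaults to the generating weather field.
    """
    cov = coverage(bird_year, min_coverage)
    if not cov.passes:
        raise CoverageError(
            f"{bird_year.bird_id}: coverage {cov.fraction:.3f} < {min_coverage}"
        )
    by = subsample_bird_year(bird_year) if do_subsample else bird_year
    if weather_fn is None and by.weather_seed is not None:
        weather_fn = weather_field(by.weather_seed)
    filled, gap_report = fill_gaps(by, seed=seed, weather_fn=weather_fn)

    fixes = annotate_energy(filled.fixes, energy_config, thermo_config,
                            use_thermo=use_thermo)
    filled = filled.with_fixes(fixes)
    daily_e = daily_energy_table(fixes)

    seg = segment_stages(filled)
    daily = daily_e.merge(
        seg.days[["date", "stage", "day_type", "day_subtype", "displacement_km"]],
        on="date", how="left",
    )
    # day-mean weather for the model-table exports
    wx = fixes.groupby(fixes["t"].dt.normalize())[["t_air", "solar"]].mean()
    daily = daily.merge(wx, left_on="date", right_index=True, how="left")

    return ProcessedBirdYear(
        bird_year=filled,
        daily=daily,
        segmentation=seg,
        coverage=cov,
        annual=annual_summary(daily, require_full_year=False),
        gap_report=gap_report,
    )


def simulate_cohort(
    n_per_strategy: int,
    strategies=None,
    sampling_interval: float = 20.0,
    base_seed: int = 1,
) -> list[BirdYear]:
    """Generate ``n_per_strategy`` synthetic bird-years for each strategy,
    with per-year seeds derived from ``base_seed``."""
    strategies = strategies or list(TEMPLATES)
    out = []
    for si, name in enumerate(strategies):
        for k in range(n_per_strategy):
            seed = (base_seed * 10007 + si * 1009 + k) & 0x7FFFFFFF
            out.append(generate_bird_year(name, sampling_interval, seed=seed))
    return out


def process_cohort(bird_years, skip_failures: bool = True, **kwargs) -> list[ProcessedBirdYear]:
    """Process a list of bird-years, skipping (by default) those rejected by
    the coverage filter or the segmentation preconditions."""
    out = []
    for by in bird_years:
        try:
            out.append(process_bird_year(by, **kwargs))
        except ValueError:
            if not skip_failures:
                raise
    return out
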