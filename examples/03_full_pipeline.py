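"""The full pipeline on one bird-year: subsample, gap-fill, energetics,
stage segmentation, and the annual summary statistics.
"""

import fullcycle as fc

by = fc.generate_bird_year("WestAfrica", 20, seed=1)
# knock a 10-day hole in mid-winter, as solar tags do at high latitude
by = fc.inject_gaps(by, [("2019-01-05", "2019-01-14")])

py = fc.process_bird_year(by, seed=0)

print(f"coverage: {py.coverage.fraction:.3f} (pass={py.coverage.passes})")
print(f"gap slots filled: {py.gap_report['n_filled']} "
      f"({py.gap_report['fraction_simulated']:.1%} of fixes simulated)")
print(f"assigned strategy: {py.segmentation.strategy}")
b = py.segmentation.boundaries
print(f"stages: colony departure {b['departure'].date()}, "
      f"winter {b['winter_start'].date()} – {b['winter_end'].date()}, "
      f"return {b['arrival'].date()}")

print(f"\nAEE = {py.annual['aee']:.0f} kJ/day "
      f"({fc.rmr_multiple(py.annual['aee']):.2f}x resting metabolic rate)")
print("mean daily hours:", {m: round(py.annual[f'hours_{m}'], 2)
                            for m in ("flap", "soar", "walk", "stationary")})

dee = py.daily["dee"].to_numpy()
for w in (1, 7, 30):
    print(f"sum of deviance, {w:2d}-day window: {fc.sum_of_deviance(dee, w):8.0f} kJ")
# Long-distance migrants concentrate expenditure: large deviance sums come
# from migration peaks balanced by quiet winters.

print("\nextreme weeks (7-day means, non-overlapping, most extreme first):")
for wk in fc.extreme_weeks(dee, dates=py.daily["date"],
                           stages=py.daily["stage"].to_numpy()):
    print(f"  {wk.kind:4s} #{wk.rank}: {wk.center_date.date()} "
          f"{wk.mean_dee:6.0f} kJ/day  ({wk.stage})")
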