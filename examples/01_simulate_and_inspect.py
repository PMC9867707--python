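"""Simulate one synthetic bird-year and inspect its structure.

Generates a West-African migrant at a 20-min fix interval, then prints the
stage schedule the generator encoded and a few raw fixes. The ground truth
stored on the bird-year (stage boundaries, migration-day counts) is what the
segmentation tests recover later.
"""

import pandas as pd

import fullcycle as fc

by = fc.generate_bird_year("WestAfrica", sampling_interval=20, seed=1)

last_day = by.end - pd.Timedelta(days=1)
print(f"bird-year {by.bird_id}: {len(by.fixes)} fixes, "
      f"{by.start.date()} – {last_day.date()}")
t = by.truth
print(f"generator truth: autumn starts day {t['departure_autumn']}, "
      f"winter day {t['winter_start']}, spring day {t['spring_start']}, "
      f"back at colony day {t['arrival_spring']}")
print(f"migration days: {t['n_migration_days_autumn']} autumn + "
      f"{t['n_migration_days_spring']} spring")

print("\nfirst fixes:")
print(by.fixes.head(3).to_string(index=False))

# behavior mix over the whole year (float is stationary-on-water)
mix = by.fixes.groupby([by.fixes["mode"], by.fixes["floating"]]).size() / len(by.fixes)
print("\nannual behavior mix (fraction of fixes):")
print(mix.round(3).to_string())
# Expect stationary to dominate (gulls rest ~18-20 h/day) with a few percent
# flapping — the expensive behavior that drives the energy budget.
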