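"""Hydrogel swelling series: generation and reduction.

Generates a rise-plateau-collapse swelling curve for a pHEMA-like gel at
pH 11 (peak 60% at 1.5 h, disintegration after 7 h) and recovers the peak
from the weight records via the swelling-ratio reduction.
"""

import nanoflux as nf

series = nf.generate_swelling_series([11.0], peak_ratio=60.0, peak_time=1.5,
                                     disintegrate_after=7.0, noise_sd=0.5,
                                     rng_seed=3)
ratios = [nf.swelling_ratio(nf.SwellingRecord(row.dry_mg, row.swollen_mg,
                                              row.time_h, row.pH))
          for row in series.itertuples()]
t_peak, peak = nf.swelling_peak(series.time_h, ratios)
print(f"{len(series)} records at pH 11")
print(f"peak swelling {peak:.1f} % at t = {t_peak:.2f} h")
print(f"disintegrated records: {int(series.disintegrated.sum())}")

# An 8 mg dry gel reaching 12.8 mg swollen is a 60% mass gain — the
# pH-11 maximum; after disintegration the weight record is flagged and
# excluded from trend analysis.
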