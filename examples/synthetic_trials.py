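"""Generate synthetic IR trials and recover the implanted-rod SAR_eff.

Creates a 10-trial synthetic measurement set for the implant at the
0.75 A drive (camera noise 0.05 K, display resolution 0.1 K, shared
ambient drift, non-exposed reference channel), applies the environmental
correction, aggregates trials, and runs the slope-based estimator.
"""

import numpy as np

from thermosar import (aggregate_trials, estimate_sar_eff, generate_preset,
                       initial_slope, true_response)
from thermosar.thermography import DEFAULT_TIMES_S, PRESETS

trials = generate_preset("implant-0.75A", seed=42)
agg = aggregate_trials(trials, corrected=True)
print("corrected aggregate (mean +/- SD over 10 trials):")
for _, row in agg.iterrows():
    print(f"  t = {row.time_min:4.0f} min   dT = {row.mean_K:+.2f} "
          f"+/- {row.sd_K:.2f} K")

c = PRESETS["implant-0.75A"]["heat_capacity"]
fit = initial_slope(agg.time_min * 60.0, agg.mean_K)
est = estimate_sar_eff(fit.slope, c)

p = trials.truth_params
truth_curve = true_response(p["p_abs"], p["mass"], c,
                            p["loss_coefficient"], DEFAULT_TIMES_S)
truth_sar = c * initial_slope(DEFAULT_TIMES_S, truth_curve).slope

print(f"\nrecovered SAR_eff: {est.sar_eff:.3f} W/kg")
print(f"generator truth (same estimator on the noiseless curve): "
      f"{truth_sar:.3f} W/kg")
print(f"relative error: {abs(est.sar_eff - truth_sar)/truth_sar:.1%}")
print("\nDeviations reflect camera noise and the 0.1 K display step; over")
print("many seeds the median recovery is unbiased (see the test suite).")
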