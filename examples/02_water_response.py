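"""Segmented midday-transpiration response to soil drying.

Each drought day contributes one point: midday transpiration normalized to
plant weight and VPD (ETW) against relative soil water content (SWC).  The
hinge fit estimates the plateau E_max, the critical soil water content
theta_cr where stomata start closing, and the decline slope below it.
Genotypes are then compared by Welch t-tests with compact letters.
"""

import numpy as np

from drylysim import synth, water_response

truths = {
    "B47": synth.LysimeterTruth("B47", e_max_true=0.8e-3, theta_cr_true=0.45,
                                slope_true=6.0e-3),
    "B128": synth.LysimeterTruth("B128", e_max_true=1.2e-3, theta_cr_true=0.28,
                                 slope_true=5.0e-3),
}

fits = {}
for g, (name, truth) in enumerate(truths.items()):
    fits[name] = {}
    for plant in range(7):
        pts = synth.simulate_midday_points(truth, n_days=10, noise_frac=0.05,
                                           seed=1000 * g + plant)
        fits[name][f"{name}_p{plant}"] = water_response.fit_segmented(pts)

table = water_response.fits_to_frame(fits)
print(table.groupby("genotype")[["e_max", "theta_cr", "slope"]].mean().round(5))

comparison = water_response.compare_genotypes(table)
print("\n", comparison.round(5).to_string(index=False))
print("\nDistinct letters = significantly different (P < 0.05).  B47's higher "
      "theta_cr means its stomata respond to drying soil much earlier than "
      "B128's; truths were 0.45 vs 0.28.")
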