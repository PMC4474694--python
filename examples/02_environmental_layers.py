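"""Derive the five predictor layers and screen their correlations.

Depth is kriged from the scattered sounding sample; slope is the maximum
eight-neighbour slope; distance-to-shore is Euclidean to the nearest land
cell; SST mean and SST-SD are per-season temporal statistics.  Pairs with
|r| > 0.7 would be flagged (the screen is advisory).
"""

import numpy as np

from seaniche import (EnvStack, SeascapeParams, correlation_screen,
                      distance_to_shore, interpolate_depth, make_seascape,
                      seasonal_sst_stats, slope_from_depth)

scape = make_seascape(SeascapeParams(seed=1))
depth = interpolate_depth(scape.bathy_points, scape.grid, method="kriging")
err = np.nanmean(np.abs(depth.values - scape.depth.values))
print(f"kriged depth vs true field: mean abs error {err:.1f} m")

slope = slope_from_depth(depth)
dist = distance_to_shore(scape.grid)
print(f"slope: up to {np.nanmax(slope.values):.2f} deg; "
      f"distance to shore: up to {np.nanmax(dist.values) / 1000:.0f} km")

mean_r, sd_r = seasonal_sst_stats(scape.sst_series)["cold"]
stack = EnvStack([depth, slope, dist, mean_r, sd_r], season="cold")
matrix, flagged = correlation_screen(stack, threshold=0.7)
print("cold-season Pearson correlations:")
print(matrix.round(2).to_string())
print("flagged pairs (|r| > 0.7):",
      [(a, b, round(r, 2)) for a, b, r in flagged] or "none")
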