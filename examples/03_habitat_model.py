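"""Fit a presence-only maximum-entropy habitat model for one species.

Sightings of the offshore-thermal species in the warm season are collapsed
to presence cells, modelled against 1000 background cells with
auto-selected features, and evaluated by 5-fold cross-validated AUC,
permutation importance, and the SST response curve.
"""

from seaniche import (SeascapeParams, build_features, cross_validate,
                      dedupe_presences, default_effort, default_truths,
                      make_seascape, response_curve, response_optimum,
                      sample_background, simulate_occurrences)

scape = make_seascape(SeascapeParams(seed=1))
stacks = scape.env_stacks()
truths = default_truths(400)
occ = simulate_occurrences(stacks, truths, default_effort(scape.grid), seed=2)

stack = stacks["warm"]
pres = dedupe_presences(occ, scape.grid, "offshore_thermal", "warm")
print(f"presence localities after deduplication: {pres.n_localities}")

bg = sample_background(scape.grid, 1000, seed=3)
fs = build_features(stack, pres.n_localities)
cv = cross_validate(pres, bg, fs, k=5, seed=4)
print(f"cross-validated AUC: {cv.auc_mean:.3f} +/- {cv.auc_sd:.3f}")
print("permutation importance (%):")
print(cv.importance.round(1).to_string())

curve = response_curve(stack, "sst", pres, bg, n_points=21)
opt = response_optimum(curve)
print(f"SST response optimum: {opt:.2f} degC "
      "(the generator placed the thermal band at 19.4 degC)")
# A high AUC with SST carrying most of the importance means the model
# recovered the species' thermal-front niche from sightings alone.
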