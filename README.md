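# seaniche

Presence-only habitat modelling and directional environmental niche overlap
for marine species on gridded seascapes.

`seaniche` is aimed at spatial ecologists who have opportunistic and
systematic sighting records of two (or more) sympatric species — the
motivating case is a pair of dolphin species sharing a semi-enclosed gulf —
and want to know whether the species prefer different habitats, which
environmental variables drive each species' distribution, and how strongly
and in which direction their environmental niches overlap. Because no such
sighting data can be redistributed here, the package ships a synthetic
seascape generator with known ground truth, so the whole workflow is testable
end to end.

## What it computes

**Environmental layers.** Five predictors on one grid of square cells with a
land/sea mask: depth (ordinary kriging of scattered soundings, exponential
variogram; inverse-distance weighting as a fallback), seabed slope (the
maximum of atan(|Δz|/d) over the eight neighbours of each cell), Euclidean
distance to the shoreline, and per-season SST mean and temporal standard
deviation from a dated raster stack. A correlation screen flags predictor
pairs with |r| > 0.7 (Pearson by default, Spearman optional).

**Maximum-entropy habitat models.** Over a training domain of cells (a
uniform background sample united with the deduplicated presence cells) the
species' distribution is the Gibbs model

    q(x) = exp(Σ_f λ_f f(x)) / Z,

whose weights λ maximise the L1-regularised log-likelihood of the presences.
Feature classes follow the auto-features convention (linear always;
quadratic from 10 presences; hinge from 15; threshold and product from 80),
each with its own regularisation scale. Suitability is reported on the
logistic scale s = e^H q / (1 + e^H q), where H is the entropy of q, so a
cell with typical presence conditions scores 0.5. Models are evaluated by
k-fold cross-validated AUC (held-out presences vs background), variable
contributions by permutation importance (normalised drop in training AUC
when one covariate is shuffled), and habitat preferences by univariate
response curves.

**Directional niche overlap.** A suitability surface with cell values n_j is
normalised by N = Σ_j n_j to a probability distribution p over the r grid
cells. The specific overlap of species i onto species k is

    SO_ik = exp( Σ_j p_ij ln p_kj − Σ_j p_ij ln p_ij ) = exp(−KL(p_i ‖ p_k)),

the probability of obtaining species i's utilisation distribution from
species k's; it is directional and lies in (0, 1]. Complete overlap
(SO_ik = 1) is tested with U_ik = −2 N_i ln SO_ik, referred to a chi-square
distribution with r − 1 degrees of freedom.

**Group attributes.** Sighting bookkeeping by species, season and survey
source; mixed-species group counts; and comparisons of group-size
(binned two-sample Kolmogorov–Smirnov), social-composition and activity
distributions (chi-square contingency tests).

## Worked example

Fit the warm-season model for the synthetic offshore-thermal species and
measure both overlap directions (`examples/03_habitat_model.py` and
`examples/04_niche_overlap.py`):

```python
from seaniche import (SeascapeParams, make_seascape, default_truths,
                      default_effort, simulate_occurrences, dedupe_presences,
                      sample_background, build_features, cross_validate)

scape = make_seascape(SeascapeParams(seed=1))
stacks = scape.env_stacks()
occ = simulate_occurrences(stacks, default_truths(400),
                           default_effort(scape.grid), seed=2)
pres = dedupe_presences(occ, scape.grid, "offshore_thermal", "warm")
bg = sample_background(scape.grid, 1000, seed=3)
fs = build_features(stacks["warm"], pres.n_localities)
cv = cross_validate(pres, bg, fs, k=5, seed=4)
```

This prints (from the example scripts):

```
presence localities after deduplication: 357
cross-validated AUC: 0.748 +/- 0.009
permutation importance (%):
depth          7.7
slope          6.0
dist_shore     4.8
sst           65.0
sst_sd        16.5
SST response optimum: 19.41 degC (the generator placed the thermal band at 19.4 degC)
```

The model beats chance (AUC 0.75), SST carries most of the importance —
matching the generator, which made this species track a 19.4 °C thermal
band — and the response-curve optimum lands on the true value. The overlap
table for the same run:

```
               i                k season  SO_ik        U   df   P
   coastal_slope offshore_thermal   cold  0.522 3168.612 6188 1.0
offshore_thermal    coastal_slope   cold  0.585  960.566 6188 1.0
   coastal_slope offshore_thermal   warm  0.703 1724.406 6188 1.0
offshore_thermal    coastal_slope   warm  0.804  954.853 6188 1.0
```

The index is asymmetric in the expected direction: the narrow offshore
species' distribution is easier to obtain from the broad coastal one
(SO = 0.585 / 0.804) than the reverse (0.522 / 0.703).

The same workflow runs from a shell via the `seaniche` command
(`synth`, `layers`, `fit`, `overlap`, `groups`, `all`, `validate`), driven
by one YAML config with a single master seed; every run writes a manifest
with per-output checksums (see `examples/06_full_pipeline.py`).

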