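# onca

Integrative predator–prey–habitat analysis for conservation monitoring of a
large Neotropical felid (the jaguar, *Panthera onca*) and its prey community,
of the kind run in little-deforested Guiana-Shield forest landscapes. The
package chains four field methodologies into one reproducible, testable
pipeline, and ships a synthetic-landscape generator with known ground truth
so every stage can be validated without access to unreleased field data.

It is written for quantitative ecologists and conservation scientists who
need the individual estimators as library functions, and for survey teams
who want the end-to-end pipeline from a shell.

## What it computes

**Presence-only habitat suitability (maxent).** The model is the Gibbs
distribution over landscape cells, raw(x) ∝ exp(Σⱼ λⱼ fⱼ(x)), fitted by
maximizing the β-regularized presence log-likelihood; at the optimum
|E_raw[fⱼ] − presence mean of fⱼ| ≤ βⱼ for every feature. Features are
linear and quadratic transforms of [0,1]-rescaled continuous layers
(rainfall, altitude, human footprint) plus class indicators (vegetation,
biogeographic unit). Training background can be restricted to the sampled
area to absorb geographic sighting bias; projection covers the full
landscape through the entropy-based logistic transform
e^H·raw/(1 + e^H·raw). Discrimination is rank-based AUC against background,
and significance comes from a 99-replicate random-presence null model: the
observed AUC must beat the 95th-ranked null AUC (p < 0.05).

**Camera-trap density (closed-population CMR).** Encounter histories
(individuals × occasions) feed the M0 estimator (constant capture
probability, joint MLE over N and p) and the Mh Burnham–Overton jackknife
(capture frequencies f₁..f_t, orders 1–5, sequential order selection).
The effective survey area is the station minimum convex polygon dilated by
½MMDM or MMDM — (half) the mean maximum distance moved by individuals
photographed at more than one station — using the exact Steiner formula
area + perimeter·b + πb². Density is D = 100·N̂/A animals per 100 km².

**Line-transect prey indices.** Kilometric index KI = contacts/km
(individuals/km for gregarious species), biomass index B = KI × adult mass,
and an effort-sufficiency diagnostic: correlate KI computed from the first
d km with the full-effort KI across surveys and find the smallest d with
r ≥ 0.9 (for homogeneous Poisson encounters this correlation is exactly
√(d/L)).

**Habitat structure.** Canopy roughness as the 3×3 focal sample SD of an
SRTM-style DEM; waveform extent (signal begin→end elevation distance) from
full-waveform LiDAR returns; per-site summaries over polygons.

**Associations.** Pairwise product–moment correlations with uncorrected
p-values (rank and Holm options behind flags), a random-forest association
scored by out-of-bag prediction correlation, and a priority-area overlay
(HFI < 15 ∧ roughness > 12).

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from onca import landscape, sdm, cmr

# a synthetic 32 x 32 km landscape on 0.5-km cells, with known truth
stack = landscape.generate_layers(seed=1, rows=64, cols=64)
truth = landscape.default_truth(stack)
sightings = landscape.generate_sightings(stack, truth, n=302, bias=True, seed=2)

# presence-only maxent SDM with bias-restricted background
features = sdm.build_features(stack)
cell = (sightings["row"] * stack.cols + sightings["col"]).to_numpy()
row_of = {c: i for i, c in enumerate(features.cell_index)}
presences = np.array([row_of[c] for c in cell])
model, auc = sdm.fit_and_score(features, presences, features.sampling_rows, seed=0)
null = sdm.null_model_test(features, auc, presences.size,
                           features.sampling_rows, seed=1, n_reps=99)
suitability = sdm.project(model, stack, features=features)

# camera-trap survey: 16 stations, 10 occasions, N = 60 with heterogeneity
stations = landscape.station_grid(n_side=4, spacing_km=2.5)
detections = landscape.simulate_cmr(truth, stations, occasions=10, seed=3)
history = cmr.build_encounter_history(detections, occasion_length_nights=1)
estimate = cmr.estimate_mh_jackknife(history)
half, full = cmr.density_from_detections(detections, estimate, stations)
```

Printing the fitted quantities gives:

```
test AUC = 0.563  null 95th = 0.542  significant = True  p = 0.02
Spearman(projected, true suitability) = 0.96
58 individuals identified; Mh-jackknife-1: N = 60.7 (SE 2.3); MMDM = 5.1 km
density: 39.6 / 100 km2 (half-MMDM, 153 km2), 20.8 / 100 km2 (MMDM, 292 km2)
```

Reading: the fitted model discriminates presences from background (AUC
0.563) better than all but ~2 of 99 models fitted to random presences —
significant despite the modest AUC, which is the point of the null-model
calibration on smooth suitability surfaces. The projection ranks cells
almost exactly as the generating truth does (ρ = 0.96). The camera-trap
survey recovers the simulated population (N̂ = 60.7 vs true 60) and shows
the well-known buffer sensitivity: the ½MMDM density is roughly double the
MMDM density, which is why the wider buffer is the recommended design.

The same stages run from a shell:

```bash
onca run --seed 1 --out runs/demo        # full pipeline, all artifacts
onca report --run-dir runs/demo
onca cmr --detections detections.csv --occasions 10 --buffer half,full
```

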