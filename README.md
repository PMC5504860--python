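# myospat

Spatial-pattern analysis of myonuclear migration in time-lapse movies of
remodelled *Drosophila* muscles.

During metamorphosis, persistent abdominal muscles (DIOMs) atrophy while
their nuclei migrate toward the cell centre (*anti-polar* migration),
then regrow while the nuclei return toward the poles (*polar*
migration). Comparing these dynamics across genotypes requires objective
descriptors of where the nuclei are inside the muscle — by eye, subtle
phenotypes are invisible. `myospat` turns a two-channel movie (cytoplasm
+ nuclei) and per-frame muscle boundary polygons into per-timepoint
nuclear-distribution features and group statistics.

## What it computes

The pipeline (each stage is a library module and a CLI subcommand):

1. **Segmentation** — bi-exponential edge-preserving smoothing (BEEPS),
   negative Laplacian-of-Gaussian enhancement at the mean nuclear radius
   (σ = 6 px), saturation thresholding, connected components, and
   removal of blobs outside the muscle boundary.
2. **Tracking** — motion-compensated mutual-nearest-neighbour matching
   with explicit clump split/merge handling; tracks fragment rather than
   guess across ambiguities.
3. **Classification** — each track x is scored with the motion cost
   M(x) = (1/nₓ) Σᵢ Dᵢ(1 − Oᵢ) (Dᵢ centroid displacement, Oᵢ overlap
   fraction per transition); tracks with M(x) > λ = 7 are fast sarcolyte
   ("external") nuclei and are purged, the rest are muscle ("internal")
   nuclei.
4. **Straightening & features** — nuclei are mapped into the muscle's
   medial-axis frame (signed perpendicular offset dx, arc length dy,
   tangent rotation α) and summarized per frame as
   * NSD — convex-hull area of nuclei / muscle area,
   * L_n, NM_lon = L_n/L_c — longitudinal nuclear spread, absolute and
     normalized by muscle length,
   * M_lat, NM_lat — lateral nuclear spread (mean nuclear width along
     the axis), absolute and normalized by the local muscle width.
5. **Statistics** — per-timepoint two-sided Mann-Whitney U between
   genotype groups on a common hours-after-head-eversion grid
   (significant when −log₁₀ p > 1.3), and migration-phase deltas of L_n
   with 95% confidence intervals.

A synthetic-movie generator (`myospat.synthetic`) renders capsule-shaped
muscles with scripted migration programs, drifting geometry, crossing
external nuclei, boundary cross-talk artifacts and imaging noise — with
full ground truth, so every stage can be validated end to end.

## Worked example

```python
from myospat.synthetic import SimConfig, simulate
from myospat.pipeline import PipelineConfig, run_pipeline

cfg = SimConfig(n_frames=50, seed=7)          # scripted anti-polar -> polar program
movie, boundaries, truth = simulate(cfg)
result = run_pipeline(movie, boundaries, PipelineConfig())

cols = ["frame", "time_h_after_HE", "NSD", "Ln_um", "NMlon", "Mlat_um", "NMlat"]
print(result.features[cols].iloc[[0, 22, 46]].round(3).to_string(index=False))
```

```
 frame  time_h_after_HE   NSD   Ln_um  NMlon  Mlat_um  NMlat
     0              0.0 0.340 412.755  0.751   11.250  0.226
    22             11.0 0.137 262.529  0.478   10.911  0.220
    46             23.0 0.263 412.542  0.750   12.904  0.260
```

Frame 0 is the pre-migration state: the nuclei span 75% of the muscle
(NM_lon = 0.75). By frame 22 (+11 h after head eversion) anti-polar
migration has pulled them toward the centre — L_n has dropped by
~150 µm and NSD has fallen accordingly. By frame 46 polar migration has
restored the original spread. M_lat stays near one nuclear diameter
throughout: a single-row arrangement. The three external nuclei that
cross the muscle are caught by their motion cost, e.g.

```python
[r for r in result.summary if r["class"] == "external"]
# track 14: frames 23-30, M = 10.6 px/transition, mean speed 27.7 um/h
```

well above λ = 7, while every internal track stays far below it.

The same pipeline runs from the shell:

```sh
myospat simulate --out fixture --seed 7
myospat run --movie fixture/movie.tif --boundaries fixture/boundaries.json --out results
myospat stats --group-a a1.csv --group-a a2.csv --group-b b1.csv --group-b b2.csv \
        --feature Ln_um --out stats.csv
myospat sweep-lambda --out sweep.csv
```

`run` writes `features.csv`, the T-by-X track table, per-transition
displacements/overlaps, per-track summaries, geometry and the resolved
configuration next to the outputs.

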