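# ohsa — road-crash blackspot detection by optimized hot-spot analysis

`ohsa` is a Python implementation of the optimized hot-spot analysis (OHSA)
workflow for road-traffic-safety studies: it takes geocoded crash events
(projected x/y in meters, tagged by participant type and severity), grids
them onto a fishnet of square cells, selects an analysis scale by
incremental spatial autocorrelation, classifies cells into confidence-tiered
hot/cold spots with the Getis-Ord Gi\* statistic, and summarizes regional
road safety with the RBT blackspot-ratio index. It is written for traffic
engineers, spatial epidemiologists and safety researchers who want the
workflow as a reproducible, scriptable library rather than a GIS desktop
tool — including a synthetic-data generator with planted ground truth so
every stage can be validated without confidential crash records.

## Method

1. **Cleaning.** Events whose distance to their nearest *non-coincident*
   neighbor exceeds mean + 3·SD of all such distances are removed as
   location outliers (coincident duplicates never shield each other).
2. **Rasterization.** A fishnet of square cells (default 200 m) is laid
   over the region polygons; each cell carries per-type crash counts
   \(x_i\) and the region of largest overlap. Zero-count cells inside the
   boundary are retained and enter the spatial-unit total \(D_n\).
3. **Scale selection.** Global Moran's I,

   $$I = \frac{D_n \sum_i \sum_j w_{ij}(x_i-\bar x)(x_j-\bar x)}{S_0 \sum_j (x_j-\bar x)^2},\qquad S_0=\sum_i\sum_j w_{ij},$$

   is evaluated over binary distance-band weights for band distances from
   500 m to 3.5 km in 100 m steps. Each I is converted to a z-score with
   the exact expectation \(E[I]=-1/(D_n-1)\) and the
   randomization-assumption variance; the distance with the highest
   z-score is the optimal analysis scale.
4. **Local statistic.** At that scale, with the focal cell included in its
   own neighborhood, each cell's Gi\* is

   $$G_i^* = \frac{\sum_j w_{ij}x_j - \bar x\sum_j w_{ij}}{S\sqrt{\left[n\sum_j w_{ij}^2 - \left(\sum_j w_{ij}\right)^2\right]/(n-1)}},\qquad S=\sqrt{\tfrac1n\sum_j x_j^2-\bar x^2},$$

   directly a z-score. Two-tailed p-values are Benjamini–Hochberg
   FDR-corrected, and cells are binned into seven tiers (hot/cold at
   90/95/99%, z cuts 1.65/1.96/2.58). A **blackspot** is a 99% hotspot
   (z > 2.58 and adjusted p < 0.01).
5. **Regional summary.** Per region c and crash type v,
   \(\mathrm{RBT}_{c,v} = Bn_{c,v}/Dn_{c,v}\): the share of the region's
   cells occupied by blackspots. RBT is validated against per-region crash
   counts by simple linear correlation.

Crash types follow the two standard axes: participants
{UA, MMA, MNA, MPA, NNA, NPA} and severity {MA, OA, SA}.

## Worked example

```python
from ohsa import *

regions = generate_regions(4, 6000.0, seed=7)          # 4 rectangular regions, 6 km extent
cfg = SimulationConfig(
    n_events=2500, background_fraction=0.5,
    clusters=[ClusterSpec((1500.0, 1500.0), 400.0, 0.5),
              ClusterSpec((4500.0, 4500.0), 700.0, 0.5)],
    seed=21)
events, truth = generate_events(regions, cfg)

lat = make_fishnet(regions, cell_size=200.0)
assign_counts(lat, events, "MMA")

scan = incremental_scan(lat, "MMA")                    # 500-3500 m, 100 m steps
d_opt, significant = select_peak(scan)
print(f"optimal scale distance: {d_opt:.0f} m (peak significant: {significant})")

w = distance_band_weights(lat, d_opt, include_self=True)
cls = classify(lat.values("MMA"), w, index=lat.cells.index)
spots = extract_blackspots(cls)
print(f"{len(spots)} blackspot cells of {lat.n_units}")
for rec in rbt_index(spots, lat, "MMA"):
    print(f"  {rec.region}: RBT = {rec.bn}/{rec.dn} = {rec.rbt:.4f}")
```

Output:

```
optimal scale distance: 900 m (peak significant: True)
203 blackspot cells of 900
  R00: RBT = 96/374 = 0.2567
  R01: RBT = 43/286 = 0.1503
  R02: RBT = 0/136 = 0.0000
  R03: RBT = 64/104 = 0.6154
```

The scan picks 900 m — between the two planted cluster scales (400 and
700 m sd) — as the band distance of strongest clustering. Both planted
clusters are recovered as contiguous blackspot fields; R02, which contains
no cluster center, has RBT 0, while R03 (small region, dense cluster) has
the worst safety level.

The same pipeline is available from the shell:

```sh
ohsa simulate --n-events 2500 --n-regions 4 --extent 6000 --seed 21 --out study/
ohsa run-all --events study/events.csv --regions study/regions.geojson \
             --axis participant --tier 99 --out study/results/
```

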