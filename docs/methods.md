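# Methods

## Scope and model

The package detects *blackspots* — grid cells where crashes of a given
type cluster beyond what spatial randomness explains — and scores regions
by how widespread those cells are. The analysis chain is: event cleaning →
fishnet rasterization → scale selection by incremental spatial
autocorrelation (Global Moran's I) → local Getis-Ord Gi\* classification
with FDR control → RBT regional summary. All coordinates are assumed to be
projected planar meters; no CRS handling is performed or attempted.

## Event cleaning

The location-outlier rule applies the 3-sigma principle to
nearest-neighbor spacing: for each event we take the distance to its
nearest *non-coincident* neighbor (exact coordinate duplicates share the
distance of their location to the nearest different location, so
duplicated outliers cannot shield each other), and remove events whose
distance exceeds mean + 3·SD of all such distances. The rule runs in a
single pass. Re-running it on cleaned output recomputes the statistics and
may remove further points; iteration to a fixed point is deliberately not
performed, as it has no principled stopping justification and the single
pass already removes the geocoding failures the rule targets. With fewer
than 3 events, or all events coincident, the input is returned unchanged
with a warning.

## Fishnet and counts

Cells are axis-aligned squares (default 200 m, a block-scale resolution
for urban crash mapping) anchored at the minimum corner of the regions'
bounding box. A cell is retained iff it overlaps some region with positive
area and is assigned the region of largest overlap (ties: first region in
input order), so cells partition exactly into regions and RBT denominators
add up. Zero-count cells inside boundaries are retained: they carry "low"
information for Gi\* and belong in the spatial-unit count Dn. (A
sensitivity variant that drops empty cells can be had by filtering the
lattice frame before analysis; the retained-all convention is the package
default and the one all tests pin.) Point-in-cell assignment uses
half-open intervals [x0+c·s, x0+(c+1)·s) in both axes, so a point on a
shared edge lands deterministically in the higher-index cell and every
point lands in exactly one cell. Events outside retained cells are counted
into a spill report, never silently dropped.

## Spatial weights

Binary distance-band weights on cell centroids: w_ij = 1 iff
dist(i,j) ≤ d, i ≠ j, with the diagonal set by `include_self`. The
threshold is inclusive and centroid-to-centroid, matching common GIS
convention. Weights are never row-standardized — the Moran and Gi\*
formulas used here are their binary-weight forms. Moran's I uses
include_self=False; Gi\* uses include_self=True (the "star" variant counts
the focal cell in its own neighborhood). On a 200 m lattice, d = 200
yields rook contiguity (diagonal centroids are ~282.8 m apart); d = 300
yields queen contiguity.

## Moran inference and the incremental scan

E[I] = −1/(Dn−1) exactly. The variance is the standard
randomization-assumption (permutation-moment) closed form with
S1 = ½·Σ(w_ij+w_ji)², S2 = Σ(w_i·+w_·i)² and the sample kurtosis b2; a
2,000-shuffle permutation oracle referees both moments in the tests. The
z-score is (I−E[I])/√Var[I] with two-tailed normal p (hot and cold
departures are both meaningful). The scan ladder defaults to 500–3500 m in
100 m steps (31 distances); band distances where the statistic is
undefined (empty neighborhoods, degenerate variance) are recorded as
skipped. The optimal scale is the global argmax of z, first occurrence on
ties, flagged insignificant (with a warning, never an error) if the peak z
is below 1.96. No smoothing or local-peak detection is applied to the
z-vs-distance curve. The scan operates on gridded counts, not raw points,
so the selected scale refers to inter-cell distances.

## Gi\* classification

Gi\* is evaluated in its binary-weight z-score form with the global mean
and S over all Dn cells. Degenerate cells — a neighborhood covering the
entire lattice makes the statistic 0/0 — are reported as NaN, excluded
from the multiple-testing family, and never classified. Two-tailed
p-values are adjusted by Benjamini–Hochberg step-up (via statsmodels);
tier binning then requires *both* the z cut and the adjusted-p condition
(99%: z > 2.58 ∧ p_adj < 0.01; 95%: 1.96 < z ≤ 2.58 ∧ p_adj < 0.05; 90%:
1.65 < z ≤ 1.96 ∧ p_adj < 0.1; mirrored for coldspots). Inequalities are
strict exactly as printed, so a value sitting on a threshold falls to the
lower tier. The 90% cut of 1.65 is the GIS-tooling convention, not the
true quantile 1.645. With Gaussian p the p-condition is nearly redundant
before correction and binding after it. A worth-knowing consequence of the
global S in the denominator: a *single* extreme cell inflates S and caps
its own z-score (one cell at 50 among 1s on a 5×5 rook lattice scores
exactly 2.0); blackspot status requires an elevated neighborhood, which is
the intended semantics of a hot spot. Inference is analytic-normal only;
conditional permutation inference for Gi\* is out of scope.

## RBT and correlation

RBT_{c,v} = Bn_{c,v}/Dn_{c,v} with Dn counting all cells of the region
(consistent with the retained-all lattice convention). "Binary
correlation" between RBT and per-region counts is implemented as simple
OLS / squared Pearson correlation, which is scale- and shift-invariant in
either variable. Cleaned (not raw) counts are used. Regions with fewer
than 3 paired observations, or zero variance in either variable, raise
errors rather than returning fragile numbers.

## Synthetic data generator

The generator emulates a prefecture-scale study: rectangular regions tiling
a square extent (random interior cut positions; real administrative shapes
add nothing to the statistics under test), and a crash point process that
is a mixture of a uniform background over the region union and
Gaussian-offspring (Thomas-like) clusters around fixed centers, with
cluster sd on the 0.3–3 km scale of urban travel modes. Clustered points
falling outside the study area are rejection-resampled, not clipped, to
avoid edge pile-ups. Participant-type and severity labels are drawn
independently of location from the observed one-year mixtures
(MMA-dominant, 65.7%; minor severity 94%). One root seed drives
deterministic sub-streams per stage, so a fixed config is bit-reproducible.

What the generator does *not* emulate: road-network constraint (crashes on
a lattice of streets, not free 2-D space), spatially varying background
intensity, label-location dependence (e.g. pedestrian crashes at
intersections), and any temporal structure. Passing tests therefore show
that the pipeline recovers planted planar Gaussian clusters at the correct
scale — not that it would resolve network-constrained clustering, where
planar distance bands are known to over-smooth.

## Study conditions used by the tests and the acceptance script

Problem sizes are chosen so the full suite runs in about a minute while
keeping Monte-Carlo error well inside the asserted bands: CSR spacing uses
400 events × 200 replicates with toroidal nearest-neighbor distances on
the square (the Clark–Evans closed form 0.5/√(n/A) is exact on a torus;
bounded-region edge bias would otherwise dominate); Moran calibration uses
an 8×8 lattice with 2,000 permutations; Gi\* type-I uses 800 multinomial
events on 400 cells, band 2 cell-widths, 200 replicates (observed
upper-tail rate ≈ 0.007 against the analytic 0.005 — slightly inflated by
spatial dependence and discreteness, inside the tolerated [0.001, 0.015]);
blackspot recovery plants one 200 m-sd cluster of 200 events over 400
background events on 400 cells; scale tracking plants clusters of sd 300,
600 and 1200 m at 70% cluster share. The RBT-coupling scenario uses an
equal-area 3×3 region mosaic: with unequal region areas the RBT
denominator confounds the planted intensity–count relationship that the
scenario exists to measure.

## Numerical conventions and degenerate inputs

Constant values (zero variance) make both statistics undefined and raise
errors; all-zero weights likewise. Percent shares in the contingency
summary print with one decimal, two decimals below 1%. Distance-band
construction uses a KD-tree with inclusive radius; brute-force all-pairs
loops referee it in tests up to 20×20 lattices. The pipeline isolates
failures per crash type (a sparse severity class with a handful of events
may legitimately yield degenerate statistics) and fails only when every
type fails; manifests record SHA-256 checksums of every artifact, and
repeated seeded runs are byte-identical.

## Known limitations

- Planar distance bands; no network-constrained kernel or weights.
- Analytic normal inference for Gi\* (no conditional randomization).
- Fishnet cells only; hexagonal or administrative spatial units are not
  implemented, and blackspot shape is confined to the cell geometry.
- The BH-then-gate FDR scheme is one defensible reading of "FDR-corrected
  tiers"; tier-wise joint schemes would differ in borderline cells.
- Single cross-section; no temporal dimension.
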