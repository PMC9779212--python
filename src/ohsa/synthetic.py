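"""Synthetic crash-event generator with known ground-truth cluster structure.

Every downstream stage of the blackspot pipeline (gridding, Moran scan,
Gi* classification, RBT summary) is testable against patterns whose
clustering is planted by construction: a uniform Poisson-like background
plus Gaussian-offspring (Thomas-like) clusters around fixed centers.

Defaults emulate a prefecture-scale study: a multi-region rectangular
study area, a participant-type mixture matching the observed one-year
crash record (motor-vehicle collisions dominate at ~66%), and cluster
standard deviations on the 0.3-3 km scale of urban travel modes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box, shape, mapping

__all__ = [
    "PARTICIPANT_TYPES",
    "SEVERITIES",
    "TYPE_MIXTURE",
    "SEVERITY_MIXTURE",
    "RegionSet",
    "ClusterSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate_regions",
    "generate_events",
    "plant_truth_cells",
]

PARTICIPANT_TYPES = ("UA", "MMA", "MNA", "MPA", "NNA", "NPA")
SEVERITIES = ("MA", "OA", "SA")

#: Participant-type mixture observed in the one-year crash record
#: (unilateral 11.1%, motor-motor 65.7%, motor-nonmotor 14.9%,
#: motor-pedestrian 3.4%, nonmotor-nonmotor 3.1%, nonmotor-pedestrian 1.8%).
TYPE_MIXTURE = {
    "UA": 0.111,
    "MMA": 0.657,
    "MNA": 0.149,
    "MPA": 0.034,
    "NNA": 0.031,
    "NPA": 0.018,
}

#: Severity mixture: minor 94.0%, ordinary 5.69%, serious 0.31%.
SEVERITY_MIXTURE = {"MA": 0.940, "OA": 0.0569, "SA": 0.0031}


@dataclass(frozen=True)
class RegionSet:
    """Administrative regions as planar polygons in projected meters."""

    regions: list[tuple[str, Polygon]]

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        for rid, poly in self.regions:
            if not poly.is_valid or poly.area <= 0:
                raise ValueError(f"region {rid!r} must be a simple polygon with positive area")

    @property
    def region_ids(self) -> list[str]:
        return [rid for rid, _ in self.regions]

    @property
    def union(self):
        from shapely.ops import unary_union

        return unary_union([poly for _, poly in self.regions])

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.union.bounds

    def to_geojson(self, path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"region_id": rid},
                "geometry": mapping(poly),
            }
            for rid, poly in self.regions
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path) -> "RegionSet":
        with open(path) as fh:
            fc = json.load(fh)
        regions = [
            (feat["properties"]["region_id"], shape(feat["geometry"]))
            for feat in fc["features"]
        ]
        return cls(regions)


@dataclass(frozen=True)
class ClusterSpec:
    """One planted Gaussian cluster: center (m), isotropic sd (m), mixture weight."""

    center: tuple[float, float]
    sd: float
    weight: float


@dataclass
class SimulationConfig:
    """Parameters of the background-plus-clusters crash point process."""

    n_events: int
    background_fraction: float = 1.0
    clusters: list[ClusterSpec] = field(default_factory=list)
    type_mixture: dict[str, float] = field(default_factory=lambda: dict(TYPE_MIXTURE))
    severity_mixture: dict[str, float] = field(default_factory=lambda: dict(SEVERITY_MIXTURE))
    seed: int = 0

    def validate(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be non-negative")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must lie in [0, 1]")
        for mix, name in ((self.type_mixture, "type_mixture"), (self.severity_mixture, "severity_mixture")):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
        if self.clusters:
            wsum = sum(c.weight for c in self.clusters)
            if abs(wsum - 1.0) > 1e-9:
                raise ValueError(f"cluster weights must sum to 1 (got {wsum})")
            for c in self.clusters:
                if c.sd <= 0:
                    raise ValueError("cluster sd must be positive")
        elif self.background_fraction < 1.0:
            raise ValueError("background_fraction < 1 requires at least one cluster")


@dataclass
class GroundTruth:
    """Which events were planted by which cluster.

    ``assignment`` maps event_id -> cluster index; background events are
    absent from the mapping.  Clustered event coordinates are kept so
    planted-truth cells can be recomputed after any gridding.
    """

    assignment: dict[str, int]
    clustered_xy: pd.DataFrame  # columns: event_id, x, y, cluster

    @classmethod
    def empty(cls) -> "GroundTruth":
        return cls({}, pd.DataFrame(columns=["event_id", "x", "y", "cluster"]))

    def to_csv(self, path) -> None:
        self.clustered_xy.to_csv(path, index=False)


def generate_regions(n_regions: int, extent: float, seed: int = 0) -> RegionSet:
    """Tile part of the square [0, extent)^2 with non-overlapping rectangles.

    The extent is cut into a ceil(sqrt(n)) x ceil(sqrt(n)) mosaic with
    seed-dependent cut positions; the first ``n_regions`` tiles (row-major)
    become regions.  Deterministic for a fixed seed.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if extent <= 0:
        raise ValueError("extent must be positive")
    if n_regions == 1:
        return RegionSet([("R00", box(0.0, 0.0, extent, extent))])

    rng = np.random.default_rng(seed)
    k = int(np.ceil(np.sqrt(n_regions)))
    # random interior cut fractions, kept away from edges to preserve area
    xcuts = np.concatenate(([0.0], np.sort(rng.uniform(0.2, 0.8, k - 1)), [1.0])) * extent
    ycuts = np.concatenate(([0.0], np.sort(rng.uniform(0.2, 0.8, k - 1)), [1.0])) * extent
    regions = []
    for idx in range(n_regions):
        r, c = divmod(idx, k)
        poly = box(xcuts[c], ycuts[r], xcuts[c + 1], ycuts[r + 1])
        regions.append((f"R{idx:02d}", poly))
    return RegionSet(regions)


def _sample_in_union(rng, n, regions: RegionSet, propose):
    """Rejection-sample n points into the union of regions.

    ``propose(rng, m)`` returns an (m, 2) array of candidate points.
    Also returns the region_id of each accepted point.
    """
    from shapely import intersects_xy

    union = regions.union
    xs = np.empty(n)
    ys = np.empty(n)
    got = 0
    guard = 0
    while got < n:
        m = max(4 * (n - got), 16)
        cand = propose(rng, m)
        ok = intersects_xy(union, cand[:, 0], cand[:, 1])  # boundary-inclusive
        accepted = cand[ok]
        take = min(n - got, len(accepted))
        xs[got : got + take] = accepted[:take, 0]
        ys[got : got + take] = accepted[:take, 1]
        got += take
        guard += 1
        if guard > 1000:
            raise RuntimeError("rejection sampling failed to place points inside regions")
    return xs, ys


def _assign_region(regions: RegionSet, xs, ys) -> np.ndarray:
    from shapely import contains_xy

    out = np.full(len(xs), "", dtype=object)
    unassigned = np.ones(len(xs), dtype=bool)
    for rid, poly in regions.regions:
        if not unassigned.any():
            break
        idx = np.where(unassigned)[0]
        inside = contains_xy(poly, xs[idx], ys[idx])
        out[idx[inside]] = rid
        unassigned[idx[inside]] = False
    if unassigned.any():
        # boundary points: assign to the first region whose closure contains them
        from shapely.geometry import Point

        for i in np.where(unassigned)[0]:
            p = Point(xs[i], ys[i])
            for rid, poly in regions.regions:
                if poly.distance(p) < 1e-9:
                    out[i] = rid
                    break
    return out.astype(str)


def generate_events(regions: RegionSet, config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a crash EventSet from uniform background plus Gaussian clusters.

    Returns the event table (event_id, x, y, region_id, participant_type,
    severity) and the GroundTruth mapping clustered events to their cluster.
    Clustered points falling outside the study area are rejection-resampled
    (no coordinate truncation, so no edge pile-ups).  Bit-reproducible for a
    fixed config seed.
    """
    config.validate()
    from shapely import intersects_xy

    union = regions.union
    for c in config.clusters:
        if not intersects_xy(union, c.center[0], c.center[1]):
            raise ValueError(f"cluster center {c.center} lies outside all regions")

    n = config.n_events
    cols = ["event_id", "x", "y", "region_id", "participant_type", "severity"]
    if n == 0:
        return pd.DataFrame(columns=cols), GroundTruth.empty()

    root = np.random.default_rng(config.seed)
    rng_src, rng_xy, rng_label = (np.random.default_rng(s) for s in root.integers(0, 2**31, 3))

    # source of each event: -1 background, k >= 0 cluster index
    probs = [config.background_fraction] + [
        (1.0 - config.background_fraction) * c.weight for c in config.clusters
    ]
    probs = np.asarray(probs) / sum(probs)
    source = rng_src.choice(len(probs), size=n, p=probs) - 1

    xs = np.empty(n)
    ys = np.empty(n)
    bg = source == -1
    if bg.any():
        (x0, y0, x1, y1) = regions.bounds

        def propose_bg(r, m):
            return np.column_stack([r.uniform(x0, x1, m), r.uniform(y0, y1, m)])

        xs[bg], ys[bg] = _sample_in_union(rng_xy, int(bg.sum()), regions, propose_bg)
    for k, c in enumerate(config.clusters):
        sel = source == k
        if not sel.any():
            continue

        def propose_cl(r, m, c=c):
            return c.center + r.normal(0.0, c.sd, size=(m, 2))

        xs[sel], ys[sel] = _sample_in_union(rng_xy, int(sel.sum()), regions, propose_cl)

    types = rng_label.choice(
        list(config.type_mixture), size=n, p=list(config.type_mixture.values())
    )
    sevs = rng_label.choice(
        list(config.severity_mixture), size=n, p=list(config.severity_mixture.values())
    )
    event_ids = np.array([f"E{i:06d}" for i in range(n)])
    events = pd.DataFrame(
        {
            "event_id": event_ids,
            "x": xs,
            "y": ys,
            "region_id": _assign_region(regions, xs, ys),
            "participant_type": types,
            "severity": sevs,
        }
    )
    clustered = source >= 0
    truth = GroundTruth(
        assignment={eid: int(s) for eid, s in zip(event_ids[clustered], source[clustered])},
        clustered_xy=pd.DataFrame(
            {
                "event_id": event_ids[clustered],
                "x": xs[clustered],
                "y": ys[clustered],
                "cluster": source[clustered].astype(int),
            }
        ).reset_index(drop=True),
    )
    return events, truth


def plant_truth_cells(truth: GroundTruth, lattice, min_events: int) -> set[int]:
    """Cells of ``lattice`` holding at least ``min_events`` planted (clustered) events.

    The acceptance surface for blackspot recovery: a detector should flag
    these cells.  Empty set when nothing was planted or the threshold is
    unattainable.
    """
    if len(truth.clustered_xy) == 0 or min_events > len(truth.clustered_xy):
        return set()
    cell_ids = lattice.locate(truth.clustered_xy["x"].to_numpy(), truth.clustered_xy["y"].to_numpy())
    counts: dict[int, int] = {}
    for cid in cell_ids:
        if cid >= 0:
            counts[cid] = counts.get(cid, 0) + 1
    return {cid for cid, c in counts.items() if c >= min_events}
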