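"""Fishnet lattice: square-cell rasterization of the study area.

Cells are axis-aligned squares (default 200 m) anchored at the minimum
corner of the regions' bounding box.  A cell is retained iff it overlaps a
region with positive area, and carries the region of largest overlap, so
cells partition cleanly into regions for per-region summaries.  Zero-count
cells inside the boundary are retained: they carry legitimate "low"
information for the local statistics and enter the spatial-unit total Dn.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping

from .synthetic import RegionSet

__all__ = ["CountLattice", "make_fishnet", "assign_counts", "ALL_TYPES"]

ALL_TYPES = "ALL"


@dataclass
class CountLattice:
    """Fishnet cells with per-crash-type event counts.

    ``cells`` is indexed by integer cell_id with columns row, col, cx, cy
    (centroid, meters) and region_id.  ``counts`` maps a crash type (or
    "ALL") to a count vector aligned with ``cells``.
    """

    cell_size: float
    origin: tuple[float, float]
    cells: pd.DataFrame
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    spill: dict[str, int] = field(default_factory=dict)

    _rc_to_id: dict[tuple[int, int], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._rc_to_id:
            self._rc_to_id = {
                (int(r), int(c)): int(cid)
                for cid, r, c in zip(self.cells.index, self.cells["row"], self.cells["col"])
            }

    @property
    def n_units(self) -> int:
        """Dn: the number of spatial units."""
        return len(self.cells)

    @property
    def centroids(self) -> np.ndarray:
        return self.cells[["cx", "cy"]].to_numpy(float)

    def values(self, crash_type: str = ALL_TYPES) -> np.ndarray:
        return self.counts[crash_type]

    def mean(self, crash_type: str = ALL_TYPES) -> float:
        return float(self.values(crash_type).mean())

    def cell_polygon(self, cell_id: int):
        r = self.cells.loc[cell_id]
        x0 = self.origin[0] + r["col"] * self.cell_size
        y0 = self.origin[1] + r["row"] * self.cell_size
        return box(x0, y0, x0 + self.cell_size, y0 + self.cell_size)

    def locate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Map points to cell ids by the half-open convention; -1 = outside."""
        col = np.floor((np.asarray(x, float) - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y, float) - self.origin[1]) / self.cell_size).astype(int)
        return np.array(
            [self._rc_to_id.get((int(r), int(c)), -1) for r, c in zip(row, col)], dtype=int
        )

    def to_geojson(self, path) -> None:
        features = []
        for cid in self.cells.index:
            props = {"cell_id": int(cid), "region_id": self.cells.loc[cid, "region_id"]}
            for t, v in self.counts.items():
                props[f"count_{t}"] = int(v[self.cells.index.get_loc(cid)])
            features.append(
                {"type": "Feature", "properties": props, "geometry": mapping(self.cell_polygon(cid))}
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    def counts_frame(self) -> pd.DataFrame:
        out = self.cells[["row", "col", "cx", "cy", "region_id"]].copy()
        for t, v in self.counts.items():
            out[f"count_{t}"] = v
        out.index.name = "cell_id"
        return out


def make_fishnet(regions: RegionSet, cell_size: float = 200.0) -> CountLattice:
    """Lay a square fishnet over the regions' bounding box.

    Retains cells overlapping a region with positive area; assigns each to
    the region of largest overlap (ties broken by region order).
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if not regions.regions:
        raise ValueError("empty RegionSet")
    x0, y0, x1, y1 = regions.bounds
    eps = 1e-9 * max(x1 - x0, y1 - y0, 1.0)
    ncols = max(1, int(np.ceil((x1 - x0 - eps) / cell_size)))
    nrows = max(1, int(np.ceil((y1 - y0 - eps) / cell_size)))

    region_bounds = [(rid, poly, poly.bounds) for rid, poly in regions.regions]
    rows, cols, cxs, cys, rids = [], [], [], [], []
    for r in range(nrows):
        cy0 = y0 + r * cell_size
        for c in range(ncols):
            cx0 = x0 + c * cell_size
            cell = None
            best_rid, best_area = None, 0.0
            for rid, poly, (bx0, by0, bx1, by1) in region_bounds:
                if cx0 >= bx1 or cx0 + cell_size <= bx0 or cy0 >= by1 or cy0 + cell_size <= by0:
                    continue  # bbox prefilter: no positive-area overlap possible
                if cell is None:
                    cell = box(cx0, cy0, cx0 + cell_size, cy0 + cell_size)
                a = cell.intersection(poly).area
                if a > best_area:
                    best_rid, best_area = rid, a
            if best_rid is not None:
                rows.append(r)
                cols.append(c)
                cxs.append(cx0 + cell_size / 2)
                cys.append(cy0 + cell_size / 2)
                rids.append(best_rid)

    cells = pd.DataFrame(
        {"row": rows, "col": cols, "cx": cxs, "cy": cys, "region_id": rids}
    )
    cells.index.name = "cell_id"
    lat = CountLattice(cell_size=float(cell_size), origin=(float(x0), float(y0)), cells=cells)
    lat.counts[ALL_TYPES] = np.zeros(len(cells), dtype=int)
    return lat


def assign_counts(
    lattice: CountLattice, events: pd.DataFrame, type_filter: str = ALL_TYPES
) -> CountLattice:
    """Aggregate events of one crash type (or ALL) into lattice cells.

    Point-in-cell uses half-open intervals, so every event lands in exactly
    one cell; events outside retained cells go to the spill report.
    """
    if type_filter == ALL_TYPES:
        sub = events
    elif type_filter in ("MA", "OA", "SA"):
        sub = events[events["severity"] == type_filter]
    else:
        sub = events[events["participant_type"] == type_filter]
    counts = np.zeros(lattice.n_units, dtype=int)
    spill = 0
    if len(sub):
        ids = lattice.locate(sub["x"].to_numpy(float), sub["y"].to_numpy(float))
        inside = ids >= 0
        spill = int((~inside).sum())
        pos = lattice.cells.index.get_indexer(ids[inside])
        np.add.at(counts, pos, 1)
    if spill:
        warnings.warn(f"{spill} events of type {type_filter} fell outside the lattice", stacklevel=2)
    lattice.counts[type_filter] = counts
    lattice.spill[type_filter] = spill
    return lattice
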