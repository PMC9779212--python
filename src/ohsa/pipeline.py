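"""End-to-end orchestration: ingest -> grid -> scan -> Gi* -> blackspots -> RBT.

``run_all`` executes the whole analysis independently for every crash type
on the chosen classification axis (participant: 6 types, severity: 3),
writing per-type artifacts and a manifest with checksums.  A failure in
one type (e.g. a sparse severity class with degenerate statistics) aborts
that type only; the run fails only when every type fails.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import hotspot, ingest, moran, rbt
from .lattice import assign_counts, make_fishnet
from .synthetic import PARTICIPANT_TYPES, SEVERITIES, RegionSet
from .weights import distance_band_weights

__all__ = ["PipelineConfig", "PipelineResult", "run_all"]


@dataclass
class PipelineConfig:
    events_path: str
    regions_path: str
    output_dir: str
    cell_size: float = 200.0
    d_min: float = 500.0
    d_max: float = 3500.0
    step: float = 100.0
    tier: int = 99
    axis: str = "participant"  # or "severity"
    seed: int = 0

    def validate(self) -> None:
        if min(self.cell_size, self.d_min, self.step) <= 0 or self.d_max < self.d_min:
            raise ValueError("cell_size, scan distances and step must be positive, d_max >= d_min")
        if self.tier not in (90, 95, 99):
            raise ValueError("tier must be one of 90, 95, 99")
        if self.axis not in ("participant", "severity"):
            raise ValueError("axis must be 'participant' or 'severity'")


@dataclass
class PipelineResult:
    manifest: dict
    per_type: dict[str, dict] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return bool(self.per_type)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> PipelineResult:
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    events, report = ingest.read_events(config.events_path)
    regions = RegionSet.from_geojson(config.regions_path)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cleaned, removed = ingest.remove_location_outliers(events)
        log.extend(str(w.message) for w in caught)
    cleaned.to_csv(out / "events_cleaned.csv", index=False)
    removed.to_csv(out / "events_removed.csv", index=False)
    ingest.crosstab(cleaned).to_frame().to_csv(out / "crosstab.csv")

    lattice = make_fishnet(regions, cell_size=config.cell_size)
    types = PARTICIPANT_TYPES if config.axis == "participant" else SEVERITIES
    tier_bin = {90: 1, 95: 2, 99: 3}[config.tier]

    result = PipelineResult(manifest={})
    scan_rows = []
    rbt_frames = []
    for t in types:
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                assign_counts(lattice, cleaned, t)
                scan = moran.incremental_scan(
                    lattice, t, d_min=config.d_min, d_max=config.d_max, step=config.step
                )
                d_opt, significant = moran.select_peak(scan)
                w = distance_band_weights(lattice, d_opt, include_self=True)
                cls = hotspot.classify(lattice.values(t), w, index=lattice.cells.index)
                spots = set(cls.table.index[cls.table["bin"] >= tier_bin])
                records = rbt.rbt_index(spots, lattice, t)
            log.extend(f"[{t}] {w.message}" for w in caught)
            log.append(f"[{t}] selected distance {d_opt:.0f} m (significant={significant})")

            scan_df = scan.to_frame()
            scan_df.insert(0, "crash_type", t)
            scan_rows.append(scan_df)
            cls.table.to_csv(out / f"hotspots_{t}.csv")
            rbt_df = rbt.records_frame(records)
            rbt_frames.append(rbt_df)
            result.per_type[t] = {
                "optimal_distance_m": d_opt,
                "peak_significant": significant,
                "n_blackspots": len(spots),
                "classification": cls,
                "rbt": records,
            }
        except (ValueError, KeyError) as exc:
            result.failures[t] = str(exc)
            log.append(f"[{t}] FAILED: {exc}")

    if scan_rows:
        pd.concat(scan_rows, ignore_index=True).to_csv(out / "scan.csv", index=False)
    if rbt_frames:
        pd.concat(rbt_frames, ignore_index=True).to_csv(out / "rbt.csv", index=False)
    (out / "run.log").write_text("\n".join(log) + "\n")

    artifacts = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    result.manifest = {
        "config": {k: getattr(config, k) for k in vars(config)},
        "n_events_in": len(events),
        "n_rejected_rows": report.n_rejected,
        "n_removed_outliers": len(removed),
        "types_ok": sorted(result.per_type),
        "types_failed": sorted(result.failures),
        "files": {p.name: _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
    if not result.ok:
        raise RuntimeError(f"all crash types failed: {result.failures}")
    return result
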