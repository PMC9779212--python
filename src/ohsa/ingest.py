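"""Crash-event ingestion: reading, validation, outlier cleaning, and summary.

The cleaning rule follows standard hot-spot-analysis practice: an event is a
location outlier when its distance to the nearest *non-coincident* neighbor
exceeds the mean of all such distances by more than three standard
deviations (the 3-sigma principle applied to nearest-neighbor distances).
Coincident duplicates never shield each other from the rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .synthetic import PARTICIPANT_TYPES, SEVERITIES

__all__ = [
    "EVENT_COLUMNS",
    "IngestReport",
    "CrosstabSummary",
    "read_events",
    "remove_location_outliers",
    "nearest_noncoincident_distances",
    "crosstab",
    "format_share",
]

EVENT_COLUMNS = ["event_id", "x", "y", "region_id", "participant_type", "severity"]


@dataclass
class IngestReport:
    """Rows rejected during parsing, with reasons."""

    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS + ["reason"])
    )

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def read_events(path) -> tuple[pd.DataFrame, IngestReport]:
    """Read a delimited event table, validating enums and coordinates.

    Invalid rows (bad participant_type/severity, non-finite coordinates,
    duplicate event_id) are collected into the report; valid rows load.
    A missing required column raises ``ValueError``.
    """
    df = pd.read_csv(path, dtype={"event_id": str, "region_id": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event file is missing required columns: {missing}")
    df = df[EVENT_COLUMNS]
    if df.empty:
        warnings.warn("event file contains no data rows", stacklevel=2)
        return df, IngestReport()

    x = pd.to_numeric(df["x"], errors="coerce")
    y = pd.to_numeric(df["y"], errors="coerce")
    bad_coord = ~(np.isfinite(x) & np.isfinite(y))
    bad_type = ~df["participant_type"].isin(PARTICIPANT_TYPES)
    bad_sev = ~df["severity"].isin(SEVERITIES)
    dup_id = df["event_id"].duplicated(keep="first")

    reason = np.select(
        [bad_coord, bad_type, bad_sev, dup_id],
        ["non-finite coordinate", "invalid participant_type", "invalid severity", "duplicate event_id"],
        default="",
    )
    bad = reason != ""
    rejected = df[bad].copy()
    rejected["reason"] = reason[bad]
    clean = df[~bad].copy()
    clean["x"] = x[~bad]
    clean["y"] = y[~bad]
    return clean.reset_index(drop=True), IngestReport(rejected.reset_index(drop=True))


def nearest_noncoincident_distances(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Distance from each point to its nearest neighbor at a distinct location.

    Points sharing exact coordinates get the distance of their shared
    location to the nearest *different* location.  Returns NaN everywhere
    when all points are coincident.
    """
    pts = np.column_stack([x, y])
    uniq, inverse = np.unique(pts, axis=0, return_inverse=True)
    if len(uniq) < 2:
        return np.full(len(pts), np.nan)
    tree = cKDTree(uniq)
    d, _ = tree.query(uniq, k=2)
    return d[:, 1][inverse]


def remove_location_outliers(
    events: pd.DataFrame, k_sigma: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop events whose nearest-non-coincident-neighbor distance is extreme.

    Threshold: mean + ``k_sigma`` * SD of all nearest-non-coincident-neighbor
    distances.  Single pass; returns (cleaned, removed) with
    ``len(cleaned) + len(removed) == len(events)``.
    """
    empty = events.iloc[0:0]
    if len(events) < 3:
        warnings.warn("fewer than 3 events; outlier removal skipped", stacklevel=2)
        return events, empty
    d = nearest_noncoincident_distances(events["x"].to_numpy(float), events["y"].to_numpy(float))
    if np.isnan(d).all():
        warnings.warn("all events coincident; outlier removal skipped", stacklevel=2)
        return events, empty
    thresh = d.mean() + k_sigma * d.std(ddof=0)
    out = d > thresh
    return events[~out].reset_index(drop=True), events[out].reset_index(drop=True)


def format_share(pct: float) -> str:
    """Percentage formatting convention: 1 decimal, 2 decimals below 1%."""
    return f"{pct:.2f}" if 0 < pct < 1 else f"{pct:.1f}"


@dataclass
class CrosstabSummary:
    """Severity x participant-type contingency table with margins and shares."""

    counts: pd.DataFrame  # severity rows x participant-type columns, int
    grand_total: int

    @property
    def type_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def severity_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def share(self, count: int) -> float:
        """Percentage of the grand total, rounded per the table convention."""
        if self.grand_total == 0:
            return 0.0
        pct = 100.0 * count / self.grand_total
        return round(pct, 2) if 0 < pct < 1 else round(pct, 1)

    @property
    def type_shares(self) -> pd.Series:
        return self.type_totals.map(self.share)

    @property
    def severity_shares(self) -> pd.Series:
        return self.severity_totals.map(self.share)

    def to_frame(self) -> pd.DataFrame:
        """Full table with Sum margins and % row/column, for CSV export."""
        t = self.counts.copy()
        t["Sum"] = self.severity_totals
        t.loc["Sum"] = t.sum(axis=0)
        pct = self.type_shares
        t.loc["%"] = [pct.get(c, 100.0 if self.grand_total else 0.0) for c in t.columns]
        return t


def crosstab(events: pd.DataFrame) -> CrosstabSummary:
    """Severity x participant-type contingency summary of an event table."""
    counts = pd.crosstab(events["severity"], events["participant_type"]) if len(events) else pd.DataFrame()
    counts = counts.reindex(index=list(SEVERITIES), columns=list(PARTICIPANT_TYPES), fill_value=0)
    counts = counts.fillna(0).astype(int)
    counts.index.name = "severity"
    counts.columns.name = "participant_type"
    total = int(counts.to_numpy().sum())
    if total == 0:
        warnings.warn("empty event set: crosstab shares reported as 0", stacklevel=2)
    return CrosstabSummary(counts=counts, grand_total=total)
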