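"""RBT index: regional blackspot ratio and its correlation with crash counts.

RBT_{c,v} = Bn_{c,v} / Dn_{c,v} — the share of a region c's spatial units
occupied by blackspots of crash type v.  A larger RBT means blackspots of
that type are more widespread and the region's road-safety level is worse.
The index is validated against per-region crash counts by simple linear
(Pearson) correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .lattice import ALL_TYPES, CountLattice

__all__ = ["RBTRecord", "CorrelationReport", "rbt_index", "correlate_rbt_counts"]


@dataclass(frozen=True)
class RBTRecord:
    region: str
    crash_type: str
    bn: int  # blackspot cells in the region
    dn: int  # all cells in the region

    @property
    def rbt(self) -> float:
        return self.bn / self.dn


@dataclass(frozen=True)
class CorrelationReport:
    crash_type: str
    slope: float
    intercept: float
    r_squared: float
    n_regions: int


def rbt_index(
    blackspots: set[int], lattice: CountLattice, crash_type: str = ALL_TYPES
) -> list[RBTRecord]:
    """One RBT record per region: blackspot cells over all cells of the region."""
    unknown = blackspots - set(lattice.cells.index)
    if unknown:
        raise ValueError(f"blackspot ids not in lattice: {sorted(unknown)[:5]}...")
    records = []
    for region, group in lattice.cells.groupby("region_id", sort=True):
        dn = len(group)
        if dn == 0:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"region {region} has no cells; omitted", stacklevel=2)
            continue
        bn = len(blackspots.intersection(group.index))
        records.append(RBTRecord(region=str(region), crash_type=crash_type, bn=bn, dn=dn))
    return records


def records_frame(records: list[RBTRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"region_id": r.region, "crash_type": r.crash_type, "Bn": r.bn, "Dn": r.dn, "RBT": r.rbt}
            for r in records
        ]
    )


def correlate_rbt_counts(
    records: list[RBTRecord], counts: dict[str, float]
) -> CorrelationReport:
    """OLS fit of RBT on per-region crash counts; r^2 is squared Pearson r."""
    pairs = [(r.rbt, counts[r.region]) for r in records if r.region in counts]
    if len(pairs) < 3:
        raise ValueError("correlation needs at least 3 regions with both RBT and counts")
    y = [p[0] for p in pairs]
    x = [p[1] for p in pairs]
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("correlation undefined: zero variance in counts or RBT")
    fit = stats.linregress(x, y)
    crash_type = records[0].crash_type if records else ALL_TYPES
    return CorrelationReport(
        crash_type=crash_type,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_regions=len(pairs),
    )
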