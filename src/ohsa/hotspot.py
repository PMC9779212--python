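"""Getis-Ord Gi* local hot-spot statistic, FDR correction, and blackspots.

For each cell i with binary distance-band weights w_ij (the focal cell is
its own neighbor — the "star" form):

    Gi* = [ sum_j w_ij x_j  -  xbar sum_j w_ij ]
          / ( S * sqrt( [ n sum_j w_ij^2 - (sum_j w_ij)^2 ] / (n - 1) ) )

    S = sqrt( (1/n) sum_j x_j^2  -  xbar^2 )

with xbar and S taken over ALL n cells including the focal one.  The Gi*
value is directly a z-score.  Cells are binned into seven confidence
tiers; a blackspot is a hotspot at the 99% tier (z > 2.58 and
FDR-adjusted p < 0.01).  A cell whose neighborhood covers the whole
lattice has a 0/0 statistic and is reported as degenerate, excluded from
the multiple-testing family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .weights import WeightsMatrix

__all__ = [
    "TIER_Z",
    "TIER_ALPHA",
    "GiClassification",
    "gi_star",
    "fdr_correct",
    "classify",
    "extract_blackspots",
]

#: z-score thresholds of the 90/95/99% confidence tiers.  2.58 and 1.96 are
#: the rounded two-tailed standard-normal critical values at alpha 0.01 and
#: 0.05; 1.65 is the conventional (not 1.645) 90% cut used by GIS tooling.
TIER_Z = {90: 1.65, 95: 1.96, 99: 2.58}
TIER_ALPHA = {90: 0.10, 95: 0.05, 99: 0.01}


@dataclass
class GiClassification:
    """Per-cell Gi* z-scores, (adjusted) p-values and confidence bins.

    ``table`` columns: gi_z, p, p_adjusted, bin, blackspot, degenerate;
    indexed like the lattice cells.  bin is +/-3, +/-2, +/-1 for the
    99/95/90% hot (positive) and cold (negative) tiers, 0 otherwise.
    """

    table: pd.DataFrame
    s_global: float
    d: float

    @property
    def blackspots(self) -> set[int]:
        return set(self.table.index[self.table["blackspot"]])


def gi_star(values, weights: WeightsMatrix) -> tuple[np.ndarray, float]:
    """Per-cell Gi* z-scores under binary include-self weights.

    Returns (gi_z, S).  Degenerate cells (neighborhood = whole lattice)
    get NaN with a warning.
    """
    if not weights.include_self:
        raise ValueError("Gi* requires include_self weights (the focal cell is its own neighbor)")
    x = np.asarray(values, float)
    n = len(x)
    if n < 2:
        raise ValueError("Gi* needs at least 2 cells")
    if weights.n != n:
        raise ValueError("weights and values have different lengths")
    xbar = x.mean()
    s = np.sqrt((x**2).mean() - xbar**2)
    if s == 0.0:
        raise ValueError("Gi* is undefined for constant values (S = 0)")

    wsum = weights.row_sums  # binary: also the row sums of squares
    local = np.asarray(weights.matrix @ x, float)
    bracket = (n * wsum - wsum**2) / (n - 1)
    gi = np.full(n, np.nan)
    ok = bracket > 0
    gi[ok] = (local[ok] - xbar * wsum[ok]) / (s * np.sqrt(bracket[ok]))
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} cells have a saturated neighborhood (0/0); "
            "reported as not significant",
            stacklevel=2,
        )
    return gi, float(s)


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    NaN entries (degenerate cells) are passed through and excluded from
    the multiple-testing family.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _bin_one(z: float, p_adj: float) -> int:
    # strict inequalities as printed; a value exactly on a threshold falls
    # to the lower tier
    if np.isnan(z) or np.isnan(p_adj):
        return 0
    if z > 2.58 and p_adj < 0.01:
        return 3
    if 1.96 < z <= 2.58 and p_adj < 0.05:
        return 2
    if 1.65 < z <= 1.96 and p_adj < 0.10:
        return 1
    if z < -2.58 and p_adj < 0.01:
        return -3
    if -2.58 <= z < -1.96 and p_adj < 0.05:
        return -2
    if -1.96 <= z < -1.65 and p_adj < 0.10:
        return -1
    return 0


def classify(values, weights: WeightsMatrix, index=None) -> GiClassification:
    """Full local hot-spot classification: Gi*, two-tailed p, BH-FDR, tiers.

    Bin assignment needs BOTH the z threshold and the adjusted-p condition
    (e.g. blackspot: z > 2.58 and adjusted p < 0.01); a value exactly on a
    threshold falls to the lower tier.
    """
    gi, s = gi_star(values, weights)
    p = 2.0 * stats.norm.sf(np.abs(gi))
    p_adj = fdr_correct(p)
    bins = np.array([_bin_one(z, q) for z, q in zip(gi, p_adj)], dtype=int)
    table = pd.DataFrame(
        {
            "gi_z": gi,
            "p": p,
            "p_adjusted": p_adj,
            "bin": bins,
            "blackspot": bins == 3,
            "degenerate": np.isnan(gi),
        },
        index=index if index is not None else pd.RangeIndex(len(gi)),
    )
    table.index.name = "cell_id"
    return GiClassification(table=table, s_global=s, d=weights.d)


def extract_blackspots(classification: GiClassification) -> set[int]:
    """Cell ids classified as hotspots at the 99% confidence tier."""
    return classification.blackspots
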