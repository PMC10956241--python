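"""Getis-Ord Gi* hotspot / coldspot classification of zone-level values.

Gi* measures, for each zone, how far the weighted local sum of values in
its neighbourhood (including the zone itself — the "star" variant sets
w_ii = 1) departs from its expectation under spatial randomness:

    z_i = (sum_j w_ij x_j - xbar * sum_j w_ij)
          / ( S * sqrt[ (n * sum_j w_ij^2 - (sum_j w_ij)^2) / (n - 1) ] )

with xbar and S the global mean and standard deviation over all n zones.
The statistic is computed on the binary contiguity weights even when a
row-standardized matrix is supplied (the binary parent is kept alongside),
which is the standard Gi* convention. Classification uses the plain
two-sided normal cutoffs 1.96 (95%) and 2.576 (99%); no multiple-testing
correction by default, with an optional Benjamini-Hochberg FDR flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .weights import SpatialWeights

Z95 = 1.96
Z99 = 2.576

CLASS_LABELS = ("cold99", "cold95", "not significant", "hot95", "hot99")


def classify(z: np.ndarray, alpha_mask: np.ndarray | None = None) -> np.ndarray:
    """Map z-scores to hotspot classes by the 1.96 / 2.576 cutoffs."""
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, "not significant", dtype=object)
    sig = np.ones(z.shape, dtype=bool) if alpha_mask is None else alpha_mask
    out[(z > Z95) & (z <= Z99) & sig] = "hot95"
    out[(z > Z99) & sig] = "hot99"
    out[(z < -Z95) & (z >= -Z99) & sig] = "cold95"
    out[(z < -Z99) & sig] = "cold99"
    return out


@dataclass
class GiStarResult:
    zone_ids: list[str]
    gi_z: np.ndarray
    classification: np.ndarray
    wave: object = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "zone_id": self.zone_ids,
                "wave": self.wave,
                "gi_z": self.gi_z,
                "classification": self.classification,
            }
        )


def gi_star(
    values: np.ndarray,
    W: SpatialWeights,
    wave=None,
    fdr: bool = False,
) -> GiStarResult:
    """Gi* z-scores and hotspot classes for one cross-section."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Gi* needs at least 3 zones")
    if n != W.n:
        raise ValueError("values length does not match W")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all values equal")
    Wb = W.binary + np.eye(n)  # self-inclusion weight 1
    xbar = x.mean()
    s = np.sqrt((x**2).mean() - xbar**2)
    wsum = Wb.sum(axis=1)
    s1 = (Wb**2).sum(axis=1)
    num = Wb @ x - xbar * wsum
    den = s * np.sqrt((n * s1 - wsum**2) / (n - 1))
    # a neighbourhood covering every zone has num = 0 and den = 0: the
    # local mean cannot deviate from the global mean, so z is 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    mask = None
    if fdr:
        p = 2.0 * norm.sf(np.abs(z))
        order = np.argsort(p)
        ranked = p[order] <= 0.05 * (np.arange(1, n + 1) / n)
        k = np.nonzero(ranked)[0].max() + 1 if ranked.any() else 0
        mask = np.zeros(n, dtype=bool)
        mask[order[:k]] = True
    return GiStarResult(list(W.zone_ids), z, classify(z, mask), wave=wave)


def hotspot_panel(panel, W: SpatialWeights, fdr: bool = False) -> pd.DataFrame:
    """Per-wave Gi* with a persistence flag (hot in every wave).

    Returns a long table: zone_id, wave, gi_z, classification,
    persistent_hotspot. Persistence mirrors zones that are significant
    hotspots (95% or beyond) in all waves.
    """
    if panel.n_waves < 1:
        raise ValueError("panel has no waves")
    results = [
        gi_star(panel.y[:, t], W, wave=panel.wave_labels[t], fdr=fdr)
        for t in range(panel.n_waves)
    ]
    frames = [r.to_frame() for r in results]
    hot = np.vstack(
        [np.isin(r.classification, ("hot95", "hot99")) for r in results]
    ).all(axis=0)
    persistent = dict(zip(panel.zone_ids, hot))
    out = pd.concat(frames, ignore_index=True)
    out["persistent_hotspot"] = out["zone_id"].map(persistent)
    return out
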