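"""Contiguity spatial weight matrices for areal data.

A weight matrix ``W`` encodes which administrative zones are neighbours:
``w_ij = 1`` if zones *i* and *j* share a boundary, 0 otherwise, with a
zero diagonal. Row standardization divides each row by its sum so that a
spatial lag ``W y`` is an average over neighbours. The admissible interval
for autoregressive parameters (rho, lambda) is ``(1/omega_min, 1/omega_max)``
where ``omega_min``/``omega_max`` are the extreme real eigenvalues of the
matrix in use; log-determinant Jacobians ``ln|I - rho W|`` are finite only
inside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DisconnectedMapError(ValueError):
    """Raised when a zone map yields an adjacency with no edges at all."""


@dataclass
class SpatialWeights:
    """An N x N contiguity weight matrix aligned with an ordered zone list.

    Attributes
    ----------
    matrix:
        The working weight matrix (binary, or row-standardized if
        ``standardized`` is True).
    zone_ids:
        Zone labels in row/column order.
    standardized:
        Whether ``matrix`` has been row-standardized.
    binary:
        The symmetric 0/1 adjacency the matrix was built from. Kept even
        after standardization because some statistics (Gi*) are defined on
        binary weights.
    isolated:
        Boolean flags marking zones with no neighbours; their rows are left
        all-zero by standardization.
    """

    matrix: np.ndarray
    zone_ids: list[str]
    standardized: bool = False
    binary: np.ndarray | None = None
    isolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("weight matrix must be square")
        if n < 2:
            raise ValueError("need at least 2 zones")
        if len(self.zone_ids) != n:
            raise ValueError("zone_ids length does not match matrix")
        if len(set(self.zone_ids)) != n:
            raise ValueError("zone_ids must be unique")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal of W must be zero")
        if np.any(self.matrix < 0):
            raise ValueError("weights must be nonnegative")
        if self.binary is None:
            self.binary = (self.matrix > 0).astype(float)
        if self.isolated is None:
            self.isolated = self.binary.sum(axis=1) == 0

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def eigenvalues(self) -> np.ndarray:
        """All eigenvalues of the working matrix (possibly complex)."""
        return np.linalg.eigvals(self.matrix)

    @property
    def eigen_bounds(self) -> tuple[float, float]:
        """Admissible open interval for rho and lambda.

        Computed from the extreme real eigenvalues of the working matrix:
        ``(1/omega_min, 1/omega_max)``. For a row-standardized matrix the
        largest eigenvalue is 1, so the upper bound is 1.
        """
        ev = self.eigenvalues()
        real = ev[np.abs(ev.imag) < 1e-9].real
        omega_min = real.min()
        omega_max = real.max()
        if omega_min >= 0:  # cannot happen for a nonempty zero-trace adjacency
            raise ValueError("weight matrix has no negative real eigenvalue")
        return (1.0 / omega_min, 1.0 / omega_max)

    # -- I/O -----------------------------------------------------------------

    def to_edges(self) -> pd.DataFrame:
        """Undirected edge list (src, dst) of the binary adjacency."""
        i, j = np.nonzero(np.triu(self.binary, k=1))
        return pd.DataFrame(
            {
                "src": [self.zone_ids[a] for a in i],
                "dst": [self.zone_ids[b] for b in j],
            }
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.zone_ids, columns=self.zone_ids).to_csv(
            path, index_label="zone_id"
        )


def contiguity_from_map(zone_map, rule: str = "queen") -> SpatialWeights:
    """Binary contiguity weights from zone polygons.

    ``queen``: any shared boundary point (corner touches count).
    ``rook``: a shared edge of positive length.
    """
    if rule not in {"queen", "rook"}:
        raise ValueError(f"unknown contiguity rule {rule!r}")
    geoms = zone_map.geometries
    n = len(geoms)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = geoms[i], geoms[j]
            if not gi.intersects(gj):
                continue
            if rule == "queen":
                W[i, j] = W[j, i] = 1.0
            else:
                inter = gi.boundary.intersection(gj.boundary)
                if getattr(inter, "length", 0.0) > 0.0:
                    W[i, j] = W[j, i] = 1.0
    if W.sum() == 0:
        raise DisconnectedMapError("no two zones are contiguous")
    isolated = W.sum(axis=1) == 0
    if isolated.any():
        names = [zone_map.zone_ids[k] for k in np.nonzero(isolated)[0]]
        warnings.warn(f"isolated zones with no neighbours: {names}", stacklevel=2)
    return SpatialWeights(W, list(zone_map.zone_ids), standardized=False)


def contiguity_from_edges(edges, zone_ids) -> SpatialWeights:
    """Binary weights from an explicit undirected edge list.

    ``edges`` is an iterable of (src, dst) pairs, or a DataFrame with
    ``src``/``dst`` columns. Duplicate edges are idempotent; self-loops and
    unknown ids are errors.
    """
    zone_ids = list(zone_ids)
    index = {z: k for k, z in enumerate(zone_ids)}
    if isinstance(edges, pd.DataFrame):
        edges = list(zip(edges["src"], edges["dst"]))
    n = len(zone_ids)
    W = np.zeros((n, n))
    for src, dst in edges:
        if src not in index or dst not in index:
            raise KeyError(f"edge ({src}, {dst}) references unknown zone id")
        if src == dst:
            raise ValueError(f"self-loop on zone {src!r} not allowed")
        W[index[src], index[dst]] = 1.0
        W[index[dst], index[src]] = 1.0
    isolated = W.sum(axis=1) == 0
    if W.sum() == 0:
        raise DisconnectedMapError("edge list produces no adjacency")
    if isolated.any():
        names = [zone_ids[k] for k in np.nonzero(isolated)[0]]
        warnings.warn(f"isolated zones with no neighbours: {names}", stacklevel=2)
    return SpatialWeights(W, zone_ids, standardized=False)


def row_standardize(w: SpatialWeights) -> SpatialWeights:
    """Divide each row by its sum; rows of isolated zones stay all-zero."""
    sums = w.binary.sum(axis=1)
    out = np.zeros_like(w.binary)
    nz = sums > 0
    out[nz] = w.binary[nz] / sums[nz, None]
    return SpatialWeights(
        out,
        list(w.zone_ids),
        standardized=True,
        binary=w.binary.copy(),
        isolated=~nz,
    )


def edges_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"src", "dst"} - set(df.columns)
    if missing:
        raise ValueError(f"edge CSV {path} missing columns {sorted(missing)}")
    return df
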