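"""Synthetic study data: zone maps, covariate fields, space-time panels,
and child-level weighted survey records.

Real DHS microdata are access-restricted, so every downstream stage of the
pipeline is exercised on data generated here. The generator emulates the
study design: 65 administrative zones observed over 4 survey waves, a
weighted child-level binary mortality outcome with wave-specific prevalence,
and zone-level covariate proportions with spatial autocorrelation.

The panel data-generating process is the general nesting space-time dynamic
model (GNS):

    y_t = rho*W*y_t + phi*y_{t-1} + gamma*W*y_{t-1} + X_t*beta + W*X_t*theta + u_t
    u_t = lambda*W*u_t + eps_t,   eps_t ~ iid N(0, sigma2 I)

where W is a row-standardized contiguity matrix. Setting subsets of
(rho, phi, gamma, lambda, theta) to zero recovers the SAR, SEM, SAC and SDM
special cases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box, mapping, shape

from .weights import SpatialWeights

# Study-scale defaults: four survey waves with the weighted child counts and
# national under-five mortality prevalences the generator is calibrated to.
DEFAULT_WAVE_LABELS: tuple[int, ...] = (2000, 2005, 2011, 2016)
DEFAULT_WAVE_COUNTS: tuple[int, ...] = (10873, 9861, 11654, 10641)
DEFAULT_WAVE_PREVALENCES: tuple[float, ...] = (0.1208, 0.0871, 0.0726, 0.06)
DEFAULT_N_ZONES = 65

# Default covariate block for GNS simulations: names with direct (beta) and
# spatial-spillover (theta) coefficients on the scale of zone proportions.
DEFAULT_COVARIATES: tuple[str, ...] = (
    "mother_illiterate",
    "not_vaccinated",
    "unimproved_water",
    "contraceptive_use",
)
DEFAULT_BETA: tuple[float, ...] = (0.4501, 0.7681, 0.5801, -0.6609)
DEFAULT_THETA: tuple[float, ...] = (-0.0078, 0.9834, 0.1356, -0.2942)


# ---------------------------------------------------------------------------
# Zone maps
# ---------------------------------------------------------------------------


@dataclass
class ZoneMap:
    """Ordered zone polygons in projected planar coordinates (km)."""

    zone_ids: list[str]
    geometries: list[Polygon]
    region_ids: list[str] | None = None
    _centroid_jitter: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.zone_ids) != len(self.geometries):
            raise ValueError("zone_ids and geometries length mismatch")
        if len(self.zone_ids) < 2:
            raise ValueError("a map needs at least 2 zones")
        if len(set(self.zone_ids)) != len(self.zone_ids):
            raise ValueError("zone_ids must be unique")
        for z, g in zip(self.zone_ids, self.geometries):
            if g.is_empty:
                raise ValueError(f"zone {z!r} has an empty geometry")
        if not np.all(np.isfinite(self.centroids())):
            raise ValueError("non-finite centroid")

    @property
    def n(self) -> int:
        return len(self.zone_ids)

    def centroids(self) -> np.ndarray:
        """(N, 2) centroid coordinates, including any generator jitter."""
        pts = np.array([[g.centroid.x, g.centroid.y] for g in self.geometries])
        if self._centroid_jitter is not None:
            pts = pts + self._centroid_jitter
        return pts

    def to_geojson(self, path) -> None:
        features = []
        for k, (z, g) in enumerate(zip(self.zone_ids, self.geometries)):
            props = {"zone_id": z}
            if self.region_ids is not None:
                props["region_id"] = self.region_ids[k]
            features.append(
                {"type": "Feature", "properties": props, "geometry": mapping(g)}
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path) -> "ZoneMap":
        with open(path) as fh:
            fc = json.load(fh)
        ids, geoms, regions = [], [], []
        for feat in fc["features"]:
            ids.append(str(feat["properties"]["zone_id"]))
            regions.append(feat["properties"].get("region_id"))
            geoms.append(shape(feat["geometry"]))
        region_ids = regions if all(r is not None for r in regions) else None
        return cls(ids, geoms, region_ids)


def generate_zone_map(
    n_side: int,
    seed: int = 0,
    n_extra: int = 0,
    jitter: float = 0.0,
) -> ZoneMap:
    """Connected lattice of ``n_side x n_side`` unit-square zones.

    ``n_extra`` appends additional unit squares in a row below the lattice
    (each contiguous with the bottom row), so the study-scale 65-zone map is
    ``generate_zone_map(8, n_extra=1)``. ``jitter`` adds a seeded uniform
    perturbation (< 0.5 units) to the centroids used for distance-based
    methods, which breaks lattice distance ties in variogram binning; the
    polygons themselves are untouched.
    """
    if n_side < 2:
        raise ValueError("n_side must be at least 2")
    if n_extra < 0 or n_extra > n_side:
        raise ValueError("n_extra must be between 0 and n_side")
    geoms, ids = [], []
    for r in range(n_side):
        for c in range(n_side):
            geoms.append(box(c, r, c + 1, r + 1))
            ids.append(f"Z{r * n_side + c:02d}")
    for e in range(n_extra):
        geoms.append(box(e, -1.0, e + 1, 0.0))  # adjacent to bottom row
        ids.append(f"Z{n_side * n_side + e:02d}")
    jit = None
    if jitter > 0:
        rng = np.random.default_rng(seed)
        jit = rng.uniform(-jitter, jitter, size=(len(ids), 2))
    return ZoneMap(ids, geoms, _centroid_jitter=jit)


def default_zone_map(seed: int = 0, jitter: float = 0.25) -> ZoneMap:
    """The study-scale stand-in map: 65 zones (8x8 lattice plus one)."""
    return generate_zone_map(8, seed=seed, n_extra=1, jitter=jitter)


# ---------------------------------------------------------------------------
# Panels and parameters
# ---------------------------------------------------------------------------


@dataclass
class ZonePanel:
    """Balanced N x T panel of zone-level proportions.

    ``y`` is (N, T), ``X`` is (N, T, k). ``mask`` marks observed cells;
    a False entry means the zone-wave cell was empty at aggregation and the
    stored value is meaningless (never silently zero).
    """

    zone_ids: list[str]
    wave_labels: list
    y: np.ndarray
    X: np.ndarray
    covariate_names: list[str]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n, t = self.y.shape
        if self.X.shape[:2] != (n, t):
            raise ValueError("X must be (N, T, k)")
        if len(self.zone_ids) != n or len(self.wave_labels) != t:
            raise ValueError("labels do not match array shapes")
        if len(self.covariate_names) != self.X.shape[2]:
            raise ValueError("covariate_names length mismatch")
        if self.mask is None:
            self.mask = np.ones((n, t), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_waves(self) -> int:
        return self.y.shape[1]

    @property
    def balanced(self) -> bool:
        return bool(self.mask.all())

    def missing_cells(self) -> list[tuple[str, object]]:
        rows, cols = np.nonzero(~self.mask)
        return [(self.zone_ids[r], self.wave_labels[c]) for r, c in zip(rows, cols)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it, wave in enumerate(self.wave_labels):
            for iz, z in enumerate(self.zone_ids):
                rec = {"zone_id": z, "wave": wave, "y": self.y[iz, it]}
                for ik, name in enumerate(self.covariate_names):
                    rec[name] = self.X[iz, it, ik]
                rec["missing"] = int(not self.mask[iz, it])
                rows.append(rec)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ZonePanel":
        required = {"zone_id", "wave", "y"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel is missing required columns {sorted(missing)}")
        cov_names = [
            c for c in df.columns if c not in {"zone_id", "wave", "y", "missing"}
        ]
        zones = list(pd.unique(df["zone_id"]))
        waves = sorted(pd.unique(df["wave"]))
        n, t, k = len(zones), len(waves), len(cov_names)
        y = np.full((n, t), np.nan)
        X = np.full((n, t, k), np.nan)
        mask = np.zeros((n, t), dtype=bool)
        zi = {z: i for i, z in enumerate(zones)}
        wi = {w: i for i, w in enumerate(waves)}
        for _, row in df.iterrows():
            a, b = zi[row["zone_id"]], wi[row["wave"]]
            y[a, b] = row["y"]
            for ik, c in enumerate(cov_names):
                X[a, b, ik] = row[c]
            mask[a, b] = not bool(row.get("missing", 0))
        return cls(zones, waves, y, X, cov_names, mask)

    @classmethod
    def from_csv(cls, path) -> "ZonePanel":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class GNSParams:
    """Parameters of the general nesting space-time dynamic model."""

    rho: float = 0.0
    phi: float = 0.0
    gamma: float = 0.0
    lam: float = 0.0
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    theta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")

    def validate_stationarity(self, W: SpatialWeights) -> None:
        """Raise if the space-time process is explosive or rho/lam inadmissible."""
        lo, hi = W.eigen_bounds
        for name, val in (("rho", self.rho), ("lam", self.lam)):
            if not (lo < val < hi):
                raise ValueError(
                    f"{name}={val} outside admissible interval ({lo:.4f}, {hi:.4f})"
                )
        A = np.eye(W.n) - self.rho * W.matrix
        C = self.phi * np.eye(W.n) + self.gamma * W.matrix
        rad = np.max(np.abs(np.linalg.eigvals(np.linalg.solve(A, C))))
        if rad >= 1.0:
            raise ValueError(
                f"nonstationary process: spectral radius of (I-rho W)^-1(phi I + gamma W) is {rad:.4f}"
            )


def paper_scale_params(k: int = len(DEFAULT_BETA), sigma2: float = 0.005) -> GNSParams:
    """GNS truth at the magnitudes of the reference study's fitted model."""
    beta = np.array(DEFAULT_BETA[:k])
    theta = np.array(DEFAULT_THETA[:k])
    return GNSParams(
        rho=0.04, phi=-0.28, gamma=-0.14, lam=-0.41, beta=beta, theta=theta, sigma2=sigma2
    )


def strong_dependence_params(k: int = len(DEFAULT_BETA), sigma2: float = 0.005) -> GNSParams:
    """GNS truth with every dependence channel clearly active.

    Used in model-selection experiments, where each submodel must pay a
    visible likelihood price for the channels it omits.
    """
    return GNSParams(
        rho=0.3,
        phi=0.35,
        gamma=-0.2,
        lam=0.3,
        beta=np.array(DEFAULT_BETA[:k]),
        theta=np.array(DEFAULT_THETA[:k]),
        sigma2=sigma2,
    )


# ---------------------------------------------------------------------------
# Covariate fields
# ---------------------------------------------------------------------------


def generate_covariates(
    W: SpatialWeights,
    T: int,
    k: int = len(DEFAULT_COVARIATES),
    seed: int = 0,
    names: list[str] | None = None,
    spatial_smooth: float = 0.6,
    time_persistence: float = 0.7,
    logit_sd: float = 0.7,
) -> tuple[np.ndarray, list[str]]:
    """Spatially autocorrelated covariate proportions, (N, T, k).

    Each covariate is a logistic-normal field: a latent Gaussian zone effect
    smoothed through W (an SAR/ICAR-like filter ``(I - a W)^-1 eps``), an
    AR(1) evolution over waves, and an inverse-logit map to (0, 1). The
    smoothing makes ``W X`` linearly independent of ``X`` in a nontrivial
    way, so spatial-Durbin (theta) terms are identifiable.
    """
    rng = np.random.default_rng(seed)
    n = W.n
    if names is None:
        names = [
            DEFAULT_COVARIATES[i] if i < len(DEFAULT_COVARIATES) else f"x{i + 1}"
            for i in range(k)
        ]
    smooth = np.linalg.inv(np.eye(n) - spatial_smooth * W.matrix)
    X = np.empty((n, T, k))
    base_mean = rng.uniform(-1.5, -0.3, size=k)  # proportions mostly 0.15-0.45
    for ik in range(k):
        z = smooth @ rng.normal(0, logit_sd, size=n)
        innov_sd = logit_sd * np.sqrt(1 - time_persistence**2)
        for t in range(T):
            if t > 0:
                z = time_persistence * z + smooth @ rng.normal(0, innov_sd, size=n)
            X[:, t, ik] = 1.0 / (1.0 + np.exp(-(base_mean[ik] + z)))
    return X, list(names)


# ---------------------------------------------------------------------------
# GNS panel simulation
# ---------------------------------------------------------------------------


def simulate_gns_panel(
    zone_map: ZoneMap,
    W: SpatialWeights,
    params: GNSParams,
    X: np.ndarray,
    T: int,
    burn_in: int = 50,
    seed: int = 0,
    wave_labels: list | None = None,
    covariate_names: list[str] | None = None,
) -> ZonePanel:
    """Simulate a zone panel from the GNS process with known parameters.

    Each period solves the simultaneous spatial system:

        y_t = (I - rho W)^-1 [ phi y_{t-1} + gamma W y_{t-1}
                               + X_t beta + W X_t theta + u_t ],
        u_t = (I - lambda W)^-1 eps_t,  eps_t ~ N(0, sigma2 I).

    The chain starts from the deterministic cross-sectional equilibrium
    ``y_0 = (I - rho W)^-1 (X_1 beta + W X_1 theta)`` and runs ``burn_in``
    periods (holding X at its first-wave value) before the T recorded waves,
    so the recorded panel is effectively drawn from the process'
    stationary regime.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    X = np.asarray(X, dtype=float)
    n = W.n
    if X.shape != (n, T, len(params.beta)):
        raise ValueError(f"X must have shape (N={n}, T={T}, k={len(params.beta)})")
    params.validate_stationarity(W)
    rng = np.random.default_rng(seed)

    I = np.eye(n)
    A = I - params.rho * W.matrix
    if abs(np.linalg.det(A)) < 1e-12:
        raise np.linalg.LinAlgError("I - rho W is singular")
    B_inv = np.linalg.inv(I - params.lam * W.matrix)
    sd = np.sqrt(params.sigma2)

    theta = params.theta if params.theta.size else np.zeros_like(params.beta)

    def exog(t_idx: int) -> np.ndarray:
        xt = X[:, t_idx, :]
        return xt @ params.beta + W.matrix @ (xt @ theta)

    y = np.linalg.solve(A, exog(0))
    for t in range(burn_in):
        u = B_inv @ rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        rhs = params.phi * y + params.gamma * (W.matrix @ y) + exog(0) + u
        y = np.linalg.solve(A, rhs)
    out = np.empty((n, T))
    for t in range(T):
        u = B_inv @ rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        rhs = params.phi * y + params.gamma * (W.matrix @ y) + exog(t) + u
        y = np.linalg.solve(A, rhs)
        out[:, t] = y
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("simulated panel contains non-finite values")
    if wave_labels is None:
        wave_labels = list(range(T))
    if covariate_names is None:
        covariate_names = [f"x{i + 1}" for i in range(X.shape[2])]
    return ZonePanel(list(zone_map.zone_ids), wave_labels, out, X, covariate_names)


def gns_mean_recursion(
    W: SpatialWeights, params: GNSParams, X: np.ndarray, T: int, burn_in: int = 50
) -> np.ndarray:
    """Analytic mean path E[y_t] of the simulator, by iterating expectations.

    Innovations have mean zero, so the expectation follows the same
    recursion with the noise removed. Returns the (N, T) mean of the
    recorded waves. Used as an independent oracle for the simulator.
    """
    n = W.n
    A = np.eye(n) - params.rho * W.matrix
    theta = params.theta if params.theta.size else np.zeros_like(params.beta)

    def exog(t_idx):
        xt = X[:, t_idx, :]
        return xt @ params.beta + W.matrix @ (xt @ theta)

    m = np.linalg.solve(A, exog(0))
    for _ in range(burn_in):
        m = np.linalg.solve(A, params.phi * m + params.gamma * (W.matrix @ m) + exog(0))
    out = np.empty((n, T))
    for t in range(T):
        m = np.linalg.solve(A, params.phi * m + params.gamma * (W.matrix @ m) + exog(t))
        out[:, t] = m
    return out


# ---------------------------------------------------------------------------
# Child-level weighted survey records
# ---------------------------------------------------------------------------


@dataclass
class ChildRecords:
    """Child-level weighted binary mortality records.

    The frame has columns ``zone_id``, ``wave``, ``died`` (1 = died before
    age five), ``weight`` (positive sampling weight, mean ~1), plus one 0/1
    column per covariate indicator.
    """

    frame: pd.DataFrame
    covariate_names: list[str]

    def __post_init__(self) -> None:
        required = {"zone_id", "wave", "died", "weight"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"records missing columns {sorted(missing)}")
        if not self.frame["died"].isin([0, 1]).all():
            raise ValueError("died must be binary")
        if not (self.frame["weight"] > 0).all():
            raise ValueError("weights must be positive")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ChildRecords":
        df = pd.read_csv(path)
        covs = [c for c in df.columns if c not in {"zone_id", "wave", "died", "weight"}]
        return cls(df, covs)


def _solve_wave_intercept(target: float, offsets: np.ndarray) -> float:
    """Intercept a such that mean(expit(a + offsets)) == target."""
    from scipy.optimize import brentq

    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf

    def f(a):
        return np.mean(1.0 / (1.0 + np.exp(-(a + offsets)))) - target

    return brentq(f, -30.0, 30.0)


def simulate_child_records(
    zone_map: ZoneMap,
    wave_prevalences=DEFAULT_WAVE_PREVALENCES,
    wave_counts=DEFAULT_WAVE_COUNTS,
    covariate_spec: dict[str, float] | None = None,
    seed: int = 0,
    W: SpatialWeights | None = None,
    zone_effect_sd: float = 0.35,
    spatial_smooth: float = 0.6,
    weight_shape: float = 4.0,
    wave_labels=None,
) -> ChildRecords:
    """Weighted child records whose per-wave weighted prevalence matches
    the configured national prevalences.

    Each zone carries a logit-scale random effect smoothed through W (so
    mortality is spatially clustered); a per-wave intercept is solved so the
    expected prevalence over the realized child-to-zone allocation equals
    the configured value exactly. Sampling weights are gamma-distributed
    with mean 1 (shape ``weight_shape``), mimicking normalized survey
    weights; weights are independent of the outcome, so they add a design
    effect of ``1 + 1/weight_shape`` to prevalence variance but no bias.
    """
    wave_prevalences = list(wave_prevalences)
    wave_counts = list(wave_counts)
    if len(wave_prevalences) != len(wave_counts):
        raise ValueError("wave_prevalences and wave_counts lengths differ")
    for p in wave_prevalences:
        if not (0.0 <= p < 1.0):
            raise ValueError("prevalences must lie in [0, 1)")
    for c in wave_counts:
        if c <= 0:
            raise ValueError("wave counts must be positive")
    if wave_labels is None:
        wave_labels = (
            list(DEFAULT_WAVE_LABELS)
            if len(wave_counts) == len(DEFAULT_WAVE_LABELS)
            else list(range(len(wave_counts)))
        )

    rng = np.random.default_rng(seed)
    n = zone_map.n
    if W is not None:
        smooth = np.linalg.inv(np.eye(n) - spatial_smooth * W.matrix)
        b = smooth @ rng.normal(0, 1, size=n)
        b = zone_effect_sd * (b - b.mean()) / b.std()
    else:
        b = rng.normal(0, zone_effect_sd, size=n)

    if covariate_spec is None:
        covariate_spec = {name: 0.3 for name in DEFAULT_COVARIATES}
    cov_names = list(covariate_spec)

    # uneven but fixed zone population shares
    shares = rng.dirichlet(np.full(n, 8.0))

    frames = []
    for t, (prev, count) in enumerate(zip(wave_prevalences, wave_counts)):
        zones = rng.choice(n, size=count, p=shares)
        offsets = b[zones]
        a = _solve_wave_intercept(prev, offsets)
        p_child = np.zeros(count) if np.isneginf(a) else 1.0 / (1.0 + np.exp(-(a + offsets)))
        died = rng.binomial(1, p_child)
        w = rng.gamma(weight_shape, 1.0 / weight_shape, size=count)
        rec = {
            "zone_id": [zone_map.zone_ids[z] for z in zones],
            "wave": wave_labels[t],
            "died": died,
            "weight": w,
        }
        for name in cov_names:
            base = covariate_spec[name]
            pz = 1.0 / (1.0 + np.exp(-(np.log(base / (1 - base)) + 0.8 * b[zones])))
            rec[name] = rng.binomial(1, pz)
        frames.append(pd.DataFrame(rec))
    return ChildRecords(pd.concat(frames, ignore_index=True), cov_names)


def aggregate_to_zones(
    records: ChildRecords,
    zone_map: ZoneMap | None = None,
    weighted_covariates: bool = True,
) -> ZonePanel:
    """Collapse child records to a zone-wave panel of weighted proportions.

    ``y_it = sum(w * died) / sum(w)`` over children in zone i, wave t; each
    covariate indicator is collapsed the same way (or unweighted if
    ``weighted_covariates`` is False). Empty zone-wave cells are flagged in
    the panel mask, never filled with zeros.
    """
    df = records.frame
    zones = list(zone_map.zone_ids) if zone_map is not None else sorted(df["zone_id"].unique())
    if zone_map is not None:
        unknown = set(df["zone_id"]) - set(zones)
        if unknown:
            raise ValueError(f"records reference zones not in map: {sorted(unknown)}")
    waves = sorted(df["wave"].unique())
    n, t, k = len(zones), len(waves), len(records.covariate_names)
    y = np.full((n, t), np.nan)
    X = np.full((n, t, k), np.nan)
    mask = np.zeros((n, t), dtype=bool)
    zi = {z: i for i, z in enumerate(zones)}
    wi = {w: i for i, w in enumerate(waves)}
    for (z, wv), grp in df.groupby(["zone_id", "wave"]):
        a, bdx = zi[z], wi[wv]
        wsum = grp["weight"].sum()
        y[a, bdx] = (grp["weight"] * grp["died"]).sum() / wsum
        for ik, name in enumerate(records.covariate_names):
            if weighted_covariates:
                X[a, bdx, ik] = (grp["weight"] * grp[name]).sum() / wsum
            else:
                X[a, bdx, ik] = grp[name].mean()
        mask[a, bdx] = True
    return ZonePanel(zones, waves, y, X, list(records.covariate_names), mask)
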