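"""Semivariogram estimation, variogram model fitting, and ordinary kriging.

The empirical semivariogram of a zonal field Z at centroid locations is

    gamma_hat(h) = 1 / (2 |N(h)|) * sum_{(i,j) in N(h)} (Z_i - Z_j)^2

where N(h) is the set of point pairs whose Euclidean separation falls in
the distance bin around h. Four theoretical families (exponential,
spherical, circular, gaussian) are fitted to it by weighted least squares;
leave-one-out (LOO) kriging cross-validation supplies the MSE and RMSSE
calibration diagnostics. Ordinary kriging solves, per target, the
variogram-form system with a Lagrange multiplier enforcing unit-sum
weights.

Conventions: for the theoretical process gamma(0) = 0; for any h > 0 the
model value includes the nugget (the discontinuity at the origin). The
kriging system uses gamma(0) = 0 on its diagonal, so prediction at an
observed site is exact exactly when the nugget is zero. "Sill" is the
total sill (nugget + partial sill); the constraint nugget <= sill is
enforced in fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist, pdist, squareform

FAMILIES = ("exponential", "spherical", "circular", "gaussian")


@dataclass
class EmpiricalVariogram:
    h: np.ndarray          # bin centers, strictly increasing
    gamma_hat: np.ndarray  # semivariance per bin
    pair_count: np.ndarray  # |N(h)| per bin

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.gamma_hat = np.asarray(self.gamma_hat, dtype=float)
        self.pair_count = np.asarray(self.pair_count, dtype=int)
        if np.any(np.diff(self.h) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if np.any(self.gamma_hat < 0) or np.any(self.pair_count < 1):
            raise ValueError("invalid empirical variogram")


@dataclass
class VariogramFit:
    family: str
    nugget: float
    sill: float
    range_: float
    mse: float | None = None
    rmsse: float | None = None
    wls_objective: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.sill < self.nugget or self.range_ <= 0:
            raise ValueError("require 0 <= nugget <= sill and range > 0")

    def __call__(self, h) -> np.ndarray:
        return variogram_model(self.family, self.nugget, self.sill, self.range_, h)


@dataclass
class KrigingResult:
    targets: np.ndarray
    prediction: np.ndarray
    variance: np.ndarray
    weights: np.ndarray | None = None


def empirical_semivariogram(
    locations: np.ndarray,
    values: np.ndarray,
    n_bins: int = 12,
    max_dist: float | None = None,
) -> EmpiricalVariogram:
    """Binned empirical semivariogram over all point pairs.

    Default ``max_dist`` is half the maximum pairwise distance; bins are
    equal-width on (0, max_dist] and empty bins are omitted.
    """
    locations = np.asarray(locations, dtype=float)
    values = np.asarray(values, dtype=float)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if locations.shape[0] < 2:
        raise ValueError("need at least 2 locations")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    d = pdist(locations)
    if d.max() == 0:
        raise ValueError("all locations coincident")
    if max_dist is None:
        max_dist = d.max() / 2.0
    sq = pdist(values[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    keep = (d > 0) & (d <= max_dist)
    idx = np.clip(np.searchsorted(edges, d[keep], side="left") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=sq[keep], minlength=n_bins)
    nz = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(
        centers[nz], sums[nz] / (2.0 * counts[nz]), counts[nz]
    )


def variogram_model(family: str, nugget: float, sill: float, range_: float, h):
    """Theoretical semivariance gamma(h) for the four standard families.

    gamma(0) = 0 exactly; for h > 0 the curve starts at the nugget and
    rises to the (total) sill, which bounded families reach at h = range
    and the exponential/gaussian approach asymptotically.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("distances must be nonnegative")
    c = sill - nugget
    hr = np.divide(h, range_)
    if family == "exponential":
        g = c * (1.0 - np.exp(-hr))
    elif family == "gaussian":
        g = c * (1.0 - np.exp(-(hr**2)))
    elif family == "spherical":
        hr_c = np.minimum(hr, 1.0)
        g = c * (1.5 * hr_c - 0.5 * hr_c**3)
    elif family == "circular":
        hr_c = np.minimum(hr, 1.0)
        g = c * (1.0 - (2.0 / np.pi) * (np.arccos(hr_c) - hr_c * np.sqrt(1.0 - hr_c**2)))
    else:
        raise ValueError(f"unknown variogram family {family!r}")
    out = np.where(h > 0, nugget + g, 0.0)
    return out if out.ndim else float(out)


def fit_variogram(
    emp: EmpiricalVariogram,
    family: str,
    weighting: str = "counts",
    n_starts: int = 8,
) -> VariogramFit:
    """Weighted least-squares fit of one family to an empirical variogram.

    Minimizes ``sum_b w_b (gamma_hat_b - gamma_model(h_b))^2`` under box
    constraints ``0 <= nugget <= sill``, ``range > 0``. ``weighting``:
    ``"counts"`` uses pair counts |N(h)| (default), ``"cressie"`` uses
    ``|N(h)| / gamma_model(h)^2`` re-evaluated each iteration. Multi-start
    over range scales; the best iterate is always returned.
    """
    if len(emp.h) < 3:
        raise ValueError("need at least 3 non-empty bins to fit a variogram")
    if weighting not in {"counts", "cressie"}:
        raise ValueError("weighting must be 'counts' or 'cressie'")
    h, g, cnt = emp.h, emp.gamma_hat, emp.pair_count.astype(float)
    g_max = max(g.max(), 1e-12)
    h_max = h.max()

    def objective(p):
        nug, psill, rng_ = p
        model = variogram_model(family, nug, nug + psill, rng_, h)
        if weighting == "counts":
            w = cnt
        else:
            w = cnt / np.maximum(model, 1e-12) ** 2
        return float(np.sum(w * (g - model) ** 2))

    best = None
    start_ranges = np.geomspace(h_max / 20.0, 2.0 * h_max, n_starts)
    x0s = [(0.0, g_max, r) for r in start_ranges]
    x0s += [(0.3 * g_max, 0.7 * g_max, r) for r in start_ranges[::2]]
    bounds = [(0.0, 10 * g_max), (1e-12, 10 * g_max), (h_max * 1e-3, 20 * h_max)]
    for x0 in x0s:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(f"variogram fit failed for family {family!r}")
    nug, psill, rng_ = best.x
    return VariogramFit(
        family, float(nug), float(nug + psill), float(rng_), wls_objective=float(best.fun)
    )


def fit_all_families(
    emp: EmpiricalVariogram,
    locations: np.ndarray | None = None,
    values: np.ndarray | None = None,
    families=FAMILIES,
    weighting: str = "counts",
) -> list[VariogramFit]:
    """Fit every family; attach LOO diagnostics when data are supplied."""
    fits = []
    for fam in families:
        fit = fit_variogram(emp, fam, weighting=weighting)
        if locations is not None and values is not None:
            fit.mse, fit.rmsse = loo_cross_validate(fit, locations, values)
        fits.append(fit)
    return fits


def select_variogram(fits: list[VariogramFit]) -> VariogramFit:
    """Lowest LOO MSE; RMSSE closest to 1 breaks ties."""
    with_diag = [f for f in fits if f.mse is not None]
    if not with_diag:
        raise ValueError("no fits carry LOO diagnostics")
    return min(with_diag, key=lambda f: (round(f.mse, 12), abs(f.rmsse - 1.0)))


def _kriging_lhs(fit: VariogramFit, locations: np.ndarray) -> np.ndarray:
    n = locations.shape[0]
    D = squareform(pdist(locations))
    off = ~np.eye(n, dtype=bool)
    G = np.zeros((n, n))
    G[off] = fit(D[off])
    lhs = np.empty((n + 1, n + 1))
    lhs[:n, :n] = G
    lhs[:n, n] = 1.0
    lhs[n, :n] = 1.0
    lhs[n, n] = 0.0
    return lhs


def ordinary_kriging(
    fit: VariogramFit,
    locations: np.ndarray,
    values: np.ndarray,
    targets: np.ndarray,
    return_weights: bool = False,
) -> KrigingResult:
    """Ordinary kriging prediction at target points.

    Solves ``[Gamma 1; 1' 0] [w; mu] = [gamma_0; 1]`` per target, where
    Gamma holds pairwise model semivariances among observations (zero
    diagonal) and gamma_0 the observation-target semivariances. Prediction
    is ``w' z`` and kriging variance ``w' gamma_0 + mu``.
    """
    locations = np.asarray(locations, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    n = locations.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    D = squareform(pdist(locations))
    dup = np.argwhere(np.triu(D == 0, k=1))
    if dup.size:
        pairs = [tuple(map(int, p)) for p in dup[:5]]
        raise ValueError(f"duplicate observation locations at index pairs {pairs}")
    lhs = _kriging_lhs(fit, locations)
    d0 = cdist(locations, targets)
    rhs = np.empty((n + 1, targets.shape[0]))
    # prediction convention: a coincident target sees the nugget, so kriging
    # is exact at data sites only when the nugget is zero
    rhs[:n] = np.where(d0 > 0, fit(d0), float(fit.nugget))
    rhs[n] = 1.0
    sol = np.linalg.solve(lhs, rhs)
    w, mu = sol[:n], sol[n]
    pred = w.T @ values
    var = np.einsum("it,it->t", w, rhs[:n]) + mu
    var = np.where(var < 0, np.where(var > -1e-8, 0.0, var), var)
    if np.any(var < 0):
        warnings.warn("negative kriging variance beyond tolerance", stacklevel=2)
    return KrigingResult(targets, pred, var, weights=w.T if return_weights else None)


def loo_cross_validate(
    fit: VariogramFit, locations: np.ndarray, values: np.ndarray
) -> tuple[float, float]:
    """Leave-one-out kriging diagnostics (MSE, RMSSE).

    Each site is predicted from all others with the fitted model; MSE is
    the mean squared prediction error and RMSSE the root mean square of
    errors standardized by the kriging SE (close to 1 when the model's
    variance scale is well calibrated).
    """
    locations = np.asarray(locations, dtype=float)
    values = np.asarray(values, dtype=float)
    n = locations.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations for cross-validation")
    err2, std2 = [], []
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        try:
            res = ordinary_kriging(fit, locations[keep], values[keep], locations[i])
        except (np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"LOO site {i} skipped: {exc}", stacklevel=2)
            continue
        e = float(res.prediction[0] - values[i])
        err2.append(e * e)
        if res.variance[0] > 0:
            std2.append(e * e / float(res.variance[0]))
    if not err2:
        raise RuntimeError("all LOO systems singular")
    mse = float(np.mean(err2))
    rmsse = float(np.sqrt(np.mean(std2))) if std2 else float("nan")
    return mse, rmsse


def simulate_gaussian_field(
    fit_or_params, locations: np.ndarray, seed: int = 0, mean: float = 0.0
) -> np.ndarray:
    """Draw one Gaussian random field realization with a given variogram.

    The implied stationary covariance is ``C(h) = sill - gamma(h)`` with
    ``C(0) = sill`` (nugget included as iid measurement noise).
    """
    fit = fit_or_params
    locations = np.asarray(locations, dtype=float)
    n = locations.shape[0]
    D = squareform(pdist(locations))
    off = ~np.eye(n, dtype=bool)
    C = np.full((n, n), fit.sill)
    C[off] = fit.sill - fit(D[off])
    C += 1e-10 * np.eye(n)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(C)
    return mean + L @ rng.normal(size=n)
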