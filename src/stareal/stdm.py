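"""Quasi-maximum-likelihood estimation of space-time dynamic panel models.

The full general nesting (GNS) specification for an N-zone panel over T
waves, with row-standardized contiguity weights W, is

    y_t = rho W y_t + phi y_{t-1} + gamma W y_{t-1}
          + X_t beta + W X_t theta + u_t,
    u_t = lambda W u_t + eps_t,      eps_t ~ iid N(0, sigma2 I_N),

where rho is contemporaneous spatial dependence, phi temporal dependence,
gamma space-time diffusion, lambda spatial error dependence and theta the
spatial-Durbin (neighbour covariate) coefficients. Submodels switch terms
off: SAR (rho), SEM (lambda), SAC (rho, lambda), SDM (rho, theta); the GNS
nests all of them. No intercept is included by default: zone and wave
levels are absorbed by the dynamic and spatial terms, and a common
intercept would be collinear with them.

Estimation is Gaussian QML conditional on the first observed wave. For
each period the innovations are

    e_t = (I - lambda W) [ (I - rho W) y_t - phi y_{t-1} - gamma W y_{t-1}
                           - X_t beta - W X_t theta ],

and the log-likelihood over T' = T - 1 usable periods is

    ll = -N T'/2 * ln(2 pi sigma2) + T' ln|I - rho W| + T' ln|I - lambda W|
         - sum_t e_t' e_t / (2 sigma2).

Given (rho, lambda) every remaining parameter enters linearly, so
(phi, gamma, beta, theta, sigma2) are concentrated out by least squares on
the lambda-filtered system and the numerical search runs over (rho, lambda)
only, multi-started from a {0, +-0.3} grid inside the admissible interval.
Standard errors come from the inverse numerical Hessian of the full
likelihood at the optimum (Wald CIs, estimate +- 1.96 SE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .synthetic import GNSParams, ZonePanel
from .weights import SpatialWeights

_EPS_BOUND = 1e-6

SIG_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "."))


def significance_code(p: float) -> str:
    for cut, code in SIG_LEVELS:
        if p < cut:
            return code
    return ""


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    name: str
    include_rho: bool = False
    include_phi: bool = False
    include_gamma: bool = False
    include_lambda: bool = False
    include_theta: bool = False

    @classmethod
    def preset(cls, name: str) -> "ModelSpec":
        presets = {
            "SAR": cls("SAR", include_rho=True),
            "SEM": cls("SEM", include_lambda=True),
            "SAC": cls("SAC", include_rho=True, include_lambda=True),
            "SDM": cls("SDM", include_rho=True, include_theta=True),
            "GNSM": cls(
                "GNSM",
                include_rho=True,
                include_phi=True,
                include_gamma=True,
                include_lambda=True,
                include_theta=True,
            ),
        }
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
        return presets[name]

    @property
    def dynamic(self) -> bool:
        return self.include_phi or self.include_gamma


PRESETS = ("SAC", "SDM", "SAR", "GNSM")  # default comparison set


# ---------------------------------------------------------------------------
# Design stacks
# ---------------------------------------------------------------------------


@dataclass
class DesignStacks:
    """Per-period arrays for the QML objective, zone order matching W.

    Arrays are (T', N) for responses/lags and (T', N, k) for covariates,
    with W-products precomputed once so the concentrated objective is a
    few dense operations per evaluation.
    """

    y: np.ndarray
    Wy: np.ndarray
    WWy: np.ndarray
    ylag: np.ndarray | None
    Wylag: np.ndarray | None
    WWylag: np.ndarray | None
    X: np.ndarray
    WX: np.ndarray
    WWX: np.ndarray
    covariate_names: list[str]
    wave_labels: list
    eigs: np.ndarray  # eigenvalues of W
    dropped_first: bool

    @property
    def n(self) -> int:
        return self.y.shape[1]

    @property
    def t_eff(self) -> int:
        return self.y.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[2]


class UnbalancedPanelError(ValueError):
    def __init__(self, cells):
        self.cells = cells
        super().__init__(f"panel is unbalanced; missing zone-wave cells: {cells}")


def build_design(
    panel: ZonePanel, W: SpatialWeights, spec: ModelSpec, drop_first: bool | None = None
) -> DesignStacks:
    """Stack the panel into regression arrays aligned with W.

    The first wave is dropped whenever lagged terms are present (default),
    or when ``drop_first`` is forced True so that several specifications
    share an identical estimation sample and their AICs are comparable.
    """
    if not panel.balanced:
        raise UnbalancedPanelError(panel.missing_cells())
    if list(panel.zone_ids) != list(W.zone_ids):
        raise ValueError("panel zone order does not match W zone order")
    if drop_first is None:
        drop_first = spec.dynamic
    if spec.dynamic and panel.n_waves < 2:
        raise ValueError("dynamic terms need at least 2 waves")
    if drop_first and panel.n_waves < 2:
        raise ValueError("cannot drop the first wave of a 1-wave panel")
    Wm = W.matrix
    t0 = 1 if drop_first else 0
    y = panel.y[:, t0:].T  # (T', N)
    X = np.moveaxis(panel.X[:, t0:, :], 0, 1)  # (T', N, k)
    Wy = y @ Wm.T
    WWy = Wy @ Wm.T
    if drop_first:
        ylag = panel.y[:, t0 - 1 : -1].T
        Wylag = ylag @ Wm.T
        WWylag = Wylag @ Wm.T
    else:
        ylag = Wylag = WWylag = None
    WX = np.einsum("ij,tjk->tik", Wm, X)
    WWX = np.einsum("ij,tjk->tik", Wm, WX)
    return DesignStacks(
        y,
        Wy,
        WWy,
        ylag,
        Wylag,
        WWylag,
        X,
        WX,
        WWX,
        list(panel.covariate_names),
        list(panel.wave_labels[t0:]),
        np.linalg.eigvals(Wm),
        drop_first,
    )


def _logdet(scale: float, eigs: np.ndarray) -> float:
    """ln|I - scale*W| from the eigenvalues of W."""
    return float(np.sum(np.log(1.0 - scale * eigs)).real)


def _bounds(stacks: DesignStacks) -> tuple[float, float]:
    real = stacks.eigs[np.abs(stacks.eigs.imag) < 1e-9].real
    return 1.0 / real.min() + _EPS_BOUND, 1.0 / real.max() - _EPS_BOUND


def _residuals(params: GNSParams, stacks: DesignStacks, spec: ModelSpec) -> np.ndarray:
    """Innovations e_t, shape (T', N)."""
    r = stacks.y - params.rho * stacks.Wy
    Wr = stacks.Wy - params.rho * stacks.WWy
    if spec.include_phi:
        r = r - params.phi * stacks.ylag
        Wr = Wr - params.phi * stacks.Wylag
    if spec.include_gamma:
        r = r - params.gamma * stacks.Wylag
        Wr = Wr - params.gamma * stacks.WWylag
    r = r - np.einsum("tnk,k->tn", stacks.X, params.beta)
    Wr = Wr - np.einsum("tnk,k->tn", stacks.WX, params.beta)
    if spec.include_theta:
        r = r - np.einsum("tnk,k->tn", stacks.WX, params.theta)
        Wr = Wr - np.einsum("tnk,k->tn", stacks.WWX, params.theta)
    return r - params.lam * Wr


def log_likelihood(
    params: GNSParams, stacks: DesignStacks, W: SpatialWeights, spec: ModelSpec
) -> float:
    """Exact conditional Gaussian log-density of the stacked panel.

    Returns -inf (optimizer-safe) when rho or lambda leaves the admissible
    interval or sigma2 is non-positive.
    """
    lo, hi = _bounds(stacks)
    if not (lo <= params.rho <= hi and lo <= params.lam <= hi):
        return -np.inf
    if params.sigma2 <= 0:
        return -np.inf
    e = _residuals(params, stacks, spec)
    nt = e.size
    tp = stacks.t_eff
    return (
        -0.5 * nt * np.log(2.0 * np.pi * params.sigma2)
        + tp * _logdet(params.rho, stacks.eigs)
        + tp * _logdet(params.lam, stacks.eigs)
        - float(np.sum(e * e)) / (2.0 * params.sigma2)
    )


# ---------------------------------------------------------------------------
# Concentrated objective
# ---------------------------------------------------------------------------


def _linear_columns(stacks: DesignStacks, spec: ModelSpec):
    """(labels, Z, WZ) for the linearly entering terms, stacked (NT', m)."""
    cols, wcols, labels = [], [], []
    if spec.include_phi:
        cols.append(stacks.ylag[..., None])
        wcols.append(stacks.Wylag[..., None])
        labels.append("phi")
    if spec.include_gamma:
        cols.append(stacks.Wylag[..., None])
        wcols.append(stacks.WWylag[..., None])
        labels.append("gamma")
    cols.append(stacks.X)
    wcols.append(stacks.WX)
    labels.extend(f"beta:{c}" for c in stacks.covariate_names)
    if spec.include_theta:
        cols.append(stacks.WX)
        wcols.append(stacks.WWX)
        labels.extend(f"theta:{c}" for c in stacks.covariate_names)
    Z = np.concatenate(cols, axis=2).reshape(-1, sum(c.shape[2] for c in cols))
    WZ = np.concatenate(wcols, axis=2).reshape(Z.shape)
    return labels, Z, WZ


def _concentrated(rho: float, lam: float, stacks: DesignStacks, spec: ModelSpec, lin):
    labels, Z, WZ = lin
    r = (stacks.y - rho * stacks.Wy).ravel()
    Wr = (stacks.Wy - rho * stacks.WWy).ravel()
    resp = r - lam * Wr
    design = Z - lam * WZ
    coef, *_ = np.linalg.lstsq(design, resp, rcond=None)
    resid = resp - design @ coef
    rss = float(resid @ resid)
    nt = resp.size
    sigma2 = max(rss / nt, 1e-300)
    tp = stacks.t_eff
    ll = (
        -0.5 * nt * (np.log(2.0 * np.pi * sigma2) + 1.0)
        + tp * _logdet(rho, stacks.eigs)
        + tp * _logdet(lam, stacks.eigs)
    )
    return ll, coef, sigma2, labels


def _params_from(coef, labels, rho, lam, sigma2) -> GNSParams:
    d = dict(zip(labels, coef))
    beta = np.array([v for lbl, v in zip(labels, coef) if lbl.startswith("beta:")])
    theta = np.array([v for lbl, v in zip(labels, coef) if lbl.startswith("theta:")])
    return GNSParams(
        rho=rho,
        phi=float(d.get("phi", 0.0)),
        gamma=float(d.get("gamma", 0.0)),
        lam=lam,
        beta=beta,
        theta=theta if theta.size else np.zeros(0),
        sigma2=sigma2,
    )


# ---------------------------------------------------------------------------
# Fit container
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    spec: ModelSpec
    params: GNSParams
    loglik: float
    aic: float
    k_free: int
    multiple_r2: float
    adjusted_r2: float
    table: pd.DataFrame  # parameter, estimate, se, ci_low, ci_high, p, code
    fitted: np.ndarray
    observed: np.ndarray
    ses_reliable: bool = True
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "loglik": self.loglik,
            "aic": self.aic,
            "k": self.k_free,
            "multiple_r2": self.multiple_r2,
            "adjusted_r2": self.adjusted_r2,
            "ses_reliable": self.ses_reliable,
            "parameters": self.table.to_dict(orient="records"),
        }


def _free_param_layout(spec: ModelSpec, k: int):
    names = []
    if spec.include_rho:
        names.append("rho")
    if spec.include_phi:
        names.append("phi")
    if spec.include_gamma:
        names.append("gamma")
    if spec.include_lambda:
        names.append("lambda")
    names.extend(f"beta:{i}" for i in range(k))
    if spec.include_theta:
        names.extend(f"theta:{i}" for i in range(k))
    names.append("sigma2")
    return names


def _pack(params: GNSParams, spec: ModelSpec) -> np.ndarray:
    vec = []
    if spec.include_rho:
        vec.append(params.rho)
    if spec.include_phi:
        vec.append(params.phi)
    if spec.include_gamma:
        vec.append(params.gamma)
    if spec.include_lambda:
        vec.append(params.lam)
    vec.extend(params.beta)
    if spec.include_theta:
        vec.extend(params.theta)
    vec.append(params.sigma2)
    return np.array(vec)


def _unpack(vec: np.ndarray, spec: ModelSpec, k: int) -> GNSParams:
    i = 0
    rho = phi = gamma = lam = 0.0
    if spec.include_rho:
        rho = vec[i]; i += 1
    if spec.include_phi:
        phi = vec[i]; i += 1
    if spec.include_gamma:
        gamma = vec[i]; i += 1
    if spec.include_lambda:
        lam = vec[i]; i += 1
    beta = vec[i : i + k]; i += k
    theta = vec[i : i + k] if spec.include_theta else np.zeros(0)
    if spec.include_theta:
        i += k
    return GNSParams(rho=rho, phi=phi, gamma=gamma, lam=lam, beta=beta,
                     theta=theta, sigma2=float(vec[i]))


def _numerical_hessian(f, x: np.ndarray) -> np.ndarray:
    p = x.size
    H = np.empty((p, p))
    h = 1e-4 * np.maximum(np.abs(x), 1e-3)
    for a in range(p):
        for b in range(a, p):
            ea = np.zeros(p); ea[a] = h[a]
            eb = np.zeros(p); eb[b] = h[b]
            fpp = f(x + ea + eb)
            fpm = f(x + ea - eb)
            fmp = f(x - ea + eb)
            fmm = f(x - ea - eb)
            H[a, b] = H[b, a] = (fpp - fpm - fmp + fmm) / (4.0 * h[a] * h[b])
    return H


def fit_stdm(
    panel: ZonePanel,
    W: SpatialWeights,
    spec: ModelSpec,
    drop_first: bool | None = None,
    compute_se: bool = True,
    start_grid=(0.0, 0.3, -0.3),
) -> ModelFit:
    """QML fit of one space-time dynamic specification.

    beta, theta, phi, gamma and sigma2 are concentrated out analytically;
    the numerical search runs over whichever of (rho, lambda) the spec
    includes, multi-started from ``start_grid``. SEs are Wald, from the
    inverse numerical Hessian of the full likelihood; if that Hessian is
    not negative definite the fit is returned with ``ses_reliable=False``.
    """
    stacks = build_design(panel, W, spec, drop_first=drop_first)
    lin = _linear_columns(stacks, spec)
    lo, hi = _bounds(stacks)

    free = [n for n, on in (("rho", spec.include_rho), ("lambda", spec.include_lambda)) if on]

    def value(v):
        rho = v[free.index("rho")] if "rho" in free else 0.0
        lam = v[free.index("lambda")] if "lambda" in free else 0.0
        return _concentrated(rho, lam, stacks, spec, lin)

    converged = True
    if free:
        def neg(v):
            return -value(v)[0]

        best = None
        grid = [g for g in start_grid if lo < g < hi]
        starts = [np.array(s) for s in np.array(np.meshgrid(*[grid] * len(free))).T.reshape(-1, len(free))]
        for x0 in starts:
            res = minimize(
                neg, x0, method="L-BFGS-B", bounds=[(lo, hi)] * len(free)
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError("no admissible starting point for (rho, lambda)")
        converged = bool(best.success)
        ll, coef, sigma2, labels = value(best.x)
        rho = best.x[free.index("rho")] if "rho" in free else 0.0
        lam = best.x[free.index("lambda")] if "lambda" in free else 0.0
    else:
        ll, coef, sigma2, labels = value(np.zeros(0))
        rho = lam = 0.0

    params = _params_from(coef, labels, float(rho), float(lam), float(sigma2))
    loglik = log_likelihood(params, stacks, W, spec)

    # fitted values: reduced-form conditional mean per period
    n = stacks.n
    A = np.eye(n) - params.rho * W.matrix
    mean = np.einsum("tnk,k->tn", stacks.X, params.beta)
    if spec.include_theta:
        mean = mean + np.einsum("tnk,k->tn", stacks.WX, params.theta)
    if spec.include_phi:
        mean = mean + params.phi * stacks.ylag
    if spec.include_gamma:
        mean = mean + params.gamma * stacks.Wylag
    fitted = np.linalg.solve(A, mean.T).T
    obs = stacks.y
    r = np.corrcoef(fitted.ravel(), obs.ravel())[0, 1]
    multiple_r2 = float(r * r)
    nt = obs.size
    k_free = len(free) + len(coef) + 1  # + sigma2
    adjusted_r2 = float(1.0 - (1.0 - multiple_r2) * (nt - 1) / (nt - k_free))
    aic = 2.0 * k_free - 2.0 * loglik

    names = _free_param_layout(spec, stacks.k)
    est = _pack(params, spec)
    se = np.full(est.size, np.nan)
    ses_reliable = False
    if compute_se:
        def full_ll(v):
            return log_likelihood(_unpack(v, spec, stacks.k), stacks, W, spec)

        H = _numerical_hessian(full_ll, est)
        try:
            cov = np.linalg.inv(-H)
            d = np.diag(cov)
            if np.all(d > 0):
                se = np.sqrt(d)
                ses_reliable = True
            else:
                se = np.sqrt(np.abs(np.diag(np.linalg.pinv(-H))))
        except np.linalg.LinAlgError:
            se = np.sqrt(np.abs(np.diag(np.linalg.pinv(-H))))

    zval = est / se
    pval = 2.0 * norm.sf(np.abs(zval))
    pretty = []
    for nm in names:
        if nm.startswith("beta:"):
            pretty.append(f"beta:{stacks.covariate_names[int(nm.split(':')[1])]}")
        elif nm.startswith("theta:"):
            pretty.append(f"theta:{stacks.covariate_names[int(nm.split(':')[1])]}")
        else:
            pretty.append(nm)
    table = pd.DataFrame(
        {
            "parameter": pretty,
            "estimate": est,
            "se": se,
            "ci_low": est - 1.96 * se,
            "ci_high": est + 1.96 * se,
            "p_value": pval,
            "code": [significance_code(p) if np.isfinite(p) else "" for p in pval],
        }
    )
    return ModelFit(
        spec,
        params,
        float(loglik),
        float(aic),
        k_free,
        multiple_r2,
        adjusted_r2,
        table,
        fitted,
        obs,
        ses_reliable=ses_reliable,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonTable:
    frame: pd.DataFrame  # model, aic, multiple_r2, adjusted_r2, selected, error
    fits: dict[str, ModelFit] = field(default_factory=dict)

    @property
    def selected(self) -> str:
        return str(self.frame.loc[self.frame["selected"], "model"].iloc[0])


def compare_models(
    panel: ZonePanel,
    W: SpatialWeights,
    specs=None,
    compute_se: bool = False,
) -> ComparisonTable:
    """Fit several specifications on an identical sample and rank by AIC.

    The first wave is dropped for every spec (even static ones) so all
    models see the same observations and their AICs are comparable. The
    AIC-minimal row is selected; ties go to the model with fewer free
    parameters, then input order. A failing member is flagged and the
    comparison proceeds.
    """
    if specs is None:
        specs = [ModelSpec.preset(p) for p in PRESETS]
    specs = [ModelSpec.preset(s) if isinstance(s, str) else s for s in specs]
    if len(specs) < 2:
        raise ValueError("need at least 2 specifications to compare")
    rows, fits = [], {}
    for order, spec in enumerate(specs):
        try:
            fit = fit_stdm(panel, W, spec, drop_first=True, compute_se=compute_se)
            fits[spec.name] = fit
            rows.append(
                {
                    "model": spec.name,
                    "aic": fit.aic,
                    "multiple_r2": fit.multiple_r2,
                    "adjusted_r2": fit.adjusted_r2,
                    "k": fit.k_free,
                    "order": order,
                    "error": "",
                }
            )
        except Exception as exc:  # noqa: BLE001 - flagged, comparison proceeds
            rows.append(
                {
                    "model": spec.name,
                    "aic": np.nan,
                    "multiple_r2": np.nan,
                    "adjusted_r2": np.nan,
                    "k": np.nan,
                    "order": order,
                    "error": str(exc),
                }
            )
    df = pd.DataFrame(rows)
    ok = df["aic"].notna()
    if not ok.any():
        raise RuntimeError("every model fit failed")
    ranked = df[ok].sort_values(["aic", "k", "order"], kind="stable")
    df["selected"] = False
    df.loc[ranked.index[0], "selected"] = True
    df = df.sort_values(["aic", "k", "order"], kind="stable", na_position="last")
    df = df.drop(columns=["order"]).reset_index(drop=True)
    return ComparisonTable(df, fits)
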