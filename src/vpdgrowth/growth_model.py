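"""Site-level growth model: log-BAI regressed on log prior basal area, a
penalized cubic-spline age smooth and summer VPD of the current and prior
year, with tree random intercepts and AR1 within-tree residuals.

Estimation is whitened penalized least squares.  The within-tree marginal
covariance is ``sigma^2 (tau J + R(phi))`` where ``J`` is all-ones (tree
random intercept, ``tau`` the variance ratio) and ``R`` the stationary
AR1 correlation matrix; for each candidate ``(lambda, phi, tau)`` the
model is whitened by the per-tree Cholesky factor and the penalized
normal equations solved.  By default all three are chosen jointly by
minimizing the REML criterion; a GCV mode instead iterates lambda-by-GCV
with moment updates of ``phi`` and ``tau``.

Wald t-tests for the VPD coefficients use the posterior covariance
``sigma^2 (X'X + lambda S)^{-1}`` of the whitened system, with residual
degrees of freedom ``n - edf(model) - n_trees``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, linalg, optimize, stats

__all__ = [
    "GrowthModelSpec",
    "GrowthModelFit",
    "VPDResponse",
    "build_spline_basis",
    "fit_growth_gamm",
    "fit_partial_smi_model",
    "wald_tests",
    "classify_response",
    "goodness_of_fit",
]

_GAUSS2 = (-1.0 / np.sqrt(3.0), 1.0 / np.sqrt(3.0))


@dataclass(frozen=True)
class GrowthModelSpec:
    basis_dim: int = 10
    smoothness_selection: str = "REML"   # "REML" or "GCV"
    include_vpd: bool = True
    include_smi: bool = False
    alpha_level: float = 0.05
    max_iter: int = 200
    tol: float = 1e-6
    fixed_phi: float | None = None
    fixed_lambda: float | None = None
    fixed_tree_var_ratio: float | None = None

    def __post_init__(self):
        if self.basis_dim < 4:
            raise ValueError("spline basis dimension must be >= 4")
        if not 0.0 < self.alpha_level < 1.0:
            raise ValueError("alpha_level must lie in (0, 1)")
        if self.smoothness_selection not in ("REML", "GCV"):
            raise ValueError("smoothness_selection must be REML or GCV")


@dataclass
class SplineBasis:
    knots: np.ndarray
    degree: int
    constraint: np.ndarray  # Z, (k x k-1) null space of the sum-to-zero constraint
    xmin: float
    xmax: float

    def design(self, x) -> np.ndarray:
        xc = np.clip(np.asarray(x, dtype=float), self.xmin, self.xmax)
        B = interpolate.BSpline.design_matrix(xc, self.knots, self.degree).toarray()
        return B @ self.constraint


@dataclass
class GrowthModelFit:
    converged: bool
    reason: str | None = None
    site_id: str | None = None
    species: str | None = None
    include_smi: bool = False
    coef: dict = field(default_factory=dict)
    se: dict = field(default_factory=dict)
    alpha_hat: float = np.nan
    beta1_hat: float = np.nan
    beta2_hat: float = np.nan
    t_beta1: float = np.nan
    t_beta2: float = np.nan
    p_beta1: float = np.nan
    p_beta2: float = np.nan
    phi_hat: float = np.nan
    sigma_tree_hat: float = np.nan
    sigma_eps_hat: float = np.nan       # AR1 innovation SD
    sigma_marg_hat: float = np.nan      # marginal residual SD
    lambda_hat: float = np.nan
    spline_coefs: np.ndarray | None = None
    edf: float = np.nan
    df_resid: float = np.nan
    r2_fluctuations: float = np.nan
    n_obs: int = 0
    n_trees: int = 0
    observed: np.ndarray | None = None
    fitted: np.ndarray | None = None          # conditional on tree BLUPs
    fitted_marginal: np.ndarray | None = None
    tree_ids: np.ndarray | None = None
    years: np.ndarray | None = None
    cov: np.ndarray | None = None
    colnames: list = field(default_factory=list)
    basis: SplineBasis | None = None


@dataclass(frozen=True)
class VPDResponse:
    site_id: str | None
    species: str | None
    class_vpd_t: str
    class_vpd_t1: str


# ---------------------------------------------------------------------------
# Spline basis


def build_spline_basis(age_values, basis_dim: int) -> tuple[np.ndarray, np.ndarray, SplineBasis]:
    """Cubic B-spline basis with knots at age quantiles plus its exact
    integrated-second-derivative penalty.

    Returns the constrained design (sum-to-zero over the data rows), the
    constrained penalty (symmetric PSD, rank ``basis_dim - 2``) and the
    reusable basis object for prediction.
    """
    x = np.asarray(age_values, dtype=float)
    xu = np.unique(x)
    k = int(basis_dim)
    if len(xu) < k:
        warnings.warn(f"only {len(xu)} distinct ages; reducing basis from {k}")
        k = max(4, len(xu))
    degree = 3
    xmin, xmax = float(xu[0]), float(xu[-1])
    n_interior = k - degree - 1
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(xu, qs)
    else:
        interior = np.empty(0)
    knots = np.concatenate([[xmin] * (degree + 1), interior, [xmax] * (degree + 1)])
    B = interpolate.BSpline.design_matrix(x, knots, degree).toarray()

    # exact second-derivative penalty: 2-point Gauss per inter-knot interval
    S = np.zeros((k, k))
    spl2 = interpolate.BSpline(knots, np.eye(k), degree, axis=0).derivative(2)
    grid = np.unique(knots)
    for a, b in zip(grid[:-1], grid[1:]):
        h = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        for g in _GAUSS2:
            d2 = spl2(mid + h * g)  # (k,)
            S += h * np.outer(d2, d2)

    # absorb sum-to-zero constraint: columns orthogonal to the column-mean vector
    c = B.mean(axis=0)
    q, _ = np.linalg.qr(c[:, None], mode="complete")
    Z = q[:, 1:]
    basis = SplineBasis(knots=knots, degree=degree, constraint=Z, xmin=xmin, xmax=xmax)
    return B @ Z, Z.T @ S @ Z, basis


# ---------------------------------------------------------------------------
# Design assembly and whitening


def _build_design(data: pd.DataFrame, spec: GrowthModelSpec):
    fixed_cols = ["log_ba_prev"]
    if spec.include_vpd:
        fixed_cols += ["vpd_t", "vpd_t1"]
    if spec.include_smi:
        fixed_cols += [c for c in ("smi_t", "smi_t1") if c in data.columns]
        if not any(c.startswith("smi") for c in fixed_cols):
            raise ValueError("include_smi requires smi_t (and optionally smi_t1) columns")
    Xf = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(float) for c in fixed_cols])
    colnames = ["intercept"] + fixed_cols
    Bz, Sz, basis = build_spline_basis(data["age"].to_numpy(float), spec.basis_dim)
    X = np.hstack([Xf, Bz])
    p_fix = Xf.shape[1]
    p = X.shape[1]
    S = np.zeros((p, p))
    S[p_fix:, p_fix:] = Sz
    rank_S = Bz.shape[1] - 1  # one linear direction survives the constraint
    colnames += [f"s(age).{i+1}" for i in range(Bz.shape[1])]
    return X, S, rank_S, p_fix, colnames, basis


def _tree_blocks(data: pd.DataFrame):
    """Row-index blocks per tree, each sorted by year."""
    blocks = []
    for tid, grp in data.groupby("tree_id", sort=True):
        idx = grp.sort_values("year").index.to_numpy()
        years = grp.sort_values("year")["year"].to_numpy()
        blocks.append((tid, idx, years))
    return blocks


def _whiten(X, y, blocks, pos, phi, tau):
    """Per-tree whitening by the Cholesky factor of tau*J + R(phi).

    ``pos`` maps original row labels to array positions.  Returns the
    whitened X, y and the total log-determinant of the covariance."""
    Xw = np.empty_like(X)
    yw = np.empty_like(y)
    logdet = 0.0
    for _, idx, years in blocks:
        rows = pos[idx]
        m = len(rows)
        if m == 1:
            v = np.sqrt(tau + 1.0)
            Xw[rows] = X[rows] / v
            yw[rows] = y[rows] / v
            logdet += 2.0 * np.log(v)
            continue
        lag = np.abs(years[:, None] - years[None, :])
        V = tau + np.power(phi, lag) if phi != 0.0 else tau + np.eye(m)
        if phi == 0.0:
            V = tau * np.ones((m, m)) + np.eye(m)
        L = linalg.cholesky(V, lower=True)
        Xw[rows] = linalg.solve_triangular(L, X[rows], lower=True)
        yw[rows] = linalg.solve_triangular(L, y[rows], lower=True)
        logdet += 2.0 * np.sum(np.log(np.diag(L)))
    return Xw, yw, logdet


def _penalized_solve(Xw, yw, S, lam):
    A = Xw.T @ Xw + lam * S
    cA, low = linalg.cho_factor(A)
    b = linalg.cho_solve((cA, low), Xw.T @ yw)
    logdet_A = 2.0 * np.sum(np.log(np.diag(cA)))
    F = linalg.cho_solve((cA, low), Xw.T @ Xw)  # influence on coefficients
    edf = float(np.trace(F))
    Ainv = linalg.cho_solve((cA, low), np.eye(A.shape[0]))
    return b, edf, logdet_A, Ainv


# ---------------------------------------------------------------------------
# Fitting


def fit_growth_gamm(data: pd.DataFrame, spec: GrowthModelSpec | None = None,
                    site_id: str | None = None, species: str | None = None) -> GrowthModelFit:
    """Fit the growth model for one site-species dataset.

    ``data`` columns: tree_id, year, log_bai, log_ba_prev, age, vpd_t,
    vpd_t1 (plus smi_t/smi_t1 for the partial-SMI variant).  Failures
    (rank deficiency, non-convergence) return a fit with
    ``converged=False`` and a reason — never an exception.
    """
    spec = spec or GrowthModelSpec()
    data = data.reset_index(drop=True)
    site_id = site_id or (data["site_id"].iloc[0] if "site_id" in data else None)
    species = species or (data["species"].iloc[0] if "species" in data else None)

    def failed(reason):
        return GrowthModelFit(converged=False, reason=reason, site_id=site_id,
                              species=species, include_smi=spec.include_smi,
                              n_obs=len(data), n_trees=data["tree_id"].nunique())

    try:
        X, S, rank_S, p_fix, colnames, basis = _build_design(data, spec)
    except (ValueError, KeyError) as exc:
        return failed(f"design construction failed: {exc}")
    y = data["log_bai"].to_numpy(float)
    n, p = X.shape
    if n <= p + 2:
        return failed(f"too few observations ({n}) for {p} coefficients")
    if np.linalg.matrix_rank(X) < p:
        return failed("rank-deficient design (e.g. constant covariate)")
    blocks = _tree_blocks(data)
    pos = np.empty(len(data), dtype=int)
    pos[np.arange(len(data))] = np.arange(len(data))
    n_trees = len(blocks)
    Mp = p_fix + 1  # unpenalized dims: fixed effects + penalty null space

    free = []
    if spec.fixed_lambda is None:
        free.append("lam")
    if spec.fixed_phi is None:
        free.append("phi")
    if spec.fixed_tree_var_ratio is None:
        free.append("tau")

    def unpack(theta):
        d = dict(zip(free, theta))
        lam = np.exp(d["lam"]) if "lam" in d else spec.fixed_lambda
        phi = np.tanh(d["phi"]) if "phi" in d else spec.fixed_phi
        tau = np.exp(d["tau"]) if "tau" in d else spec.fixed_tree_var_ratio
        return lam, phi, tau

    def reml_score(theta):
        lam, phi, tau = unpack(theta)
        if not np.isfinite(lam) or lam <= 0 or abs(phi) > 0.995 or tau > 1e6:
            return 1e12
        try:
            Xw, yw, logdet_V = _whiten(X, y, blocks, pos, phi, tau)
            b, edf, logdet_A, _ = _penalized_solve(Xw, yw, S, lam)
        except linalg.LinAlgError:
            return 1e12
        r = yw - Xw @ b
        rss_pen = float(r @ r + lam * b @ S @ b)
        if rss_pen <= 0:
            return 1e12
        sig2 = rss_pen / (n - Mp)
        score = ((n - Mp) * np.log(sig2) + logdet_V + logdet_A - rank_S * np.log(lam))
        return score if np.isfinite(score) else 1e12

    try:
        if spec.smoothness_selection == "REML" or not free:
            if free:
                x0 = {"lam": 0.0, "phi": np.arctanh(0.3), "tau": np.log(0.5)}
                theta0 = np.array([x0[f] for f in free])
                res = optimize.minimize(
                    reml_score, theta0, method="Nelder-Mead",
                    options={"maxiter": spec.max_iter * 10, "xatol": spec.tol * 100,
                             "fatol": spec.tol * 100},
                )
                theta = res.x
                opt_ok = np.isfinite(res.fun) and res.fun < 1e11
            else:
                theta = np.empty(0)
                opt_ok = True
            lam, phi, tau = unpack(theta)
        else:
            lam, phi, tau, opt_ok = _gcv_iterate(X, y, S, blocks, pos, spec, n, Mp)
    except linalg.LinAlgError:
        return failed("linear algebra failure during optimization")

    if not opt_ok:
        return failed("smoothness/variance optimization failed to converge")

    Xw, yw, _ = _whiten(X, y, blocks, pos, phi, tau)
    try:
        b, edf, _, Ainv = _penalized_solve(Xw, yw, S, lam)
    except linalg.LinAlgError:
        return failed("singular penalized system at optimum")
    resid_w = yw - Xw @ b
    rss = float(resid_w @ resid_w)
    sig2 = rss / max(n - edf, 1.0)
    cov = sig2 * Ainv
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    if np.any(se[:p_fix] == 0):
        return failed("degenerate standard error")

    df_resid = max(n - edf - n_trees, 3.0)
    coef = dict(zip(colnames, b))
    se_d = dict(zip(colnames, se))

    sigma_marg = float(np.sqrt(sig2))
    fit = GrowthModelFit(
        converged=True, site_id=site_id, species=species, include_smi=spec.include_smi,
        coef=coef, se=se_d,
        alpha_hat=float(coef.get("log_ba_prev", np.nan)),
        beta1_hat=float(coef.get("vpd_t", np.nan)),
        beta2_hat=float(coef.get("vpd_t1", np.nan)),
        phi_hat=float(phi),
        sigma_tree_hat=float(np.sqrt(tau) * sigma_marg),
        sigma_eps_hat=float(sigma_marg * np.sqrt(max(1.0 - phi**2, 0.0))),
        sigma_marg_hat=sigma_marg,
        lambda_hat=float(lam),
        spline_coefs=b[p_fix:].copy(),
        edf=float(edf), df_resid=float(df_resid),
        n_obs=n, n_trees=n_trees,
        observed=y.copy(),
        tree_ids=data["tree_id"].to_numpy(),
        years=data["year"].to_numpy(),
        cov=cov, colnames=list(colnames), basis=basis,
    )

    # marginal and conditional (BLUP) fitted values
    eta = X @ b
    fitted = eta.copy()
    for tid, idx, years in blocks:
        rows = pos[idx]
        m = len(rows)
        r = y[rows] - eta[rows]
        if tau > 0:
            lag = np.abs(years[:, None] - years[None, :])
            V = tau + np.power(phi, lag)
            blup = float(tau * np.ones(m) @ np.linalg.solve(V, r))
        else:
            blup = 0.0
        fitted[rows] = eta[rows] + blup
    fit.fitted_marginal = eta
    fit.fitted = fitted
    fit.r2_fluctuations = goodness_of_fit(fit)

    t1, p1, t2, p2 = _vpd_tests(fit)
    fit.t_beta1, fit.p_beta1, fit.t_beta2, fit.p_beta2 = t1, p1, t2, p2
    return fit


def _gcv_iterate(X, y, S, blocks, pos, spec, n, Mp):
    """Spec's iterative scheme: lambda by GCV given (phi, tau); moment
    updates of phi (within-tree residual lag-1 autocorrelation) and tau
    (between-tree variance of residual means); repeat to tolerance."""
    phi = 0.0 if spec.fixed_phi is None else spec.fixed_phi
    tau = 0.5 if spec.fixed_tree_var_ratio is None else spec.fixed_tree_var_ratio
    lam = 1.0 if spec.fixed_lambda is None else spec.fixed_lambda
    prev = np.array([lam, phi, tau])
    for _ in range(spec.max_iter):
        Xw, yw, _ = _whiten(X, y, blocks, pos, phi, tau)

        def gcv(loglam):
            b, edf, _, _ = _penalized_solve(Xw, yw, S, np.exp(loglam))
            r = yw - Xw @ b
            return n * float(r @ r) / (n - min(edf, n - 1)) ** 2

        if spec.fixed_lambda is None:
            res = optimize.minimize_scalar(gcv, bounds=(-12, 12), method="bounded")
            lam = float(np.exp(res.x))
        b, _, _, _ = _penalized_solve(Xw, yw, S, lam)
        resid = y - X @ b
        means, within = [], []
        num = den = 0.0
        for _, idx, years in blocks:
            r = resid[pos[idx]]
            means.append(r.mean())
            d = r - r.mean()
            within.append(d)
            if len(d) > 2:
                num += float(d[1:] @ d[:-1])
                den += float(d @ d)
        w_all = np.concatenate(within)
        sig2_w = float(w_all @ w_all) / max(len(w_all) - 1, 1)
        if spec.fixed_phi is None:
            phi = float(np.clip(num / den if den > 0 else 0.0, -0.95, 0.95))
        if spec.fixed_tree_var_ratio is None:
            between = float(np.var(means, ddof=1)) if len(means) > 1 else 0.0
            tau = max((between - sig2_w / np.mean([len(w) for w in within])) / max(sig2_w, 1e-12), 0.0)
        cur = np.array([lam, phi, tau])
        if np.all(np.abs(cur - prev) <= spec.tol * (1.0 + np.abs(prev))):
            return lam, phi, tau, True
        prev = cur
    return lam, phi, tau, False


def _vpd_tests(fit: GrowthModelFit):
    out = []
    for name in ("vpd_t", "vpd_t1"):
        if name not in fit.coef:
            out += [np.nan, np.nan]
            continue
        b, s = fit.coef[name], fit.se[name]
        if s <= 0:
            out += [np.nan, np.nan]
            continue
        t = b / s
        p = 2.0 * stats.t.sf(abs(t), fit.df_resid)
        out += [float(t), float(p)]
    return out[0], out[1], out[2], out[3]


def wald_tests(fit: GrowthModelFit) -> dict:
    """t statistics and two-sided p-values for the VPD coefficients."""
    if not fit.converged:
        raise ValueError("wald_tests requires a converged fit")
    return {
        "vpd_t": {"estimate": fit.beta1_hat, "se": fit.se.get("vpd_t", np.nan),
                  "t": fit.t_beta1, "p": fit.p_beta1},
        "vpd_t1": {"estimate": fit.beta2_hat, "se": fit.se.get("vpd_t1", np.nan),
                   "t": fit.t_beta2, "p": fit.p_beta2},
        "df": fit.df_resid,
    }


def classify_response(fit: GrowthModelFit, alpha_level: float = 0.05) -> VPDResponse:
    """Sign/significance classes for both VPD covariates."""
    def one(t, p):
        if not fit.converged or not np.isfinite(t) or not np.isfinite(p):
            return "nonconvergent"
        if p < alpha_level:
            return "negative" if t < 0 else "positive"
        return "nonsignificant"

    if not fit.converged:
        return VPDResponse(fit.site_id, fit.species, "nonconvergent", "nonconvergent")
    return VPDResponse(fit.site_id, fit.species,
                       one(fit.t_beta1, fit.p_beta1), one(fit.t_beta2, fit.p_beta2))


def fit_partial_smi_model(data: pd.DataFrame, spec: GrowthModelSpec | None = None,
                          **kw) -> GrowthModelFit:
    """Growth model augmented with linear summer-SMI covariates, so the
    VPD tests are conditional on soil moisture."""
    base = spec or GrowthModelSpec()
    spec_smi = GrowthModelSpec(**{**base.__dict__, "include_smi": True})
    return fit_growth_gamm(data, spec_smi, **kw)


def goodness_of_fit(fit: GrowthModelFit, observed=None) -> float:
    """Squared Pearson correlation between observed and fitted log-BAI,
    pooled over trees."""
    obs = fit.observed if observed is None else np.asarray(observed, dtype=float)
    if fit.fitted is None:
        raise ValueError("fit has no stored fitted values")
    pred = fit.fitted
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    r = np.corrcoef(obs, pred)[0, 1]
    return float(r * r)
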