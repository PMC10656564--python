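"""Statistical layer relating canopy structure to mortality rate.

Weighted binning of per-unit mortality rates, weighted linear regression,
continuous piecewise (segmented) regression with exhaustive breakpoint
search and BIC model selection, beta regression for proportion outcomes,
a random-intercept mixed model, bootstrap mediation analysis, and
random-forest importance / partial-dependence analysis.

Weights throughout are tree counts: a bin (or unit) containing more trees
carries proportionally more weight, matching how the binned mortality-rate
series are constructed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

@dataclass
class BinnedSeries:
    """Weighted binned series of rates along one covariate."""

    edges: np.ndarray
    centers: np.ndarray          # non-empty bins only
    mean: np.ndarray             # weighted mean rate per bin
    q1: np.ndarray               # unweighted first quartile of rates
    q3: np.ndarray
    weight: np.ndarray           # total tree count per bin

    def __len__(self) -> int:
        return len(self.centers)


def bin_weighted(x, rate, weight, bin_width: float) -> BinnedSeries:
    """Bin rates along ``x`` with tree-count weights.

    Bins are aligned to multiples of ``bin_width``; empty bins are dropped.
    Per-bin statistics: weighted mean rate, unweighted Q1/Q3, total weight.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = np.asarray(x, dtype=float)
    rate = np.asarray(rate, dtype=float)
    w = np.asarray(weight, dtype=float)
    ok = np.isfinite(x) & np.isfinite(rate) & np.isfinite(w)
    x, rate, w = x[ok], rate[ok], w[ok]
    if len(x) == 0:
        e = np.array([])
        return BinnedSeries(e, e, e, e, e, e)
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    idx = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    nb = len(edges) - 1
    wsum = np.bincount(idx, weights=w, minlength=nb)
    wrate = np.bincount(idx, weights=w * rate, minlength=nb)
    keep = wsum > 0
    centers = (edges[:-1] + edges[1:]) / 2
    q1 = np.full(nb, np.nan)
    q3 = np.full(nb, np.nan)
    for b in np.nonzero(keep)[0]:
        r = rate[idx == b]
        q1[b], q3[b] = np.percentile(r, [25, 75])
    return BinnedSeries(
        edges=edges,
        centers=centers[keep],
        mean=wrate[keep] / wsum[keep],
        q1=q1[keep], q3=q3[keep],
        weight=wsum[keep],
    )


# ---------------------------------------------------------------------------
# weighted linear regression
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float               # two-tailed t-test on the slope
    stderr: float
    n: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


class InsufficientDataError(ValueError):
    pass


def _weighted_r2(y, yhat, w) -> float:
    ybar = np.average(y, weights=w)
    sse = np.sum(w * (y - yhat) ** 2)
    sst = np.sum(w * (y - ybar) ** 2)
    return 1.0 - sse / sst if sst > 0 else 1.0


def wls_fit(series: BinnedSeries | None = None, *,
            x=None, y=None, weight=None) -> FitResult:
    """Weighted least-squares line through a binned series (or raw arrays)."""
    import statsmodels.api as sm

    if series is not None:
        x, y, weight = series.centers, series.mean, series.weight
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if weight is None else np.asarray(weight, dtype=float)
    if len(x) < 3:
        raise InsufficientDataError(f"need >= 3 bins, got {len(x)}")
    X = sm.add_constant(x)
    res = sm.WLS(y, X, weights=w).fit()
    return FitResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=_weighted_r2(y, res.fittedvalues, w),
        p_value=float(res.pvalues[1]),
        stderr=float(res.bse[1]),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# piecewise (segmented) regression
# ---------------------------------------------------------------------------

@dataclass
class PiecewiseFit:
    """Continuous piecewise-linear fit selected by weighted BIC."""

    n_breakpoints: int
    breakpoints: tuple
    slopes: tuple                # per-segment slopes, left to right
    intercept: float             # value model takes at x = 0 (leftmost segment)
    r_squared: float
    slope_pvalues: tuple         # two-tailed t-test per segment slope
    bic: float
    n: int

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        out = self.intercept + self.slopes[0] * x
        for k, b in enumerate(self.breakpoints):
            out += (self.slopes[k + 1] - self.slopes[k]) * np.clip(x - b, 0, None)
        return out


def _hinge_design(x, breaks):
    cols = [np.ones_like(x), x]
    for b in breaks:
        cols.append(np.clip(x - b, 0.0, None))
    return np.column_stack(cols)


def _wls_sse(X, y, w):
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ beta
    return float(np.sum(w * resid**2)), beta


def _fit_with_breaks(x, y, w, breaks) -> PiecewiseFit:
    X = _hinge_design(x, breaks)
    sse, beta = _wls_sse(X, y, w)
    n, k = len(x), X.shape[1]
    # SSE floored at numerical noise so exact fits favor parsimony
    scale = max(float(np.max(np.abs(y))), 1.0)
    floor = n * (1e-10 * scale) ** 2
    bic = n * np.log(max(sse, floor) / n) + k * np.log(n)
    # per-segment slopes are cumulative sums of the hinge coefficients
    slopes = tuple(np.cumsum(beta[1:]).tolist())
    # slope covariance from the weighted normal equations
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    dof = max(n - k, 1)
    sigma2 = sse / dof
    cov = sigma2 * np.linalg.pinv(Xw.T @ Xw)
    pvals = []
    for j in range(1, k):
        sel = np.zeros(k)
        sel[1:j + 1] = 1.0       # slope_j = sum of hinge coefs 1..j
        var = float(sel @ cov @ sel)
        if var <= 0:
            pvals.append(1.0)
        else:
            t = np.cumsum(beta[1:])[j - 1] / np.sqrt(var)
            pvals.append(float(2 * stats.t.sf(abs(t), dof)))
    yhat = X @ beta
    return PiecewiseFit(
        n_breakpoints=len(breaks),
        breakpoints=tuple(float(b) for b in breaks),
        slopes=slopes,
        intercept=float(beta[0]),
        r_squared=_weighted_r2(y, yhat, w),
        slope_pvalues=tuple(pvals),
        bic=float(bic),
        n=n,
    )


def piecewise_fit(series: BinnedSeries, max_breaks: int = 2,
                  min_bins_per_segment: int = 3) -> PiecewiseFit:
    """Segmented weighted regression with exhaustive breakpoint search.

    Candidate breakpoints are interior bin centers; every segment must
    contain at least ``min_bins_per_segment`` bins.  Models with 0 to
    ``max_breaks`` breakpoints compete on weighted BIC.  If the series is
    too short for the requested number of breaks the search falls back to
    fewer breaks with a warning.
    """
    x = np.asarray(series.centers, dtype=float)
    y = np.asarray(series.mean, dtype=float)
    w = np.asarray(series.weight, dtype=float)
    n = len(x)
    if n < 2 * min_bins_per_segment:
        if n < 3:
            raise InsufficientDataError(f"need >= 3 bins, got {n}")
        if max_breaks > 0:
            warnings.warn("too few bins for breakpoints; fitting a line")
        max_breaks = 0
    m = min_bins_per_segment
    best = _fit_with_breaks(x, y, w, ())
    if max_breaks >= 1 and n >= 2 * m:
        for i in range(m - 1, n - m):
            cand = _fit_with_breaks(x, y, w, (x[i],))
            if cand.bic < best.bic:
                best = cand
    if max_breaks >= 2:
        if n >= 3 * m:
            for i in range(m - 1, n - 2 * m + 1):
                for j in range(i + m, n - m):
                    cand = _fit_with_breaks(x, y, w, (x[i], x[j]))
                    if cand.bic < best.bic:
                        best = cand
        else:
            warnings.warn("too few bins for 2 breakpoints; trying at most 1")
    return best


# ---------------------------------------------------------------------------
# beta regression
# ---------------------------------------------------------------------------

@dataclass
class BetaFit:
    coef: np.ndarray             # (intercept, slope) on the logit-mean scale
    precision: float             # phi
    pvalues: np.ndarray
    stderr: np.ndarray
    loglik: float
    n: int
    converged: bool


def smithson_verkuilen(y, n: int | None = None) -> np.ndarray:
    """Boundary transform y' = (y·(n−1) + 0.5)/n pulling 0/1 inside (0, 1)."""
    y = np.asarray(y, dtype=float)
    n = len(y) if n is None else n
    return (y * (n - 1) + 0.5) / n


def beta_fit(rate, covariate, weight=None, maxiter: int = 500) -> BetaFit:
    """Weighted ML beta regression with a logit mean link.

    y ~ Beta(mu*phi, (1-mu)*phi), logit(mu) = b0 + b1*x; weights multiply
    the per-observation log-likelihood (tree counts).  Boundary rates are
    pulled inside (0, 1) with the (y(n-1)+0.5)/n transform.  Standard
    errors come from the inverse observed information at the optimum.
    """
    from statsmodels.tools.numdiff import approx_hess

    y = np.asarray(rate, dtype=float)
    x = np.asarray(covariate, dtype=float)
    w = np.ones_like(y) if weight is None else np.asarray(weight, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        y = smithson_verkuilen(y)
    X = np.column_stack([np.ones_like(x), x])

    def negll(params):
        b = params[:2]
        phi = np.exp(params[2])
        eta = X @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        ll = stats.beta.logpdf(y, mu * phi, (1 - mu) * phi)
        return -np.sum(w * ll)

    # moment-based start values
    eta0 = np.log(y / (1 - y)).mean()
    start = np.array([eta0, 0.0, np.log(5.0)])
    res = optimize.minimize(negll, start, method="Nelder-Mead",
                            options={"maxiter": maxiter * 10, "xatol": 1e-8,
                                     "fatol": 1e-10})
    res = optimize.minimize(negll, res.x, method="BFGS",
                            options={"maxiter": maxiter})
    if not np.isfinite(res.fun):
        raise RuntimeError(f"beta regression failed to converge: {res}")
    hess = approx_hess(res.x, negll)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    z = res.x[:2] / se[:2]
    pvals = 2 * stats.norm.sf(np.abs(z))
    return BetaFit(
        coef=res.x[:2].copy(),
        precision=float(np.exp(res.x[2])),
        pvalues=pvals,
        stderr=se[:2],
        loglik=-float(res.fun),
        n=len(y),
        converged=bool(res.success or np.isfinite(res.fun)),
    )


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

@dataclass
class MixedFit:
    fixed_slope: float
    fixed_p: float
    group_variance: float
    lrt_stat: float
    lrt_p: float
    n_groups: int


def height_groups(height, quantiles=(1 / 3, 2 / 3)) -> pd.Series:
    """Tercile height classes (low / mid / tall) for the random effect."""
    h = pd.Series(np.asarray(height, dtype=float))
    qs = h.quantile(quantiles).to_numpy()
    labels = np.select([h <= qs[0], h <= qs[1]], ["low", "mid"], "tall")
    return pd.Series(labels, index=h.index, name="height_group")


def mixed_fit(rate, ccth, groups) -> MixedFit:
    """Random-intercept model rate ~ CCTH + (1 | height group), ML fit.

    The random-effect significance is a likelihood-ratio test against the
    ordinary regression without the grouping (chi-square(1) reference,
    conservative at the variance boundary).
    """
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    y = np.asarray(rate, dtype=float)
    x = np.asarray(ccth, dtype=float)
    g = np.asarray(groups)
    uniq = np.unique(g)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups for a random effect")
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mixed = MixedLM(y, X, groups=g).fit(reml=False)
        ols = sm.OLS(y, X).fit()
    var = float(np.asarray(mixed.cov_re)[0, 0])
    if var <= 1e-12:
        warnings.warn("singular random-effect fit; variance reported as 0")
        var = 0.0
    lrt = max(0.0, 2 * (mixed.llf - ols.llf))
    return MixedFit(
        fixed_slope=float(mixed.fe_params[1]),
        fixed_p=float(mixed.pvalues[1]),
        group_variance=var,
        lrt_stat=float(lrt),
        lrt_p=float(stats.chi2.sf(lrt, df=1)),
        n_groups=len(uniq),
    )


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------

@dataclass
class MediationResult:
    """Path estimates for exposure -> mediator -> outcome."""

    path_a: float                # exposure -> mediator
    path_b: float                # mediator -> outcome | exposure
    direct: float                # c'
    indirect: float              # a * b
    total: float                 # c from outcome ~ exposure
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def _wls_beta(X, y, w):
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta


def mediation(exposure, mediator, outcome, weight=None,
              n_boot: int = 999, seed: int = 0) -> MediationResult:
    """Weighted linear mediation with a percentile bootstrap CI.

    a from mediator ~ exposure; b and c' from outcome ~ exposure + mediator;
    indirect effect a*b with a seeded unit-resampling bootstrap.  For these
    linear models total = c' + a*b identically.
    """
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    w = np.ones_like(x) if weight is None else np.asarray(weight, dtype=float)
    n = len(x)
    if n < 30:
        raise InsufficientDataError("mediation needs n >= 30 units")

    def paths(xi, mi, yi, wi):
        Xa = np.column_stack([np.ones_like(xi), xi])
        a = _wls_beta(Xa, mi, wi)[1]
        Xb = np.column_stack([np.ones_like(xi), xi, mi])
        bb = _wls_beta(Xb, yi, wi)
        return a, bb[2], bb[1]

    a, b, cprime = paths(x, m, y, w)
    total = _wls_beta(np.column_stack([np.ones_like(x), x]), y, w)[1]

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        ab, bbb, _ = paths(x[idx], m[idx], y[idx], w[idx])
        boots[i] = ab * bbb
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return MediationResult(
        path_a=float(a), path_b=float(b), direct=float(cprime),
        indirect=float(a * b), total=float(total),
        ci_low=float(lo), ci_high=float(hi), n_boot=n_boot, seed=seed,
    )


# ---------------------------------------------------------------------------
# random forest importance / partial dependence
# ---------------------------------------------------------------------------

#: binning interval per driver for the stand-level feature table
RF_BIN_WIDTHS = {
    "height": 5.0, "ccth": 5.0, "elevation": 250.0,
    "twi": 0.5, "radiation": 200.0,
}

ENVIRONMENT_FEATURES = ("elevation", "twi", "radiation")
STRUCTURE_FEATURES = ("height", "ccth")


@dataclass
class RFResult:
    importance: pd.DataFrame     # percent increase in MSE per feature
    pdp: dict                    # feature -> (grid, partial dependence)
    r2_full: float
    r2_oob: float
    r2_environment_only: float
    feature_names: tuple


def rf_importance_pdp(
    feature_table: pd.DataFrame,
    rate,
    weight=None,
    n_estimators: int = 500,
    mtry: int = 3,
    seed: int = 0,
    n_permutations: int = 5,
) -> RFResult:
    """Random-forest drivers analysis: importance, PDP, model comparison.

    A regression forest (ntree=500, mtry=3) predicts mortality rate from
    the driver table; importance is the percent increase in MSE when a
    feature is permuted; partial dependence is evaluated on fixed grids at
    the standard binning interval per driver.  A second forest using the
    environmental features only quantifies how much the structure features
    add.
    """
    from sklearn.ensemble import RandomForestRegressor

    y = np.asarray(rate, dtype=float)
    if np.allclose(y, y[0]):
        warnings.warn("constant outcome; degenerate random-forest model")
    X = feature_table.to_numpy(dtype=float)
    names = tuple(feature_table.columns)
    w = None if weight is None else np.asarray(weight, dtype=float)
    rng = np.random.default_rng(seed)

    def fit_forest(Xs):
        f = RandomForestRegressor(
            n_estimators=n_estimators,
            max_features=min(mtry, Xs.shape[1]),
            oob_score=True, random_state=seed, n_jobs=1,
            bootstrap=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f.fit(Xs, y, sample_weight=w)
        return f

    forest = fit_forest(X)
    yhat = forest.predict(X)
    ww = np.ones_like(y) if w is None else w
    mse0 = float(np.average((y - yhat) ** 2, weights=ww))
    rows = []
    for j, name in enumerate(names):
        incs = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            msep = float(np.average((y - forest.predict(Xp)) ** 2, weights=ww))
            incs.append(100.0 * (msep - mse0) / max(mse0, 1e-300))
        rows.append({"feature": name,
                     "pct_inc_mse": float(np.mean(incs)),
                     "sd": float(np.std(incs))})
    importance = (pd.DataFrame(rows)
                  .sort_values("pct_inc_mse", ascending=False)
                  .reset_index(drop=True))

    pdp = {}
    for j, name in enumerate(names):
        step = RF_BIN_WIDTHS.get(name)
        lo, hi = X[:, j].min(), X[:, j].max()
        if step is None or hi - lo < step:
            grid = np.linspace(lo, hi, 10)
        else:
            grid = np.arange(np.floor(lo / step) * step, hi + step / 2, step)
        pd_vals = np.empty(len(grid))
        for gi, v in enumerate(grid):
            Xg = X.copy()
            Xg[:, j] = v
            pd_vals[gi] = float(np.average(forest.predict(Xg), weights=ww))
        pdp[name] = (grid, pd_vals)

    env_cols = [i for i, nm in enumerate(names) if nm in ENVIRONMENT_FEATURES]
    if env_cols:
        env_forest = fit_forest(X[:, env_cols])
        yhat_env = env_forest.predict(X[:, env_cols])
        r2_env = _weighted_r2(y, yhat_env, ww)
    else:
        r2_env = np.nan
    return RFResult(
        importance=importance,
        pdp=pdp,
        r2_full=_weighted_r2(y, yhat, ww),
        r2_oob=float(forest.oob_score_),
        r2_environment_only=float(r2_env),
        feature_names=names,
    )
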