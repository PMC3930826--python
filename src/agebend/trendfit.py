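"""Per-probe trend smoothing, LOOCV model selection, and significance filtering.

Each probe's expression-versus-age relationship is smoothed with one of five
competing regression families — linear, quadratic, cubic polynomials, an
unpenalized quadratic B-spline, or tri-cube-weighted local quadratic
regression (LOESS). Model families are compared genome-wide by
leave-one-out cross-validation; individual probes are then filtered with an
F-test of the quadratic age model against the intercept-only null
(unadjusted p < alpha, the first of the two-stage filters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly
from scipy import stats
from scipy.interpolate import BSpline, make_lsq_spline

from .dataio import ExpressionDataset

__all__ = [
    "MODELS",
    "TrendFit",
    "ModelComparison",
    "fit_trend",
    "loocv_error",
    "compare_models",
    "probe_p_value",
    "filter_probes",
]

MODELS = ("linear", "quadratic", "cubic", "qbspline", "loess")
_POLY_DEGREE = {"linear": 1, "quadratic": 2, "cubic": 3}

#: Smallest positive subnormal double; p-value floor when SSE2 underflows.
P_FLOOR = float(np.nextafter(0.0, 1.0))


@dataclass
class TrendFit:
    """One probe's fitted smoothing model.

    ``coefficients`` holds raw-age-scale polynomial coefficients (ascending,
    beta0..beta_d) for the polynomial families, and a parameter dict for
    qbspline (knots + spline coefficients) and loess (span). ``p_value`` is
    the age-association F-test p and is populated for polynomial models only.
    """

    model: str
    coefficients: object
    fitted: np.ndarray
    sse: float
    p_value: float | None = None
    age_min: float = field(default=np.nan)
    age_max: float = field(default=np.nan)
    _predict: object = field(default=None, repr=False, compare=False)

    def predict(self, ages) -> np.ndarray:
        """Evaluate the smoothed trend at ``ages`` (no extrapolation)."""
        ages = np.asarray(ages, dtype=float)
        if ages.min() < self.age_min - 1e-9 or ages.max() > self.age_max + 1e-9:
            raise ValueError(
                f"requested ages outside fitted range [{self.age_min}, {self.age_max}]"
            )
        return self._predict(ages)


@dataclass
class ModelComparison:
    """Genome-wide LOOCV comparison of smoothing model families."""

    models: list
    mean_errors: dict
    per_probe_errors: pd.DataFrame
    pairwise_p: pd.DataFrame
    winner: str


def _validate_xy(ages, values):
    t = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or y.shape != t.shape:
        raise ValueError("ages and values must be 1-D of equal length")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input")
    return t, y


def _fit_polynomial(t, y, degree):
    n = len(t)
    if n < degree + 1:
        raise ValueError(
            f"underdetermined: degree {degree} needs at least {degree + 1} points"
        )
    mu, sigma = t.mean(), t.std()
    if sigma == 0:
        raise ValueError("all ages identical: polynomial fit underdetermined")
    ts = (t - mu) / sigma
    X = np.vander(ts, degree + 1, increasing=True)
    beta_s, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta_s
    # report coefficients on the raw-age scale: compose with (t - mu)/sigma
    shift = npoly.Polynomial([-mu / sigma, 1.0 / sigma])
    raw = npoly.Polynomial(beta_s)(shift).coef
    raw = np.pad(raw, (0, degree + 1 - len(raw)))
    sse = float(np.sum((y - fitted) ** 2))

    def predict(x, _mu=mu, _sigma=sigma, _beta=beta_s):
        xs = (np.asarray(x, float) - _mu) / _sigma
        return np.vander(xs, len(_beta), increasing=True) @ _beta

    return raw, fitted, sse, predict


def _fit_qbspline(t, y, n_interior_knots=2):
    n = len(t)
    if n < 6:
        raise ValueError("qbspline requires at least 6 points")
    order = np.argsort(t, kind="stable")
    ts, ys = t[order], y[order]
    if ts[0] == ts[-1]:
        raise ValueError("qbspline degenerate: all ages identical")
    qs = np.linspace(0, 100, n_interior_knots + 2)[1:-1]
    interior = np.percentile(ts, qs)
    interior = interior[(interior > ts[0]) & (interior < ts[-1])]
    k = 2
    knots = np.concatenate([[ts[0]] * (k + 1), interior, [ts[-1]] * (k + 1)])
    try:
        spl = make_lsq_spline(ts, ys, knots, k=k)
    except Exception as exc:  # singular designs from heavy age duplication
        raise ValueError(f"qbspline fit degenerate for this age design: {exc}")
    fitted_sorted = spl(ts)
    fitted = np.empty_like(fitted_sorted)
    fitted[order] = fitted_sorted
    sse = float(np.sum((y - fitted) ** 2))
    coeffs = {"knots": np.asarray(spl.t), "coefficients": np.asarray(spl.c), "degree": k}

    def predict(x, _spl=spl):
        return _spl(np.asarray(x, float))

    return coeffs, fitted, sse, predict


def _loess_predict_one(t, y, x0, span):
    """Tri-cube-weighted local quadratic regression evaluated at x0."""
    n = len(t)
    d = np.abs(t - x0)
    r = max(int(np.ceil(span * n)), 3)
    h = np.sort(d)[min(r, n) - 1]
    if h == 0:
        h = max(np.sort(d)[-1] * 1e-9, 1e-9)
    w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
    use = w > 0
    if use.sum() < 3:
        use = d <= np.sort(d)[min(2, n - 1)]
        w = np.where(use, 1.0, 0.0)
    sw = np.sqrt(w[use])
    ts = t[use] - x0
    X = np.column_stack([np.ones(use.sum()), ts, ts**2])
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y[use] * sw, rcond=None)
    return beta[0]


def _fit_loess(t, y, span=0.75):
    if len(t) < 6:
        raise ValueError("loess requires at least 6 points")
    if np.ptp(t) == 0:
        raise ValueError("loess degenerate: all ages identical")

    def predict(x, _t=t, _y=y, _span=span):
        x = np.asarray(x, float)
        return np.array([_loess_predict_one(_t, _y, xi, _span) for xi in x])

    fitted = predict(t)
    sse = float(np.sum((y - fitted) ** 2))
    return {"span": span}, fitted, sse, predict


def fit_trend(ages, values, model: str = "quadratic", **options) -> TrendFit:
    """Least-squares fit of one smoothing model to a single probe.

    Polynomial models standardize ages internally for conditioning and report
    coefficients back on the raw-age scale; their ``p_value`` is the
    F-test of the model against the intercept-only null.
    """
    t, y = _validate_xy(ages, values)
    if model in _POLY_DEGREE:
        deg = _POLY_DEGREE[model]
        coeffs, fitted, sse, predict = _fit_polynomial(t, y, deg)
        p = _poly_p_value(y, sse, deg)
    elif model == "qbspline":
        coeffs, fitted, sse, predict = _fit_qbspline(
            t, y, options.get("n_interior_knots", 2))
        p = None
    elif model == "loess":
        coeffs, fitted, sse, predict = _fit_loess(t, y, options.get("span", 0.75))
        p = None
    else:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    return TrendFit(
        model=model, coefficients=coeffs, fitted=fitted, sse=sse, p_value=p,
        age_min=float(t.min()), age_max=float(t.max()), _predict=predict,
    )


def _poly_p_value(y, sse_model, degree):
    n = len(y)
    df_resid = n - degree - 1
    if df_resid <= 0:
        return None
    sse0 = float(np.sum((y - y.mean()) ** 2))
    if sse0 == 0:
        return 1.0
    if sse_model <= sse0 * 1e-12:  # exact fit up to round-off
        return P_FLOOR
    f = ((sse0 - sse_model) / degree) / (sse_model / df_resid)
    p = float(stats.f.sf(f, degree, df_resid))
    return max(p, P_FLOOR)


def loocv_error(ages, values, model: str = "quadratic", **options) -> float:
    """Mean squared leave-one-out prediction error for one probe.

    Every sample is held out in turn, the model refit on the remainder, and
    the held-out value predicted; prediction at the held-out age may sit at
    the edge of (but inside) the training hull for the min/max ages, which
    the underlying predictors allow.
    """
    t, y = _validate_xy(ages, values)
    n = len(t)
    errs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fit = fit_trend(t[mask], y[mask], model, **options)
        errs[i] = (y[i] - fit._predict(np.array([t[i]]))[0]) ** 2
    return float(errs.mean())


def compare_models(dataset: ExpressionDataset, models=MODELS, **options) -> ModelComparison:
    """Genome-wide LOOCV comparison of smoothing families.

    Per-probe LOOCV errors are computed for every model; families are
    compared pairwise with two-sided Wilcoxon signed-rank tests on the
    per-probe errors, and the winner is the family with the minimal mean
    error.
    """
    models = list(models)
    if not models:
        raise ValueError("at least one model required")
    errors = {}
    for m in models:
        col = np.empty(dataset.n_probes)
        for i, pid in enumerate(dataset.probe_ids):
            try:
                col[i] = loocv_error(dataset.ages, dataset.values[i], m, **options)
            except ValueError as exc:
                raise ValueError(f"LOOCV failed for probe {pid!r} under {m}: {exc}")
        errors[m] = col
    per_probe = pd.DataFrame(errors, index=dataset.probe_ids)
    means = {m: float(per_probe[m].mean()) for m in models}
    pairwise = pd.DataFrame(np.nan, index=models, columns=models)
    for i, a in enumerate(models):
        for b in models[i + 1:]:
            diff = per_probe[a] - per_probe[b]
            if np.allclose(diff, 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(per_probe[a], per_probe[b]).pvalue)
            pairwise.loc[a, b] = pairwise.loc[b, a] = p
    winner = min(models, key=lambda m: means[m])
    return ModelComparison(
        models=models, mean_errors=means, per_probe_errors=per_probe,
        pairwise_p=pairwise, winner=winner,
    )


def probe_p_value(ages, values) -> float:
    """F-test p-value of the quadratic age model against no age association.

    F = ((SSE0 - SSE2)/2) / (SSE2/(n-3)) with SSE0 the intercept-only
    residual sum of squares; p is the upper tail of F(2, n-3). A constant
    probe returns 1; a perfect quadratic fit returns the smallest positive
    double.
    """
    t, y = _validate_xy(ages, values)
    if len(t) < 4:
        raise ValueError("probe_p_value requires n >= 4")
    fit = fit_trend(t, y, "quadratic")
    return _poly_p_value(y, fit.sse, 2)


def quadratic_fit_table(dataset: ExpressionDataset) -> pd.DataFrame:
    """Vectorized quadratic fit of every probe (shared design matrix).

    Returns a DataFrame indexed by probe id with raw-scale coefficients
    beta0..beta2, residual SSE and the quadratic-vs-null F-test p-value.
    Numerically identical to per-probe :func:`fit_trend` (same standardized
    design) but one matrix solve for the whole dataset.
    """
    t = dataset.ages
    n = len(t)
    if n < 4:
        raise ValueError("need n >= 4 samples")
    mu, sigma = t.mean(), t.std()
    if sigma == 0:
        raise ValueError("all ages identical")
    ts = (t - mu) / sigma
    X = np.vander(ts, 3, increasing=True)
    pinv = np.linalg.pinv(X)
    Y = dataset.values
    beta_s = Y @ pinv.T  # probes x 3, standardized-age scale
    fitted = beta_s @ X.T
    resid = Y - fitted
    sse2 = np.sum(resid**2, axis=1)
    sse0 = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((sse0 - sse2) / 2) / (sse2 / (n - 3))
        p = stats.f.sf(f, 2, n - 3)
    p = np.where(sse0 == 0, 1.0, p)
    p = np.where((sse2 <= sse0 * 1e-12) & (sse0 > 0), P_FLOOR, p)
    p = np.maximum(p, P_FLOOR)

    # raw-age-scale coefficients via composition with (t - mu)/sigma
    a, b, c = beta_s[:, 0], beta_s[:, 1], beta_s[:, 2]
    m = mu / sigma
    beta0 = a - b * m + c * m**2
    beta1 = (b - 2 * c * m) / sigma
    beta2 = c / sigma**2
    return pd.DataFrame(
        {
            "beta0": beta0, "beta1": beta1, "beta2": beta2,
            "sse": sse2, "p_value": p,
        },
        index=pd.Index(dataset.probe_ids, name="probe_id"),
    )


def filter_probes(dataset: ExpressionDataset, alpha: float = 0.05):
    """Keep probes whose quadratic age model beats the null at p < alpha.

    No multiple-testing correction is applied at this stage: probe filtering
    is the first of two filters (the dataset-level screen is the other), and
    the permutation summary quantifies the expected false-positive load
    instead.

    Returns ``(significant_probe_ids, fit_table)`` where the table holds
    every probe's quadratic coefficients, SSE, p-value and a
    ``significant`` flag.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    table = quadratic_fit_table(dataset)
    table["significant"] = table["p_value"] < alpha
    significant = [pid for pid, s in zip(table.index, table["significant"]) if s]
    return significant, table
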