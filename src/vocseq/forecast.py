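"""Emergence forecasting: ARFIMA with long memory, model comparison by
rolling-origin cross-validation, and the repertoire-depletion check.

The moving-emergence series produced by :mod:`vocseq.entropy` are short,
aseasonal and potentially long-memoried (new call variants keep arriving
at slowly varying rates).  Five model families are compared:

* ARIMA — short-memory autoregressive baseline;
* ARFIMA — fractional differencing order ``d`` in (-0.5, 0.5) captures
  long memory; the headline model;
* ETS — additive exponential smoothing (error/trend);
* TBATS (non-seasonal reduction) — Box-Cox transform + linear trend +
  ARMA errors;
* TSLM — a linear trend regression.

Comparison uses a rolling forecasting origin: models are refitted on
expanding prefixes and scored on the h-step-ahead value only, for
h = 1..h_max with h_max at most half the series length; errors are
aggregated into per-(model, h) MAE and RMSE.

The ARFIMA implementation is self-contained: ``d`` is estimated by
profile likelihood over a grid with local refinement, the series is
fractionally differenced by the truncated binomial expansion, and the
ARMA(p, q) part (p, q <= 2, chosen by AIC) is fitted by exact maximum
likelihood.  Forecasting inverts the model to its AR(infinity) form.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("ARIMA", "ARFIMA", "ETS", "TBATS", "TSLM")


class DegenerateSeriesError(ValueError):
    """The series is constant (or too short) and cannot be modelled."""


# ---------------------------------------------------------------------------
# Fractional differencing
# ---------------------------------------------------------------------------

def frac_diff_weights(d: float, m: int) -> np.ndarray:
    """First ``m`` coefficients of (1 - B)^d: w_0 = 1,
    w_j = w_{j-1} (j - 1 - d) / j."""
    w = np.empty(m)
    w[0] = 1.0
    for j in range(1, m):
        w[j] = w[j - 1] * (j - 1 - d) / j
    return w


def frac_diff(x: np.ndarray, d: float) -> np.ndarray:
    """Fractionally difference a series, truncating the binomial expansion
    at the series length."""
    x = np.asarray(x, dtype=float)
    w = frac_diff_weights(d, len(x))
    # y_t = sum_{j=0}^{t} w_j x_{t-j}
    return np.convolve(x, w)[: len(x)]


# ---------------------------------------------------------------------------
# ARFIMA fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArfimaConfig:
    """Search ranges and tolerances for :func:`fit_arfima`.

    The coarse profile-likelihood grid covers ``d_bounds`` in steps of
    ``d_step``; the best grid point is refined by bounded scalar
    optimisation to ``d_tol``.  ARMA order is selected by AIC over
    ``p, q <= max_pq`` at the coarse optimum unless ``fixed_order`` pins
    it.  ``fixed_d`` skips the d search entirely (d = 0 reduces the fit to
    a plain ARMA fit of the same order).
    """

    d_bounds: tuple[float, float] = (-0.49, 0.49)
    d_step: float = 0.1
    d_tol: float = 1e-3
    max_pq: int = 2
    fixed_order: tuple[int, int] | None = None
    fixed_d: float | None = None


@dataclass
class ArfimaFit:
    """A fitted ARFIMA(p, d, q) model with its AR/MA polynomials."""

    d: float
    order: tuple[int, int]
    ar: np.ndarray          # phi_1..phi_p  (1 - phi_1 B - ...)
    ma: np.ndarray          # theta_1..theta_q  (1 + theta_1 B + ...)
    sigma2: float
    loglik: float
    aic: float
    mean: float
    n: int

    def to_dict(self) -> dict:
        return {
            "d": self.d,
            "p": self.order[0],
            "q": self.order[1],
            "ar": list(map(float, self.ar)),
            "ma": list(map(float, self.ma)),
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "aic": self.aic,
            "mean": self.mean,
            "n": self.n,
        }


def _arma_fit(y: np.ndarray, order: tuple[int, int]):
    from statsmodels.tsa.arima.model import ARIMA

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ARIMA(y, order=(order[0], 0, order[1]), trend="n")
        return model.fit(method_kwargs={"maxiter": 200})


def _profile_loglik(xc: np.ndarray, d: float, order: tuple[int, int]) -> float:
    y = frac_diff(xc, d)
    if order == (0, 0):
        # analytic Gaussian log-likelihood of the differenced series
        n = len(y)
        var = float((y ** 2).mean())
        if var <= 0:
            return -np.inf
        return -0.5 * n * (math.log(2 * math.pi * var) + 1.0)
    try:
        return float(_arma_fit(y, order).llf)
    except Exception:
        return -np.inf


def fit_arfima(x: Sequence[float], config: ArfimaConfig | None = None) -> ArfimaFit:
    """Fit an ARFIMA model by profiling the likelihood over ``d``.

    The series is demeaned, fractionally differenced at each candidate
    ``d`` (truncated binomial expansion), and an ARMA model is fitted to
    the differenced series; ``d`` maximising the profile likelihood is
    refined locally, then the ARMA order is chosen by AIC.
    """
    config = config or ArfimaConfig()
    x = np.asarray(x, dtype=float)
    if len(x) < 20:
        raise DegenerateSeriesError(f"series length {len(x)} < 20")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("constant series cannot be fitted")
    mean = float(x.mean())
    xc = x - mean
    lo, hi = config.d_bounds

    if config.fixed_order is not None:
        orders = [tuple(config.fixed_order)]
    else:
        orders = [(p, q) for p in range(config.max_pq + 1) for q in range(config.max_pq + 1)]

    def select_order(d):
        y = frac_diff(xc, d)
        best, best_aic, best_order = None, np.inf, None
        for order in orders:
            try:
                res = _arma_fit(y, order)
            except Exception:
                continue
            if res.aic < best_aic:
                best, best_aic, best_order = res, float(res.aic), order
        if best is None:
            raise RuntimeError("ARFIMA ARMA-order stage failed for every candidate order")
        return best, best_order

    if config.fixed_d is not None:
        d_hat = float(config.fixed_d)
        best, best_order = select_order(d_hat)
    else:
        # coarse pass: profile d against a white-noise ARMA(0,0) likelihood
        # (analytic), then pick the ARMA order there, then refine d locally
        # with the selected order.
        grid = np.arange(lo + 0.04, hi - 0.04 + 1e-9, config.d_step)
        profile = [_profile_loglik(xc, d, (0, 0)) for d in grid]
        if not np.isfinite(profile).any():
            raise RuntimeError("ARFIMA d-profile stage failed on every grid point")
        d0 = float(grid[int(np.argmax(profile))])
        _, best_order = select_order(d0)
        span = 1.5 * config.d_step
        res = optimize.minimize_scalar(
            lambda d: -_profile_loglik(xc, d, best_order),
            bounds=(max(lo, d0 - span), min(hi, d0 + span)),
            method="bounded",
            options={"xatol": config.d_tol},
        )
        d_hat = float(res.x)
        best, best_order = select_order(d_hat)

    return ArfimaFit(
        d=d_hat,
        order=best_order,
        ar=np.asarray(best.arparams, dtype=float),
        ma=np.asarray(best.maparams, dtype=float),
        sigma2=float(best.params[-1]),
        loglik=float(best.llf),
        aic=float(best.aic),
        mean=mean,
        n=len(x),
    )


# ---------------------------------------------------------------------------
# ARFIMA forecasting via the AR(infinity) representation
# ---------------------------------------------------------------------------

def _power_series_divide(num: np.ndarray, den: np.ndarray, m: int) -> np.ndarray:
    """Coefficients of num(B)/den(B) up to order m-1 (den[0] must be 1)."""
    out = np.zeros(m)
    num = np.pad(num[:m], (0, max(0, m - len(num))))
    for j in range(m):
        acc = num[j]
        for i in range(1, min(j, len(den) - 1) + 1):
            acc -= den[i] * out[j - i]
        out[j] = acc
    return out


def _pi_weights(fit: ArfimaFit, m: int) -> np.ndarray:
    """AR(infinity) coefficients pi(B) = Phi(B)(1-B)^d / Theta(B)."""
    ar_poly = np.r_[1.0, -fit.ar]
    ma_poly = np.r_[1.0, fit.ma]
    fd = frac_diff_weights(fit.d, m)
    num = np.convolve(ar_poly, fd)[:m]
    return _power_series_divide(num, ma_poly, m)


def _psi_weights(pi: np.ndarray, m: int) -> np.ndarray:
    """MA(infinity) coefficients psi(B) = 1/pi(B)."""
    return _power_series_divide(np.array([1.0]), pi, m)


def arfima_forecast(
    fit: ArfimaFit,
    x: Sequence[float],
    horizon: int,
    level: float = 0.95,
) -> pd.DataFrame:
    """Point forecasts and a symmetric interval path.

    Inverts the model to its AR(infinity) form (truncated at the history
    length plus horizon), iterates point forecasts, and builds interval
    widths from the cumulative MA(infinity) variance.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    x = np.asarray(x, dtype=float)
    m = len(x) + horizon
    pi = _pi_weights(fit, m)
    psi = _psi_weights(pi, horizon)
    hist = list(x - fit.mean)
    points = []
    for _ in range(horizon):
        past = hist[::-1]
        acc = 0.0
        for j in range(1, min(len(past), m - 1) + 1):
            acc -= pi[j] * past[j - 1]
        hist.append(acc)
        points.append(acc)
    points = np.array(points) + fit.mean
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(fit.sigma2 * np.cumsum(psi[:horizon] ** 2))
    return pd.DataFrame(
        {
            "h": np.arange(1, horizon + 1),
            "forecast": points,
            "lo": points - z * se,
            "hi": points + z * se,
        }
    )


# ---------------------------------------------------------------------------
# The comparison model set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForecastModelSpec:
    """One entry of the model-comparison set."""

    family: Literal["ARIMA", "ARFIMA", "ETS", "TBATS", "TSLM"]
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


def _forecast_arima(train: np.ndarray, h: int, options: dict) -> np.ndarray:
    from statsmodels.tsa.arima.model import ARIMA

    max_pq = options.get("max_pq", 2)
    best, best_aic = None, np.inf
    for d in (0, 1):
        for p in range(max_pq + 1):
            for q in range(max_pq + 1):
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = ARIMA(
                            train, order=(p, d, q), trend="c" if d == 0 else "n"
                        ).fit(method_kwargs={"maxiter": 100})
                except Exception:
                    continue
                if res.aic < best_aic:
                    best, best_aic = res, res.aic
    if best is None:
        raise RuntimeError("ARIMA: every candidate order failed")
    return np.asarray(best.forecast(h))


def _forecast_arfima(train: np.ndarray, h: int, options: dict) -> np.ndarray:
    config = options.get("config") or ArfimaConfig(max_pq=1)
    fit = fit_arfima(train, config)
    return arfima_forecast(fit, train, h)["forecast"].to_numpy()


def _forecast_ets(train: np.ndarray, h: int, options: dict) -> np.ndarray:
    from statsmodels.tsa.exponential_smoothing.ets import ETSModel

    variants = [dict(trend=None), dict(trend="add"), dict(trend="add", damped_trend=True)]
    best, best_aic = None, np.inf
    for kw in variants:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = ETSModel(train, error="add", **kw).fit(disp=False)
        except Exception:
            continue
        if res.aic < best_aic:
            best, best_aic = res, res.aic
    if best is None:
        raise RuntimeError("ETS: every variant failed")
    return np.asarray(best.forecast(h))


def _forecast_tbats(train: np.ndarray, h: int, options: dict) -> np.ndarray:
    """Non-seasonal TBATS reduction: Box-Cox + linear trend + ARMA errors."""
    from statsmodels.tsa.arima.model import ARIMA

    shift = 0.0
    if train.min() <= 0:
        shift = 1e-6 - float(train.min())
    shifted = train + shift
    if np.ptp(shifted) == 0:
        lam, y = 1.0, shifted - 1.0
    else:
        y, lam = stats.boxcox(shifted)
    t = np.arange(len(y), dtype=float)
    beta = np.polyfit(t, y, 1)
    trend = np.polyval(beta, t)
    resid = y - trend
    best, best_aic = None, np.inf
    for p in (0, 1):
        for q in (0, 1):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = ARIMA(resid, order=(p, 0, q), trend="n").fit(
                        method_kwargs={"maxiter": 100}
                    )
            except Exception:
                continue
            if res.aic < best_aic:
                best, best_aic = res, res.aic
    future_t = np.arange(len(y), len(y) + h, dtype=float)
    fc = np.polyval(beta, future_t)
    if best is not None:
        fc = fc + np.asarray(best.forecast(h))
    back = special.inv_boxcox(fc, lam)
    back = np.where(np.isfinite(back), back, np.polyval(beta, future_t))
    return back - shift


def _forecast_tslm(train: np.ndarray, h: int, options: dict) -> np.ndarray:
    t = np.arange(len(train), dtype=float)
    beta = np.polyfit(t, train, 1)
    future_t = np.arange(len(train), len(train) + h, dtype=float)
    return np.polyval(beta, future_t)


_FORECASTERS: dict[str, Callable[[np.ndarray, int, dict], np.ndarray]] = {
    "ARIMA": _forecast_arima,
    "ARFIMA": _forecast_arfima,
    "ETS": _forecast_ets,
    "TBATS": _forecast_tbats,
    "TSLM": _forecast_tslm,
}


def fit_and_forecast(spec: ForecastModelSpec, train: np.ndarray, h: int) -> np.ndarray:
    """Fit one model on a training prefix and forecast ``h`` steps."""
    return _FORECASTERS[spec.family](np.asarray(train, float), h, spec.options)


# ---------------------------------------------------------------------------
# Rolling-origin cross-validation
# ---------------------------------------------------------------------------

@dataclass
class ForecastEval:
    """Per-(model, horizon) errors from rolling-origin cross-validation."""

    table: pd.DataFrame            # family, h, mae, rmse, n_folds, n_failed
    winner: str | None
    disqualified: list[str]
    h_max: int
    min_train: int

    def summary(self) -> pd.DataFrame:
        """Mean MAE/RMSE per model across horizons."""
        return (
            self.table.groupby("family")[["mae", "rmse"]].mean().reset_index()
        )


def admissible_horizons(series_length: int) -> range:
    """Forecast horizons admitted for a series: 1 .. floor(length / 2)."""
    return range(1, series_length // 2 + 1)


def rolling_origin_cv(
    x: Sequence[float],
    models: Sequence[ForecastModelSpec],
    h_max: int | None = None,
    min_train: int = 8,
) -> ForecastEval:
    """Expanding-window cross-validation of the model set.

    For each origin ``o`` from ``min_train`` to ``L - 1`` every model is
    fitted on ``x[:o]`` and forecasts up to ``min(h_max, L - o)`` steps;
    the error at exactly step ``h`` feeds the (model, h) cell.  For each
    horizon the fold count is ``L - min_train - h + 1``.  A model failing
    on a fold has that fold recorded as missing; models failing more than
    25% of folds are disqualified from winner selection.  The winner has
    the lowest mean RMSE across horizons (MAE is reported alongside).
    """
    x = np.asarray(x, dtype=float)
    L = len(x)
    if h_max is None:
        h_max = L // 2
    if h_max > L // 2:
        raise ValueError(f"h_max={h_max} exceeds half the series length ({L // 2})")
    if min_train < 8:
        raise ValueError("min_train must be >= 8")
    if min_train >= L:
        raise ValueError("min_train must be smaller than the series length")

    errors: dict[str, dict[int, list[float]]] = {
        m.family: {h: [] for h in range(1, h_max + 1)} for m in models
    }
    failed: dict[str, int] = {m.family: 0 for m in models}
    n_folds_total = L - min_train

    for o in range(min_train, L):
        hs = min(h_max, L - o)
        train = x[:o]
        for m in models:
            try:
                fc = fit_and_forecast(m, train, hs)
            except Exception as exc:
                failed[m.family] += 1
                logger.info("%s failed at origin %d: %s", m.family, o, exc)
                continue
            for h in range(1, hs + 1):
                errors[m.family][h].append(float(x[o + h - 1] - fc[h - 1]))

    rows = []
    for m in models:
        for h in range(1, h_max + 1):
            e = np.array(errors[m.family][h])
            n_expected = L - min_train - h + 1
            rows.append(
                (
                    m.family,
                    h,
                    float(np.abs(e).mean()) if e.size else np.nan,
                    float(np.sqrt((e ** 2).mean())) if e.size else np.nan,
                    int(e.size),
                    n_expected - int(e.size),
                )
            )
    table = pd.DataFrame(
        rows, columns=["family", "h", "mae", "rmse", "n_folds", "n_failed"]
    )
    disqualified = [
        fam for fam, nf in failed.items() if nf > 0.25 * n_folds_total
    ]
    eligible = table[~table["family"].isin(disqualified)].dropna(subset=["rmse"])
    winner = None
    if len(eligible):
        mean_rmse = eligible.groupby("family")["rmse"].mean()
        winner = str(mean_rmse.idxmin())
    return ForecastEval(
        table=table,
        winner=winner,
        disqualified=disqualified,
        h_max=h_max,
        min_train=min_train,
    )


# ---------------------------------------------------------------------------
# Final forecast and depletion report
# ---------------------------------------------------------------------------

@dataclass
class DepletionReport:
    """Would the repertoire have run dry had the session continued?

    ``depleted`` is true when the point-forecast path touches zero (or
    below) within an extension of ``extra_fraction`` of the observed
    series length — i.e., emergence of new call variants would have
    stopped.  Forecasts are reported unclipped; ``outside_unit`` flags
    any point outside [0, 1].
    """

    depleted: bool
    extension_steps: int
    mean_forecast: float
    min_forecast: float
    outside_unit: bool

    def to_dict(self) -> dict:
        return {
            "depleted": self.depleted,
            "extension_steps": self.extension_steps,
            "mean_forecast": self.mean_forecast,
            "min_forecast": self.min_forecast,
            "outside_unit": self.outside_unit,
        }


def forecast_emergence(
    fit: ArfimaFit,
    x: Sequence[float],
    horizon_rule: Literal["half_length", "explicit"] = "half_length",
    horizon: int | None = None,
    extra_fraction: float = 0.5,
    level: float = 0.95,
) -> tuple[pd.DataFrame, DepletionReport]:
    """Forecast an emergence series and evaluate repertoire depletion.

    With the ``half_length`` rule the horizon is half the series length.
    The depletion check extends the point-forecast path to
    ``ceil(extra_fraction * length)`` steps and asks whether it ever
    reaches zero.
    """
    x = np.asarray(x, dtype=float)
    if horizon_rule == "half_length":
        horizon = len(x) // 2
    elif horizon_rule == "explicit":
        if horizon is None:
            raise ValueError("explicit horizon_rule requires horizon")
    else:
        raise ValueError(f"unknown horizon_rule {horizon_rule!r}")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if horizon > 5 * len(x):
        raise ValueError("horizon exceeds 5x the series length (extrapolation guard)")

    ext = max(1, math.ceil(extra_fraction * len(x)))
    path_full = arfima_forecast(fit, x, max(horizon, ext), level=level)
    path = path_full.iloc[:horizon].copy()
    path["outside_unit"] = (path["forecast"] < 0) | (path["forecast"] > 1)
    ext_points = path_full["forecast"].to_numpy()[:ext]
    report = DepletionReport(
        depleted=bool((ext_points <= 0).any()),
        extension_steps=ext,
        mean_forecast=float(path["forecast"].mean()),
        min_forecast=float(ext_points.min()),
        outside_unit=bool(path["outside_unit"].any()),
    )
    return path, report
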