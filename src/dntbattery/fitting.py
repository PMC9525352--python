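"""Least-squares concentration-response fitting and benchmark concentrations.

Fits are performed on replicate-level percent-of-control responses against
log10 concentration (the solvent control at c = 0 is used only for
normalization and never enters the fit).  Model comparison uses AICc and the
benchmark concentration (BMC) is derived from the selected fit: analytically
for the sigmoid, by root bracketing for the bell.  Confidence intervals come
from a nonparametric percentile bootstrap that resamples replicate wells
within each concentration group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from . import curves
from .errors import FitInfeasibleError, SelectionError
from .screen import ResponseSeries

SIGMOID_PARAMS = ("bottom", "top", "log10_ec50", "hill")
BELL_PARAMS = ("bottom", "top", "log10_ec50", "hill", "log10_ec50_secondary", "hill_secondary")


@dataclass
class FitResult:
    model: str  # "sigmoid" | "bell"
    params: dict[str, float]
    rss: float
    n_points: int
    aicc: float
    converged: bool
    c_min: float
    c_max: float

    def predict(self, conc) -> np.ndarray:
        p = self.params
        if self.model == "sigmoid":
            return curves.sigmoid(conc, p["bottom"], p["top"], p["log10_ec50"], p["hill"])
        return curves.bell(
            conc,
            p["bottom"],
            p["top"],
            p["log10_ec50"],
            p["hill"],
            p["log10_ec50_secondary"],
            p["hill_secondary"],
        )


@dataclass
class BMCEstimate:
    """Benchmark concentration at a stated BMR, optionally with bootstrap CI.

    ``censored`` means the fitted curve never deviates by the BMR within the
    tested concentration range; censored estimates carry no CI.
    """

    bmr: float
    direction: str
    bmc: float = np.nan
    censored: bool = True
    ci_lower: float = np.nan
    ci_upper: float = np.nan
    n_boot: int = 0
    seed: int | None = None
    unreliable: bool = False
    compound_id: str = ""
    endpoint_id: str = ""
    model: str = ""

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_lower, self.ci_upper)

    @property
    def has_ci(self) -> bool:
        return np.isfinite(self.ci_lower) and np.isfinite(self.ci_upper)


def _aicc(rss: float, n: int, n_params: int) -> float:
    k = n_params + 1  # + residual variance
    if n - k - 1 <= 0:
        return np.inf
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _ls(fun, x0, bounds):
    return least_squares(fun, x0, bounds=bounds, method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)


def _fit_sigmoid(c, y, x0=None):
    logc = np.log10(c)
    lo_c, hi_c = logc.min() - 3.0, logc.max() + 3.0
    y_lo, y_hi = y.min() - 50.0, y.max() + 50.0

    def resid(p):
        return curves.sigmoid(c, *p) - y

    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    else:
        mid = float(np.median(logc))
        for h in (1.5, -1.5):
            starts.append(np.array([min(y.min(), 100.0), max(y.max(), 100.0), mid, h]))
    best = None
    for s in starts:
        bounds = (
            [y_lo, y_lo, lo_c, 0.05 if s[3] > 0 else -15.0],
            [y_hi, y_hi, hi_c, 15.0 if s[3] > 0 else -0.05],
        )
        s = np.clip(s, bounds[0], bounds[1])
        try:
            res = _ls(resid, s, bounds)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    return best


def _fit_bell(c, y, x0=None):
    logc = np.log10(c)
    lo_c, hi_c = logc.min() - 3.0, logc.max() + 3.0
    y_lo, y_hi = y.min() - 100.0, y.max() + 100.0

    def resid(p):
        return curves.bell(c, *p) - y

    bounds = ([y_lo, y_lo, lo_c, 0.05, lo_c, 0.05], [y_hi, y_hi, hi_c, 15.0, hi_c, 15.0])
    starts = []
    if x0 is not None:
        starts.append(np.clip(np.asarray(x0, dtype=float), bounds[0], bounds[1]))
    else:
        i_peak = int(np.argmax(np.abs(y - curves.CONTROL_LEVEL)))
        peak_logc = float(logc[i_peak])
        starts.append(
            np.clip(
                np.array([y.min(), y.max(), peak_logc - 0.5, 2.0, peak_logc + 0.5, 2.0]),
                bounds[0],
                bounds[1],
            )
        )
        starts.append(
            np.clip(
                np.array([y.min(), y.max(), logc.min(), 1.0, logc.max(), 1.0]),
                bounds[0],
                bounds[1],
            )
        )
    best = None
    for s in starts:
        try:
            res = _ls(resid, s, bounds)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    return best


def fit_curve(series: ResponseSeries, model: str = "sigmoid", x0=None) -> FitResult:
    """Fit one model family to a series; never raises on optimizer failure.

    Requires at least 4 distinct non-control concentrations for the sigmoid
    and 5 for the bell (:class:`FitInfeasibleError` otherwise).  A failed
    optimization returns ``converged=False`` rather than throwing.
    """
    n_conc = len(series.concentrations)
    need = 4 if model == "sigmoid" else 5
    if n_conc < need:
        raise FitInfeasibleError(
            f"{model} fit needs >= {need} distinct concentrations, got {n_conc}"
        )
    c, y = series.pooled()
    res = _fit_sigmoid(c, y, x0) if model == "sigmoid" else _fit_bell(c, y, x0)
    names = SIGMOID_PARAMS if model == "sigmoid" else BELL_PARAMS
    if res is None or not np.all(np.isfinite(res.x)):
        return FitResult(model, dict.fromkeys(names, np.nan), np.inf, len(y), np.inf, False,
                         float(series.concentrations[0]), series.c_max)
    p = dict(zip(names, (float(v) for v in res.x)))
    if model == "sigmoid" and p["top"] < p["bottom"]:
        # orientation normalization: identical curve with top >= bottom
        p["bottom"], p["top"], p["hill"] = p["top"], p["bottom"], -p["hill"]
    rss = float(2 * res.cost)
    return FitResult(
        model=model,
        params=p,
        rss=rss,
        n_points=len(y),
        aicc=_aicc(rss, len(y), len(names)),
        converged=True,
        c_min=float(series.concentrations[0]),
        c_max=series.c_max,
    )


def select_model(fits: list[FitResult]) -> FitResult:
    """Lowest-AICc converged fit; exact ties go to the sigmoid (fewer params)."""
    conv = [f for f in fits if f.converged]
    if not conv:
        raise SelectionError("no converged fit to select from")
    return min(conv, key=lambda f: (f.aicc, f.model != "sigmoid"))


def bmc_from_fit(
    fit: FitResult,
    bmr: float,
    direction: str,
    tested_range: tuple[float, float] | None = None,
) -> BMCEstimate:
    """Point BMC from a converged fit; censoring is a valid outcome."""
    if tested_range is None:
        tested_range = (fit.c_min, fit.c_max)
    c_max = tested_range[1]
    if not fit.converged:
        return BMCEstimate(bmr=bmr, direction=direction, model=fit.model)
    if fit.model == "sigmoid":
        p = fit.params
        bmc = curves.sigmoid_bmc(
            p["bottom"], p["top"], p["log10_ec50"], p["hill"], bmr, direction, c_max
        )
    else:
        bmc = curves.bmc_numeric(fit.predict, bmr, direction, c_max)
    if bmc is None:
        return BMCEstimate(bmr=bmr, direction=direction, model=fit.model)
    return BMCEstimate(bmr=bmr, direction=direction, bmc=float(bmc), censored=False, model=fit.model)


def bmc_ci(
    series: ResponseSeries,
    fit: FitResult,
    bmr: float,
    direction: str | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> BMCEstimate:
    """Percentile-bootstrap CI for the BMC (resampling wells within groups).

    Refits the selected model to each resample (warm-started at the full-data
    parameters) and takes the 2.5/97.5 percentiles of the resulting BMC
    distribution.  The solvent-control wells are a concentration group too:
    when the series carries them, each resample redraws the controls and
    renormalizes, so control-mean uncertainty propagates into the CI.  With
    more than half of the resamples censored or failed the CI is flagged
    ``unreliable``.  Noise-free series short-circuit to a degenerate CI
    equal to the point estimate.
    """
    if direction is None:
        direction = series.direction
    est = bmc_from_fit(fit, bmr, direction)
    est.compound_id, est.endpoint_id = series.compound_id, series.endpoint_id
    est.seed, est.n_boot = seed, n_boot
    if est.censored:
        return est
    ctrl = series.control_values
    ctrl_flat = ctrl is None or len(ctrl) < 2 or np.ptp(ctrl) == 0
    if all(np.ptp(v) == 0 for v in series.values) and ctrl_flat:
        est.ci_lower = est.ci_upper = est.bmc  # degenerate: no well-level noise
        return est
    rng = np.random.default_rng(seed)
    x0 = np.array([fit.params[k] for k in (SIGMOID_PARAMS if fit.model == "sigmoid" else BELL_PARAMS)])
    boot: list[float] = []
    n_fail = 0

    def draw(v: np.ndarray) -> np.ndarray:
        # with-replacement resample, deviations from the original group mean
        # inflated by sqrt(n/(n-1)) so Var(mean*) matches s^2/n (small groups
        # otherwise make the bootstrap systematically narrow)
        vv = v[rng.integers(0, len(v), len(v))]
        if len(v) > 1:
            vv = v.mean() + (vv - v.mean()) * np.sqrt(len(v) / (len(v) - 1))
        return vv

    for _ in range(n_boot):
        values = [draw(v) for v in series.values]
        if not ctrl_flat:
            ctrl_mean = draw(ctrl).mean()
            if ctrl_mean > 0:
                values = [v * (curves.CONTROL_LEVEL / ctrl_mean) for v in values]
        bs = replace(series, values=values)
        bfit = fit_curve(bs, fit.model, x0=x0)
        best = bmc_from_fit(bfit, bmr, direction) if bfit.converged else None
        if best is None or best.censored:
            n_fail += 1
        else:
            boot.append(best.bmc)
    if n_fail > n_boot // 2:
        est.unreliable = True
    if boot:
        est.ci_lower, est.ci_upper = (float(q) for q in np.percentile(boot, [2.5, 97.5]))
        # the point estimate can sit marginally outside the percentile band
        est.ci_lower = min(est.ci_lower, est.bmc)
        est.ci_upper = max(est.ci_upper, est.bmc)
    else:
        est.unreliable = True
    return est


def fit_and_estimate(
    series: ResponseSeries,
    bmr: float,
    direction: str | None = None,
    models: tuple[str, ...] = ("sigmoid",),
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[FitResult, BMCEstimate]:
    """Convenience path: fit candidate models, select, derive BMC with CI."""
    fits = []
    for m in models:
        try:
            fits.append(fit_curve(series, m))
        except FitInfeasibleError:
            continue
    fit = select_model(fits)
    est = bmc_ci(series, fit, bmr, direction, n_boot=n_boot, seed=seed)
    return fit, est
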