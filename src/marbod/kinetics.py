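"""Logistic biodegradation-kinetics models and nonlinear least-squares fitting.

Cumulative BOD curves from polymer biodegradation assays are S-shaped: a lag
phase, an exponential mineralization phase, and a plateau as the accessible
carbon is exhausted. Three nested log-logistic forms describe this:

variable slope (3 parameters)
    ``Y = BOD_L / (1 + (a/X)**b)``
fixed slope (2 parameters)
    the same with the slope pinned at ``b = 1``
asymmetric (4 parameters)
    ``Y = BOD_L / (1 + (2**(1/S) - 1) * (a/X)**b)**S``

where ``X`` is time (days), ``Y`` cumulative BOD (mg O2/L), ``BOD_L`` the
ultimate BOD (the asymptote, a kinetics-independent measure of ultimate
biodegradability), ``a`` the half-degradation time (all three forms pass
through ``BOD_L/2`` at ``X = a``), ``b`` the dimensionless slope (a proxy
for biodegradation rate) and ``S`` the asymmetry of the approach to the
plateau. At ``X = 0`` the curves are continued by their limit, 0.

Fitting is bound-constrained least squares over the pooled per-replicate
points, with asymptotic (Wald) 95% confidence intervals from the Jacobian
at the optimum. A series whose corrected signal never rises above zero is
not fitted: it yields a *refused* fit flagged not-calculable, carrying the
mean of the final three observations as a point estimate of ``BOD_L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import ValidationError
from .preprocess import CorrectedSeries

__all__ = [
    "ModelForm",
    "KineticFit",
    "model_value",
    "fit",
    "half_degradation_time",
    "PARAM_NAMES",
]


class ModelForm(str, Enum):
    FIXED_SLOPE = "fixed_slope"
    VARIABLE_SLOPE = "variable_slope"
    ASYMMETRIC = "asymmetric"

    @property
    def n_params(self) -> int:
        return len(PARAM_NAMES[self])


PARAM_NAMES: dict[ModelForm, tuple[str, ...]] = {
    ModelForm.FIXED_SLOPE: ("bod_l", "a"),
    ModelForm.VARIABLE_SLOPE: ("bod_l", "a", "b"),
    ModelForm.ASYMMETRIC: ("bod_l", "a", "b", "s"),
}


def _predict(form: ModelForm, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Vectorized model curve; 0 at x = 0 by continuity (valid for b > 0)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros(x.shape, dtype=float)
    pos = x > 0
    xp = x[pos]
    # extreme trial parameters (e.g. S near its lower bound) overflow the
    # inner power; the ratio still collapses to the correct limit of 0
    with np.errstate(over="ignore"):
        if form is ModelForm.FIXED_SLOPE:
            bod_l, a = theta
            out[pos] = bod_l / (1.0 + a / xp)
        elif form is ModelForm.VARIABLE_SLOPE:
            bod_l, a, b = theta
            out[pos] = bod_l / (1.0 + (a / xp) ** b)
        else:
            bod_l, a, b, s = theta
            out[pos] = bod_l / (1.0 + (2.0 ** (1.0 / s) - 1.0) * (a / xp) ** b) ** s
    return out


def model_value(
    form: ModelForm | str,
    params: Mapping[str, float],
    x: float | Sequence[float] | np.ndarray,
):
    """Evaluate a kinetic model at time(s) ``x`` (days).

    ``params`` maps parameter names (``bod_l``, ``a``, and per form ``b``,
    ``s``) to values; all must be positive. Scalar in, scalar out.
    """
    form = ModelForm(form)
    names = PARAM_NAMES[form]
    missing = set(names) - set(params)
    if missing:
        raise ValidationError(f"{form.value}: missing parameters {sorted(missing)}")
    theta = np.array([float(params[n]) for n in names])
    if np.any(theta <= 0):
        raise ValidationError(f"{form.value}: parameters must be positive")
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x_arr < 0):
        raise ValidationError("time must be >= 0")
    y = _predict(form, theta, x_arr)
    return float(y[0]) if np.isscalar(x) or np.ndim(x) == 0 else y


@dataclass(eq=False)
class KineticFit:
    """Result of fitting one kinetic model to one corrected series.

    ``ci`` holds 95% confidence intervals; ``ci_calculable[name]`` is False
    when the covariance entry is singular or non-finite (reported as "n.c.",
    not calculable). ``refused`` marks a series whose signal was
    indistinguishable from noise; only a ``bod_l`` point estimate (mean of
    the final three observations) is then carried.
    """

    model: ModelForm
    params: dict[str, float]
    ci: dict[str, tuple[float, float]]
    ci_calculable: dict[str, bool]
    rss: float
    n_obs: int
    df: int
    refused: bool = False
    warnings: tuple[str, ...] = ()

    @property
    def bod_l(self) -> float:
        return self.params["bod_l"]

    @property
    def a(self) -> float:
        return self.params["a"]

    @property
    def b(self) -> float | None:
        return self.params.get("b", 1.0 if self.model is ModelForm.FIXED_SLOPE else None)

    @property
    def s(self) -> float | None:
        return self.params.get("s")

    def predict(self, x) -> np.ndarray:
        if self.refused:
            raise ValidationError("refused fit has no curve")
        return model_value(self.model, self.params, x)

    def to_dict(self) -> dict:
        def _pair(v):
            lo, hi = v
            return [None if not np.isfinite(lo) else float(lo),
                    None if not np.isfinite(hi) else float(hi)]

        return {
            "model": self.model.value,
            "params": {k: float(v) for k, v in self.params.items()},
            "ci95": {k: _pair(v) for k, v in self.ci.items()},
            "ci_calculable": dict(self.ci_calculable),
            "rss": None if not np.isfinite(self.rss) else float(self.rss),
            "n_obs": self.n_obs,
            "df": self.df,
            "refused": self.refused,
            "warnings": list(self.warnings),
        }


def _pooled_points(series: CorrectedSeries) -> tuple[np.ndarray, np.ndarray]:
    reps = np.atleast_2d(np.asarray(series.bod_replicates, dtype=float))
    x = np.tile(np.asarray(series.times, dtype=float), reps.shape[0])
    y = reps.ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def _refused_fit(form: ModelForm, series: CorrectedSeries, n_obs: int, reason: str) -> KineticFit:
    tail = np.asarray(series.bod_corrected, dtype=float)[-3:]
    est = float(np.mean(tail))
    nan_ci = (float("nan"), float("nan"))
    return KineticFit(
        model=form,
        params={"bod_l": est},
        ci={"bod_l": nan_ci},
        ci_calculable={"bod_l": False},
        rss=float("nan"),
        n_obs=n_obs,
        df=max(n_obs - form.n_params, 0),
        refused=True,
        warnings=(reason,),
    )


def _initial_a(times: np.ndarray, mean_curve: np.ndarray) -> float:
    """Earliest time the replicate-mean curve crosses half its maximum
    (linear interpolation between the bracketing readings)."""
    half = np.nanmax(mean_curve) / 2.0
    above = np.flatnonzero(mean_curve >= half)
    if above.size == 0:
        return float(times[len(times) // 2])
    i = above[0]
    if i == 0:
        return max(float(times[0]), 1e-6)
    t0, t1 = times[i - 1], times[i]
    y0, y1 = mean_curve[i - 1], mean_curve[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (half - y0) * (t1 - t0) / (y1 - y0))


def fit(series: CorrectedSeries, model: ModelForm | str = ModelForm.VARIABLE_SLOPE) -> KineticFit:
    """Fit one kinetic model to a blank-corrected series.

    All per-replicate points are pooled and weighted equally. Parameters are
    bound-constrained (all strictly positive; ``b <= 20``, ``S`` in
    [0.01, 100], ``BOD_L`` and ``a`` within 10x the observed maxima).
    Starting values are deterministic and data-driven, so the fit is
    reproducible with no random state.
    """
    form = ModelForm(model)
    names = PARAM_NAMES[form]
    k = form.n_params
    x, y = _pooled_points(series)
    n = x.size

    n_positive_time = int(np.sum(x > 0))
    if n == 0 or np.max(y) <= 0:
        return _refused_fit(form, series, n, "signal indistinguishable from noise")
    if n_positive_time < k + 1:
        return _refused_fit(form, series, n, "too few observations to fit")

    ymax = float(np.max(y))
    tmax = float(np.max(x))
    x0_map = {
        "bod_l": 1.1 * ymax,
        "a": _initial_a(np.asarray(series.times, float), np.asarray(series.bod_corrected, float)),
        "b": 1.0,
        "s": 1.0,
    }
    lo_map = {"bod_l": 1e-9, "a": 1e-9, "b": 1e-9, "s": 0.01}
    hi_map = {"bod_l": 10.0 * ymax, "a": 10.0 * tmax, "b": 20.0, "s": 100.0}
    x0 = np.array([np.clip(x0_map[p], lo_map[p] * 1.01, hi_map[p] * 0.99) for p in names])
    lo = np.array([lo_map[p] for p in names])
    hi = np.array([hi_map[p] for p in names])

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _predict(form, theta, x) - y

    res = optimize.least_squares(
        residuals, x0, bounds=(lo, hi), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
    )
    theta = res.x
    rss = float(np.sum(res.fun ** 2))
    df = n - k

    ci: dict[str, tuple[float, float]] = {}
    calculable: dict[str, bool] = {}
    warnings: tuple[str, ...] = ()
    if not res.success:
        warnings = ("optimizer did not report convergence",)

    se = np.full(k, np.nan)
    if df >= 1:
        jtj = res.jac.T @ res.jac
        try:
            cov = np.linalg.inv(jtj) * (rss / df)
            diag = np.diag(cov)
            with np.errstate(invalid="ignore"):
                se = np.where(diag >= 0, np.sqrt(diag), np.nan)
        except np.linalg.LinAlgError:
            pass
    tq = stats.t.ppf(0.975, df) if df >= 1 else np.nan
    for i, name in enumerate(names):
        half = tq * se[i]
        lo_i, hi_i = theta[i] - half, theta[i] + half
        ok = bool(np.isfinite(lo_i) and np.isfinite(hi_i))
        ci[name] = (float(lo_i), float(hi_i)) if ok else (float("nan"), float("nan"))
        calculable[name] = ok

    return KineticFit(
        model=form,
        params={name: float(v) for name, v in zip(names, theta)},
        ci=ci,
        ci_calculable=calculable,
        rss=rss,
        n_obs=n,
        df=df,
        warnings=warnings,
    )


def half_degradation_time(fitted: KineticFit) -> float:
    """The time at which the fitted curve reaches half of ``BOD_L``.

    For every model form this is the parameter ``a`` itself (the asymmetric
    form's normalizing constant ``2**(1/S) - 1`` is chosen precisely so the
    curve passes through ``BOD_L/2`` at ``X = a``).
    """
    if fitted.refused:
        raise ValidationError("refused fit has no half-degradation time")
    return fitted.params["a"]
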