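"""Nested model comparison: extra-sum-of-squares F-test, AICc, and the
step-up selection policy.

The three kinetic forms are nested (fixed slope ⊂ variable slope ⊂
asymmetric), so a more complex model always fits at least as well in RSS.
Whether the improvement is worth the extra parameter is judged twice:

* the extra-sum-of-squares F-test — a small p-value favours the complex
  model;
* the small-sample corrected Akaike criterion (AICc), reported as
  ``delta_aicc = AICc(simple) − AICc(complex)`` so a *positive* value
  favours the complex model.

Selection steps up from simple to complex only when the F-test is
significant, ΔAICc is positive, **and** every parameter the complex model
adds has a calculable, finite confidence interval. The identifiability
clause matters in practice: the asymmetry parameter of the 4-parameter form
can improve RSS significantly while its own confidence interval spans the
whole real line, in which case the extra parameter is noise-fitting and the
simpler model is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import ValidationError
from .kinetics import PARAM_NAMES, KineticFit, ModelForm, fit
from .preprocess import CorrectedSeries

__all__ = [
    "ModelComparison",
    "SelectionResult",
    "f_test",
    "aicc",
    "aicc_compare",
    "compare_models",
    "select_model",
]

#: selection ladder, simplest first
LADDER = (ModelForm.FIXED_SLOPE, ModelForm.VARIABLE_SLOPE, ModelForm.ASYMMETRIC)


@dataclass(frozen=True)
class ModelComparison:
    """One rung of the ladder: simple vs complex on the same data."""

    simple: KineticFit
    complex: KineticFit
    f_stat: float
    p_value: float
    delta_aicc: float
    preferred: str  # "simple" | "complex"

    def to_dict(self) -> dict:
        return {
            "simple": self.simple.model.value,
            "complex": self.complex.model.value,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "delta_aicc": self.delta_aicc,
            "preferred": self.preferred,
        }


@dataclass(frozen=True)
class SelectionResult:
    """Fits of all three forms plus the comparisons and the chosen fit."""

    fits: dict[ModelForm, KineticFit]
    comparisons: tuple[ModelComparison, ...]
    selected: KineticFit
    warnings: tuple[str, ...] = ()


def _check_nested(simple: KineticFit, complex: KineticFit) -> None:
    if simple.refused or complex.refused:
        raise ValidationError("cannot compare refused fits")
    if simple.n_obs != complex.n_obs:
        raise ValidationError("fits are not on the same data (n_obs differs)")
    if simple.model.n_params >= complex.model.n_params:
        raise ValidationError("'simple' must have fewer parameters than 'complex'")


def f_test(simple: KineticFit, complex: KineticFit) -> tuple[float, float]:
    """Extra-sum-of-squares F-test for nested least-squares fits.

    ``F = ((rss_s − rss_c)/(df_s − df_c)) / (rss_c/df_c)``, referred to the
    F distribution with ``(df_s − df_c, df_c)`` degrees of freedom. When the
    complex model fits no better (optimizer noise can leave rss_c slightly
    above rss_s), F is clamped to 0 and p to 1.
    """
    _check_nested(simple, complex)
    if complex.df < 1:
        raise ValidationError("complex fit has no residual degrees of freedom")
    ddf = simple.df - complex.df
    if complex.rss >= simple.rss:
        return 0.0, 1.0
    if complex.rss == 0.0:
        return math.inf, 0.0
    f_stat = ((simple.rss - complex.rss) / ddf) / (complex.rss / complex.df)
    p = float(stats.f.sf(f_stat, ddf, complex.df))
    return float(f_stat), p


def aicc(fitted: KineticFit, variant: str = "aicc") -> float:
    """(Corrected) Akaike information criterion of a least-squares fit.

    ``AIC = n·ln(rss/n) + 2K`` with ``K = n_params + 1`` (the error variance
    counts as a parameter); the ``aicc`` variant adds the small-sample term
    ``2K(K+1)/(n − K − 1)``.
    """
    if variant not in ("aicc", "aic"):
        raise ValidationError(f"unknown AIC variant {variant!r}")
    if fitted.refused:
        raise ValidationError("refused fit has no AIC")
    n = fitted.n_obs
    k = fitted.model.n_params + 1
    rss = max(fitted.rss, 1e-300)  # a numerically perfect fit
    val = n * math.log(rss / n) + 2 * k
    if variant == "aicc":
        if n - k - 1 <= 0:
            raise ValidationError(f"too few points (n={n}) for AICc with K={k}")
        val += 2 * k * (k + 1) / (n - k - 1)
    return val


def aicc_compare(
    simple: KineticFit, complex: KineticFit, variant: str = "aicc"
) -> float:
    """``AICc(simple) − AICc(complex)``: positive favours the complex model."""
    _check_nested(simple, complex)
    return aicc(simple, variant) - aicc(complex, variant)


def _new_params_identifiable(simple: KineticFit, complex: KineticFit) -> bool:
    new = set(PARAM_NAMES[complex.model]) - set(PARAM_NAMES[simple.model])
    return all(complex.ci_calculable.get(p, False) for p in new)


def compare_models(
    series: CorrectedSeries, alpha: float = 0.05, aic_variant: str = "aicc"
) -> SelectionResult:
    """Fit the full ladder and apply the step-up policy.

    A step from the current model to the next is taken only when the F-test
    p-value is below ``alpha``, ΔAICc is positive, and the added parameters
    are identifiable (finite, calculable CIs). If a more complex fit fails
    or the data cannot support its AICc, the current model is kept.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    fits: dict[ModelForm, KineticFit] = {}
    warnings: list[str] = []

    base = fit(series, LADDER[0])
    fits[LADDER[0]] = base
    if base.refused:
        return SelectionResult(fits=fits, comparisons=(), selected=base,
                               warnings=base.warnings)

    current = base
    comparisons: list[ModelComparison] = []
    for form in LADDER[1:]:
        candidate = fit(series, form)
        fits[form] = candidate
        if candidate.refused:
            warnings.append(f"{form.value}: fit refused; kept {current.model.value}")
            continue
        try:
            f_stat, p = f_test(current, candidate)
            delta = aicc_compare(current, candidate, aic_variant)
        except ValidationError as exc:
            warnings.append(f"{form.value}: comparison unavailable ({exc})")
            continue
        step_up = (
            p < alpha and delta > 0 and _new_params_identifiable(current, candidate)
        )
        comparisons.append(
            ModelComparison(
                simple=current,
                complex=candidate,
                f_stat=f_stat,
                p_value=p,
                delta_aicc=delta,
                preferred="complex" if step_up else "simple",
            )
        )
        if step_up:
            current = candidate

    return SelectionResult(
        fits=fits,
        comparisons=tuple(comparisons),
        selected=current,
        warnings=tuple(warnings),
    )


def select_model(
    series: CorrectedSeries, alpha: float = 0.05, aic_variant: str = "aicc"
) -> KineticFit:
    """Return the kinetic fit chosen by the step-up policy (see
    :func:`compare_models`). Deterministic given the data."""
    return compare_models(series, alpha=alpha, aic_variant=aic_variant).selected
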