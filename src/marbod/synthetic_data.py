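"""Synthetic respirometry experiments with the statistical structure the
analysis assumes.

The generator emulates a standard 28-day marine biodegradation trial:
daily cumulative-BOD readings, duplicate bottles per treatment, a PHB
positive control with a strong sigmoidal curve, blanks carrying a slowly
drifting background respiration, and additive homoscedastic Gaussian
measurement noise. Raw readings are clipped at zero — a manometric
respirometer cannot report negative cumulative O2 uptake.

Randomness is counter-based: one experiment seed spawns an independent
stream per bottle, so adding a material to a spec does not perturb the
readings of bottles that were already there.

:func:`scenario_library` provides presets for a reference panel of
commercial compostable products, coatings and prototype polymers spanning
all four biodegradability classes, each parameterized by its published
logistic slope, ultimate BOD and day-28 %C+.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .io_experiment import (
    BLANK_MATERIAL_ID,
    BottleSeries,
    Experiment,
    MaterialMeta,
    Role,
)
from .kinetics import ModelForm, model_value

__all__ = [
    "MaterialKinetics",
    "SimSpec",
    "simulate",
    "scenario_library",
    "REFERENCE_PANEL",
    "PanelEntry",
    "CPLUS_ID",
    "PHB_FORMULA",
]

CPLUS_ID = "C+"
PHB_FORMULA = {"C": 4, "H": 6, "O": 2}  # PHB repeat unit


@dataclass(frozen=True)
class MaterialKinetics:
    """True kinetic parameters of one simulated material."""

    bod_l: float
    a: float = 10.0
    b: float = 1.0
    s: float = 1.0
    form: ModelForm = ModelForm.VARIABLE_SLOPE

    def params(self) -> dict[str, float]:
        p = {"bod_l": self.bod_l, "a": self.a}
        if self.form is not ModelForm.FIXED_SLOPE:
            p["b"] = self.b
        if self.form is ModelForm.ASYMMETRIC:
            p["s"] = self.s
        return p

    def curve(self, days: np.ndarray) -> np.ndarray:
        return np.asarray(model_value(self.form, self.params(), days))


def _default_days() -> np.ndarray:
    return np.arange(0.0, 29.0)


@dataclass(frozen=True)
class SimSpec:
    """Complete description of one synthetic trial.

    ``blank_base``/``blank_slope`` define a linear background respiration
    ``blank(t) = base + slope·t``; the defaults put the day-28 blank near
    1 mg O2/L, about 1% of the default control and inside the <2% QA gate,
    while keeping the blank far enough above zero that clipping of noisy
    readings is rare. ``noise_sd`` is the additive Gaussian measurement
    noise in mg O2/L (default 0.3, the scale of a manometric sensor's
    resolution); with ``heteroscedastic=True`` the noise SD instead scales
    with the signal (``noise_sd`` at the curve maximum).
    """

    materials: Mapping[str, MaterialKinetics] = field(default_factory=dict)
    cplus: MaterialKinetics = MaterialKinetics(bod_l=110.0, a=8.0, b=2.0)
    blank_base: float = 0.6
    blank_slope: float = 1.0 / 70.0
    noise_sd: float = 0.3
    heteroscedastic: bool = False
    n_replicates: int = 2
    days: np.ndarray = field(default_factory=_default_days)
    seed: int = 0
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.blank_base < 0 or self.blank_slope < 0:
            raise ValidationError("blank level must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        for mid, mk in {**dict(self.materials), CPLUS_ID: self.cplus}.items():
            for name, v in mk.params().items():
                if v <= 0:
                    raise ValidationError(f"{mid}: parameter {name} must be > 0")
        days = np.asarray(self.days, dtype=float)
        if days.ndim != 1 or days.size < 2 or np.any(np.diff(days) <= 0) or days[0] < 0:
            raise ValidationError("days must be a strictly increasing 1-D grid, >= 0")
        object.__setattr__(self, "days", days)


def _blank_level(spec: SimSpec, days: np.ndarray) -> np.ndarray:
    return spec.blank_base + spec.blank_slope * days


def _noisy(
    signal: np.ndarray, spec: SimSpec, rng: np.random.Generator
) -> np.ndarray:
    if spec.noise_sd == 0:
        return np.maximum(signal, 0.0)
    if spec.heteroscedastic:
        top = max(float(np.max(signal)), 1e-12)
        sd = spec.noise_sd * signal / top
    else:
        sd = np.full_like(signal, spec.noise_sd)
    return np.maximum(signal + rng.normal(0.0, 1.0, signal.shape) * sd, 0.0)


def simulate(spec: SimSpec) -> Experiment:
    """Generate a complete :class:`Experiment` from a :class:`SimSpec`.

    Deterministic given ``spec.seed``. Treatment bottles read
    ``curve(day) + blank(day) + noise``; blanks read ``blank(day) + noise``;
    everything is clipped at zero.
    """
    days = spec.days
    blank = _blank_level(spec, days)
    bottles: list[BottleSeries] = []

    plan: list[tuple[str, Role, np.ndarray]] = []
    for _ in range(spec.n_replicates):
        plan.append((BLANK_MATERIAL_ID, Role.BLANK, blank))
    cplus_signal = spec.cplus.curve(days) + blank
    for _ in range(spec.n_replicates):
        plan.append((CPLUS_ID, Role.POSITIVE_CONTROL, cplus_signal))
    for mid, mk in spec.materials.items():
        signal = mk.curve(days) + blank
        for _ in range(spec.n_replicates):
            plan.append((mid, Role.SAMPLE, signal))

    rep_counter: dict[str, int] = {}
    for idx, (mid, role, signal) in enumerate(plan):
        rep = rep_counter.get(mid, 0) + 1
        rep_counter[mid] = rep
        rng = np.random.default_rng([int(spec.seed), idx])
        bottles.append(
            BottleSeries(
                bottle_id=f"{mid}-{rep}",
                role=role,
                material_id=mid,
                replicate=rep,
                times=days.copy(),
                bod=_noisy(signal, spec, rng),
            )
        )

    materials = [
        MaterialMeta(
            material_id=CPLUS_ID,
            label=spec.labels.get(CPLUS_ID, "PHB powder positive control"),
            mass_concentration=100.0,
            formula=PHB_FORMULA,
        )
    ]
    for mid in spec.materials:
        materials.append(
            MaterialMeta(material_id=mid, label=spec.labels.get(mid, mid))
        )
    return Experiment(bottles=bottles, materials=materials)


# ---------------------------------------------------------------------------
# Reference panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelEntry:
    """Published headline numbers for one reference-panel material:
    day-28 %C+, verdict, and (where the fit converged) the variable-slope
    parameters b and ultimate BOD. ``b`` is None where it was not
    calculable (flat, signal-free curves)."""

    material_id: str
    label: str
    pct_cplus_28: float
    category: str
    b: float | None
    bod_l: float


REFERENCE_PANEL: tuple[PanelEntry, ...] = (
    PanelEntry("ID017", "PE bag (negative control)", 1.2, "non", None, 1.3),
    PanelEntry("ID016", "Home-compostable bag", 17.6, "slightly", 1.40, 22.2),
    PanelEntry("ID045", "Home-compostable bag", 7.8, "slightly", 0.85, 19.8),
    PanelEntry("ID015", "Industrial-compostable bag", 5.4, "slightly", 1.75, 7.6),
    PanelEntry("ID072", "Industrial-compostable bag", 13.4, "slightly", 1.50, 27.4),
    PanelEntry("ID073", "Industrial-compostable bag", 15.6, "slightly", 1.84, 21.6),
    PanelEntry("ID079", "Compostable net", 0.8, "non", 2.81, 1.2),
    PanelEntry("IC-Y", "Conventional coating", 2.3, "non", 2.21, 3.5),
    PanelEntry("IC-B", "Alternative coating", 42.0, "moderately", 1.65, 54.2),
    PanelEntry("GL09", "First-generation polymer", 0.5, "non", None, 0.1),
    PanelEntry("GL12", "First-generation polymer", 16.5, "slightly", 2.73, 20.7),
    PanelEntry("GL18", "Second-generation polymer", 21.4, "moderately", 2.24, 29.2),
    PanelEntry("GL19", "Second-generation polymer", 10.0, "slightly", 1.82, 18.2),
    PanelEntry("GL20", "Second-generation polymer", 13.1, "slightly", 1.71, 27.8),
)

#: default half-degradation time for presets (days); the published table
#: prints no half-degradation times, so presets place it mid-assay.
DEFAULT_A = 10.0

# The tuned control asymptote is clamped into a physically plausible window:
# >= 110 mg/L keeps the control above the 60%-of-ThOD QA gate (100 mg/L PHB
# ceiling = 167.3 mg O2/L) and <= 165 mg/L keeps it below that ceiling.
_CPLUS_BODL_RANGE = (110.0, 165.0)


def _panel_kinetics(entry: PanelEntry) -> MaterialKinetics:
    b = entry.b if entry.b is not None else 1.0
    return MaterialKinetics(bod_l=entry.bod_l, a=DEFAULT_A, b=b)


def _tuned_cplus(entry: PanelEntry, day: float = 28.0) -> MaterialKinetics:
    """Positive-control kinetics tuned so the simulated day-28 %C+ matches
    the panel's published value (clamped to a plausible asymptote)."""
    shape = MaterialKinetics(bod_l=1.0, a=8.0, b=2.0)
    sample_28 = float(_panel_kinetics(entry).curve(np.array([day]))[0])
    needed_cplus_28 = sample_28 * 100.0 / entry.pct_cplus_28
    bod_l = needed_cplus_28 / float(shape.curve(np.array([day]))[0])
    bod_l = float(np.clip(bod_l, *_CPLUS_BODL_RANGE))
    return replace(shape, bod_l=bod_l)


def scenario_library() -> dict[str, SimSpec]:
    """Named simulation presets.

    One preset per reference-panel material (sample at its published b and
    ultimate BOD, control tuned so the simulated %C+ lands on the published
    value), plus ``"PE"`` as an alias for the polyethylene negative control
    and ``"C+"`` for a control-only trial.
    """
    lib: dict[str, SimSpec] = {}
    for entry in REFERENCE_PANEL:
        lib[entry.material_id] = SimSpec(
            materials={entry.material_id: _panel_kinetics(entry)},
            cplus=_tuned_cplus(entry),
            labels={entry.material_id: entry.label},
        )
    lib["PE"] = lib["ID017"]
    lib["C+"] = SimSpec(materials={})
    return lib
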