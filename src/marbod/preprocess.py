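"""Blank correction, %C+ normalization, ThOD, and QA gates.

The raw signal in every treatment bottle contains the background respiration
of the inoculum itself. The trial-level blanks measure that background; the
mean blank BOD at each time is subtracted from every treatment (including
the positive control). Blank-corrected treatment BOD is then expressed as a
percentage of the blank-corrected positive-control BOD at the same time
(%C+), which is the normalization the whole classification scheme runs on.

Two quality gates guard a trial:

* the blank BOD at the assessment day must stay below 2% of the raw
  positive-control BOD (signal-to-noise gate);
* the corrected positive-control BOD must exceed 60% of the theoretical
  oxygen demand (ThOD) implied by its dose and elemental composition
  (inoculum-activity gate).

Both thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateTrialError, ExtrapolationError, ValidationError
from .io_experiment import BottleSeries, Experiment, MaterialMeta, Role

__all__ = [
    "CorrectedSeries",
    "QAResult",
    "align_to_grid",
    "blank_correct",
    "pct_cplus",
    "thod",
    "qa_gates",
    "BLANK_GATE_MAX",
    "CPLUS_GATE_MIN",
]

#: blank BOD at the assessment day must be < 2% of the raw positive control
BLANK_GATE_MAX = 0.02
#: corrected positive-control BOD must be > 60% of its ThOD-implied maximum
CPLUS_GATE_MIN = 0.60

# standard atomic masses (g/mol)
_ATOMIC_MASS = {
    "C": 12.011,
    "H": 1.008,
    "O": 15.999,
    "N": 14.007,
    "S": 32.06,
    "P": 30.974,
}

# g O2 demanded per mole of each element under complete oxidation
# (C -> CO2, H -> H2O, S -> SO3, P -> P2O5; O in the material offsets demand)
_O2_PER_MOL = {"C": 32.0, "H": 8.0, "O": -16.0, "S": 24.0, "P": 40.0}


@dataclass(eq=False)
class CorrectedSeries:
    """Blank-corrected, replicate-resolved time course for one material.

    ``bod_corrected`` is the replicate mean; ``bod_replicates`` keeps the
    per-replicate corrected values (shape ``(n_replicates, n_times)``) for
    pooled fitting. ``pct_cplus`` is the %C+ track, defined only at times
    where the positive control has positive corrected BOD (NaN elsewhere).
    """

    material_id: str
    times: np.ndarray
    bod_corrected: np.ndarray
    bod_replicates: np.ndarray
    pct_cplus: np.ndarray | None = None

    def value_at(self, day: float) -> float:
        """Linearly interpolated corrected (replicate-mean) BOD at ``day``."""
        return float(
            _interp_one(self.times, self.bod_corrected, day, what=self.material_id)
        )

    def pct_cplus_at(self, day: float) -> float:
        if self.pct_cplus is None:
            raise ValidationError(f"{self.material_id}: %C+ track not computed")
        ok = np.isfinite(self.pct_cplus)
        if not ok.any():
            raise DegenerateTrialError(
                f"{self.material_id}: positive control never positive"
            )
        return float(
            _interp_one(self.times[ok], self.pct_cplus[ok], day, what="%C+")
        )


@dataclass(frozen=True)
class QAResult:
    """Outcome of the two trial-level quality gates.

    ``cplus_fraction_of_thod`` / ``cplus_pass`` are None (indeterminate)
    when the positive control's elemental composition is unknown.
    """

    blank_fraction_of_cplus: float
    cplus_fraction_of_thod: float | None
    blank_pass: bool
    cplus_pass: bool | None

    def to_dict(self) -> dict:
        return {
            "blank_fraction_of_cplus": self.blank_fraction_of_cplus,
            "cplus_fraction_of_thod": self.cplus_fraction_of_thod,
            "blank_pass": self.blank_pass,
            "cplus_pass": self.cplus_pass,
        }


def _interp_one(times: np.ndarray, values: np.ndarray, day: float, *, what: str) -> float:
    if day < times[0] or day > times[-1]:
        raise ExtrapolationError(
            f"{what}: day {day} outside observed range [{times[0]}, {times[-1]}]"
        )
    return float(np.interp(day, times, values))


def align_to_grid(
    bottles: Sequence[BottleSeries], grid: Sequence[float]
) -> dict[str, np.ndarray]:
    """Linearly interpolate each bottle onto a common time grid.

    Exact at observed times. Requesting a grid point outside a bottle's
    observed range raises :class:`ExtrapolationError` rather than
    extrapolating silently.
    """
    grid = np.asarray(grid, dtype=float)
    out: dict[str, np.ndarray] = {}
    for b in bottles:
        if grid.size and (grid.min() < b.times[0] or grid.max() > b.times[-1]):
            raise ExtrapolationError(
                f"bottle {b.bottle_id}: grid [{grid.min()}, {grid.max()}] outside "
                f"observed range [{b.times[0]}, {b.times[-1]}]"
            )
        out[b.bottle_id] = np.interp(grid, b.times, b.bod)
    return out


def _material_grid(
    material_bottles: Sequence[BottleSeries], blanks: Sequence[BottleSeries]
) -> np.ndarray:
    """Union of the material's observed times, restricted to the time span
    covered by every replicate and every blank."""
    lo = max(b.times[0] for b in [*material_bottles, *blanks])
    hi = min(b.times[-1] for b in [*material_bottles, *blanks])
    if hi < lo:
        raise ValidationError(
            f"{material_bottles[0].material_id}: no common time support with blanks"
        )
    times = np.unique(np.concatenate([b.times for b in material_bottles]))
    grid = times[(times >= lo) & (times <= hi)]
    if grid.size == 0:
        raise ValidationError(
            f"{material_bottles[0].material_id}: no common time support with blanks"
        )
    return grid


def blank_correct(exp: Experiment) -> dict[str, CorrectedSeries]:
    """Blank-correct every non-blank material and attach the %C+ track.

    For each material the grid is the union of its replicates' observed times
    inside the span shared with the blanks; the mean blank BOD (interpolated
    onto that grid) is subtracted from each replicate. Negative corrected
    values are retained, not clipped, so replicate noise stays unbiased.
    """
    blanks = exp.blanks
    out: dict[str, CorrectedSeries] = {}
    material_ids = [exp.cplus_material_id, *exp.sample_material_ids]
    for mid in material_ids:
        mb = sorted(exp.bottles_for(mid), key=lambda b: b.replicate)
        grid = _material_grid(mb, blanks)
        blank_vals = align_to_grid(blanks, grid)
        blank_mean = np.mean([blank_vals[b.bottle_id] for b in blanks], axis=0)
        rep_vals = align_to_grid(mb, grid)
        reps = np.vstack([rep_vals[b.bottle_id] - blank_mean for b in mb])
        out[mid] = CorrectedSeries(
            material_id=mid,
            times=grid,
            bod_corrected=reps.mean(axis=0),
            bod_replicates=reps,
        )

    cplus = out[exp.cplus_material_id]
    for series in out.values():
        # %C+ defined where both series are observed and the control is > 0
        lo = max(series.times[0], cplus.times[0])
        hi = min(series.times[-1], cplus.times[-1])
        pct = np.full_like(series.times, np.nan)
        inside = (series.times >= lo) & (series.times <= hi)
        cp = np.interp(series.times[inside], cplus.times, cplus.bod_corrected)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = 100.0 * series.bod_corrected[inside] / cp
        vals[cp <= 0] = np.nan
        pct[inside] = vals
        series.pct_cplus = pct
    return out


def pct_cplus(
    corrected: CorrectedSeries, cplus: CorrectedSeries, day: float
) -> float:
    """Blank-corrected BOD of a material as % of the positive control at ``day``.

    Raises :class:`DegenerateTrialError` when the control's corrected BOD at
    that day is not positive (the trial carries no reference signal).
    """
    num = corrected.value_at(day)
    den = cplus.value_at(day)
    if den <= 0:
        raise DegenerateTrialError(
            f"positive control corrected BOD at day {day} is {den:.3g} <= 0"
        )
    return 100.0 * num / den


def thod(formula: Mapping[str, int], n_source: str = "nitrate") -> float:
    """Theoretical oxygen demand (g O2 per g material) from the repeat unit.

    Complete-oxidation stoichiometry: C to CO2, H to H2O, S to SO3, P to
    P2O5. With ``n_source="nitrate"`` nitrogen is oxidized to NO3- (each mole
    of N demands 2 mol O2 beyond the reduced case, net +40 g O2/mol); with
    ``"ammonium"`` nitrogen leaves as NH3 and withholds three H from
    oxidation (net -24 g O2/mol). The protocol uses nitrate as the nitrogen
    source, so nitrate is the default.
    """
    if not formula:
        raise ValidationError("empty formula")
    unsupported = set(formula) - set(_ATOMIC_MASS)
    if unsupported:
        raise ValidationError(f"unsupported elements: {sorted(unsupported)}")
    if "C" not in formula:
        raise ValidationError("formula contains no carbon")
    if n_source not in ("nitrate", "ammonium"):
        raise ValidationError(f"unknown n_source {n_source!r}")
    n_term = 40.0 if n_source == "nitrate" else -24.0
    o2 = sum(_O2_PER_MOL.get(el, 0.0) * n for el, n in formula.items())
    o2 += n_term * formula.get("N", 0)
    mw = sum(_ATOMIC_MASS[el] * n for el, n in formula.items())
    return o2 / mw


def qa_gates(
    exp: Experiment,
    corrected: Mapping[str, CorrectedSeries],
    cplus_meta: MaterialMeta | None = None,
    *,
    n_source: str = "nitrate",
    day: float | None = None,
) -> QAResult:
    """Evaluate the blank and positive-control quality gates at the
    assessment day.

    blank gate
        mean raw blank BOD / mean raw positive-control BOD < 2%.
    control gate
        corrected positive-control BOD / (dose x ThOD) > 60%; reported as
        indeterminate (None) when the control's formula is unknown.
    """
    day = exp.assessment_day if day is None else day
    cid = exp.cplus_material_id
    if cplus_meta is None:
        cplus_meta = exp.meta_for(cid)

    blank_mean = float(
        np.mean([_interp_one(b.times, b.bod, day, what=b.bottle_id) for b in exp.blanks])
    )
    cplus_raw = float(
        np.mean(
            [
                _interp_one(b.times, b.bod, day, what=b.bottle_id)
                for b in exp.bottles_for(cid)
            ]
        )
    )
    if cplus_raw <= 0:
        raise DegenerateTrialError("raw positive-control BOD <= 0 at assessment day")
    blank_fraction = blank_mean / cplus_raw

    cplus_fraction: float | None = None
    cplus_pass: bool | None = None
    if cplus_meta.formula is not None:
        thod_val = thod(cplus_meta.formula, n_source=n_source)
        ceiling = cplus_meta.mass_concentration * thod_val  # mg O2 / L
        cplus_fraction = corrected[cid].value_at(day) / ceiling
        cplus_pass = cplus_fraction > CPLUS_GATE_MIN

    return QAResult(
        blank_fraction_of_cplus=blank_fraction,
        cplus_fraction_of_thod=cplus_fraction,
        blank_pass=blank_fraction < BLANK_GATE_MAX,
        cplus_pass=cplus_pass,
    )
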