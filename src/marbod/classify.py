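"""Four-class marine-biodegradability verdict and the end-to-end pipeline.

A material's blank-corrected BOD at the assessment day (28 d by default),
expressed as a percentage of the PHB positive control (%C+), maps onto four
classes::

    %C+ > 60        readily biodegradable
    20 < %C+ <= 60  moderately biodegradable
    5  < %C+ <= 20  slightly biodegradable
    %C+ <= 5        non-biodegradable

The boundaries are closed on the lower class (exactly 5 is "non", exactly
20 "slightly", exactly 60 "moderately"). Classification uses the observed
day-28 signal, not the fitted asymptote: the thresholds are defined for a
fixed 28-day window, while the ultimate BOD from the kinetic fit is
reported alongside as the exposure-time-independent estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .errors import DegenerateTrialError, MarbodError, ValidationError
from .io_experiment import Experiment
from .kinetics import KineticFit, ModelForm
from .model_selection import SelectionResult, compare_models
from .preprocess import QAResult, blank_correct, pct_cplus, qa_gates

__all__ = ["Category", "AssessmentReport", "classify", "assess", "THRESHOLDS"]


class Category(str, Enum):
    NON = "non"
    SLIGHTLY = "slightly"
    MODERATELY = "moderately"
    READILY = "readily"


#: upper %C+ bound of each class below "readily" (closed on the lower class)
THRESHOLDS = ((5.0, Category.NON), (20.0, Category.SLIGHTLY), (60.0, Category.MODERATELY))


def classify(pct_cplus: float) -> Category:
    """Map a %C+ value to its biodegradability class.

    Negative values (a blank-dominated, essentially inert material) map to
    ``non``; NaN is an error.
    """
    if math.isnan(pct_cplus):
        raise ValidationError("%C+ is NaN")
    for bound, cat in THRESHOLDS:
        if pct_cplus <= bound:
            return cat
    return Category.READILY


@dataclass(eq=False)
class AssessmentReport:
    """Per-material verdict: headline %C+, class, selected kinetic fit, QA."""

    material_id: str
    label: str
    pct_cplus: float
    category: Category
    selection: SelectionResult
    qa: QAResult
    assessment_day: float

    @property
    def fit(self) -> KineticFit:
        return self.selection.selected

    def to_dict(self) -> dict:
        f = self.fit
        return {
            "material_id": self.material_id,
            "label": self.label,
            "assessment_day": self.assessment_day,
            "pct_cplus": self.pct_cplus,
            "category": self.category.value,
            "selected_model": f.model.value,
            "fit": f.to_dict(),
            "comparisons": [c.to_dict() for c in self.selection.comparisons],
            "qa": self.qa.to_dict(),
            "warnings": list(self.selection.warnings),
        }


def assess(
    exp: Experiment,
    *,
    alpha: float = 0.05,
    aic_variant: str = "aicc",
    n_source: str = "nitrate",
    assessment_day: float | None = None,
) -> list[AssessmentReport]:
    """Run the full pipeline on every sample material of an experiment.

    blank-correct → %C+ at the assessment day → kinetic model selection →
    classification, with the trial-level QA gates attached to every report.
    A QA failure flags the report but does not block it. Reports are sorted
    by material id.
    """
    day = exp.assessment_day if assessment_day is None else assessment_day
    if day <= 0:
        raise ValidationError("assessment_day must be > 0")
    corrected = blank_correct(exp)
    cid = exp.cplus_material_id
    qa = qa_gates(exp, corrected, n_source=n_source, day=day)

    reports: list[AssessmentReport] = []
    for mid in exp.sample_material_ids:
        series = corrected[mid]
        pct = pct_cplus(series, corrected[cid], day)
        selection = compare_models(series, alpha=alpha, aic_variant=aic_variant)
        reports.append(
            AssessmentReport(
                material_id=mid,
                label=exp.meta_for(mid).label,
                pct_cplus=pct,
                category=classify(pct),
                selection=selection,
                qa=qa,
                assessment_day=day,
            )
        )
    return reports
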