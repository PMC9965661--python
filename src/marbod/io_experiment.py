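"""Data model and CSV readers/writers for BOD respirometry experiments.

An *experiment* is a set of incubation bottles monitored over ~28 days with a
manometric respirometer. Each bottle plays one of three roles:

``blank``
    inoculated seawater with no test material; measures background
    respiration of the inoculum itself.
``positive_control``
    a fully marine-biodegradable reference polymer (PHB) that anchors the
    %C+ normalization.
``sample``
    a test material (commercial product or prototype polymer).

The on-disk representation is a long-format CSV, one row per bottle per
reading, with the exact header::

    bottle_id,role,material_id,replicate,day,bod_mg_l

An optional metadata sidecar describes materials::

    material_id,label,mass_conc_mg_l,formula

where ``formula`` is a Hill-notation repeat-unit formula (e.g. ``C4H6O2``
for PHB), used for theoretical-oxygen-demand calculations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "Role",
    "BLANK_MATERIAL_ID",
    "BottleSeries",
    "MaterialMeta",
    "Experiment",
    "read_experiment",
    "write_experiment",
    "parse_formula",
    "format_formula",
]

BLANK_MATERIAL_ID = "BLANK"

#: exact CSV header of the bottle time-series file
CSV_COLUMNS = ("bottle_id", "role", "material_id", "replicate", "day", "bod_mg_l")

#: exact CSV header of the optional material-metadata sidecar
META_COLUMNS = ("material_id", "label", "mass_conc_mg_l", "formula")


class Role(str, Enum):
    BLANK = "blank"
    POSITIVE_CONTROL = "positive_control"
    SAMPLE = "sample"


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-notation formula string into an element-count map.

    >>> parse_formula("C4H6O2")
    {'C': 4, 'H': 6, 'O': 2}
    """
    text = text.strip()
    if not text:
        raise FormatError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos or not m.group(0):
            break
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(text):
        raise FormatError(f"cannot parse formula {text!r}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Render an element-count map in Hill order (C, H, then alphabetical)."""
    keys = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in keys)


@dataclass(eq=False)
class BottleSeries:
    """One bottle's raw cumulative-BOD time course.

    Parameters
    ----------
    times : array-like of float
        Reading times in days, strictly increasing, first reading >= 0.
    bod : array-like of float
        Cumulative BOD in mg O2 / L, same length as ``times``. Raw readings
        are non-negative (the instrument reports cumulative O2 uptake);
        negative values only appear downstream, after blank correction.
    """

    bottle_id: str
    role: Role
    material_id: str
    replicate: int
    times: np.ndarray
    bod: np.ndarray

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        self.times = np.asarray(self.times, dtype=float)
        self.bod = np.asarray(self.bod, dtype=float)
        if self.times.ndim != 1 or self.bod.ndim != 1:
            raise ValidationError(f"bottle {self.bottle_id}: times/bod must be 1-D")
        if len(self.times) != len(self.bod):
            raise ValidationError(
                f"bottle {self.bottle_id}: times and bod differ in length"
            )
        if len(self.times) == 0:
            raise ValidationError(f"bottle {self.bottle_id}: empty series")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.bod)):
            raise ValidationError(f"bottle {self.bottle_id}: non-finite values")
        if self.times[0] < 0:
            raise ValidationError(f"bottle {self.bottle_id}: negative time")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"bottle {self.bottle_id}: times not strictly increasing"
            )
        if np.any(self.bod < 0):
            raise ValidationError(
                f"bottle {self.bottle_id}: raw BOD must be non-negative"
            )
        if self.role is Role.BLANK and self.material_id != BLANK_MATERIAL_ID:
            raise ValidationError(
                f"bottle {self.bottle_id}: blank bottles must use material_id "
                f"{BLANK_MATERIAL_ID!r}"
            )
        if self.role is not Role.BLANK and self.material_id == BLANK_MATERIAL_ID:
            raise ValidationError(
                f"bottle {self.bottle_id}: material_id {BLANK_MATERIAL_ID!r} is "
                "reserved for blanks"
            )
        if int(self.replicate) != self.replicate or self.replicate < 1:
            raise ValidationError(
                f"bottle {self.bottle_id}: replicate must be a positive integer"
            )
        self.replicate = int(self.replicate)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BottleSeries):
            return NotImplemented
        return (
            self.bottle_id == other.bottle_id
            and self.role == other.role
            and self.material_id == other.material_id
            and self.replicate == other.replicate
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.bod, other.bod)
        )


@dataclass(frozen=True)
class MaterialMeta:
    """Material-level metadata used for ThOD and reporting.

    ``mass_concentration`` is the test-material dose in mg material / L
    (100 mg/L in the standard protocol). ``formula`` is the repeat-unit
    elemental composition; it may be None for heteropolymers or blends of
    unknown composition, in which case ThOD-based QA is indeterminate.
    """

    material_id: str
    label: str = ""
    mass_concentration: float = 100.0
    formula: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.mass_concentration <= 0:
            raise ValidationError(
                f"material {self.material_id}: mass_concentration must be > 0"
            )
        if self.formula is not None:
            f = dict(self.formula)
            if not f:
                raise ValidationError(f"material {self.material_id}: empty formula")
            for el, n in f.items():
                if int(n) != n or n <= 0:
                    raise ValidationError(
                        f"material {self.material_id}: formula count for {el} "
                        "must be a positive integer"
                    )
            object.__setattr__(self, "formula", {el: int(n) for el, n in f.items()})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MaterialMeta):
            return NotImplemented
        return (
            self.material_id == other.material_id
            and self.label == other.label
            and self.mass_concentration == other.mass_concentration
            and (dict(self.formula) if self.formula else None)
            == (dict(other.formula) if other.formula else None)
        )


@dataclass(eq=False)
class Experiment:
    """A validated respirometry trial: bottles plus material metadata.

    Invariants enforced at construction: at least one blank and one positive
    control bottle; every non-blank material has a metadata entry; bottle ids
    are unique.
    """

    bottles: list[BottleSeries]
    materials: list[MaterialMeta] = field(default_factory=list)
    assessment_day: float = 28.0

    def __post_init__(self) -> None:
        if not self.bottles:
            raise ValidationError("experiment has no bottles")
        if self.assessment_day <= 0:
            raise ValidationError("assessment_day must be > 0")
        ids = [b.bottle_id for b in self.bottles]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate bottle_id")
        roles = {b.role for b in self.bottles}
        if Role.BLANK not in roles:
            raise ValidationError("experiment has no blank bottle")
        if Role.POSITIVE_CONTROL not in roles:
            raise ValidationError("experiment has no positive control bottle")
        cplus_ids = {
            b.material_id for b in self.bottles if b.role is Role.POSITIVE_CONTROL
        }
        if len(cplus_ids) > 1:
            raise ValidationError(
                f"multiple positive-control materials: {sorted(cplus_ids)}"
            )
        meta_ids = {m.material_id for m in self.materials}
        missing = {
            b.material_id
            for b in self.bottles
            if b.role is not Role.BLANK and b.material_id not in meta_ids
        }
        # default-construct metadata (100 mg/L, unknown formula) for bare CSVs
        for mid in sorted(missing):
            self.materials.append(MaterialMeta(material_id=mid, label=mid))

    # -- convenience views -------------------------------------------------

    @property
    def cplus_material_id(self) -> str:
        return next(
            b.material_id for b in self.bottles if b.role is Role.POSITIVE_CONTROL
        )

    @property
    def sample_material_ids(self) -> list[str]:
        return sorted(
            {b.material_id for b in self.bottles if b.role is Role.SAMPLE}
        )

    def bottles_for(self, material_id: str) -> list[BottleSeries]:
        return [b for b in self.bottles if b.material_id == material_id]

    @property
    def blanks(self) -> list[BottleSeries]:
        return [b for b in self.bottles if b.role is Role.BLANK]

    def meta_for(self, material_id: str) -> MaterialMeta:
        for m in self.materials:
            if m.material_id == material_id:
                return m
        raise KeyError(material_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Experiment):
            return NotImplemented
        return (
            self.assessment_day == other.assessment_day
            and sorted(self.bottles, key=lambda b: b.bottle_id)
            == sorted(other.bottles, key=lambda b: b.bottle_id)
            and sorted(self.materials, key=lambda m: m.material_id)
            == sorted(other.materials, key=lambda m: m.material_id)
        )


def read_experiment(
    path: str | Path,
    format: str = "csv",
    *,
    meta_path: str | Path | None = None,
    assessment_day: float = 28.0,
) -> Experiment:
    """Read a long-format bottle CSV (plus optional metadata sidecar).

    Raises :class:`FormatError` for a malformed file (missing column,
    unparseable cell) and :class:`ValidationError` for well-formed input that
    violates the experiment invariants (duplicated readings, non-monotone
    times, missing blank or positive control).
    """
    if format != "csv":
        raise FormatError(f"unsupported format {format!r}")
    path = Path(path)
    try:
        # round_trip parsing keeps write->read lossless to the last ulp
        df = pd.read_csv(
            path,
            dtype={"bottle_id": str, "material_id": str},
            float_precision="round_trip",
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    dup = df.duplicated(subset=["bottle_id", "day"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicated reading for bottle {row['bottle_id']!r} "
            f"at day {row['day']}"
        )

    bottles: list[BottleSeries] = []
    for bottle_id, grp in df.groupby("bottle_id", sort=False):
        roles = grp["role"].unique()
        if len(roles) != 1:
            raise ValidationError(f"bottle {bottle_id!r}: inconsistent role labels")
        try:
            role = Role(roles[0])
        except ValueError as exc:
            raise FormatError(
                f"bottle {bottle_id!r}: unknown role {roles[0]!r}"
            ) from exc
        reps = grp["replicate"].unique()
        if len(reps) != 1:
            raise ValidationError(
                f"bottle {bottle_id!r}: inconsistent replicate labels"
            )
        grp = grp.sort_values("day")
        bottles.append(
            BottleSeries(
                bottle_id=str(bottle_id),
                role=role,
                material_id=str(grp["material_id"].iloc[0]),
                replicate=int(reps[0]),
                times=grp["day"].to_numpy(dtype=float),
                bod=grp["bod_mg_l"].to_numpy(dtype=float),
            )
        )

    materials: list[MaterialMeta] = []
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, dtype={"material_id": str})
        for col in META_COLUMNS:
            if col not in mdf.columns:
                raise FormatError(f"{meta_path}: missing required column {col!r}")
        for _, row in mdf.iterrows():
            formula = None
            if isinstance(row["formula"], str) and row["formula"].strip():
                formula = parse_formula(row["formula"])
            materials.append(
                MaterialMeta(
                    material_id=str(row["material_id"]),
                    label="" if pd.isna(row["label"]) else str(row["label"]),
                    mass_concentration=float(row["mass_conc_mg_l"]),
                    formula=formula,
                )
            )
    return Experiment(bottles=bottles, materials=materials, assessment_day=assessment_day)


def write_experiment(
    exp: Experiment,
    path: str | Path,
    *,
    meta_path: str | Path | None = None,
) -> None:
    """Write an experiment to the long-format CSV dialect (lossless).

    Floats are written with shortest-round-trip ``repr`` so that
    ``read_experiment(write_experiment(exp))`` reproduces ``exp`` exactly.
    If ``meta_path`` is given the material metadata sidecar is written too.
    """
    rows = []
    for b in exp.bottles:
        for t, y in zip(b.times, b.bod):
            rows.append((b.bottle_id, b.role.value, b.material_id, b.replicate, t, y))
    df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    df.to_csv(path, index=False)
    if meta_path is not None:
        mrows = [
            (
                m.material_id,
                m.label,
                m.mass_concentration,
                format_formula(m.formula) if m.formula else "",
            )
            for m in exp.materials
        ]
        pd.DataFrame(mrows, columns=list(META_COLUMNS)).to_csv(meta_path, index=False)
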