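"""Domain types and CSV I/O for serum aromatic-metabolite cohorts.

A cohort is a tidy per-sample table: subject metadata (cohort group, sampling
day, APACHE II score) plus, for each of eight aromatic acids, a concentration
measurement in µmol/L that may be left-censored at the analytical limit of
detection (LOD) or limit of quantitation (LOQ), and an optional relative
chromatographic peak area (analyte peak area over internal-standard peak
area, dimensionless).

Censored concentrations are stored as explicit statuses, never as sentinel
numbers; in CSV they appear as the literal tokens ``<LOD`` and ``<LOQ``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "Cohort",
    "CensorStatus",
    "CohortTable",
    "Measurement",
    "MetabolitePanel",
    "SampleRecord",
    "SchemaError",
    "ValidationError",
    "default_panel",
    "read_cohort",
    "write_cohort",
]

#: Canonical analyte order: phenylalanine metabolites first, then tyrosine
#: metabolites, p-HPhLA (3-(4-hydroxyphenyl)lactic acid) last.
ANALYTES: tuple[str, ...] = (
    "benzoic",
    "phenylpropionic",
    "phenyllactic",
    "p_hydroxybenzoic",
    "homovanillic",
    "p_hydroxyphenylacetic",
    "p_hydroxyphenylpropionic",
    "p_hphla",
)

BELOW_LOD_TOKEN = "<LOD"
BELOW_LOQ_TOKEN = "<LOQ"


class SchemaError(ValueError):
    """A required column is missing or the file layout is wrong."""


class ValidationError(ValueError):
    """A cell or record violates the cohort-table contract."""


class Cohort(str, enum.Enum):
    """Outcome group of a subject."""

    HEALTHY = "healthy"
    SURVIVOR = "survivor"
    NON_SURVIVOR = "non_survivor"


class CensorStatus(str, enum.Enum):
    QUANTIFIED = "quantified"
    BELOW_LOQ = "below_loq"
    BELOW_LOD = "below_lod"


@dataclass(frozen=True)
class Measurement:
    """One analyte concentration, possibly left-censored.

    ``value`` is present (µmol/L) only for quantified measurements; censored
    measurements carry no number — any numeric recovery is an explicit
    downstream imputation step.
    """

    status: CensorStatus
    value: float | None = None

    def __post_init__(self) -> None:
        if self.status is CensorStatus.QUANTIFIED:
            if self.value is None or self.value < 0:
                raise ValidationError(
                    "quantified measurement requires a nonnegative value"
                )
        elif self.value is not None:
            raise ValidationError(f"{self.status.value} measurement must not carry a value")

    @property
    def is_censored(self) -> bool:
        return self.status is not CensorStatus.QUANTIFIED


@dataclass(frozen=True)
class MetabolitePanel:
    """The eight-analyte panel with per-analyte censoring limits.

    ``lod`` entries may be ``None``: benzoic acid and p-HPhLA are ubiquitous
    in human serum, so a detection limit cannot be established for them and
    only the LOQ applies.  ``response_factor`` links concentration to relative
    peak area and is used only by the synthetic generator.
    """

    analytes: tuple[str, ...]
    lod: Mapping[str, float | None]
    loq: Mapping[str, float]
    response_factor: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.analytes) != 8:
            raise ValidationError("panel must contain exactly 8 analytes")
        if len(set(self.analytes)) != len(self.analytes):
            raise ValidationError("analyte names must be unique")
        for a in self.analytes:
            loq = self.loq[a]
            if loq <= 0:
                raise ValidationError(f"LOQ must be positive for {a}")
            lod = self.lod.get(a)
            if lod is not None and not 0 < lod < loq:
                raise ValidationError(f"LOD must satisfy 0 < LOD < LOQ for {a}")


def default_panel() -> MetabolitePanel:
    """The study panel with its published LOD/LOQ values (µmol/L)."""
    lod = {
        "benzoic": None,
        "phenylpropionic": 0.01,
        "phenyllactic": 0.4,
        "p_hydroxybenzoic": 0.2,
        "homovanillic": 0.1,
        "p_hydroxyphenylacetic": 0.1,
        "p_hydroxyphenylpropionic": 0.1,
        "p_hphla": None,
    }
    loq = {
        "benzoic": 0.7,
        "phenylpropionic": 0.59,
        "phenyllactic": 0.5,
        "p_hydroxybenzoic": 0.6,
        "homovanillic": 0.5,
        "p_hydroxyphenylacetic": 0.6,
        "p_hydroxyphenylpropionic": 0.5,
        "p_hphla": 0.5,
    }
    rf = {a: 1.0 for a in ANALYTES}
    return MetabolitePanel(analytes=ANALYTES, lod=lod, loq=loq, response_factor=rf)


@dataclass(frozen=True)
class SampleRecord:
    """One serum sample: metadata plus one Measurement per panel analyte.

    ``relative_areas`` holds the relative chromatographic peak area for each
    analyte whose peak exists in the chromatogram; analytes below the
    detection limit have no entry (``None``).
    """

    subject_id: str
    cohort: Cohort
    day: int
    measurements: Mapping[str, Measurement]
    relative_areas: Mapping[str, float | None] = field(default_factory=dict)
    apache2: int | None = None

    def __post_init__(self) -> None:
        if self.cohort is Cohort.HEALTHY:
            if self.day != 0:
                raise ValidationError(
                    f"healthy subject {self.subject_id}: day must be 0"
                )
            if self.apache2 is not None:
                raise ValidationError(
                    f"healthy subject {self.subject_id}: APACHE II must be absent"
                )
        for analyte, area in self.relative_areas.items():
            if area is not None and area < 0:
                raise ValidationError(
                    f"negative relative area for {analyte} in {self.subject_id}"
                )


@dataclass(frozen=True)
class CohortTable:
    """All samples of a study, in row order, plus the analyte panel."""

    panel: MetabolitePanel
    samples: tuple[SampleRecord, ...]

    def __post_init__(self) -> None:
        keys = set()
        healthy_subjects: dict[str, int] = {}
        for i, s in enumerate(self.samples):
            if set(s.measurements) != set(self.panel.analytes):
                raise ValidationError(
                    f"row {i}: measurements keyed by {sorted(s.measurements)}, "
                    f"expected the panel analytes"
                )
            key = (s.subject_id, s.day)
            if key in keys:
                raise ValidationError(f"row {i}: duplicate (subject_id, day) {key}")
            keys.add(key)
            if s.cohort is Cohort.HEALTHY:
                healthy_subjects[s.subject_id] = healthy_subjects.get(s.subject_id, 0) + 1
        for sid, n in healthy_subjects.items():
            if n != 1:
                raise ValidationError(f"healthy subject {sid} has {n} samples, expected 1")

    def __len__(self) -> int:
        return len(self.samples)

    # ---- convenience views -------------------------------------------------

    def indices(
        self, cohort: Cohort | None = None, day: int | None = None
    ) -> list[int]:
        """Row indices filtered by cohort group and/or sampling day."""
        out = []
        for i, s in enumerate(self.samples):
            if cohort is not None and s.cohort is not cohort:
                continue
            if day is not None and s.day != day:
                continue
            out.append(i)
        return out

    def n_subjects(self) -> int:
        return len({s.subject_id for s in self.samples})

    def area_matrix(
        self, rows: Sequence[int] | None = None, variables: Sequence[str] | None = None
    ) -> np.ndarray:
        """Relative-area matrix (samples x analytes).

        Analytes with no chromatographic peak (below the detection limit)
        contribute area 0 — the peak genuinely does not exist, so zero is the
        measured signal, not an imputation.
        """
        rows = range(len(self.samples)) if rows is None else rows
        variables = self.panel.analytes if variables is None else tuple(variables)
        X = np.zeros((len(list(rows)), len(variables)))
        for r, i in enumerate(rows):
            areas = self.samples[i].relative_areas
            for c, a in enumerate(variables):
                v = areas.get(a)
                X[r, c] = 0.0 if v is None else v
        return X

    def measurement_column(self, analyte: str, rows: Sequence[int] | None = None) -> list[Measurement]:
        rows = range(len(self.samples)) if rows is None else rows
        return [self.samples[i].measurements[analyte] for i in rows]


# ---- CSV I/O ---------------------------------------------------------------
#
# Dialect: comma-separated, dot decimal, UTF-8.  Columns: subject_id, cohort,
# day, apache2, conc_<analyte> x8, then optional area_<analyte> x8.  Censored
# concentrations appear as the literal tokens "<LOD" / "<LOQ"; absent apache2
# or areas as empty cells.


def _parse_measurement(cell: str, row: int, col: str) -> Measurement:
    cell = cell.strip()
    if cell == BELOW_LOD_TOKEN:
        return Measurement(CensorStatus.BELOW_LOD)
    if cell == BELOW_LOQ_TOKEN:
        return Measurement(CensorStatus.BELOW_LOQ)
    try:
        value = float(cell)
    except ValueError as exc:
        raise ValidationError(f"row {row}, column {col}: unparseable cell {cell!r}") from exc
    if value < 0:
        raise ValidationError(f"row {row}, column {col}: negative concentration {value}")
    return Measurement(CensorStatus.QUANTIFIED, value)


def read_cohort(path, panel: MetabolitePanel | None = None) -> CohortTable:
    """Read a cohort CSV, mapping censoring tokens to explicit statuses.

    Raises :class:`SchemaError` when a required column is missing and
    :class:`ValidationError` (with the offending row index) for bad cells.
    """
    panel = default_panel() if panel is None else panel
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["subject_id", "cohort", "day", "apache2"] + [
        f"conc_{a}" for a in panel.analytes
    ]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    area_cols = {a: f"area_{a}" for a in panel.analytes if f"area_{a}" in df.columns}

    samples = []
    for row, rec in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, rec))
        cohort_label = rec["cohort"].strip()
        try:
            cohort = Cohort(cohort_label)
        except ValueError as exc:
            raise ValidationError(
                f"row {row}: unknown cohort label {cohort_label!r}"
            ) from exc
        try:
            day = int(rec["day"])
        except ValueError as exc:
            raise ValidationError(f"row {row}: unparseable day {rec['day']!r}") from exc
        apache_cell = rec["apache2"].strip()
        apache2 = int(apache_cell) if apache_cell else None
        measurements = {
            a: _parse_measurement(rec[f"conc_{a}"], row, f"conc_{a}") for a in panel.analytes
        }
        areas: dict[str, float | None] = {}
        for a, col in area_cols.items():
            cell = rec[col].strip()
            areas[a] = float(cell) if cell else None
        samples.append(
            SampleRecord(
                subject_id=rec["subject_id"],
                cohort=cohort,
                day=day,
                apache2=apache2,
                measurements=measurements,
                relative_areas=areas,
            )
        )
    return CohortTable(panel=panel, samples=tuple(samples))


def _format_measurement(m: Measurement) -> str:
    if m.status is CensorStatus.BELOW_LOD:
        return BELOW_LOD_TOKEN
    if m.status is CensorStatus.BELOW_LOQ:
        return BELOW_LOQ_TOKEN
    return repr(m.value)


def write_cohort(table: CohortTable, path) -> None:
    """Write the dialect :func:`read_cohort` accepts; read∘write is identity."""
    panel = table.panel
    has_areas = any(s.relative_areas for s in table.samples) or not table.samples
    cols = ["subject_id", "cohort", "day", "apache2"]
    cols += [f"conc_{a}" for a in panel.analytes]
    if has_areas:
        cols += [f"area_{a}" for a in panel.analytes]
    rows = []
    for s in table.samples:
        row = {
            "subject_id": s.subject_id,
            "cohort": s.cohort.value,
            "day": str(s.day),
            "apache2": "" if s.apache2 is None else str(s.apache2),
        }
        for a in panel.analytes:
            row[f"conc_{a}"] = _format_measurement(s.measurements[a])
        if has_areas:
            for a in panel.analytes:
                v = s.relative_areas.get(a)
                row[f"area_{a}"] = "" if v is None else repr(v)
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
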