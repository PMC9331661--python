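"""Censoring imputation, autoscaling and the sample-selection workflow.

The modelled (target) class is "healthy volunteers + survivors".  Before the
one-class model is fitted, survivor admission samples are screened for
atypically high concentrations; a flagged admission sample is replaced by the
patient's earliest clean later-day sample, and patients with no clean sample
are excluded.  Every sample ends up in exactly one of six named groups:
calibration, test, survivors (outliers), survivors (others), non-survivors
(admission day) and non-survivors (others).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import CensorStatus, Cohort, CohortTable, Measurement

__all__ = [
    "ScalingParams",
    "SplitAssignment",
    "assign_groups",
    "autoscale",
    "impute_half_min",
    "imputed_concentration_matrix",
    "screen_outliers",
    "unscale",
]


@dataclass(frozen=True)
class ScalingParams:
    """Column means and (n-1)-denominator standard deviations for autoscaling."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sd <= 0):
            raise ValueError("all scaling standard deviations must be positive")


def autoscale(
    X: np.ndarray, params: ScalingParams | None = None
) -> tuple[np.ndarray, ScalingParams]:
    """Center to mean 0 and scale to unit sample standard deviation.

    When ``params`` is given (test or new data) the *calibration* scaling is
    applied unchanged — new data never re-fits the scaling.
    """
    X = np.asarray(X, dtype=float)
    if params is None:
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit scaling parameters")
        sd = X.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(f"zero-variance column(s) {bad.tolist()}: cannot autoscale")
        params = ScalingParams(mean=X.mean(axis=0), sd=sd)
    return (X - params.mean) / params.sd, params


def unscale(X_scaled: np.ndarray, params: ScalingParams) -> np.ndarray:
    return np.asarray(X_scaled, dtype=float) * params.sd + params.mean


def impute_half_min(values: Sequence[Measurement | float | None]) -> np.ndarray:
    """Replace censored entries by half the minimum of the quantified values.

    Below-LOQ entries follow the same rule as below-LOD entries: no separate
    treatment of the LOD–LOQ band is defined for the summary statistics, and
    one rule keeps them reproducible.
    """
    numeric: list[float | None] = []
    for v in values:
        if isinstance(v, Measurement):
            numeric.append(v.value if v.status is CensorStatus.QUANTIFIED else None)
        else:
            numeric.append(None if v is None else float(v))
    present = [v for v in numeric if v is not None]
    if not present:
        raise ValueError("all values censored: no minimum exists to impute from")
    fill = min(present) / 2.0
    return np.array([fill if v is None else v for v in numeric], dtype=float)


def imputed_concentration_matrix(
    table: CohortTable, rows: Sequence[int] | None = None,
    variables: Sequence[str] | None = None,
) -> np.ndarray:
    """Per-analyte half-minimum-imputed concentration matrix (samples x analytes).

    The imputation minimum is taken over the *whole* table for each analyte,
    so subsetted rows are imputed consistently with the full cohort.
    """
    variables = table.panel.analytes if variables is None else tuple(variables)
    full = np.column_stack(
        [impute_half_min(table.measurement_column(a)) for a in variables]
    )
    return full if rows is None else full[list(rows)]


def screen_outliers(
    table: CohortTable,
    rows: Sequence[int] | None = None,
    gamma: float = 0.01,
    n_components: int = 3,
    fence: float = 3.0,
) -> np.ndarray:
    """Flag samples whose concentrations are atypically high.

    A sample is an outlier if either screen fires:

    * univariate — any analyte concentration above ``q3 + fence x IQR`` of the
      pooled healthy + survivor distribution (extreme-outlier fence, default
      3 IQR);
    * multivariate — full distance from a one-class model of the pooled
      healthy + survivor relative areas beyond the outer (outlier) cutoff at
      Bonferroni-corrected significance ``gamma / n``.

    ``rows`` defaults to all survivor samples.  Returns a boolean flag per
    screened row, aligned with ``rows``.
    """
    from . import simca  # local import: simca depends on this module's autoscale

    if rows is None:
        rows = table.indices(cohort=Cohort.SURVIVOR)
    rows = list(rows)
    pool = table.indices(cohort=Cohort.HEALTHY) + table.indices(cohort=Cohort.SURVIVOR)
    if len(pool) < 8:
        raise ValueError("need at least 8 healthy+survivor samples to screen outliers")

    # analytes never quantified anywhere cannot be fenced or imputed; skip them
    usable = [
        a for a in table.panel.analytes
        if any(m.status is CensorStatus.QUANTIFIED for m in table.measurement_column(a))
    ]
    conc_pool = imputed_concentration_matrix(table, pool, usable)
    q1 = np.percentile(conc_pool, 25, axis=0)
    q3 = np.percentile(conc_pool, 75, axis=0)
    iqr = q3 - q1
    if np.all(iqr == 0) and np.all(conc_pool == conc_pool[0]):
        warnings.warn("degenerate pool: all samples identical, no outliers flagged")
        return np.zeros(len(rows), dtype=bool)
    upper = q3 + fence * iqr
    conc_rows = imputed_concentration_matrix(table, rows, usable)
    uni_flag = np.any(conc_rows > upper, axis=1)

    # Multivariate screen on the relative-area matrix of the pool.
    X_pool = table.area_matrix(pool)
    keep = np.flatnonzero(X_pool.std(axis=0, ddof=1) > 0)
    multi_flag = np.zeros(len(rows), dtype=bool)
    if keep.size >= 2:
        A = min(n_components, keep.size - 1, len(pool) - 1)
        try:
            model = simca.fit_simca(
                X_pool[:, keep], n_components=A, alpha=gamma,
                variables=[table.panel.analytes[j] for j in keep],
            )
            f_out = simca.outlier_cutoff(model.dist, gamma, len(pool))
            _, f = simca.classify(model, table.area_matrix(rows)[:, keep])
            multi_flag = f > f_out
        except ValueError:  # degenerate distance distribution
            pass

    return uni_flag | multi_flag


@dataclass(frozen=True)
class SplitAssignment:
    """The six disjoint, exhaustive sample groups of the modelling workflow."""

    calibration: tuple[int, ...]
    test: tuple[int, ...]
    survivors_outliers: tuple[int, ...]
    survivors_others: tuple[int, ...]
    non_survivors: tuple[int, ...]
    non_survivors_others: tuple[int, ...]

    def __post_init__(self) -> None:
        groups = [
            self.calibration, self.test, self.survivors_outliers,
            self.survivors_others, self.non_survivors, self.non_survivors_others,
        ]
        flat = [i for g in groups for i in g]
        if len(flat) != len(set(flat)):
            raise ValueError("groups are not pairwise disjoint")

    @property
    def modeled(self) -> tuple[int, ...]:
        """Target-class rows (calibration + test)."""
        return tuple(self.calibration) + tuple(self.test)

    def covers(self, n: int) -> bool:
        flat = set(self.modeled) | set(self.survivors_outliers) | set(
            self.survivors_others
        ) | set(self.non_survivors) | set(self.non_survivors_others)
        return flat == set(range(n))

    def to_dict(self) -> dict[str, list[int]]:
        return {
            "calibration": list(self.calibration),
            "test": list(self.test),
            "survivors_outliers": list(self.survivors_outliers),
            "survivors_others": list(self.survivors_others),
            "non_survivors": list(self.non_survivors),
            "non_survivors_others": list(self.non_survivors_others),
        }


def assign_groups(
    table: CohortTable,
    flags: Mapping[int, bool],
    split: tuple[Sequence[int], Sequence[int]] | None = None,
) -> SplitAssignment:
    """Run the sample-replacement workflow and partition all samples.

    ``flags`` maps survivor sample row -> outlier flag (rows absent from the
    mapping are treated as clean).  Per survivor patient, the admission
    (day-0) sample is chosen; if flagged, the earliest non-flagged later-day
    sample replaces it and the skipped flagged samples join the outlier
    group; if no clean sample exists the patient is excluded and all its
    flagged samples join the outlier group.  When the chosen sample is clean
    the patient's remaining samples are *not* screened and become
    "survivors (others)".

    ``split`` optionally provides (calibration rows, test rows) covering the
    modelled class; without it the whole modelled class is placed in
    ``calibration`` pending a later representative split.
    """
    modeled: list[int] = list(table.indices(cohort=Cohort.HEALTHY))
    surv_outliers: list[int] = []
    surv_others: list[int] = []

    by_patient: dict[str, list[int]] = {}
    for i in table.indices(cohort=Cohort.SURVIVOR):
        by_patient.setdefault(table.samples[i].subject_id, []).append(i)

    for sid in sorted(by_patient):
        rows = sorted(by_patient[sid], key=lambda i: table.samples[i].day)
        chosen = None
        skipped_flagged: list[int] = []
        for i in rows:
            if flags.get(i, False):
                skipped_flagged.append(i)
            else:
                chosen = i
                break
        if chosen is None:  # only one sample, or every sample an outlier
            surv_outliers.extend(rows)
            continue
        modeled.append(chosen)
        surv_outliers.extend(skipped_flagged)
        surv_others.extend(i for i in rows if i != chosen and i not in skipped_flagged)

    non_surv = table.indices(cohort=Cohort.NON_SURVIVOR, day=0)
    non_surv_others = [
        i for i in table.indices(cohort=Cohort.NON_SURVIVOR) if table.samples[i].day != 0
    ]

    if split is None:
        calibration, test = tuple(modeled), ()
    else:
        calibration, test = tuple(split[0]), tuple(split[1])
        if set(calibration) | set(test) != set(modeled):
            raise ValueError("split does not cover the modelled class exactly")

    assignment = SplitAssignment(
        calibration=calibration,
        test=tuple(test),
        survivors_outliers=tuple(surv_outliers),
        survivors_others=tuple(surv_others),
        non_survivors=tuple(non_surv),
        non_survivors_others=tuple(non_surv_others),
    )
    assert assignment.covers(len(table)), "six groups must partition the cohort"
    return assignment
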