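"""Synthetic cohort generator for censored serum aromatic-acid panels.

The study data were never deposited, so every downstream stage is exercised
on cohorts generated to mimic the published summary structure: three groups
(healthy volunteers, ICU survivors, ICU non-survivors) with right-skewed
positive concentrations matched to published median/IQR values, per-analyte
zero-inflation reproducing the observed detection occurrence, left-censoring
at the analytical LOD/LOQ, a longitudinal repeat-sampling pattern, integer
APACHE II severity scores, and injectable high-concentration outliers.

Model
-----
For each group and analyte the concentration *conditional on the analyte
being present* follows a log-normal law fitted by quantile matching to the
(median, q1, q3) triple; with probability ``1 - detection_fraction`` the
analyte is absent altogether (zero inflation), which reproduces the widely
differing detection occurrences without a mechanistic model.  Analytes are
drawn independently — no between-analyte correlation structure is published.

Repeat samples from the same patient share a subject-level log-scale shift
(sd 0.2), giving within-subject correlation over days.  Relative peak areas
are concentration x response_factor x multiplicative log-normal noise (5%),
present whenever the analyte's peak exists; areas are deliberately never
truncated at the top of a calibration range.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import (
    ANALYTES,
    CensorStatus,
    Cohort,
    CohortTable,
    Measurement,
    MetabolitePanel,
    SampleRecord,
    default_panel,
)

__all__ = [
    "CohortConfig",
    "ConfigError",
    "GroupDistribution",
    "default_distributions",
    "generate_cohort",
    "inject_outliers",
    "lognormal_params",
]

_Z75 = float(stats.norm.ppf(0.75))


class ConfigError(ValueError):
    """Infeasible generator configuration."""


def lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) matched to a (median, q1, q3) triple.

    mu = ln(median); sigma = ln(q3/q1) / (2 z_{0.75}).  The fitted law
    reproduces the median and the quartile ratio q3/q1 exactly; the
    individual quartiles are reproduced exactly when the triple is
    log-symmetric (median = sqrt(q1 q3)) and to within a few percent for the
    mildly asymmetric published triples.  Degenerate q1 = median = q3 gives
    sigma = 0, a point mass.
    """
    if not (0 < q1 <= median <= q3):
        raise ValueError(
            f"quantiles must satisfy 0 < q1 <= median <= q3, got ({median}, {q1}, {q3})"
        )
    mu = float(np.log(median))
    sigma = float(np.log(q3 / q1) / (2.0 * _Z75))
    return mu, sigma


@dataclass(frozen=True)
class GroupDistribution:
    """Published summary structure of one cohort group.

    ``concentration``: per-analyte (median, q1, q3) in µmol/L of the latent
    concentration *given the analyte is present*; ``detection_fraction``:
    per-analyte fraction of samples in which the analyte is detected at all;
    ``apache2``: (median, q1, q3) of the severity score, or None for healthy
    volunteers.
    """

    concentration: Mapping[str, tuple[float, float, float]]
    detection_fraction: Mapping[str, float]
    apache2: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        for a, (m, q1, q3) in self.concentration.items():
            if not (0 < q1 <= m <= q3):
                raise ValueError(f"{a}: quantiles disordered ({m}, {q1}, {q3})")
        for a, f in self.detection_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{a}: detection fraction {f} outside [0, 1]")


def default_distributions() -> dict[Cohort, GroupDistribution]:
    """Group distributions reproducing the published cohort summaries.

    Numeric medians/IQRs are the published per-group values (µmol/L);
    detection fractions are the published per-group detection counts over the
    group size.  For analytes whose published quantiles are censored
    ("<LOD"/"<LOQ") the latent conditional-on-detection quantiles are
    synthetic choices placed in or near the LOD–LOQ band, so that after
    censoring the generated tables show the same censored quantile pattern.
    """
    healthy = GroupDistribution(
        concentration={
            "benzoic": (1.3, 0.8, 1.8),
            "phenylpropionic": (0.45, 0.25, 0.73),
            "phenyllactic": (0.7, 0.5, 0.85),
            "p_hydroxybenzoic": (0.3, 0.2, 0.45),
            "homovanillic": (0.3, 0.2, 0.5),
            "p_hydroxyphenylacetic": (0.4, 0.25, 0.55),
            "p_hydroxyphenylpropionic": (0.3, 0.2, 0.45),
            "p_hphla": (2.1, 1.6, 2.6),
        },
        detection_fraction={
            "benzoic": 1.0,
            "phenylpropionic": 37 / 52,
            "phenyllactic": 34 / 52,
            "p_hydroxybenzoic": 0.0,
            "homovanillic": 1 / 52,
            "p_hydroxyphenylacetic": 28 / 52,
            "p_hydroxyphenylpropionic": 0.0,
            "p_hphla": 1.0,
        },
        apache2=None,
    )
    survivor = GroupDistribution(
        concentration={
            "benzoic": (1.9, 1.2, 2.7),
            "phenylpropionic": (0.35, 0.2, 0.55),
            "phenyllactic": (1.2, 0.7, 1.7),
            "p_hydroxybenzoic": (0.45, 0.3, 0.65),
            "homovanillic": (0.45, 0.3, 0.7),
            "p_hydroxyphenylacetic": (0.9, 0.5, 1.9),
            "p_hydroxyphenylpropionic": (0.35, 0.2, 0.5),
            "p_hphla": (2.9, 2.2, 3.4),
        },
        detection_fraction={
            "benzoic": 1.0,
            "phenylpropionic": 19 / 44,
            "phenyllactic": 32 / 44,
            "p_hydroxybenzoic": 4 / 44,
            "homovanillic": 9 / 44,
            "p_hydroxyphenylacetic": 32 / 44,
            "p_hydroxyphenylpropionic": 2 / 44,
            "p_hphla": 43 / 44,
        },
        apache2=(7.0, 5.0, 11.0),
    )
    non_survivor = GroupDistribution(
        concentration={
            "benzoic": (2.5, 1.5, 5.1),
            "phenylpropionic": (0.4, 0.2, 0.6),
            "phenyllactic": (4.0, 2.5, 7.0),
            "p_hydroxybenzoic": (1.0, 0.5, 1.9),
            "homovanillic": (2.2, 0.8, 6.3),
            "p_hydroxyphenylacetic": (9.6, 2.8, 18.5),
            "p_hydroxyphenylpropionic": (0.4, 0.25, 0.6),
            "p_hphla": (14.8, 6.5, 32.6),
        },
        detection_fraction={
            "benzoic": 1.0,
            "phenylpropionic": 16 / 35,
            "phenyllactic": 1.0,
            "p_hydroxybenzoic": 20 / 35,
            "homovanillic": 26 / 35,
            "p_hydroxyphenylacetic": 33 / 35,
            "p_hydroxyphenylpropionic": 9 / 35,
            "p_hphla": 1.0,
        },
        apache2=(20.0, 16.0, 26.0),
    )
    return {
        Cohort.HEALTHY: healthy,
        Cohort.SURVIVOR: survivor,
        Cohort.NON_SURVIVOR: non_survivor,
    }


@dataclass(frozen=True)
class CohortConfig:
    """Population sizes and sampling pattern of a generated cohort.

    Defaults reproduce the study population: 52 healthy volunteers with one
    sample each and 79 ICU patients (44 survivors, 35 non-survivors) of whom
    28 contribute 2 samples, 9 contribute 3, 5 contribute 4 and 1 contributes
    5 — 196 samples from 131 subjects in total.
    """

    n_healthy: int = 52
    n_survivors: int = 44
    n_nonsurvivors: int = 35
    longitudinal: Mapping[int, int] = field(
        default_factory=lambda: {2: 28, 3: 9, 4: 5, 5: 1}
    )
    outlier_rate: float = 0.0
    outlier_multiplier: float = 20.0
    subject_effect_sd: float = 0.2
    area_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_healthy, self.n_survivors, self.n_nonsurvivors) < 0:
            raise ConfigError("group sizes must be nonnegative")
        n_patients = self.n_survivors + self.n_nonsurvivors
        n_multi = sum(self.longitudinal.values())
        if n_multi > n_patients:
            raise ConfigError(
                f"longitudinal pattern needs {n_multi} patients, only {n_patients} exist"
            )
        if any(k < 2 for k in self.longitudinal):
            raise ConfigError("longitudinal keys are samples-per-patient, must be >= 2")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ConfigError("outlier_rate must lie in [0, 1]")


def _apache_draw(rng: np.random.Generator, triple: tuple[float, float, float]) -> int:
    mu, sigma = lognormal_params(*triple)
    score = int(round(float(rng.lognormal(mu, sigma))))
    return int(np.clip(score, 0, 71))  # the scale's range


def _draw_sample(
    rng: np.random.Generator,
    panel: MetabolitePanel,
    dist: GroupDistribution,
    subject_shift: float,
    area_noise_sd: float,
) -> tuple[dict[str, Measurement], dict[str, float | None]]:
    measurements: dict[str, Measurement] = {}
    areas: dict[str, float | None] = {}
    for a in panel.analytes:
        detected = rng.random() < dist.detection_fraction[a]
        mu, sigma = lognormal_params(*dist.concentration[a])
        conc = float(rng.lognormal(mu + subject_shift, sigma)) if detected else 0.0
        lod = panel.lod.get(a)
        if not detected or (lod is not None and conc < lod):
            # no chromatographic peak: censored at LOD, no area
            measurements[a] = Measurement(CensorStatus.BELOW_LOD)
            areas[a] = None
            continue
        area = conc * panel.response_factor[a] * float(rng.lognormal(0.0, area_noise_sd))
        areas[a] = area
        if conc < panel.loq[a]:
            measurements[a] = Measurement(CensorStatus.BELOW_LOQ)
        else:
            measurements[a] = Measurement(CensorStatus.QUANTIFIED, conc)
    return measurements, areas


def generate_cohort(
    config: CohortConfig | None = None,
    distributions: Mapping[Cohort, GroupDistribution] | None = None,
    panel: MetabolitePanel | None = None,
) -> CohortTable:
    """Generate a cohort table; deterministic for a fixed (config, seed).

    Healthy volunteers contribute one day-0 sample each.  Every patient
    contributes a day-0 (admission) sample; patients selected for the
    longitudinal pattern contribute further samples on later days, drawn from
    the same group law with the subject's log-scale shift.
    """
    config = CohortConfig() if config is None else config
    distributions = default_distributions() if distributions is None else distributions
    panel = default_panel() if panel is None else panel
    rng = np.random.default_rng(config.seed)

    samples: list[SampleRecord] = []

    for i in range(config.n_healthy):
        m, ar = _draw_sample(
            rng, panel, distributions[Cohort.HEALTHY], 0.0, config.area_noise_sd,
        )
        samples.append(
            SampleRecord(
                subject_id=f"H{i + 1:03d}", cohort=Cohort.HEALTHY, day=0,
                measurements=m, relative_areas=ar, apache2=None,
            )
        )

    patients = [(f"S{i + 1:03d}", Cohort.SURVIVOR) for i in range(config.n_survivors)]
    patients += [(f"N{i + 1:03d}", Cohort.NON_SURVIVOR) for i in range(config.n_nonsurvivors)]

    # Assign the repeat-sampling pattern across the whole patient pool.
    n_samples_per_patient = {sid: 1 for sid, _ in patients}
    order = rng.permutation(len(patients))
    slots = []
    for k, count in sorted(config.longitudinal.items()):
        slots += [k] * count
    for pos, k in zip(order, slots):
        n_samples_per_patient[patients[pos][0]] = k

    for sid, cohort in patients:
        dist = distributions[cohort]
        shift = float(rng.normal(0.0, config.subject_effect_sd))
        apache2 = _apache_draw(rng, dist.apache2) if dist.apache2 is not None else None
        n_k = n_samples_per_patient[sid]
        extra_days = sorted(rng.choice(np.arange(2, 15), size=n_k - 1, replace=False)) if n_k > 1 else []
        for day in [0, *map(int, extra_days)]:
            # admission-day samples follow the group law exactly; the
            # subject-level shift models within-patient correlation of repeats
            m, ar = _draw_sample(rng, panel, dist, shift if day > 0 else 0.0,
                                 config.area_noise_sd)
            samples.append(
                SampleRecord(
                    subject_id=sid, cohort=cohort, day=day,
                    measurements=m, relative_areas=ar, apache2=apache2,
                )
            )

    table = CohortTable(panel=panel, samples=tuple(samples))
    if config.outlier_rate > 0:
        table, _ = inject_outliers(
            table, config.outlier_rate, config.outlier_multiplier, seed=config.seed + 1
        )
    return table


def inject_outliers(
    table: CohortTable, rate: float, multiplier: float, seed: int
) -> tuple[CohortTable, list[int]]:
    """Multiply one random analyte of selected survivor samples by ``multiplier``.

    Exactly ``round(rate x n_survivor_samples)`` survivor samples are altered;
    the altered row indices are returned as ground truth for outlier-recovery
    tests.  The boosted analyte is chosen among the sample's quantified
    analytes so the result is an unambiguous, atypically high concentration.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if multiplier <= 1.0:
        raise ValueError("multiplier must exceed 1")
    survivor_rows = table.indices(cohort=Cohort.SURVIVOR)
    n_alter = int(round(rate * len(survivor_rows)))
    if n_alter == 0:
        return table, []
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(survivor_rows, size=n_alter, replace=False).tolist())

    new_samples = list(table.samples)
    for idx in chosen:
        s = new_samples[idx]
        quantified = [
            a for a in table.panel.analytes
            if s.measurements[a].status is CensorStatus.QUANTIFIED
        ]
        analyte = str(rng.choice(quantified))
        old = s.measurements[analyte]
        new_meas = dict(s.measurements)
        new_meas[analyte] = Measurement(CensorStatus.QUANTIFIED, old.value * multiplier)
        new_areas = dict(s.relative_areas)
        if new_areas.get(analyte) is not None:
            new_areas[analyte] = new_areas[analyte] * multiplier
        new_samples[idx] = replace(s, measurements=new_meas, relative_areas=new_areas)
    return CohortTable(panel=table.panel, samples=tuple(new_samples)), chosen
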