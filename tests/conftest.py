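import numpy as np
import pytest

from aromet.cohort import (
    ANALYTES,
    CensorStatus,
    Cohort,
    CohortTable,
    Measurement,
    SampleRecord,
    default_panel,
)


def make_sample(subject_id, cohort, day=0, apache2=None, conc=None, areas=None):
    """Build a SampleRecord with quantified defaults, overridable per analyte.

    ``conc`` maps analyte -> float (quantified), "<LOD" or "<LOQ".
    """
    conc = conc or {}
    areas = areas or {}
    measurements = {}
    rel_areas = {}
    for j, a in enumerate(ANALYTES):
        v = conc.get(a, 1.0 + 0.1 * j)
        if v == "<LOD":
            measurements[a] = Measurement(CensorStatus.BELOW_LOD)
            rel_areas[a] = None
        elif v == "<LOQ":
            measurements[a] = Measurement(CensorStatus.BELOW_LOQ)
            rel_areas[a] = areas.get(a, 0.3)
        else:
            measurements[a] = Measurement(CensorStatus.QUANTIFIED, float(v))
            rel_areas[a] = areas.get(a, float(v))
    return SampleRecord(
        subject_id=subject_id,
        cohort=Cohort(cohort),
        day=day,
        apache2=apache2,
        measurements=measurements,
        relative_areas=rel_areas,
    )


@pytest.fixture
def panel():
    return default_panel()


@pytest.fixture
def small_table(panel):
    """Three hand-built samples, one per cohort group."""
    samples = (
        make_sample("H001", "healthy"),
        make_sample("S001", "survivor", apache2=7, conc={"phenylpropionic": "<LOQ"}),
        make_sample("N001", "non_survivor", apache2=21, conc={"homovanillic": "<LOD"}),
    )
    return CohortTable(panel=panel, samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
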