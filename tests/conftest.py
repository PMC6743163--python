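import numpy as np
import pandas as pd
import pytest

from metcal import (
    ActivityProfile,
    BmrReferenceTable,
    Participant,
)
from metcal.simulate import GeneratorConfig, generate_validation_cohort


@pytest.fixture(scope="session")
def bmr_table() -> BmrReferenceTable:
    return BmrReferenceTable.default()


@pytest.fixture(scope="session")
def worked_participant() -> Participant:
    """53 kg, 158 cm, 45-year-old woman used in the worked examples."""
    return Participant(id="worked", age=45, weight=53.0, height=158.0)


@pytest.fixture(scope="session")
def worked_profile() -> ActivityProfile:
    """Median-like questionnaire answers: sleep 7.2 h/day, work hours
    (13.9, 12.1, 11.4, 1.1) h/week, 36 min moderate + 7.4 min vigorous."""
    return ActivityProfile(
        sleep_hours_per_day=7.2,
        work_hours=(13.9, 12.1, 11.4, 1.1),
        offduty_hours=(0.6, 7.4 / 60.0, 0.0),
    )


@pytest.fixture(scope="session")
def random_cohort():
    """100 seeded validation records covering a realistic input range."""
    cfg = GeneratorConfig.validation_default(n=100, seed=424242)
    return generate_validation_cohort(cfg)
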