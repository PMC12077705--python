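import datetime as dt

import pytest
from hypothesis import settings

from ehrpfs.lexicon import default_lexicon
from ehrpfs.synthetic import GeneratorConfig, generate_cohort

settings.register_profile("ci", max_examples=50, deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient synthetic cohort with ground truth."""
    return generate_cohort(GeneratorConfig(n_patients=12, seed=7))


def make_date(day: int) -> dt.date:
    """Day-offset helper: day 0 = 2010-01-01."""
    return dt.date(2010, 1, 1) + dt.timedelta(days=day)
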