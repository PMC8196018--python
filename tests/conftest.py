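import numpy as np
import pytest

from atnpower import generate_cohort, paper_calibrated
from atnpower.enrichment import subject_summary
from atnpower.pipeline import analysis_frame


@pytest.fixture(scope="session")
def preset_cohort():
    """One calibrated cohort shared across read-only tests."""
    return generate_cohort(paper_calibrated(seed=11))


@pytest.fixture(scope="session")
def preset_analysis(preset_cohort):
    """(long modeling frame, scalers, subject summary) for the shared cohort."""
    frame, scalers = analysis_frame(preset_cohort)
    return frame, scalers, subject_summary(frame)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
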