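"""Shared fixtures.

The expensive hierarchical fit is session-scoped and reused by the
shrinkage, convergence and recovery tests.
"""

import numpy as np
import pytest

from lossaversion.hba_fit import fit_hba
from lossaversion.synthetic_data import CohortSpec, generate_cohort
from lossaversion.task_design import assemble_task


@pytest.fixture(scope="session")
def task0():
    return assemble_task(0)


@pytest.fixture(scope="session")
def cohort7(task0):
    """The default 25-subject synthetic cohort (seed 7), with ROI BOLD."""
    return generate_cohort(CohortSpec(seed=7), task=task0, with_bold=True,
                           bold_noise_sd=0.5)


@pytest.fixture(scope="session")
def full_fit(cohort7):
    """Single-risk-attitude hierarchical fit at default chain settings."""
    return fit_hba(cohort7.choices, seed=1)


@pytest.fixture(scope="session")
def tiny_choices(task0, cohort7):
    """One subject's choices, for MLE and likelihood unit tests."""
    return cohort7.choices.for_subject(cohort7.subject_ids[0])
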