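import io
import warnings

import numpy as np
import pytest

from serostack.cohort import assign_time_groups, read_cohort, stratified_split
from serostack.learners import CVPlan, load_search_spaces
from serostack.simulate import MarkerEffect, SimulationConfig, simulate_cohort

# sklearn convergence chatter is irrelevant to the properties under test
warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)

TOY_CSV = """subject_id,sample_id,status,ytd_months,age,hrt,ocp,diabetes,CA19-9,MUC16
A1,A1-0,1,11,64.0,no,yes,no,34.2,low
A2,A2-0,1,25.5,58.5,yes,no,yes,120.0,18.0
B1,B1-0,0,,61.2,no,no,no,9.1,12.5
"""


@pytest.fixture
def toy_cohort():
    return read_cohort(io.StringIO(TOY_CSV))


@pytest.fixture(scope="session")
def fast_spaces():
    return load_search_spaces(profile="fast")


@pytest.fixture(scope="session")
def fast_plan():
    return CVPlan(n_folds=5, n_repeats=1, seed=11)


def small_config(seed=0, **kw):
    """A desk-scale cohort configuration used across tests."""
    defaults = dict(n_cases=60, n_controls=100, n_markers=12,
                    longitudinal_fraction=0.2, seed=seed)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def persistent_effects(n=5, delta=1.5, names=None):
    """Markers whose case shift does not decay with time to diagnosis."""
    names = names or [f"M{i:03d}" for i in range(1, n + 1)]
    return tuple(MarkerEffect(nm, delta, 50.0) for nm in names[:n])


@pytest.fixture(scope="session")
def informative_split():
    """A grouped, train/test-split cohort with strong persistent signal."""
    cfg = SimulationConfig(
        n_cases=120, n_controls=280, n_markers=20,
        effects=persistent_effects(5, 1.5), seed=101,
    )
    cohort = assign_time_groups(simulate_cohort(cfg))
    part = stratified_split(cohort, seed=102)
    train = cohort.subset((part == "train").to_numpy())
    test = cohort.subset((part == "test").to_numpy())
    return cohort, train, test


@pytest.fixture(scope="session")
def null_split():
    """Same structure, no marker or covariate effects."""
    cfg = SimulationConfig(n_cases=120, n_controls=280, n_markers=20, seed=201).null()
    cohort = assign_time_groups(simulate_cohort(cfg))
    part = stratified_split(cohort, seed=202)
    train = cohort.subset((part == "train").to_numpy())
    test = cohort.subset((part == "test").to_numpy())
    return cohort, train, test
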