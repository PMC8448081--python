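import numpy as np
import pandas as pd
import pytest

from dualchange import scales as sc
from dualchange import synthetic as sy
from dualchange.pipeline import wide_from_long


@pytest.fixture(scope="session")
def scales():
    return sc.default_scales()


@pytest.fixture(scope="session")
def outcome_defs():
    return sc.outcome_scales()


@pytest.fixture(scope="session")
def default_cohort_wide():
    """Moderate default cohort, wide format, shared across tests."""
    result = sy.generate_cohort(sy.SimulationConfig(n_participants=500, seed=20240901))
    return wide_from_long(result.data)


def null_config(n=89, seed=0, r=0.0):
    """Cohort config with zero true change and given pre/post correlation."""
    return sy.SimulationConfig(
        n_participants=n,
        true_change=0.0,
        post_sds=sy.DEFAULT_PRE_SDS,
        pre_post_correlation=r,
        student_shift_sd=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_wide(pre: dict, post: dict, cohort=None) -> pd.DataFrame:
    """Small wide frame from per-outcome score lists."""
    n = len(next(iter(pre.values())))
    df = pd.DataFrame({"participant_id": [f"P{i}" for i in range(n)]})
    if cohort is not None:
        df["cohort"] = cohort
    for o in sc.OUTCOMES:
        df[f"pre_{o}"] = pre[o]
        df[f"post_{o}"] = post[o]
    return df
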