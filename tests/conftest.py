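import numpy as np
import pandas as pd
import pytest

from looktimes import GeneratorConfig, build_contrast_scheme, simulate_experiment


@pytest.fixture(scope="session")
def single_scheme():
    return build_contrast_scheme("single_experiment")


@pytest.fixture(scope="session")
def aggregate_scheme():
    return build_contrast_scheme("aggregate")


@pytest.fixture(scope="session")
def study_trials():
    """One synthetic brightness experiment at the study's size (48 subjects)."""
    return simulate_experiment(GeneratorConfig(seed=20210919))


@pytest.fixture(scope="session")
def censored_heavy_trials():
    """High-mean scenario with substantial ceiling censoring in 2-Change cells."""
    beta = dict(GeneratorConfig().beta)
    beta["(Intercept)"] = 3.8
    return simulate_experiment(GeneratorConfig(beta=beta, seed=77))


def make_trials(values_by_cell, fam=30.0):
    """Hand-build a tiny validated trial table.

    ``values_by_cell``: list of (subject_id, condition, first_test,
    {trial_type: looking_s}) entries.
    """
    rows = []
    for sid, cond, ft, vals in values_by_cell:
        order = (("one_change", "two_change") if ft == "one_change_first"
                 else ("two_change", "one_change"))
        for idx, tt in enumerate(order, start=1):
            v = vals[tt]
            rows.append(dict(
                subject_id=sid, experiment="brightness", condition=cond,
                familiarization_group="small", first_test=ft, trial_type=tt,
                trial_index=idx, familiarization_looking_s=fam,
                looking_s=v, censored=bool(np.isclose(v, 60.0)),
            ))
    return pd.DataFrame(rows)
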