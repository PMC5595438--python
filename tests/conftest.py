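import numpy as np
import pandas as pd
import pytest

from lifecal import SimulationSpec, simulate_dataset
from lifecal.turning_points import TABLE_COLUMNS, TTTPTable


def make_table(ages, delta_e=None, feature_ids=None, species="human",
               age_unit="year", n_simple=0) -> TTTPTable:
    """Turning-point table straight from arrays (optionally padded with
    simple features), for exercising scoring/enrichment in isolation."""
    ages = np.asarray(ages, dtype=float)
    n = len(ages)
    if delta_e is None:
        delta_e = np.ones(n)
    delta_e = np.asarray(delta_e, dtype=float)
    if feature_ids is None:
        feature_ids = [f"g{i + 1:05d}" for i in range(n + n_simple)]
    age_full = np.r_[ages, np.full(n_simple, np.nan)]
    de_full = np.r_[delta_e, np.full(n_simple, np.nan)]
    table = pd.DataFrame({
        "feature_id": feature_ids,
        "age": age_full,
        "age_rounded": np.round(age_full),
        "delta_e": de_full,
        "pre_direction": np.where(np.isnan(age_full), "",
                                  np.where(de_full >= 0, "upward", "downward")),
        "post_class": np.where(np.isnan(age_full), "simple", "unclassified"),
        "p_pre": np.nan, "p_post": np.nan, "q_pre": np.nan, "q_post": np.nan,
    }, columns=TABLE_COLUMNS)
    return TTTPTable(table, species=species, age_unit=age_unit)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort reused across module tests."""
    spec = SimulationSpec(seed=11, n_samples=120, n_genes=80, fraction_simple=0.4)
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def cohort_ds(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def cohort_truth(small_cohort):
    return small_cohort[1]
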