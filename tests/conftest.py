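"""Shared fixtures: one small synthetic cohort processed end to end."""

import numpy as np
import pandas as pd
import pytest

from metabosig import simcohort, preprocess, splits


@pytest.fixture(scope="session")
def small_spec():
    return simcohort.CohortSpec(
        n_subjects=80, n_features=300, n_planted=30, planted_log2fc=2.0,
        case_prevalence=0.3, planted_frac_up=0.5, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    meta = simcohort.generate_cohort(small_spec)
    table, planted = simcohort.generate_peak_table(meta, small_spec)
    return meta, table, planted


@pytest.fixture(scope="session")
def processed(small_cohort):
    meta, table, _ = small_cohort
    norm, fc = preprocess.run_default_pipeline(table, meta)
    return norm, fc


@pytest.fixture(scope="session")
def plan(small_cohort):
    meta, _, _ = small_cohort
    return splits.make_plan(meta, "class_label", secondary="treatment", seed=3)


@pytest.fixture(scope="session")
def per_sample(small_cohort):
    meta, _, _ = small_cohort
    return meta.drop_duplicates("sample_id").set_index("sample_id")
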