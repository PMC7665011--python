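"""Shared fixtures: deterministic synthetic cohorts reused across test files."""

import dataclasses

import pytest

import myotrace as mt
from myotrace import pipeline, synthetic


@pytest.fixture(scope="session")
def control_params():
    return mt.default_params("control", "intact")


@pytest.fixture(scope="session")
def noiseless_control_params(control_params):
    return dataclasses.replace(control_params, noise_sd_mN=0.0, period_cv=0.0)


@pytest.fixture(scope="session")
def noiseless_control_bundle(noiseless_control_params):
    return mt.simulate_strip(noiseless_control_params, 1800.0, 10.0)


@pytest.fixture(scope="session")
def spont_tables():
    """Per-strip spontaneous tables for default 9-strip cohorts of each group."""
    out = {}
    for group, master_seed in (("control", 1), ("cancer", 2)):
        bundles = synthetic.simulate_cohort(9, mt.default_params(group),
                                            master_seed=master_seed)
        out[group] = pipeline.spontaneous_table(bundles)
    return out


@pytest.fixture(scope="session")
def dissection_cohort():
    """10 control strips under the pre/post-atropine duration-series protocol."""
    dur = synthetic.efs_dissection_duration()
    return synthetic.simulate_cohort(
        10, mt.default_params("control"), master_seed=3, duration_s=dur,
        protocol=synthetic.efs_dissection_protocol())


@pytest.fixture(scope="session")
def gsk_cohort():
    """10 urothelium-intact control strips with a GSK1016790A window."""
    return synthetic.simulate_cohort(
        10, mt.default_params("control", "intact"), master_seed=4,
        protocol=synthetic.drug_protocol("GSK1016790A"))
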