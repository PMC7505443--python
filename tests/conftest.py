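import pytest

from uti_episodes import (
    build_analysis_rows,
    generate_cohort_data,
    scenario_presets,
)


@pytest.fixture(scope="session")
def null_bundle():
    sc = scenario_presets("null_effect", n_patients=1500, seed=11)
    return sc, generate_cohort_data(sc, 11)


@pytest.fixture(scope="session")
def null_rows(null_bundle):
    sc, bundle = null_bundle
    return build_analysis_rows(bundle, sc.study_start, sc.study_end)


@pytest.fixture(scope="session")
def confounded_bundle():
    sc = scenario_presets("confounded_null", n_patients=2500, seed=21)
    return sc, generate_cohort_data(sc, 21)


@pytest.fixture(scope="session")
def confounded_rows(confounded_bundle):
    sc, bundle = confounded_bundle
    return build_analysis_rows(bundle, sc.study_start, sc.study_end)


@pytest.fixture(scope="session")
def harmful_bundle():
    sc = scenario_presets("harmful_delay", n_patients=2500, seed=31)
    return sc, generate_cohort_data(sc, 31)


@pytest.fixture(scope="session")
def harmful_rows(harmful_bundle):
    sc, bundle = harmful_bundle
    return build_analysis_rows(bundle, sc.study_start, sc.study_end)
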