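import pytest

import exposomekit as ek


@pytest.fixture(scope="session")
def cohort():
    """Default-scale cohort: 100 women, 161 samples, 61 repeat donors."""
    return ek.synthetic_data.generate_cohort(seed=11)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default-configuration pipeline run shared across tests."""
    cfg = ek.PipelineConfig(seed=3)
    cfg.associations.max_untargeted_outcomes = 25
    return ek.run_pipeline(cfg)


@pytest.fixture(scope="session")
def target_matrix(cohort):
    """Censored targeted concentrations from the default panel."""
    specs, mloqs, classes = ek.synthetic_data.default_target_panel()
    matrix, truth = ek.synthetic_data.generate_target_truth(
        cohort, specs, mloqs, seed=11, analyte_class=classes
    )
    return matrix, truth
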