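import dataclasses

import pytest

from cnvassoc.synthcohort import (CaseParams, CNMatrixParams, SimulationConfig,
                                  default_trait_params)


def zero_noise_params():
    params = default_trait_params()
    return {trait: {cell: (mean, 0.0) for cell, (mean, _) in cells.items()}
            for trait, cells in params.items()}


@pytest.fixture
def small_config():
    """Compact study: enough subjects for calling yet fast to simulate."""
    return SimulationConfig(
        seed=7, n_men=60, n_women=50,
        cases=CaseParams(n_cases=12, n_control_pool=400),
        cn_matrix=CNMatrixParams(n_probes=80, n_subjects=30,
                                 cnvr_start=20, cnvr_end=32),
    )


@pytest.fixture
def study_config():
    """Full published cohort size (574 men, 493 women)."""
    return SimulationConfig(seed=11)


def with_params(config, **overrides):
    return dataclasses.replace(config, **overrides)
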