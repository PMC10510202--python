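import numpy as np
import pytest
from hypothesis import settings

import efieldstats as es

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

#: master seed for every seeded test fixture
SEED = 11


@pytest.fixture(scope="session")
def default_config() -> es.CohortConfig:
    return es.load_default_config()


@pytest.fixture(scope="session")
def default_cohort(default_config) -> list[es.SubjectRecord]:
    return es.generate_cohort(default_config.params.with_seed(SEED))


@pytest.fixture(scope="session")
def diagnosis_summaries(default_config):
    """Per-protocol five-group (n, mean, sd) summaries from the default
    configuration's cell moments."""
    params = default_config.params

    def build(protocol: es.Protocol) -> list[es.GroupSummary]:
        return [
            es.GroupSummary(
                label=d.value,
                n=params.group_sizes[d],
                mean=params.cell_moments[d][protocol][0],
                sd=params.cell_moments[d][protocol][1],
            )
            for d in es.Diagnosis
        ]

    return {p: build(p) for p in es.Protocol}


@pytest.fixture(scope="session")
def omnibus_summaries(default_config):
    """Pooled cohort + two singleton templates, per protocol."""
    return {
        p: [default_config.transdiagnostic[p]] + default_config.template_summaries(p)
        for p in es.Protocol
    }


def small_params(n_per_group: int = 8, seed: int = SEED, **overrides) -> es.CohortParams:
    """A reduced two-diagnosis parameterization for fast structural tests."""
    cells = {
        es.Diagnosis.healthy: {
            es.Protocol.motor_TMS: (84.2, 14.5),
            es.Protocol.prefrontal_TMS: (79.2, 13.1),
            es.Protocol.motor_tES: (0.343, 0.059),
            es.Protocol.prefrontal_tES: (0.310, 0.052),
        },
        es.Diagnosis.depression: {
            es.Protocol.motor_TMS: (81.1, 17.2),
            es.Protocol.prefrontal_TMS: (78.3, 17.3),
            es.Protocol.motor_tES: (0.327, 0.080),
            es.Protocol.prefrontal_tES: (0.299, 0.070),
        },
    }
    n = 2 * n_per_group
    kwargs = dict(
        cell_moments=cells,
        group_sizes={es.Diagnosis.healthy: n_per_group, es.Diagnosis.depression: n_per_group},
        sex_counts={es.Sex.male: n // 2, es.Sex.female: n - n // 2},
        templates={
            "MNI-152": {
                es.Protocol.motor_TMS: 78.16,
                es.Protocol.prefrontal_TMS: 80.14,
                es.Protocol.motor_tES: 0.293,
                es.Protocol.prefrontal_tES: 0.294,
            },
            "Ernie": {
                es.Protocol.motor_TMS: 81.46,
                es.Protocol.prefrontal_TMS: 72.58,
                es.Protocol.motor_tES: 0.286,
                es.Protocol.prefrontal_tES: 0.244,
            },
        },
        seed=seed,
    )
    kwargs.update(overrides)
    return es.CohortParams(**kwargs)
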