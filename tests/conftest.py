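import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from tcrep.simulate import GeneratorConfig, generate_cohort
from tcrep.pipeline import AnalysisConfig, analyze_cohort


def small_generator_config(**overrides) -> GeneratorConfig:
    """Desk-scale cohort small enough for unit tests (seconds, not minutes)."""
    base = dict(
        n_per_group={"healthy": 12, "MM": 12},
        n_clonotypes_per_sample=800,
        depth_log_mean=float(np.log(4000.0)),
        n_public_families=300,
        n_spiked_clusters=12,
        motif_size=6,
        seed=11,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_generator_config())


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    reps, meta, gt = small_cohort
    cfg = AnalysisConfig(
        n_permutations=100,
        model_families=("random_forest", "penalized_logistic"),
        seed=11,
    )
    return analyze_cohort(reps, meta, cfg, ground_truth=gt)
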