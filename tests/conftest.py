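import pytest
from hypothesis import settings

from lncaut import CohortConfig, generate_cohort
from lncaut.pipeline import PipelineConfig
from lncaut.synthetic import write_cohort

# reproducible property tests: fixed example generation, no local database
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig(seed=11)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One default-size synthetic cohort shared across the suite."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A scaled-down cohort for fast pipeline-level tests."""
    return CohortConfig(
        n_tumor=30,
        n_normal=15,
        n_lncrna=40,
        n_gene=300,
        n_sites=150,
        n_at_plus=30,
        n_at_minus=20,
        n_at_both=5,
        n_at_unknown=5,
        n_planted_lnc=4,
        n_drugs=8,
        n_planted_drugs=3,
        seed=5,
    )


@pytest.fixture()
def pipeline_run(tmp_path, small_config):
    """Write the small cohort to disk and return a ready PipelineConfig."""
    cohort = generate_cohort(small_config)
    paths = write_cohort(cohort, tmp_path / "cohort", small_config)
    fields = {k: str(v) for k, v in paths.items() if k in PipelineConfig.__dataclass_fields__}
    config = PipelineConfig(**fields, outdir=str(tmp_path / "results"), seed=small_config.seed)
    return cohort, config
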