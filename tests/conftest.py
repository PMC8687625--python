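import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_warnings():
    # the generator's decoys legitimately trigger zero-target warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def study7():
    from cfig.synthetic import SyntheticStudyConfig, generate_study

    return generate_study(SyntheticStudyConfig(seed=7))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, study7):
    """One full pipeline run on the seed-7 study, shared across tests."""
    from cfig.pipeline import PipelineConfig, run_pipeline
    from cfig.synthetic import write_study

    root = tmp_path_factory.mktemp("run7")
    write_study(study7, root / "study")
    cfg = PipelineConfig(
        study_dir=str(root / "study"),
        output_dir=str(root / "out"),
        threshold_mode="median",
        seed=7,
    )
    report = run_pipeline(cfg)
    return cfg, report, root
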