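import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One generated input bundle shared across the session (seed 11)."""
    from vdnet.simulate import ScenarioConfig, generate_scenario

    out = tmp_path_factory.mktemp("bundle")
    manifest = generate_scenario(ScenarioConfig(seed=11), out)
    return out, manifest


@pytest.fixture(scope="session")
def pipeline_run(bundle, tmp_path_factory):
    """One full pipeline run on the shared bundle."""
    from vdnet.pipeline import PipelineConfig, run_pipeline

    bundle_dir, manifest = bundle
    out = tmp_path_factory.mktemp("run")
    report = run_pipeline(
        PipelineConfig(bundle_dir=str(bundle_dir), out_dir=str(out), seed=11)
    )
    return report, out, manifest
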