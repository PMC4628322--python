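import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ref():
    """A small synthetic universe shared by read-level tests."""
    from apexmir.simulate import build_reference

    return build_reference(n_known=5, n_novel=3, n_decoys=5, seed=11)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One end-to-end pipeline run on a small synthetic universe."""
    from apexmir.pipeline import RunConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = RunConfig(
        seed=7, outdir=str(outdir), n_known=5, n_novel=3, n_decoys=5,
        depth=20_000, degradome_depth=4_000,
    )
    return run_pipeline(cfg)
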