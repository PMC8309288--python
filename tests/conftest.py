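import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from fleshmark.pipeline import run_pipeline  # noqa: E402


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full pipeline run (seed 7, homoplasy accession included), shared by
    design/genotyping/acceptance tests."""
    outdir = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(7, outdir=outdir, chengwoo=True)


@pytest.fixture(scope="session")
def experiment(pipeline_result):
    return pipeline_result.experiment


@pytest.fixture(scope="session")
def discovery_variants(pipeline_result):
    return pipeline_result.discovery_variants
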