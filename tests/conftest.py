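import pytest

from mirtfnet.pipeline import run_pipeline
from mirtfnet.synth import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    return generate_bundle(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_run(default_bundle):
    b = default_bundle
    return run_pipeline(
        b.associations, b.targets, b.annotations, b.ppi, b.regulation,
        b.disease_sets,
    )


def run_bundle(bundle):
    return run_pipeline(
        bundle.associations, bundle.targets, bundle.annotations,
        bundle.ppi, bundle.regulation, bundle.disease_sets,
    )
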