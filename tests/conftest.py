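import pytest
from hypothesis import HealthCheck, settings

from kdrkit import default_gene_model
from kdrkit.synthetic import reference_layout

settings.register_profile(
    "kdrkit",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("kdrkit")


@pytest.fixture(scope="session")
def model():
    """Packaged four-site VSSC model with the synthetic reference attached."""
    return default_gene_model(with_reference=True)


@pytest.fixture(scope="session")
def layout():
    return reference_layout()


@pytest.fixture(scope="session")
def assay(model):
    return model.pasa
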