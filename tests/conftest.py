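import pytest
from hypothesis import settings

from rgdtools import fixtures

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def small_catalog():
    """100-record synthetic pathogenic-variant catalog with planted mix."""
    records, truth = fixtures.generate_variant_catalog(seed=7, n=100)
    return records, truth


@pytest.fixture(scope="session")
def symptom_catalog():
    """20 synthetic disorders with symptom associations and scored truth."""
    disorders, associations, truth = fixtures.generate_symptom_catalog(
        seed=3, n_disorders=20, n_symptoms=12
    )
    return disorders, associations, truth
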