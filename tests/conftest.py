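import pytest

from lirscan import FixtureSpec, generate_annotations, generate_proteome


@pytest.fixture(scope="session")
def proteome_fixture():
    """Default-condition synthetic proteome with recorded ground truth."""
    return generate_proteome(FixtureSpec(seed=42))


@pytest.fixture(scope="session")
def annotation_fixture():
    """Annotation table with one GO term enriched among pseudo-LIRCPs."""
    return generate_annotations(
        FixtureSpec(n_proteins=200, plant_rate=0.1, anchored_fraction=1.0, seed=42)
    )
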