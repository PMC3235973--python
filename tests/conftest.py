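import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_db_and_abstractions():
    from dkaval.synthetic_data import paper_fixture

    return paper_fixture()


@pytest.fixture(scope="session")
def fixture_pipeline(fixture_db_and_abstractions):
    """End-to-end run on the published validation sample."""
    from dkaval.pipeline import run_validation

    db, records = fixture_db_and_abstractions
    return run_validation(db, records)
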