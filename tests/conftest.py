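import pytest

from sarqc.config import default_config
from sarqc.records import ActivityRecord


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture
def make_record():
    """Activity-record factory with sensible defaults for single-field tests."""

    counter = {"n": 0}

    def _make(**kwargs) -> ActivityRecord:
        counter["n"] += 1
        base = dict(
            record_id=f"R{counter['n']:04d}",
            document_id="DOC1",
            document_year=2001,
            assay_id="A1",
            compound_id="C1",
            published_type="IC50",
            published_relation="=",
            published_value=50.0,
            published_units="nM",
        )
        base.update(kwargs)
        return ActivityRecord(**base)

    return _make
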