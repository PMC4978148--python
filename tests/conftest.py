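import pytest

from bidslite.fixtures import FixtureSpec, generate_dataset
from bidslite.rules_engine import RuleSet


@pytest.fixture(scope="session")
def rules():
    return RuleSet.default()


@pytest.fixture(scope="session")
def valid_dataset(tmp_path_factory):
    """A small valid three-subject dataset, generated once per session."""
    root = tmp_path_factory.mktemp("fixture") / "ds"
    model = generate_dataset(FixtureSpec(seed=11), root)
    return root, model


@pytest.fixture()
def defect_dataset(tmp_path):
    """A fresh valid dataset per test, safe to mutate."""
    root = tmp_path / "ds"
    generate_dataset(FixtureSpec(seed=11), root)
    return root
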