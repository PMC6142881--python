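import pandas as pd
import pytest

from ndfa import pipeline


@pytest.fixture(scope="session")
def reference_fixture() -> pd.DataFrame:
    """Published per-site reference-plant δ¹⁵N values (9 species per site)."""
    return pipeline.read_references_csv(pipeline.packaged_fixture("reference_plants"))


@pytest.fixture(scope="session")
def bvalue_fixture():
    """Published glasshouse shoot/root δ¹⁵N of the two fully-fixing landraces."""
    return pipeline.read_bvalue_csv(pipeline.packaged_fixture("bvalue_glasshouse"))


@pytest.fixture(scope="session")
def trial_means_fixture() -> pd.DataFrame:
    """Published per-landrace field-trial means (two sites, five landraces)."""
    return pd.read_csv(pipeline.packaged_fixture("field_trial_means"))
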