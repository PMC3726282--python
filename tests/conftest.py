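import pandas as pd
import pytest

from butomics import load_fixture


@pytest.fixture(scope="session")
def table1_stats():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2_fc():
    return load_fixture("table2_fc")


@pytest.fixture(scope="session")
def table3_pairs():
    return load_fixture("table3_pairs")


@pytest.fixture(scope="session")
def table4():
    return load_fixture("table4")


@pytest.fixture(scope="session")
def table5_scores():
    return load_fixture("table5_scores")


@pytest.fixture(scope="session")
def table5_score_matrix(table5_scores) -> pd.DataFrame:
    return table5_scores[["s24", "s48", "s72"]].set_axis([24, 48, 72], axis=1)
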