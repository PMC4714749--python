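from pathlib import Path

import pandas as pd
import pytest

from fgga import GoDag, GoTerm, diamond_dag, toy7_dag

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def diamond() -> GoDag:
    """Four-term diamond: child GO:0000004 with two parents under the root."""
    return diamond_dag()


@pytest.fixture
def toy7() -> GoDag:
    """Seven-term toy DAG with one diamond and one chain branch."""
    return toy7_dag()


@pytest.fixture
def single_edge() -> GoDag:
    return GoDag([GoTerm("GO:A"), GoTerm("GO:B")], [("GO:B", "GO:A")])


@pytest.fixture
def uniform_eta():
    def make(dag, value=1.0):
        return pd.Series(float(value), index=list(dag.term_ids))

    return make
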