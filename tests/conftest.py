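from pathlib import Path

import pytest

from odmconvert import CellGrid, fixture_table1, load_grid

REPO = Path(__file__).resolve().parent.parent
TABLE1_CSV = REPO / "examples" / "table1.csv"


@pytest.fixture
def model():
    """The worked-example form: 1 group, 8 items, 12 semantic codes."""
    return fixture_table1()


@pytest.fixture
def grid() -> CellGrid:
    """The worked-example office template, loaded from the shipped CSV."""
    return load_grid(TABLE1_CSV)
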