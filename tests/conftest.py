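import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from nbescore import default_table, fixture_set


@pytest.fixture(scope="session")
def table():
    """The shipped default bond-energy table."""
    return default_table()


@pytest.fixture(scope="session")
def fixtures():
    """The committed hand-verified fixture panel."""
    return fixture_set()


@pytest.fixture(scope="session")
def table_values(table):
    """The default table as a plain dict keyed by (el_a, el_b, order),
    for use by the brute-force oracles."""
    return {(k.element_a, k.element_b, k.order): table[k] for k in table}


@pytest.fixture()
def smiles_file(tmp_path, fixtures):
    """A SMILES line file of the whole fixture panel."""
    path = tmp_path / "fixtures.smi"
    lines = ["# fixture panel"]
    lines += [f"{fx.smiles}\t{fx.name}" for fx in fixtures]
    path.write_text("\n".join(lines) + "\n")
    return path
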