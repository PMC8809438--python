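import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper module

import floraphylo as fp


@pytest.fixture(scope="session")
def cherry_plus_one():
    """((A:1,B:1):1,C:2); — d(A,B)=2, d(A,C)=d(B,C)=4."""
    return fp.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def balanced_four():
    """((A:1,B:1):1,(C:1,D:1):1);"""
    return fp.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def caterpillar_four():
    """(((A:1,B:1):1,C:2):1,D:3); — the worked NTI example tree."""
    return fp.parse_newick("(((A:1,B:1):1,C:2):1,D:3);")


@pytest.fixture(scope="session")
def kunlun_mini():
    return fp.make_fixture("kunlun-mini")


@pytest.fixture
def kunlun_mini_paths(kunlun_mini, tmp_path):
    """The kunlun-mini fixture written out as the pipeline's file inputs."""
    return kunlun_mini.write(tmp_path / "inputs")


def clade_table(ages, counts, genera=None, **extra):
    """Shorthand CladeAgeTable constructor for tests."""
    n = len(ages)
    df = pd.DataFrame(
        {
            "genus": genera if genera is not None else [f"g{i}" for i in range(n)],
            "age_ma": ages,
            "species_count": counts,
            **extra,
        }
    )
    return fp.CladeAgeTable(df)
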