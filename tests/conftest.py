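import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from metalloprof import reference_db as rdb
from metalloprof import synthetic_data as sd

# nine des rows spanning class -> domain: 1 class, 1 fold, 2 superfamilies,
# 2 families, 3 domains
NINE_ROW_DES = """\
# tiny hand-written fixture
1\tcl\tb\tb\tAll beta proteins
2\tcf\tb.6\t-\tCupredoxin-like fold
3\tsf\tb.6.1\t-\tCupredoxins
4\tfa\tb.6.1.2\t-\tPeriplasmic domain of cytochrome c oxidase subunit II
5\tfa\tb.6.1.3\t-\tMultidomain cupredoxins
6\tsf\tb.6.2\t-\tSecond superfamily
7\tdm\tb.6.1.2\td00001\tcytochrome c oxidase subunit II domain
8\tdm\tb.6.1.3\td00002\tcopper-containing nitrite reductase NirK
9\tdm\tb.6.1.3\td00003\tmulticopper oxidase (laccase)
"""

NINE_ROW_CLA = """\
# classification lines
d00001\tsynth\tA:\tb.6.1.2\t7\tcl=1,cf=2,sf=3,fa=4,dm=7
d00002\tsynth\tA:\tb.6.1.3\t8\tcl=1,cf=2,sf=3,fa=5,dm=8
d00003\tsynth\tA:\tb.6.1.3\t9\tcl=1,cf=2,sf=3,fa=5,dm=9
"""

NINE_ROW_FASTA = """\
>d00001 cytochrome c oxidase subunit II domain
MAHEVLKQGWWDNPEKRATYEQLGHS
>d00002 copper-containing nitrite reductase NirK
MSDKATHQWLNCCVIPRGEYTRAFDK
>d00003 multicopper oxidase (laccase)
MKLWHETNNDAGYQRPCVISTTLFEA
"""


@pytest.fixture(scope="session")
def nine_row_hierarchy():
    return rdb.parse_hierarchy(NINE_ROW_CLA, NINE_ROW_DES, NINE_ROW_FASTA)


@pytest.fixture(scope="session")
def sim_fixture():
    """Default synthetic hierarchy (6 Fe + 4 Cu families)."""
    return sd.make_hierarchy_fixture(sd.SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_reference(sim_fixture):
    return sd.reference_from_fixture(sim_fixture)


@pytest.fixture(scope="session")
def fixture_taxonomy():
    from metalloprof import taxonomy as tx
    nodes, names, table = sd.make_taxonomy_fixture()
    return tx.load_taxonomy(nodes, names), table
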