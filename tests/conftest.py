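import json
import pathlib

import pytest

from protfam import fixtures


@pytest.fixture(scope="session")
def world():
    return fixtures.generate_world(seed=1)


@pytest.fixture(scope="session")
def fixture_dir(world, tmp_path_factory):
    d = tmp_path_factory.mktemp("planted")
    fixtures.emit_inputs(world, d)
    return pathlib.Path(d)


@pytest.fixture(scope="session")
def manifest(fixture_dir):
    with open(fixture_dir / "manifest.json") as fh:
        return json.load(fh)


# A three-record Swiss-Prot flat-file fixture authored alongside its
# expectation (cross-checked by hand against a line-oriented read).
SPROT_DAT = """\
ID   AMY1_TEST               Reviewed;         412 AA.
AC   P00001; Q99999;
DE   RecName: Full=Alpha-amylase;
DE   AltName: Full=1,4-alpha-D-glucan glucanohydrolase;
DE            Short=AA;
OS   Testus exampleus.
DR   Pfam; PF00128; Alpha-amylase; 2.
DR   Pfam; PF02806; Alpha-amylase_C; 1.
CC   -!- SIMILARITY: Belongs to the glycosyl hydrolase 13 family.
SQ   SEQUENCE   412 AA;  46589 MW;  ABCDEF1234567890 CRC64;
//
ID   POLC_TEST               Reviewed;         900 AA.
AC   P00002;
DE   RecName: Full=DNA polymerase I;
OS   Testus secundus.
DR   Pfam; PF00476; DNA_pol_A; 1.
CC   -!- SIMILARITY: In the C-terminal section; belongs to the DNA
CC       polymerase type-A family.
SQ   SEQUENCE   900 AA;  99999 MW;  0000000000000000 CRC64;
//
ID   NOFAM_TEST              Reviewed;         100 AA.
AC   P00003;
DE   RecName: Full=Uncharacterized protein;
OS   Testus tertius.
SQ   SEQUENCE   100 AA;  11111 MW;  0000000000000000 CRC64;
//
"""


@pytest.fixture()
def sprot_dat_text():
    return SPROT_DAT
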