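from pathlib import Path

import numpy as np
import pytest

from ubrbox.model import AtomRecord, StructureModel

#: user-supplied deposited structures live here (see data/README.md)
DATA_DIR = Path(__file__).resolve().parents[1] / "data"

MINIMAL_PDB = """\
CRYST1   10.000   12.000   14.000  90.00  90.00  90.00 P 1
ATOM      1  N   GLY A   1       1.000   2.000   3.000  1.00 10.00           N
ATOM      2  CA  GLY A   1       2.200   2.500   3.300  1.00 10.00           C
ATOM      3  C   GLY A   1       3.400   1.800   2.900  1.00 10.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path) -> Path:
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


def atom(name, element, resname, resnum, chain, pos, **kw) -> AtomRecord:
    return AtomRecord(name=name, element=element, residue_name=resname,
                      residue_number=resnum, chain_id=chain,
                      position=np.asarray(pos, float), **kw)


def single_atom_p1_model(edge: float = 10.0) -> StructureModel:
    return StructureModel(
        id="p1", atoms=[atom("ZN", "Zn", "ZN", 1, "A", (1.0, 1.0, 1.0), het=True)],
        unit_cell=(edge, edge, edge, 90.0, 90.0, 90.0), space_group="P 1",
        symmetry_ops=[(np.eye(3), np.zeros(3))])
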