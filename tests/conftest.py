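import numpy as np
import pytest

from conformo.structio import StructureModel


def pdb_line(serial, resnum, x, y, z, atom="CA", chain="A", occ=1.00, altloc=" ",
             record="ATOM", icode=" "):
    return (
        f"{record:<6s}{serial:5d} {atom:^4s}{altloc}ALA {chain}{resnum:4d}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}           C  "
    )


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Hand-written fixture with residues 84, 100, 249 on chain A."""
    lines = [
        pdb_line(1, 84, 0.0, 0.0, 0.0),
        pdb_line(2, 100, 1.0, 1.0, 1.0),
        pdb_line(3, 249, 3.0, 4.0, 0.0),
        pdb_line(4, 84, 9.0, 9.0, 9.0, chain="B"),
        pdb_line(5, 500, 2.0, 2.0, 2.0, record="HETATM"),
        "END",
    ]
    path = tmp_path / "mini.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


def random_model(rng, n=10, structure_id="rand", start_res=1):
    coords = {start_res + i: rng.uniform(-10, 10, 3) for i in range(n)}
    return StructureModel(structure_id, "A", coords)


def rigid_copy(model, rng):
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-15, 15, 3)
    return model.transformed(rot, trans)
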