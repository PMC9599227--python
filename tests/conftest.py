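import numpy as np
import pytest

from nhpi.structure import Atom, Chain, Model, Residue, Structure


# Hand-written fixed-column fixture: a Gln (9 atoms) and a partial Phe
# (8 atoms) -> 17 ATOM records, one water, REMARK metadata.
TWO_RESIDUE_PDB = """\
REMARK   2 RESOLUTION.    1.39 ANGSTROMS.
REMARK   3   R VALUE            (WORKING SET) : 0.167
ATOM      1  N   GLN A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  GLN A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   GLN A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  O   GLN A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  CB  GLN A   1       2.010  -0.760  -1.210  1.00 10.00           C
ATOM      6  CG  GLN A   1       3.530  -0.830  -1.260  1.00 10.00           C
ATOM      7  CD  GLN A   1       4.090  -1.590  -2.450  1.00 10.00           C
ATOM      8  OE1 GLN A   1       3.370  -2.310  -3.140  1.00 10.00           O
ATOM      9  NE2 GLN A   1       5.390  -1.450  -2.690  1.00 10.00           N
ATOM     10  N   PHE B   2       5.000   5.000   0.000  1.00 12.00           N
ATOM     11  CB  PHE B   2       6.900   5.100   1.400  1.00 12.00           C
ATOM     12  CG  PHE B   2       7.500   5.200   2.760  1.00 12.00           C
ATOM     13  CD1 PHE B   2       8.880   5.210   2.910  1.00 12.00           C
ATOM     14  CE1 PHE B   2       9.440   5.310   4.170  1.00 12.00           C
ATOM     15  CZ  PHE B   2       8.630   5.410   5.290  1.00 12.00           C
ATOM     16  CE2 PHE B   2       7.250   5.400   5.150  1.00 12.00           C
ATOM     17  CD2 PHE B   2       6.690   5.300   3.890  1.00 12.00           C
HETATM   18  O   HOH C   3       9.000   9.000   9.000  1.00 20.00           O
END
"""


@pytest.fixture
def two_residue_pdb() -> str:
    return TWO_RESIDUE_PDB


def structure_from_residues(residue_groups, model_indices=None) -> Structure:
    """Assemble residues (list per chain 'A', 'B', ...) into a Structure."""
    models = []
    if not isinstance(residue_groups[0], list):
        residue_groups = [residue_groups]
    for mi, residues in enumerate(residue_groups):
        serial = 1
        for res in residues:
            for a in res.atoms:
                a.serial = serial
                serial += 1
        models.append(Model(index=mi + 1, chains=[Chain("A", residues)]))
    return Structure(models=models, id="TEST")


def hexagon(radius: float = 1.39, z: float = 0.0) -> np.ndarray:
    ang = np.radians(60.0 * np.arange(6))
    return np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.full(6, z)]
    )


def residue_from_coords(resname, names, coords, seqnum=1) -> Residue:
    atoms = [
        Atom(name=n, element=n[0] if not n[0].isdigit() else "C", serial=i + 1, coords=c)
        for i, (n, c) in enumerate(zip(names, coords))
    ]
    return Residue(resname=resname, seqnum=seqnum, atoms=atoms)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=rng).as_matrix()
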