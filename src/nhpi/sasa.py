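"""Shrake-Rupley solvent-accessible surface area and burial classes.

Each heavy atom is expanded by the solvent probe radius and sampled with a
deterministic Fibonacci sphere; a sample point is accessible when it lies
outside every neighbouring expanded sphere.  Burial of a donor-ring pair
is classified from the summed accessible area of the two whole residues:

    buried             pair ASA < 30 A^2
    intermediate       30 <= ASA <= 60
    partially_exposed  60 < ASA < 120
    fully_exposed      ASA >= 120

Hydrogens are excluded (heavy-atom convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure

__all__ = [
    "DEFAULT_RADII",
    "SasaResult",
    "shrake_rupley_sasa",
    "classify_pair_burial",
    "fibonacci_sphere",
]

# van der Waals radii (A) by element, NACCESS/Chothia-style values.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

DEFAULT_PROBE = 1.4  # A, water
DEFAULT_N_POINTS = 960


@dataclass
class SasaResult:
    per_atom: np.ndarray  # A^2, aligned with atom_addresses
    atom_addresses: list[tuple]  # (chain, resname, seqnum, icode, atom name)
    per_residue: dict[tuple, float]  # (chain, resname, seqnum, icode) -> A^2
    probe: float
    n_points: int

    def residue_asa(self, chain_id: str, seqnum: int, icode: str = "") -> float:
        for (c, rn, sn, ic), asa in self.per_residue.items():
            if c == chain_id and sn == seqnum and ic == icode:
                return asa
        raise KeyError(f"no residue {chain_id}:{seqnum}{icode} in SASA result")

    def pair_asa(
        self,
        donor: tuple[str, int] | tuple[str, int, str],
        ring: tuple[str, int] | tuple[str, int, str],
    ) -> float:
        """Whole-residue ASA sum of a donor-ring pair."""
        return self.residue_asa(*donor) + self.residue_asa(*ring)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, near-uniform unit vectors (golden-angle spiral)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    structure: Structure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: Optional[dict[str, float]] = None,
    fallback_radius: Optional[float] = None,
    include_hydrogens: bool = False,
    model_index: int = 0,
) -> SasaResult:
    """Per-atom and per-residue solvent-accessible surface area.

    ASA of atom *i* is ``4 pi (r_i + probe)^2 * accessible/n_points``.
    Exactly coincident expanded spheres are resolved by point ownership
    (the lower-index atom keeps the boundary points) so total area is
    conserved in the degenerate limit.
    """
    radii = radii or DEFAULT_RADII
    model = structure.models[model_index]

    coords: list[np.ndarray] = []
    radii_list: list[float] = []
    addresses: list[tuple] = []
    res_keys: list[tuple] = []
    for chain in model.chains:
        for res in chain.residues:
            rkey = (chain.chain_id, res.resname, res.seqnum, res.icode)
            for atom in res.atoms:
                el = atom.element.upper()
                if not include_hydrogens and el in ("H", "D"):
                    continue
                r = radii.get(el, fallback_radius)
                if r is None:
                    raise ValueError(
                        f"no van der Waals radius for element {atom.element!r} "
                        f"(atom {atom.name!r}) and no fallback_radius given"
                    )
                coords.append(atom.coords)
                radii_list.append(r)
                addresses.append((*rkey, atom.name))
                res_keys.append(rkey)

    if not coords:
        raise ValueError("structure has no heavy atoms")
    xyz = np.asarray(coords)
    rad = np.asarray(radii_list)
    n_atoms = len(rad)
    sphere = fibonacci_sphere(n_points)

    tree = cKDTree(xyz)
    max_reach = 2.0 * (rad.max() + probe)
    eps = 1e-9

    per_atom = np.zeros(n_atoms)
    for i in range(n_atoms):
        ri = rad[i] + probe
        pts = xyz[i] + ri * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(xyz[i], max_reach):
            if j == i:
                continue
            rj = rad[j] + probe
            if np.linalg.norm(xyz[j] - xyz[i]) >= ri + rj:
                continue
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            if j < i:
                accessible &= d2 > rj * rj + eps
            else:
                accessible &= d2 >= rj * rj - eps
        per_atom[i] = 4.0 * np.pi * ri * ri * accessible.sum() / n_points

    per_residue: dict[tuple, float] = {}
    for rkey, asa in zip(res_keys, per_atom):
        per_residue[rkey] = per_residue.get(rkey, 0.0) + float(asa)

    return SasaResult(
        per_atom=per_atom,
        atom_addresses=addresses,
        per_residue=per_residue,
        probe=probe,
        n_points=n_points,
    )


BURIAL_CLASSES = ("buried", "intermediate", "partially_exposed", "fully_exposed")


def classify_pair_burial(pair_asa: float) -> str:
    """Burial class of a donor-ring pair from its summed residue ASA."""
    if pair_asa < 0:
        raise ValueError(f"negative pair ASA {pair_asa}")
    if pair_asa < 30.0:
        return "buried"
    if pair_asa <= 60.0:
        return "intermediate"
    if pair_asa < 120.0:
        return "partially_exposed"
    return "fully_exposed"
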