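"""Minimal structure hierarchy and PDB-format I/O.

Coordinates are read from fixed-column PDB records into a small
Model/Chain/Residue/Atom hierarchy that the geometry and screening layers
consume.  gemmi does the heavy lifting of record parsing and formatting;
this module adds the altloc/model policies, metadata extraction and the
stricter validation the pipeline contracts require.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Model",
    "Structure",
    "PDBParseError",
    "PDBWriteError",
    "parse_structure",
    "write_structure",
]

WATER_RESNAMES = frozenset({"HOH", "WAT"})

# Symmetric bound on what an 8.3 coordinate field can hold without risking
# sign-column overflow on reflection/translation of the same structure.
_COORD_LIMIT = 999.999


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input."""


class PDBWriteError(ValueError):
    """Raised when a structure cannot be represented in PDB columns."""


@dataclass
class Atom:
    name: str
    element: str
    serial: int
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    bfactor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.name.strip():
            raise ValueError("atom name must be non-empty")
        self.name = self.name.strip()


@dataclass
class Residue:
    resname: str
    seqnum: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def address(self) -> tuple[str, int, str]:
        return (self.resname, self.seqnum, self.icode)

    def get(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __getitem__(self, name: str) -> Atom:
        a = self.get(name)
        if a is None:
            raise KeyError(f"{self.resname} {self.seqnum}: no atom {name!r}")
        return a

    def __contains__(self, name: str) -> bool:
        return self.get(name) is not None

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_RESNAMES


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def get(self, seqnum: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.seqnum == seqnum and r.icode == icode:
                return r
        return None


@dataclass
class Model:
    index: int
    chains: list[Chain] = field(default_factory=list)

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    def get_chain(self, chain_id: str) -> Optional[Chain]:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def residues(self) -> Iterator[tuple[str, Residue]]:
        for c in self.chains:
            for r in c.residues:
                yield c.chain_id, r

    def atoms(self) -> Iterator[Atom]:
        for _, r in self.residues():
            yield from r.atoms


@dataclass
class Structure:
    models: list[Model]
    id: str = ""
    resolution: Optional[float] = None
    r_factor: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("Structure requires at least one model")

    @property
    def first_model(self) -> Model:
        return self.models[0]

    @property
    def n_models(self) -> int:
        return len(self.models)

    def atom_count(self, include_waters: bool = True) -> int:
        n = 0
        for _, res in self.first_model.residues():
            if include_waters or not res.is_water:
                n += len(res.atoms)
        return n

    def water_count(self) -> int:
        """Number of water residues (resname HOH/WAT) in the first model."""
        return sum(1 for _, r in self.first_model.residues() if r.is_water)


_R_WORK_RE = re.compile(
    r"^REMARK\s+3\s+R VALUE\s+\(WORKING SET\)\s*:\s*([0-9.]+)", re.M
)


def _validate_coordinate_records(text: str) -> int:
    """Pre-scan ATOM/HETATM records; return their count.

    gemmi is forgiving about broken fixed-column records, so the numeric
    fields are checked here first and a malformed line is reported with its
    line number.
    """
    n = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        n += 1
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated coordinate record")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed {what} coordinate field "
                    f"{line[lo:hi]!r}"
                ) from None
    return n


def _collapse_altlocs(atoms: list[Atom], policy: str) -> list[Atom]:
    if policy == "keep_all":
        return atoms
    if policy != "highest_occupancy":
        raise ValueError(f"unknown altloc policy {policy!r}")
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        prev = best.get(a.name)
        if prev is None:
            best[a.name] = a
            order.append(a.name)
        elif (a.occupancy, _altloc_rank(a.altloc)) > (
            prev.occupancy,
            _altloc_rank(prev.altloc),
        ):
            best[a.name] = a
    return [best[name] for name in order]


def _altloc_rank(altloc: str) -> int:
    # ties broken toward the lexicographically smaller altloc
    return -ord(altloc) if altloc else 0


def parse_structure(
    source: str,
    altloc: str = "highest_occupancy",
    models: str = "all",
    structure_id: str = "",
    resolution: Optional[float] = None,
    r_factor: Optional[float] = None,
) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Parameters
    ----------
    source : str
        PDB-format text with at least one ATOM or HETATM record.
    altloc : {"highest_occupancy", "keep_all"}
        Alternate-location policy.  The default keeps, for each atom name,
        the conformer with the highest occupancy (ties broken toward the
        lexicographically smaller altloc).
    models : {"all", "first"}
        Keep every MODEL block (trajectory mode) or only the first.
    resolution, r_factor
        Override metadata when the header lacks REMARK 2 / REMARK 3.
    """
    if models not in ("all", "first"):
        raise ValueError(f"unknown model policy {models!r}")
    if not source.strip():
        raise PDBParseError("empty input: no PDB records found")
    n_records = _validate_coordinate_records(source)
    if n_records == 0:
        raise PDBParseError("input contains no ATOM or HETATM records")

    st = gemmi.read_pdb_string(source)
    if resolution is None and st.resolution > 0:
        resolution = float(st.resolution)
    if r_factor is None:
        m = _R_WORK_RE.search(source)
        if m:
            r_factor = float(m.group(1))

    out_models: list[Model] = []
    for i, gm in enumerate(st):
        chains: list[Chain] = []
        for gc in gm:
            residues: list[Residue] = []
            for gr in gc:
                atoms = [
                    Atom(
                        name=ga.name,
                        element=ga.element.name,
                        serial=ga.serial,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        altloc="" if ga.altloc in ("\x00", " ", "") else ga.altloc,
                        occupancy=float(ga.occ),
                        bfactor=float(ga.b_iso),
                        is_hetero=(gr.het_flag == "H"),
                    )
                    for ga in gr
                ]
                residues.append(
                    Residue(
                        resname=gr.name,
                        seqnum=gr.seqid.num,
                        icode=gr.seqid.icode.strip(),
                        atoms=_collapse_altlocs(atoms, altloc),
                    )
                )
            chains.append(Chain(chain_id=gc.name, residues=residues))
        out_models.append(Model(index=i + 1, chains=chains))
        if models == "first":
            break

    return Structure(
        models=out_models,
        id=structure_id or st.name,
        resolution=resolution,
        r_factor=r_factor,
    )


def parse_structure_file(path, **kwargs) -> Structure:
    with open(path) as fh:
        return parse_structure(fh.read(), **kwargs)


def write_structure(structure: Structure) -> str:
    """Render a :class:`Structure` as fixed-column PDB text.

    Raises :class:`PDBWriteError` when any coordinate exceeds what the
    8.3 columns can hold.
    """
    for model in structure.models:
        for atom in model.atoms():
            if np.any(np.abs(atom.coords) > _COORD_LIMIT):
                raise PDBWriteError(
                    f"coordinate {np.max(np.abs(atom.coords)):.3f} of atom "
                    f"{atom.name!r} not representable in PDB 8.3 columns"
                )

    st = gemmi.Structure()
    st.name = structure.id or "XXXX"
    for model in structure.models:
        gm = gemmi.Model(model.index)
        for chain in model.chains:
            gc = gemmi.Chain(chain.chain_id)
            for res in chain.residues:
                gr = gemmi.Residue()
                gr.name = res.resname
                gr.seqid = gemmi.SeqId(res.seqnum, res.icode or " ")
                gr.het_flag = "H" if (res.atoms and res.atoms[0].is_hetero) else "A"
                for atom in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element or "X")
                    ga.serial = atom.serial
                    ga.pos = gemmi.Position(*atom.coords)
                    ga.altloc = atom.altloc or "\x00"
                    ga.occ = atom.occupancy
                    ga.b_iso = atom.bfactor
                    gr.add_atom(ga)
                gc.add_residue(gr)
            gm.add_chain(gc)
        st.add_model(gm)
    st.raw_remarks = []
    if structure.resolution is not None:
        st.resolution = structure.resolution
    return st.make_pdb_string()


def write_structure_file(structure: Structure, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_structure(structure))
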