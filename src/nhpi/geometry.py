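"""Ring frames, amide donors and the six-parameter NH-pi pair geometry.

An NH-pi contact between a side-chain amide (Gln/Asn, or acetamide as the
small-molecule model) and a six-membered aromatic ring (Phe, or
benzene/toluene) is described by six parameters:

* bond conformation - ``d_NM`` (donor N to ring centroid M, A), ``theta``
  (acute angle between the M->N vector and the ring normal, deg) and
  ``omega`` (N-H...M angle at the hydrogen, deg; the hydrogen pointing at
  the ring, i.e. the larger of the two amide hydrogens, is reported);
* side-chain position - ``d_CgPi`` (reference carbon Cgamma to centroid,
  A), ``tau`` (signed elevation of the centroid->Cgamma vector above the
  ring plane, deg; positive on the +normal side) and ``chi`` (in-plane
  angle between the projected Cgamma->N vector and the projected ring
  substituent Cbeta->Cgamma bond, deg, unsigned in [0, 180]).

Amide hydrogens are always placed theoretically at 1.0 A from N in the
amide plane with trigonal sp2 geometry; hydrogens present in the input are
ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .structure import Residue

__all__ = [
    "GeometryConfig",
    "RingFrame",
    "AmideDonor",
    "PairGeometry",
    "GeometryError",
    "build_ring_frame",
    "build_amide_donor",
    "compute_pair_geometry",
    "RING_ATOM_ORDERS",
    "DONOR_ATOM_MAPS",
]


class GeometryError(ValueError):
    """Raised for undefined or degenerate geometric constructions."""


# Canonical ring traversal orders.  The normal sign is fixed so that this
# order appears counter-clockwise when viewed from the +normal side.
RING_ATOM_ORDERS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CE1", "CZ", "CE2", "CD2"),
    "BNZ": ("C1", "C2", "C3", "C4", "C5", "C6"),
    "TOL": ("C1", "C2", "C3", "C4", "C5", "C6"),
}

# Ring substituent bond (Cbeta -> Cgamma analogue): (tail, head) atom names.
RING_SUBSTITUENTS: dict[str, tuple[str, str]] = {
    "PHE": ("CB", "CG"),
    "TOL": ("CM", "C1"),
}

# Donor atom mapping: N, carbonyl C (amide-plane apex), carbonyl O,
# reference carbon (the "Cgamma" of the six-parameter set).
DONOR_ATOM_MAPS: dict[str, dict[str, str]] = {
    "GLN": {"N": "NE2", "C": "CD", "O": "OE1", "CG": "CG"},
    "ASN": {"N": "ND2", "C": "CG", "O": "OD1", "CG": "CB"},
    # acetamide: methyl carbon plays Cgamma, carbonyl carbon plays Cdelta
    "ACM": {"N": "N", "C": "C", "O": "O", "CG": "CM"},
}

PLANARITY_RMS_LIMIT = 0.1  # A


@dataclass
class GeometryConfig:
    """Conventions for the six-parameter computation.

    d_cg_pi_mode : {"centroid", "plane"}
        ``centroid`` measures ``|Cgamma - M|`` (default; the reading
        consistent with the published crystal geometry), ``plane`` the
        perpendicular distance of Cgamma from the ring plane.
    hydrogen_bond_length : float
        N-H distance for theoretical hydrogen placement, A.
    """

    d_cg_pi_mode: str = "centroid"
    omega_vertex: str = "H"
    hydrogen_bond_length: float = 1.0

    def __post_init__(self) -> None:
        if self.d_cg_pi_mode not in ("centroid", "plane"):
            raise ValueError(f"unknown d_cg_pi_mode {self.d_cg_pi_mode!r}")
        if self.omega_vertex != "H":
            raise ValueError("only the H-vertex omega convention is supported")


@dataclass
class RingFrame:
    center_M: np.ndarray
    normal_n: np.ndarray
    inplane_x: np.ndarray
    inplane_y: np.ndarray
    substituent_CbCg: Optional[np.ndarray]
    atoms_used: tuple[str, ...]
    planarity_rms: float
    is_planar: bool
    address: tuple = ()


@dataclass
class AmideDonor:
    N_pos: np.ndarray
    H_positions: np.ndarray  # (2, 3)
    Cgamma_pos: np.ndarray
    Cdelta_pos: np.ndarray
    parent: tuple = ()


@dataclass
class PairGeometry:
    d_NM: float
    theta: float
    omega: float
    d_CgPi: float
    tau: float
    chi: float
    donor_address: tuple = ()
    ring_address: tuple = ()
    h_used: int = 0

    def as_dict(self) -> dict:
        return {
            "d_NM": self.d_NM,
            "theta": self.theta,
            "omega": self.omega,
            "d_CgPi": self.d_CgPi,
            "tau": self.tau,
            "chi": self.chi,
        }


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError(f"cannot normalize near-zero {what}")
    return v / n


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = np.dot(_unit(u), _unit(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def build_ring_frame(residue: Residue, address: tuple = ()) -> RingFrame:
    """Centroid, oriented normal and in-plane axes of a six-carbon ring.

    The normal is taken from the least-squares plane of the six ring
    carbons, with its sign fixed by the canonical traversal order
    (right-hand rule), so the sign of ``tau`` is reproducible.  A ring
    whose planarity RMS exceeds 0.1 A is flagged but still returned.
    """
    order = RING_ATOM_ORDERS.get(residue.resname)
    if order is None:
        # fall back to C1..C6 naming for synthetic rings
        order = RING_ATOM_ORDERS["BNZ"]
    missing = [name for name in order if name not in residue]
    if missing:
        raise GeometryError(
            f"{residue.resname} {residue.seqnum}: missing ring atoms {missing}"
        )
    coords = np.array([residue[name].coords for name in order])
    center = coords.mean(axis=0)
    centered = coords - center

    # least-squares plane normal: singular vector of the smallest singular value
    _, _, vt = np.linalg.svd(centered)
    normal = vt[2]
    # orient by the canonical traversal (Newell summation gives the CCW normal)
    newell = np.sum(np.cross(centered, np.roll(centered, -1, axis=0)), axis=0)
    if np.dot(normal, newell) < 0:
        normal = -normal
    normal = _unit(normal, "ring normal")

    planarity_rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))

    substituent = None
    sub = RING_SUBSTITUENTS.get(residue.resname)
    if sub is not None and sub[0] in residue and sub[1] in residue:
        substituent = _unit(
            residue[sub[1]].coords - residue[sub[0]].coords, "substituent bond"
        )

    if substituent is not None:
        proj = substituent - np.dot(substituent, normal) * normal
        x_axis = _unit(proj) if np.linalg.norm(proj) > 1e-9 else None
    else:
        x_axis = None
    if x_axis is None:
        x_axis = _unit(centered[0] - np.dot(centered[0], normal) * normal)
    y_axis = np.cross(normal, x_axis)

    return RingFrame(
        center_M=center,
        normal_n=normal,
        inplane_x=x_axis,
        inplane_y=y_axis,
        substituent_CbCg=substituent,
        atoms_used=order,
        planarity_rms=planarity_rms,
        is_planar=planarity_rms <= PLANARITY_RMS_LIMIT,
        address=address or (residue.resname, residue.seqnum, residue.icode),
    )


def build_amide_donor(
    residue: Residue,
    config: Optional[GeometryConfig] = None,
    address: tuple = (),
) -> AmideDonor:
    """Donor N with two theoretically placed hydrogens.

    Hydrogens are placed at ``hydrogen_bond_length`` (default 1.0 A) from
    N, in the amide plane defined by the carbonyl C, the carbonyl O and N,
    with trigonal sp2 geometry: each H-N-C angle is 120 deg and the two
    hydrogens sit on opposite sides of the N-C axis.
    """
    config = config or GeometryConfig()
    amap = DONOR_ATOM_MAPS.get(residue.resname)
    if amap is None:
        raise GeometryError(f"{residue.resname}: not a supported amide donor")
    missing = [label for label in amap.values() if label not in residue]
    if missing:
        raise GeometryError(
            f"{residue.resname} {residue.seqnum}: missing donor atoms {missing}"
        )
    N = residue[amap["N"]].coords
    C = residue[amap["C"]].coords
    O = residue[amap["O"]].coords
    CG = residue[amap["CG"]].coords

    c_hat = _unit(C - N, "N->C bond")
    plane_normal = np.cross(O - C, N - C)
    if np.linalg.norm(plane_normal) < 1e-9:
        raise GeometryError("near-linear amide: plane undefined")
    plane_normal = _unit(plane_normal)
    e2 = _unit(np.cross(plane_normal, c_hat))

    L = config.hydrogen_bond_length
    cos120, sin120 = -0.5, np.sqrt(3.0) / 2.0
    h1 = N + L * (cos120 * c_hat + sin120 * e2)
    h2 = N + L * (cos120 * c_hat - sin120 * e2)

    return AmideDonor(
        N_pos=N,
        H_positions=np.array([h1, h2]),
        Cgamma_pos=CG,
        Cdelta_pos=C,
        parent=address or (residue.resname, residue.seqnum, residue.icode),
    )


def compute_pair_geometry(
    donor: AmideDonor,
    ring: RingFrame,
    config: Optional[GeometryConfig] = None,
) -> PairGeometry:
    """The six NH-pi parameters for one donor-ring pair.

    ``omega`` is evaluated at both amide hydrogens and the maximum is
    reported (``h_used`` records the winner); ``chi`` is NaN when the
    Cgamma->N vector is parallel to the ring normal or the ring has no
    substituent bond.
    """
    config = config or GeometryConfig()
    M = ring.center_M
    n = ring.normal_n
    N = donor.N_pos
    CG = donor.Cgamma_pos

    v = N - M
    d_NM = float(np.linalg.norm(v))
    if d_NM < 1e-9:
        raise GeometryError("donor N coincides with ring centroid")
    # acute angle between the M->N vector and +/-normal
    cos_t = abs(np.dot(v / d_NM, n))
    theta = float(np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0))))

    omegas = [_angle_deg(N - h, M - h) for h in donor.H_positions]
    h_used = int(np.argmax(omegas))
    omega = float(omegas[h_used])

    w = CG - M
    d_cg = float(np.linalg.norm(w))
    if d_cg < 1e-9:
        raise GeometryError("reference carbon coincides with ring centroid")
    if config.d_cg_pi_mode == "centroid":
        d_CgPi = d_cg
    else:
        d_CgPi = float(abs(np.dot(w, n)))
    tau = float(np.degrees(np.arcsin(np.clip(np.dot(w, n) / d_cg, -1.0, 1.0))))

    chi = float("nan")
    if ring.substituent_CbCg is not None:
        u = N - CG
        u_p = u - np.dot(u, n) * n
        s = ring.substituent_CbCg
        s_p = s - np.dot(s, n) * n
        if np.linalg.norm(u_p) > 1e-9 and np.linalg.norm(s_p) > 1e-9:
            chi = _angle_deg(u_p, s_p)

    return PairGeometry(
        d_NM=d_NM,
        theta=theta,
        omega=omega,
        d_CgPi=d_CgPi,
        tau=tau,
        chi=chi,
        donor_address=donor.parent,
        ring_address=ring.address,
        h_used=h_used,
    )
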