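"""Acetamide-toluene rigid scan grid in the toluene-anchored frame.

The interaction space of the amide nitrogen over a toluene ring is
sampled on a quadrant lattice expressed in a frame anchored on the
toluene: origin at the substituted ring carbon C1, x-axis along the
methyl-carbon -> C1 bond, z-axis along the ring normal, y completing a
right-handed system.  Toluene's symmetry about the x-axis and the ring
plane lets one quadrant (y >= 0, z > 0) represent the whole space.  The
default lattice is 0 to 4.8 A in steps of 0.4 A along x and y and 2.0 to
5.0 A in steps of 0.2 A along z - 13 x 13 x 16 = 2704 points, endpoints
inclusive.

No energies are computed here: every point is emitted as an XYZ geometry
(acetamide posed with its N constrained to the lattice site) for an
external quantum-chemistry engine, and tabulated energies are ingested
back and projected against the derived six-parameter geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    AmideDonor,
    GeometryConfig,
    GeometryError,
    PairGeometry,
    build_ring_frame,
    compute_pair_geometry,
)
from .structure import Residue

__all__ = [
    "GridSpec",
    "GridPoint",
    "EnergySurface",
    "TolueneFrame",
    "build_toluene_frame",
    "generate_scan_grid",
    "write_scan_directory",
    "attach_energies_and_project",
]


@dataclass
class GridSpec:
    """Inclusive lattice ranges (A) in the toluene frame."""

    x_start: float = 0.0
    x_stop: float = 4.8
    x_step: float = 0.4
    y_start: float = 0.0
    y_stop: float = 4.8
    y_step: float = 0.4
    z_start: float = 2.0
    z_stop: float = 5.0
    z_step: float = 0.2

    def __post_init__(self) -> None:
        for ax in ("x", "y", "z"):
            if getattr(self, f"{ax}_step") <= 0:
                raise ValueError(f"{ax}_step must be positive")
            if getattr(self, f"{ax}_stop") < getattr(self, f"{ax}_start"):
                raise ValueError(f"empty {ax} range")

    def _axis(self, ax: str) -> np.ndarray:
        start = getattr(self, f"{ax}_start")
        stop = getattr(self, f"{ax}_stop")
        step = getattr(self, f"{ax}_step")
        n = int(round((stop - start) / step)) + 1
        return start + step * np.arange(n)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(len(self._axis(ax)) for ax in "xyz")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz


@dataclass
class TolueneFrame:
    origin: np.ndarray  # C1 position
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def to_world(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (
            self.origin
            + np.outer(xyz[..., 0], self.x_axis).reshape(xyz.shape)
            + np.outer(xyz[..., 1], self.y_axis).reshape(xyz.shape)
            + np.outer(xyz[..., 2], self.z_axis).reshape(xyz.shape)
        )

    def to_frame(self, world: np.ndarray) -> np.ndarray:
        R = np.column_stack([self.x_axis, self.y_axis, self.z_axis])
        return (np.asarray(world, dtype=float) - self.origin) @ R


@dataclass
class GridPoint:
    index: int
    frame_xyz: tuple[float, float, float]
    n_target: np.ndarray  # world coordinates of the constrained N
    atoms: list[tuple[str, np.ndarray]]  # full complex (toluene + acetamide)
    donor: AmideDonor
    geometry: PairGeometry
    energy: Optional[float] = None


def build_toluene_frame(residue: Residue) -> TolueneFrame:
    """Anchor the scan frame on a toluene residue.

    C1 is the methyl-substituted ring carbon (origin); the x-axis runs
    along the methyl-carbon (CM) -> C1 bond projected into the ring
    plane; z is the ring normal (canonical C1..C6 traversal); y completes
    a right-handed frame.  The frame is rigid-motion covariant: a
    pre-transformed toluene yields the identically transformed frame.
    """
    if "C1" not in residue or "CM" not in residue:
        raise GeometryError("toluene must contain atoms C1 (ring) and CM (methyl)")
    ring = build_ring_frame(residue)
    c1 = residue["C1"].coords
    cm = residue["CM"].coords
    x = c1 - cm
    x = x - np.dot(x, ring.normal_n) * ring.normal_n
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise GeometryError("CM->C1 bond is perpendicular to the ring plane")
    x = x / nx
    z = ring.normal_n
    y = np.cross(z, x)
    return TolueneFrame(origin=c1, x_axis=x, y_axis=y, z_axis=z)


# rigid acetamide internal geometry (A, deg)
_N_C = 1.33
_C_O = 1.23
_C_CM = 1.52
_N_H = 1.0
_ANG_NCO = 122.0
_ANG_NCC = 116.0


def _acetamide_at(
    n_world: np.ndarray, down: np.ndarray, in_plane: np.ndarray
) -> tuple[list[tuple[str, np.ndarray]], AmideDonor]:
    """Acetamide posed with N at ``n_world``.

    ``down`` is the direction the N-H bisector points (toward the ring);
    the amide plane is spanned by ``down`` and ``in_plane``.
    """
    up = -down
    C = n_world + _N_C * up
    # sp2 substituents on the carbonyl carbon, in the amide plane
    co_dir = math.cos(math.radians(_ANG_NCO)) * (-up) + math.sin(
        math.radians(_ANG_NCO)
    ) * in_plane
    cc_dir = math.cos(math.radians(_ANG_NCC)) * (-up) - math.sin(
        math.radians(_ANG_NCC)
    ) * in_plane
    O = C + _C_O * co_dir
    CM = C + _C_CM * cc_dir
    # amide hydrogens: 120 deg from N->C, in plane, bisector along ``down``
    h1 = n_world + _N_H * (-0.5 * up + (math.sqrt(3) / 2) * in_plane)
    h2 = n_world + _N_H * (-0.5 * up - (math.sqrt(3) / 2) * in_plane)
    atoms = [("N", n_world), ("C", C), ("O", O), ("CM", CM)]
    donor = AmideDonor(
        N_pos=n_world,
        H_positions=np.array([h1, h2]),
        Cgamma_pos=CM,
        Cdelta_pos=C,
        parent=("ACM", 1, ""),
    )
    return atoms, donor


def generate_scan_grid(
    spec: Optional[GridSpec] = None,
    toluene: Optional[Residue] = None,
    config: Optional[GeometryConfig] = None,
) -> list[GridPoint]:
    """One posed acetamide-toluene complex per lattice site.

    The acetamide N is constrained to the site; the molecule starts in a
    canonical orientation (N-H bisector toward -z, amide plane containing
    the z- and x-axes).  Derived six-parameter geometry is attached to
    every point.  Iteration order is x-major, then y, then z; indices are
    sequential from 0.
    """
    from .synthetic import make_ideal_ring  # deferred: avoids module cycle

    spec = spec or GridSpec()
    config = config or GeometryConfig()
    if toluene is None:
        toluene = make_ideal_ring("toluene")
    frame = build_toluene_frame(toluene)
    ring = build_ring_frame(toluene)
    tol_atoms = [(a.element or a.name[0], a.coords) for a in toluene.atoms]

    points: list[GridPoint] = []
    index = 0
    down = -frame.z_axis
    in_plane = frame.x_axis
    for x in spec._axis("x"):
        for y in spec._axis("y"):
            for z in spec._axis("z"):
                n_world = frame.to_world(np.array([x, y, z]))
                ac_atoms, donor = _acetamide_at(n_world, down, in_plane)
                geom = compute_pair_geometry(donor, ring, config)
                elements = [
                    *tol_atoms,
                    ("N", ac_atoms[0][1]),
                    ("C", ac_atoms[1][1]),
                    ("O", ac_atoms[2][1]),
                    ("C", ac_atoms[3][1]),
                ]
                points.append(
                    GridPoint(
                        index=index,
                        frame_xyz=(float(x), float(y), float(z)),
                        n_target=n_world,
                        atoms=elements,
                        donor=donor,
                        geometry=geom,
                    )
                )
                index += 1
    return points


def _xyz_text(point: GridPoint, comment: str) -> str:
    lines = [str(len(point.atoms)), comment]
    for el, c in point.atoms:
        lines.append(f"{el:<2s} {c[0]:12.6f} {c[1]:12.6f} {c[2]:12.6f}")
    return "\n".join(lines) + "\n"


def write_scan_directory(points: Sequence[GridPoint], outdir) -> Path:
    """Emit one XYZ file per grid point plus a TSV manifest.

    The manifest maps grid index -> filename -> frame coordinates and the
    constrained world-space N position, so any external engine can be run
    and its energies joined back by index.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in points:
        fname = f"point_{p.index:05d}.xyz"
        x, y, z = p.frame_xyz
        comment = f"grid index {p.index} frame x={x:.3f} y={y:.3f} z={z:.3f}"
        (outdir / fname).write_text(_xyz_text(p, comment))
        rows.append(
            {
                "index": p.index,
                "filename": fname,
                "x": x,
                "y": y,
                "z": z,
                "n_x": p.n_target[0],
                "n_y": p.n_target[1],
                "n_z": p.n_target[2],
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return outdir


@dataclass
class EnergySurface:
    table: pd.DataFrame  # index, frame coords, six parameters, energy
    global_minimum: pd.Series
    n_missing: int
    envelope_d_NM: pd.DataFrame  # min-energy envelope vs d_NM (theta-filtered)
    projection: pd.DataFrame  # energy vs tau (angular-filtered)
    filters: dict


def attach_energies_and_project(
    points: Sequence[GridPoint],
    energies: Mapping[int, float] | pd.DataFrame,
    theta_range: tuple[float, float] = (0.0, 20.0),
    angle_filter_on: str = "chi",
    angle_range: tuple[float, float] = (40.0, 50.0),
    envelope_bin: float = 0.1,
) -> EnergySurface:
    """Join ingested energies onto the grid and build the projections.

    * global minimum over points with energies (ties -> first index);
    * minimum-energy envelope vs d_NM over points with ``theta`` inside
      ``theta_range`` (open interval), binned at ``envelope_bin`` A;
    * energy vs tau over points whose ``angle_filter_on`` parameter
      (``"chi"`` or ``"tau"``; both conventions are in circulation) lies
      inside ``angle_range`` (open interval).

    Points without an energy are excluded; their count is reported.
    """
    if angle_filter_on not in ("chi", "tau"):
        raise ValueError("angle_filter_on must be 'chi' or 'tau'")
    if isinstance(energies, pd.DataFrame):
        energies = dict(zip(energies["index"].astype(int), energies["energy"]))

    rows = []
    n_missing = 0
    for p in points:
        e = energies.get(p.index)
        if e is None:
            n_missing += 1
            continue
        x, y, z = p.frame_xyz
        rows.append(
            {
                "index": p.index,
                "x": x,
                "y": y,
                "z": z,
                **p.geometry.as_dict(),
                "energy": float(e),
            }
        )
    if not rows:
        raise ValueError("no grid points carry energies")
    table = pd.DataFrame(rows)

    imin = int(table["energy"].idxmin())  # idxmin: first occurrence on ties
    gmin = table.loc[imin]

    th = table[(table["theta"] > theta_range[0]) & (table["theta"] < theta_range[1])]
    if len(th):
        bins = (th["d_NM"] / envelope_bin).round().astype(int)
        env = (
            th.assign(_bin=bins)
            .groupby("_bin", as_index=False)
            .apply(
                lambda g: g.loc[g["energy"].idxmin(), ["d_NM", "energy"]],
                include_groups=False,
            )
            .sort_values("d_NM")
            .reset_index(drop=True)
        )
    else:
        env = pd.DataFrame(columns=["d_NM", "energy"])

    ang = table[
        (table[angle_filter_on] > angle_range[0])
        & (table[angle_filter_on] < angle_range[1])
    ]
    projection = ang[["tau", "d_CgPi", "energy"]].reset_index(drop=True)

    return EnergySurface(
        table=table,
        global_minimum=gmin,
        n_missing=n_missing,
        envelope_d_NM=env,
        projection=projection,
        filters={
            "theta_range": theta_range,
            "angle_filter_on": angle_filter_on,
            "angle_range": angle_range,
        },
    )
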