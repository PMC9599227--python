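"""Synthetic fixtures: ideal rings, planted donor-ring pairs, decoy
structures, trajectories with a planted cutoff occupancy, and two-state
melting curves.

Every generator is deterministic given its seed.  ``plant_pair_fragment``
is the constructive inverse of the six-parameter definitions: it places a
rigid amide fragment around an ideal ring so that the measured pair
geometry reproduces the requested parameters, or rejects the request with
the violated constraint named.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.spatial.transform import Rotation

from .geometry import (
    GeometryConfig,
    PairGeometry,
    build_amide_donor,
    build_ring_frame,
    compute_pair_geometry,
)
from .structure import Atom, Chain, Model, Residue, Structure

__all__ = [
    "PlantSpec",
    "PlantedPair",
    "PlantInfeasibleError",
    "make_ideal_ring",
    "plant_pair_fragment",
    "generate_decoy_structure",
    "generate_trajectory",
    "generate_melt_curve",
]

RING_RADIUS = 1.39  # aromatic C-C bond length = circumradius, A
CB_CG = 1.51  # A, exocyclic substituent bond
N_CD = 1.33  # amide N-C, A
CD_CG = 1.52  # carbonyl C - alpha-side C, A
CD_OE = 1.23  # C=O, A
ANG_N_CD_CG = 116.0  # deg
ANG_N_CD_OE = 122.0  # deg

_TOL = 1e-7  # planting acceptance tolerance (A, deg)


class PlantInfeasibleError(ValueError):
    """Raised when a requested parameter combination cannot be built."""


@dataclass
class PlantSpec:
    """Target geometry for a planted donor-ring pair.

    ``d_NM``/``theta`` are required; ``omega``, ``tau`` and ``chi`` are
    optional targets.  ``azimuth`` rotates the under-determined N position
    about the ring normal; ``jitter`` is a per-coordinate Gaussian sigma
    applied after construction (A).
    """

    d_NM: float
    theta: float
    omega: Optional[float] = None
    tau: Optional[float] = None
    chi: Optional[float] = None
    azimuth: float = 0.0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.d_NM <= 0:
            raise ValueError("d_NM must be positive")
        if not 0 <= self.theta <= 90:
            raise ValueError("theta must be in [0, 90] deg")
        if self.omega is not None and not 0 < self.omega <= 180:
            raise ValueError("omega must be in (0, 180] deg")
        if self.tau is not None and not -90 <= self.tau <= 90:
            raise ValueError("tau must be in [-90, 90] deg")
        if self.chi is not None and not 0 <= self.chi <= 180:
            raise ValueError("chi must be in [0, 180] deg")

    def requested(self) -> dict[str, float]:
        out = {"d_NM": self.d_NM, "theta": self.theta}
        for name in ("omega", "tau", "chi"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        return out


@dataclass
class PlantedPair:
    donor_residue: Residue
    ring_residue: Residue
    geometry: PairGeometry
    spec: PlantSpec

    def residues(self) -> tuple[Residue, Residue]:
        return self.donor_residue, self.ring_residue


def _apply_pose(coords: np.ndarray, pose) -> np.ndarray:
    if pose is None:
        return coords
    R, t = pose
    return coords @ np.asarray(R).T + np.asarray(t)


def _mk_residue(resname: str, seqnum: int, names, coords, serial0: int = 1) -> Residue:
    atoms = [
        Atom(
            name=n,
            element="C" if n.startswith("C") else n[0],
            serial=serial0 + i,
            coords=c,
        )
        for i, (n, c) in enumerate(zip(names, coords))
    ]
    return Residue(resname=resname, seqnum=seqnum, atoms=atoms)


def make_ideal_ring(
    kind: str = "benzene", pose=None, seqnum: int = 1
) -> Residue:
    """Ideal planar six-carbon ring, C-C = 1.39 A.

    ``benzene``: C1..C6 hexagon centred at the origin, normal +z.
    ``phenylalanine``: PHE naming (CG..CD2) centred at the origin with CB
    in-plane at 1.51 A from CG (so the Cbeta->Cgamma substituent vector is
    defined).  ``toluene``: C1..C6 + methyl CM in the canonical scan pose,
    C1 at the origin and CM at (-1.51, 0, 0).  ``pose`` is an optional
    rigid transform ``(R, t)``.
    """
    hexagon = lambda phases, center: [
        center + RING_RADIUS * np.array([math.cos(p), math.sin(p), 0.0])
        for p in np.radians(phases)
    ]
    if kind == "benzene":
        names = ["C1", "C2", "C3", "C4", "C5", "C6"]
        coords = hexagon(60.0 * np.arange(6), np.zeros(3))
        resname = "BNZ"
    elif kind == "phenylalanine":
        names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2", "CB"]
        coords = hexagon(60.0 * np.arange(6), np.zeros(3))
        coords.append(np.array([RING_RADIUS + CB_CG, 0.0, 0.0]))
        resname = "PHE"
    elif kind == "toluene":
        names = ["C1", "C2", "C3", "C4", "C5", "C6", "CM"]
        center = np.array([RING_RADIUS, 0.0, 0.0])
        coords = hexagon(180.0 + 60.0 * np.arange(6), center)
        coords.append(np.array([-CB_CG, 0.0, 0.0]))
        resname = "TOL"
    else:
        raise ValueError(f"unknown ring kind {kind!r}")
    coords = _apply_pose(np.array(coords), pose)
    return _mk_residue(resname, seqnum, names, coords)


def _perp(v: np.ndarray) -> np.ndarray:
    """Some unit vector perpendicular to v."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(v, ref)) > 0.9 * np.linalg.norm(v):
        ref = np.array([1.0, 0.0, 0.0])
    w = np.cross(v, ref)
    return w / np.linalg.norm(w)


def _solve_alpha(d: float, omega_deg: float) -> float:
    """Angle between N->H and N->M so that the N-H...M angle at H is omega.

    Law-of-cosines route: with |NH| = 1 and |NM| = d, the angle at H is
    omega(alpha) = acos((1 - d cos a) / sqrt(d^2 - 2 d cos a + 1)).
    """
    if omega_deg == 180.0:
        return 0.0  # H on the N-M segment
    target = math.cos(math.radians(omega_deg))

    def f(cos_a: float) -> float:
        denom = math.sqrt(max(d * d - 2 * d * cos_a + 1.0, 1e-300))
        return (1.0 - d * cos_a) / denom - target

    lo, hi = -1.0 + 1e-12, 1.0 - 1e-12
    if f(lo) * f(hi) > 0:
        raise PlantInfeasibleError(
            f"omega = {omega_deg} deg unreachable at d_NM = {d} A"
        )
    return math.acos(brentq(f, lo, hi, xtol=1e-15))


def _build_donor_atoms(
    N: np.ndarray,
    M: np.ndarray,
    alpha: Optional[float],
    phi_h: float,
    phi_a: float,
    side: float,
) -> dict[str, np.ndarray]:
    """Rigid amide fragment given the free orientation angles.

    ``alpha`` orients the reference N-H bond relative to N->M (None means
    no omega target: the amide C points straight away from the ring along
    M->N).  ``phi_h`` spins H about the N-M axis, ``phi_a`` spins the
    amide plane about the N-H bond, ``side`` picks the Cgamma branch.
    """
    m_hat = (M - N) / np.linalg.norm(M - N)
    if alpha is None:
        c_hat = -m_hat  # N->C away from the ring
        p0 = _perp(c_hat)
        q_hat = math.cos(phi_a) * p0 + math.sin(phi_a) * np.cross(c_hat, p0)
    else:
        p0 = _perp(m_hat)
        p_hat = math.cos(phi_h) * p0 + math.sin(phi_h) * np.cross(m_hat, p0)
        h_hat = math.cos(alpha) * m_hat + math.sin(alpha) * p_hat
        q0 = _perp(h_hat)
        q_hat = math.cos(phi_a) * q0 + math.sin(phi_a) * np.cross(h_hat, q0)
        # amide C at 120 deg from the reference H, in the plane (h, q)
        c_hat = -0.5 * h_hat + (math.sqrt(3) / 2) * q_hat
        q_hat = (h_hat + 0.5 * c_hat) / (math.sqrt(3) / 2)  # in-plane perp of c_hat

    CD = N + N_CD * c_hat
    nd_hat = -c_hat  # CD -> N direction
    plane_n = np.cross(c_hat, q_hat)
    plane_n /= np.linalg.norm(plane_n)
    r_hat = np.cross(plane_n, nd_hat)
    CG = CD + CD_CG * (
        math.cos(math.radians(ANG_N_CD_CG)) * nd_hat
        + side * math.sin(math.radians(ANG_N_CD_CG)) * r_hat
    )
    OE = CD + CD_OE * (
        math.cos(math.radians(ANG_N_CD_OE)) * nd_hat
        - side * math.sin(math.radians(ANG_N_CD_OE)) * r_hat
    )
    return {"CG": CG, "CD": CD, "OE1": OE, "NE2": N}


def plant_pair_fragment(
    spec: PlantSpec,
    config: Optional[GeometryConfig] = None,
    rng: Optional[np.random.Generator] = None,
    donor_seqnum: int = 1,
    ring_seqnum: int = 2,
) -> PlantedPair:
    """Build a Gln-like donor and Phe-like ring realising ``spec``.

    The ring sits in its canonical frame (centroid at the origin, normal
    +z, substituent along +x).  N is placed exactly on the
    (d_NM, theta, azimuth) cone; the reference hydrogen orientation is
    solved in closed form for omega; the two remaining rigid-body spins
    are tuned numerically when tau and/or chi are requested.  The result
    is verified by measurement and rejected (:class:`PlantInfeasibleError`)
    when any requested parameter cannot be reproduced to 1e-7 - e.g. an
    omega so small that the second amide hydrogen necessarily beats it.
    """
    config = config or GeometryConfig()
    ring_res = make_ideal_ring("phenylalanine", seqnum=ring_seqnum)
    ring = build_ring_frame(ring_res)
    M = ring.center_M

    th = math.radians(spec.theta)
    az = math.radians(spec.azimuth)
    # theta folds to the acute angle, so either side of the plane realises
    # it; a negative tau target needs N (and Cgamma) below the ring plane
    z_sign = -1.0 if (spec.tau is not None and spec.tau < 0) else 1.0
    N = M + spec.d_NM * np.array(
        [
            math.sin(th) * math.cos(az),
            math.sin(th) * math.sin(az),
            z_sign * math.cos(th),
        ]
    )
    alpha = None if spec.omega is None else _solve_alpha(spec.d_NM, spec.omega)

    targets = spec.requested()
    tunable = [k for k in ("omega", "tau", "chi") if k in targets]
    # with no omega target the reference-H tilt alpha is a free variable
    free_alpha = spec.omega is None and bool(tunable)

    def measure(x, side: float):
        if free_alpha:
            a, phi_h, phi_a = x
        else:
            a, (phi_h, phi_a) = alpha, x
        atoms = _build_donor_atoms(N, M, a, phi_h, phi_a, side)
        res = _mk_residue("GLN", donor_seqnum, atoms.keys(), atoms.values())
        donor = build_amide_donor(res, config)
        return res, donor, compute_pair_geometry(donor, ring, config)

    def residuals(x, side):
        _, _, geom = measure(x, side)
        vals = geom.as_dict()
        out = []
        for k in tunable:
            v = vals[k]
            out.append(1e3 if math.isnan(v) else v - targets[k])
        return out if out else [0.0]

    spins = (0.0, math.pi / 2, math.pi, 3 * math.pi / 2)
    alphas = (math.pi / 3, 2 * math.pi / 3) if free_alpha else (None,)
    best = None
    for side in (1.0, -1.0):
        for a0 in alphas:
            for ph in spins:
                for pa in spins:
                    x0 = [a0, ph, pa] if free_alpha else [ph, pa]
                    if tunable:
                        # the closed-form construction is often already exact
                        r0 = float(np.max(np.abs(residuals(x0, side))))
                        if r0 < _TOL:
                            best = (r0, x0, side)
                            break
                        sol = least_squares(
                            residuals,
                            x0=x0,
                            args=(side,),
                            xtol=1e-15,
                            ftol=1e-15,
                            gtol=1e-15,
                        )
                        cand = (float(np.max(np.abs(sol.fun))), list(sol.x), side)
                    else:
                        cand = (0.0, x0, side)
                    if best is None or cand[0] < best[0]:
                        best = cand
                    if best[0] < _TOL:
                        break
                if best[0] < _TOL:
                    break
            if best[0] < _TOL:
                break
        if best[0] < _TOL:
            break

    err, x_best, side = best
    donor_res, donor, geom = measure(x_best, side)
    vals = geom.as_dict()
    worst_name = max(targets, key=lambda k: abs(vals[k] - targets[k]))
    worst = abs(vals[worst_name] - targets[worst_name])
    if worst > _TOL:
        raise PlantInfeasibleError(
            f"cannot realise {worst_name} = {targets[worst_name]:.3f} "
            f"(best achievable differs by {worst:.3g}; "
            f"requested {targets})"
        )

    if spec.jitter > 0:
        if rng is None:
            rng = np.random.default_rng()
        for res in (donor_res, ring_res):
            for atom in res.atoms:
                atom.coords = atom.coords + rng.normal(0.0, spec.jitter, 3)
        donor = build_amide_donor(donor_res, config)
        geom = compute_pair_geometry(donor, build_ring_frame(ring_res), config)

    return PlantedPair(
        donor_residue=donor_res, ring_residue=ring_res, geometry=geom, spec=spec
    )


# ---------------------------------------------------------------------------
# structures


def _transform_residue(res: Residue, R: np.ndarray, t: np.ndarray) -> Residue:
    atoms = [
        Atom(
            name=a.name,
            element=a.element,
            serial=a.serial,
            coords=R @ a.coords + t,
            altloc=a.altloc,
            occupancy=a.occupancy,
            bfactor=a.bfactor,
            is_hetero=a.is_hetero,
        )
        for a in res.atoms
    ]
    return Residue(resname=res.resname, seqnum=res.seqnum, icode=res.icode, atoms=atoms)


_GLY_TEMPLATE = {
    "N": np.array([-0.57, 1.29, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.52, 0.07, 0.0]),
    "O": np.array([2.15, 1.12, 0.15]),
}


def _gly_filler(seqnum: int, origin: np.ndarray) -> Residue:
    names = list(_GLY_TEMPLATE)
    coords = [origin + _GLY_TEMPLATE[n] for n in names]
    res = _mk_residue("GLY", seqnum, names, coords)
    for a in res.atoms:
        a.element = a.name[0]
    return res


def _sample_pass_spec(rng: np.random.Generator) -> PlantSpec:
    # margins >= 0.2 A / 5 deg inside the cutoffs
    return PlantSpec(
        d_NM=rng.uniform(2.9, 4.05),
        theta=rng.uniform(2.0, 19.5),
        omega=rng.uniform(126.0, 172.0),
        azimuth=rng.uniform(0.0, 360.0),
    )


def _sample_fail_spec(rng: np.random.Generator) -> PlantSpec:
    # margins >= 0.2 A / 5 deg outside at least one cutoff
    mode = rng.integers(3)
    if mode == 0:  # distance failure (also beyond the enumeration radius)
        return PlantSpec(
            d_NM=rng.uniform(4.8, 7.4),
            theta=rng.uniform(2.0, 19.5),
            omega=rng.uniform(126.0, 172.0),
            azimuth=rng.uniform(0.0, 360.0),
        )
    if mode == 1:  # theta failure
        return PlantSpec(
            d_NM=rng.uniform(2.9, 4.05),
            theta=rng.uniform(30.5, 65.0),
            omega=rng.uniform(126.0, 172.0),
            azimuth=rng.uniform(0.0, 360.0),
        )
    return PlantSpec(  # omega failure
        d_NM=rng.uniform(2.9, 4.05),
        theta=rng.uniform(2.0, 19.5),
        omega=rng.uniform(95.0, 114.5),
        azimuth=rng.uniform(0.0, 360.0),
    )


def _plant_with_retry(sample, rng: np.random.Generator, tries: int = 20) -> PlantedPair:
    for _ in range(tries):
        try:
            return plant_pair_fragment(sample(rng))
        except PlantInfeasibleError:
            continue
    raise PlantInfeasibleError("could not sample a feasible plant spec")


_CELL = 26.0  # A between planted fragments; keeps cross-pair d_NM > 4.5 A


def _cell_origin(k: int, n_total: int) -> np.ndarray:
    m = max(1, math.ceil(n_total ** (1.0 / 3.0)))
    ix, rem = divmod(k, m * m)
    iy, iz = divmod(rem, m)
    return _CELL * np.array([ix, iy, iz], dtype=float)


def generate_decoy_structure(
    n_pass: int, n_fail: int, seed: int, with_filler: bool = True
) -> Structure:
    """Structure embedding planted passing and failing Gln-Phe pairs.

    Passing pairs are sampled with >= 0.2 A / 5 deg margins inside every
    cutoff, failing pairs outside at least one; fragments are isolated on
    a 26 A lattice so no cross-pair contact can screen.  Glycine filler
    residues keep donors/rings the only candidates.  Deterministic per
    seed (byte-identical PDB output).
    """
    if n_pass < 0 or n_fail < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    n_total = n_pass + n_fail
    residues: list[Residue] = []
    seq = 1
    for k in range(n_total):
        sampler = _sample_pass_spec if k < n_pass else _sample_fail_spec
        pair = _plant_with_retry(sampler, rng)
        R = Rotation.random(random_state=rng).as_matrix()
        t = _cell_origin(k, n_total + 1)
        d = _transform_residue(pair.donor_residue, R, t)
        r = _transform_residue(pair.ring_residue, R, t)
        d.seqnum, r.seqnum = seq, seq + 1
        residues.extend([d, r])
        seq += 2
        if with_filler:
            residues.append(_gly_filler(seq, t + np.array([0.0, 0.0, 10.0])))
            seq += 1

    serial = 1
    for res in residues:
        for a in res.atoms:
            a.serial = serial
            serial += 1
    chain = Chain(chain_id="A", residues=residues)
    return Structure(models=[Model(index=1, chains=[chain])], id="DECO")


def generate_trajectory(
    n_frames: int,
    pass_fraction: float,
    noise_sigma: float = 0.02,
    seed: int = 0,
    pass_spec: Optional[PlantSpec] = None,
    fail_spec: Optional[PlantSpec] = None,
) -> Structure:
    """Multi-model structure of one Gln-Phe pair with planted occupancy.

    Exactly ``floor(pass_fraction * n_frames)`` frames (a seeded random
    subset) carry in-cutoff geometry; the rest are planted outside the
    cutoffs.  Gaussian coordinate jitter of ``noise_sigma`` A is applied
    per frame.
    """
    if not 0.0 <= pass_fraction <= 1.0:
        raise ValueError("pass_fraction must be in [0, 1]")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    pass_spec = pass_spec or PlantSpec(d_NM=3.3, theta=8.4, omega=159.2)
    fail_spec = fail_spec or PlantSpec(d_NM=6.0, theta=40.0, omega=150.0)
    base = {
        True: plant_pair_fragment(pass_spec),
        False: plant_pair_fragment(fail_spec),
    }
    n_pass = math.floor(pass_fraction * n_frames)
    pass_frames = set(rng.choice(n_frames, size=n_pass, replace=False).tolist())

    models = []
    for i in range(n_frames):
        pair = base[i in pass_frames]
        residues = []
        for res, seqnum in zip(pair.residues(), (1, 2)):
            moved = _transform_residue(res, np.eye(3), np.zeros(3))
            moved.seqnum = seqnum
            if noise_sigma > 0:
                for a in moved.atoms:
                    a.coords = a.coords + rng.normal(0.0, noise_sigma, 3)
            residues.append(moved)
        serial = 1
        for res in residues:
            for a in res.atoms:
                a.serial = serial
                serial += 1
        models.append(Model(index=i + 1, chains=[Chain("A", residues)]))
    return Structure(models=models, id="TRAJ")


# ---------------------------------------------------------------------------
# melting curves


def generate_melt_curve(
    tm: float = 40.0,
    amplitude: float = 2500.0,
    baseline_slope: float = -6.0,
    baseline_intercept: float = 500.0,
    gap_slope: float = -0.004,
    width: float = 1.5,
    t_start: float = 4.0,
    t_stop: float = 80.0,
    t_step: float = 0.5,
    noise_sigma: float = 0.0,
    seed: Optional[int] = None,
):
    """Two-state sigmoidal melting curve with linear baselines.

    The unfolded baseline is ``baseline_intercept + baseline_slope * T``;
    the folded state sits ``amplitude * (1 + gap_slope * T)`` above it;
    the folded fraction is a logistic of ``width`` (deg C) centred on
    ``tm``.  Gaussian noise of ``noise_sigma`` (signal units) is seeded.
    Returns (temperatures, ellipticities) arrays.
    """
    if not t_start < tm < t_stop:
        raise ValueError("tm must lie inside the temperature range")
    T = np.arange(t_start, t_stop + 0.5 * t_step, t_step)
    theta_u = baseline_intercept + baseline_slope * T
    gap = amplitude * (1.0 + gap_slope * T)
    F = 1.0 / (1.0 + np.exp((T - tm) / width))
    y = theta_u + F * gap
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, size=T.shape)
    return T, y
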