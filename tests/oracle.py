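"""Independent brute-force implementation of the six pair parameters.

Deliberately coded from the definitions along different numerical routes
than the package: Newell summation for the ring normal (not SVD), the
law of cosines for the N-H...M angle (not direct vectors), Rodrigues
rotation for hydrogen placement (not an in-plane basis), and an explicit
projector matrix for the in-plane azimuth.  Used only as a test oracle.
"""

import math

import numpy as np


def _ang(u, v):
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _rodrigues(v, axis, angle_deg):
    k = axis / np.linalg.norm(axis)
    t = math.radians(angle_deg)
    return (
        v * math.cos(t)
        + np.cross(k, v) * math.sin(t)
        + k * np.dot(k, v) * (1 - math.cos(t))
    )


def oracle_hydrogens(N, CD, OE1, bond_length=1.0):
    """Amide hydrogens by Rodrigues rotation of the C->N bond direction."""
    p = np.cross(OE1 - CD, N - CD)
    u = (N - CD) / np.linalg.norm(N - CD)
    return [N + bond_length * _rodrigues(u, p, s * 60.0) for s in (+1, -1)]


def oracle_six_params(ring_xyz, cb, cg_ring, N, hydrogens, CG, mode="centroid"):
    """The six parameters straight from their definitions.

    ring_xyz: (6, 3) ring carbons in canonical traversal order;
    cb, cg_ring: substituent bond tail/head; hydrogens: two H positions.
    """
    ring_xyz = np.asarray(ring_xyz, dtype=float)
    M = ring_xyz.mean(axis=0)
    centered = ring_xyz - M
    normal = np.zeros(3)
    for i in range(6):
        normal += np.cross(centered[i], centered[(i + 1) % 6])
    normal /= np.linalg.norm(normal)

    v = N - M
    d_NM = float(np.linalg.norm(v))
    theta = min(_ang(v, normal), _ang(v, -normal))

    omegas = []
    for H in hydrogens:
        a = np.linalg.norm(N - H)
        b = np.linalg.norm(M - H)
        c = np.linalg.norm(N - M)
        cosw = (a * a + b * b - c * c) / (2 * a * b)
        omegas.append(math.degrees(math.acos(max(-1.0, min(1.0, cosw)))))
    omega = max(omegas)

    w = CG - M
    if mode == "centroid":
        d_cg = float(np.linalg.norm(w))
    else:
        d_cg = float(abs(np.dot(w, normal)))
    tau = 90.0 - _ang(normal, w)

    P = np.eye(3) - np.outer(normal, normal)
    u_p = P @ (N - CG)
    s_p = P @ (np.asarray(cg_ring) - np.asarray(cb))
    if np.linalg.norm(u_p) < 1e-9 or np.linalg.norm(s_p) < 1e-9:
        chi = float("nan")
    else:
        chi = _ang(u_p, s_p)

    return {
        "d_NM": d_NM,
        "theta": theta,
        "omega": omega,
        "d_CgPi": d_cg,
        "tau": tau,
        "chi": chi,
    }


def compare_implementations(n_placements: int, seed: int) -> float:
    """Worst |implementation - oracle| over random rigid placements."""
    from scipy.spatial.transform import Rotation

    from nhpi.geometry import (
        build_amide_donor,
        build_ring_frame,
        compute_pair_geometry,
    )
    from nhpi.synthetic import make_ideal_ring
    from nhpi.structure import Atom, Residue

    rng = np.random.default_rng(seed)
    gln_coords = np.array(
        [[-1.39, -0.76, 0.0], [0.0, 0.0, 0.0], [-0.6, 1.2, 0.0], [1.33, 0.0, 0.0]]
    )
    names = ["CG", "CD", "OE1", "NE2"]
    order = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")

    worst = 0.0
    done = 0
    while done < n_placements:
        Rr = Rotation.random(random_state=rng).as_matrix()
        ring_res = make_ideal_ring("phenylalanine", pose=(Rr, rng.uniform(-5, 5, 3)))
        Rd = Rotation.random(random_state=rng).as_matrix()
        td = rng.uniform(-8, 8, 3)
        donor_res = Residue(
            resname="GLN",
            seqnum=1,
            atoms=[
                Atom(name=nm, element=nm[0], serial=i + 1, coords=Rd @ c + td)
                for i, (nm, c) in enumerate(zip(names, gln_coords))
            ],
        )
        ring = build_ring_frame(ring_res)
        donor = build_amide_donor(donor_res)
        if np.linalg.norm(donor.N_pos - ring.center_M) < 0.5:
            continue
        geom = compute_pair_geometry(donor, ring).as_dict()
        expected = oracle_six_params(
            np.array([ring_res[nm].coords for nm in order]),
            cb=ring_res["CB"].coords,
            cg_ring=ring_res["CG"].coords,
            N=donor_res["NE2"].coords,
            hydrogens=oracle_hydrogens(
                donor_res["NE2"].coords,
                donor_res["CD"].coords,
                donor_res["OE1"].coords,
            ),
            CG=donor_res["CG"].coords,
        )
        for key, val in expected.items():
            if math.isnan(val):
                assert math.isnan(geom[key])
                continue
            worst = max(worst, abs(geom[key] - val))
        done += 1
    return worst
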