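"""Pair enumeration, NH-pi cutoff screening and collagen register labels.

The screening criteria for a genuine NH-pi contact are strict
inequalities on the three bond-conformation parameters:

    d_NM < 4.3 A,  theta < 25 deg,  omega > 120 deg

Candidate pairs are first enumerated with a looser centroid distance
(d_NM <= 4.5 A by default) so near-miss geometry is retained for
population statistics.  In collagen triple helices each passing pair is
additionally labelled by register: an inter-chain Y-X contact within the
same Gly-X-Y triplet is *lateral*, a Y-X' contact with the next triplet of
the following chain (leading -> middle -> trailing) is *axial*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    GeometryConfig,
    GeometryError,
    PairGeometry,
    build_amide_donor,
    build_ring_frame,
    compute_pair_geometry,
)
from .structure import Model, Residue, Structure

__all__ = [
    "ScreenConfig",
    "PairRecord",
    "DatasetEntry",
    "enumerate_candidate_pairs",
    "screen_pairs",
    "screen_summary",
    "classify_collagen_register",
    "infer_chain_roles",
    "filter_dataset_entries",
    "records_to_frame",
]


@dataclass
class ScreenConfig:
    enumeration_dmax: float = 4.5
    cutoff_d_NM: float = 4.3
    cutoff_theta: float = 25.0
    cutoff_omega: float = 120.0
    donor_resnames: tuple[str, ...] = ("GLN",)
    ring_resnames: tuple[str, ...] = ("PHE",)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)

    def __post_init__(self) -> None:
        if self.enumeration_dmax < self.cutoff_d_NM:
            raise ValueError("enumeration_dmax must be >= cutoff_d_NM")
        if min(self.cutoff_d_NM, self.cutoff_theta, self.cutoff_omega) <= 0:
            raise ValueError("cutoffs must be positive")

    def passes(self, geom: PairGeometry) -> bool:
        return (
            geom.d_NM < self.cutoff_d_NM
            and geom.theta < self.cutoff_theta
            and geom.omega > self.cutoff_omega
        )


@dataclass
class PairRecord:
    geometry: PairGeometry
    donor_chain: str
    ring_chain: str
    pass_flag: Optional[bool] = None
    register: str = "n/a"

    @property
    def donor_address(self) -> tuple:
        return (self.donor_chain, *self.geometry.donor_address)

    @property
    def ring_address(self) -> tuple:
        return (self.ring_chain, *self.geometry.ring_address)


@dataclass
class DatasetEntry:
    entry_id: str
    resolution: Optional[float] = None
    r_factor: Optional[float] = None
    min_chain_length: Optional[int] = None
    experimental: bool = True
    full_coordinates: bool = True
    representative_chains: tuple[str, ...] = ()


def _iter_named_residues(
    model: Model, resnames: Sequence[str]
) -> Iterable[tuple[str, Residue]]:
    for chain_id, res in model.residues():
        if res.resname in resnames:
            yield chain_id, res


def enumerate_candidate_pairs(
    structure: Structure,
    config: Optional[ScreenConfig] = None,
    model_index: int = 0,
) -> list[PairRecord]:
    """All donor-ring pairs with d_NM within the enumeration distance.

    One record per (donor residue, ring residue) combination; donor and
    ring must be distinct residues.  Residues lacking the atoms needed for
    the construction are skipped silently (partial side chains).
    """
    config = config or ScreenConfig()
    model = structure.models[model_index]

    donors = []
    for chain_id, res in _iter_named_residues(model, config.donor_resnames):
        try:
            donors.append((chain_id, res, build_amide_donor(res, config.geometry)))
        except GeometryError:
            continue
    rings = []
    for chain_id, res in _iter_named_residues(model, config.ring_resnames):
        try:
            rings.append((chain_id, res, build_ring_frame(res)))
        except GeometryError:
            continue

    records: list[PairRecord] = []
    for d_chain, d_res, donor in donors:
        for r_chain, r_res, ring in rings:
            if d_chain == r_chain and d_res.address == r_res.address:
                continue
            if np.linalg.norm(donor.N_pos - ring.center_M) > config.enumeration_dmax:
                continue
            geom = compute_pair_geometry(donor, ring, config.geometry)
            records.append(PairRecord(geometry=geom, donor_chain=d_chain, ring_chain=r_chain))
    return records


def screen_pairs(
    records: Iterable[PairRecord], config: Optional[ScreenConfig] = None
) -> list[PairRecord]:
    """Set ``pass_flag`` on each record per the strict NH-pi cutoffs."""
    config = config or ScreenConfig()
    return [replace(r, pass_flag=config.passes(r.geometry)) for r in records]


def screen_summary(records: Sequence[PairRecord]) -> dict:
    n = len(records)
    n_pass = sum(1 for r in records if r.pass_flag)
    return {
        "n_candidates": n,
        "n_pass": n_pass,
        "pass_fraction": (n_pass / n) if n else float("nan"),
    }


# ---------------------------------------------------------------------------
# collagen register


def _principal_axis(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[0]


def infer_chain_roles(
    structure: Structure, model_index: int = 0
) -> Optional[dict[str, str]]:
    """Assign leading/middle/trailing roles from the one-residue stagger.

    The helix axis is the principal axis of all C-alpha atoms, oriented
    N-terminus -> C-terminus.  At equal residue numbers the leading chain
    sits one residue rise further toward the C-terminal direction, so the
    chains are ranked by mean axial projection over their shared residue
    numbers (descending: leading, middle, trailing).  Returns None when
    the structure does not look like a three-chain staggered helix.
    """
    model = structure.models[model_index]
    if len(model.chains) != 3:
        return None
    ca: dict[str, dict[int, np.ndarray]] = {}
    for chain in model.chains:
        ca[chain.chain_id] = {
            r.seqnum: r["CA"].coords for r in chain.residues if "CA" in r
        }
    common = set.intersection(*(set(d) for d in ca.values()))
    if len(common) < 6:
        return None
    common = sorted(common)
    all_pts = np.array([ca[c][s] for c in ca for s in common])
    axis = _principal_axis(all_pts)
    # orient axis from N- to C-terminus
    direction = np.mean(
        [ca[c][common[-1]] - ca[c][common[0]] for c in ca], axis=0
    )
    if np.dot(axis, direction) < 0:
        axis = -axis
    mean_proj = {
        c: float(np.mean([ca[c][s] @ axis for s in common])) for c in ca
    }
    spreads = sorted(mean_proj.values())
    if spreads[2] - spreads[0] < 1.0:  # no discernible stagger
        return None
    ranked = sorted(mean_proj, key=mean_proj.get, reverse=True)
    return dict(zip(ranked, ("leading", "middle", "trailing")))


_NEXT_CHAIN = {"leading": "middle", "middle": "trailing"}


def _triplet_position(chain_residues: list[Residue], seqnum: int) -> Optional[tuple[int, str]]:
    """(triplet index, position letter G/X/Y) from the chain's Gly spacing."""
    gly = [r.seqnum for r in chain_residues if r.resname == "GLY"]
    if len(gly) < 2:
        return None
    steps = {b - a for a, b in zip(gly, gly[1:])}
    if steps != {3}:
        return None
    phase = (seqnum - gly[0]) % 3
    letter = {0: "G", 1: "X", 2: "Y"}[phase]
    triplet = (seqnum - gly[0]) // 3
    return triplet, letter


def classify_collagen_register(
    record: PairRecord,
    structure: Structure,
    chain_roles: Optional[dict[str, str]] = None,
    triplet_offset_map: Optional[dict[str, int]] = None,
    model_index: int = 0,
) -> str:
    """Register label for a donor-ring pair in a collagen triple helix.

    Returns ``"axial"`` for a Y-position donor on chain *i* with an
    X-position ring on the next triplet of chain *i+1* (in the
    leading -> middle -> trailing sense), ``"lateral"`` for the
    same-triplet Y-X contact, ``"none"`` for any other collagen pairing
    and ``"n/a"`` when the input is not recognisably a staggered
    three-chain Gly-X-Y helix.
    """
    if chain_roles is None:
        chain_roles = infer_chain_roles(structure, model_index)
    if chain_roles is None:
        return "n/a"
    triplet_offset_map = triplet_offset_map or {}

    model = structure.models[model_index]
    d_chain = model.get_chain(record.donor_chain)
    r_chain = model.get_chain(record.ring_chain)
    if d_chain is None or r_chain is None:
        return "n/a"
    d_pos = _triplet_position(d_chain.residues, record.geometry.donor_address[1])
    r_pos = _triplet_position(r_chain.residues, record.geometry.ring_address[1])
    if d_pos is None or r_pos is None:
        return "n/a"

    d_role = chain_roles.get(record.donor_chain)
    r_role = chain_roles.get(record.ring_chain)
    if d_role is None or r_role is None:
        return "n/a"
    if _NEXT_CHAIN.get(d_role) != r_role:
        return "none"
    if d_pos[1] != "Y" or r_pos[1] != "X":
        return "none"

    d_trip = d_pos[0] + triplet_offset_map.get(record.donor_chain, 0)
    r_trip = r_pos[0] + triplet_offset_map.get(record.ring_chain, 0)
    if r_trip == d_trip:
        return "lateral"
    if r_trip == d_trip + 1:
        return "axial"
    return "none"


# ---------------------------------------------------------------------------
# dataset filtering


def filter_dataset_entries(
    entries: Iterable[DatasetEntry],
    max_resolution: float = 2.0,
    max_r_factor: float = 0.25,
    min_chain_length: int = 40,
) -> tuple[list[DatasetEntry], list[tuple[DatasetEntry, str]]]:
    """Apply the structure-quality filters for dataset assembly.

    Keeps entries with resolution <= 2.0 A, R-factor <= 0.25 and minimum
    chain length >= 40 residues (inclusive bounds), that are experimental
    with full coordinates.  Sequence-identity clustering is *not*
    performed; a precomputed representative-chain list travels with each
    entry untouched.  Returns (accepted, rejected-with-reason).
    """
    accepted: list[DatasetEntry] = []
    rejected: list[tuple[DatasetEntry, str]] = []
    for e in entries:
        if e.resolution is None or e.r_factor is None or e.min_chain_length is None:
            rejected.append((e, "missing metadata"))
        elif not e.experimental:
            rejected.append((e, "not an experimental structure"))
        elif not e.full_coordinates:
            rejected.append((e, "incomplete coordinates"))
        elif e.resolution > max_resolution:
            rejected.append((e, f"resolution {e.resolution:.3f} > {max_resolution}"))
        elif e.r_factor > max_r_factor:
            rejected.append((e, f"R-factor {e.r_factor:.3f} > {max_r_factor}"))
        elif e.min_chain_length < min_chain_length:
            rejected.append(
                (e, f"chain length {e.min_chain_length} < {min_chain_length}")
            )
        else:
            accepted.append(e)
    return accepted, rejected


def records_to_frame(records: Sequence[PairRecord]) -> pd.DataFrame:
    """Tabulate records: addresses, six parameters, pass flag, register."""
    rows = []
    for r in records:
        row = {
            "donor": ":".join(map(str, r.donor_address)),
            "ring": ":".join(map(str, r.ring_address)),
            **r.geometry.as_dict(),
            "h_used": r.geometry.h_used,
            "pass": r.pass_flag,
            "register": r.register,
        }
        rows.append(row)
    return pd.DataFrame(rows)
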