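import numpy as np
import pytest

from nhpi.geometry import PairGeometry
from nhpi.screening import (
    DatasetEntry,
    PairRecord,
    ScreenConfig,
    classify_collagen_register,
    enumerate_candidate_pairs,
    filter_dataset_entries,
    infer_chain_roles,
    screen_pairs,
    screen_summary,
)
from nhpi.structure import Atom, Chain, Model, Residue, Structure
from nhpi.synthetic import PlantSpec, generate_decoy_structure, plant_pair_fragment


def _record(d_nm, theta, omega, donor_chain="A", ring_chain="B",
            donor=("GLN", 5, ""), ring=("PHE", 6, "")):
    geom = PairGeometry(
        d_NM=d_nm, theta=theta, omega=omega, d_CgPi=5.0, tau=50.0, chi=90.0,
        donor_address=donor, ring_address=ring,
    )
    return PairRecord(geometry=geom, donor_chain=donor_chain, ring_chain=ring_chain)


class TestScreening:
    def test_crystal_pair_values_pass(self):
        # published leading-middle pair geometry sits well inside the cutoffs
        recs = screen_pairs([_record(3.3, 8.4, 159.2)])
        assert recs[0].pass_flag is True

    def test_far_pair_fails(self):
        # the non-interacting trailing-leading pair distance
        recs = screen_pairs([_record(7.4, 8.0, 160.0)])
        assert recs[0].pass_flag is False

    @pytest.mark.parametrize(
        "d, th, om",
        [(4.3, 8.0, 160.0), (3.3, 25.0, 160.0), (3.3, 8.0, 120.0), (4.3, 25.0, 120.0)],
    )
    def test_boundary_values_fail(self, d, th, om):
        """Cutoffs are strict inequalities; equality fails."""
        assert screen_pairs([_record(d, th, om)])[0].pass_flag is False

    def test_summary_and_permutation_invariance(self):
        recs = [_record(3.3, 8.0, 160.0), _record(5.0, 8.0, 160.0),
                _record(3.3, 40.0, 160.0)]
        s1 = screen_summary(screen_pairs(recs))
        s2 = screen_summary(screen_pairs(recs[::-1]))
        assert s1 == s2 == {"n_candidates": 3, "n_pass": 1, "pass_fraction": 1 / 3}

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScreenConfig(enumeration_dmax=4.0, cutoff_d_NM=4.3)


class TestEnumeration:
    def test_planted_pair_vs_decoy(self):
        st = generate_decoy_structure(1, 1, seed=3)
        recs = enumerate_candidate_pairs(st)
        # the far decoy may or may not enter the 4.5 A enumeration window,
        # but the planted pair always does
        assert 1 <= len(recs) <= 2
        assert sum(r.pass_flag for r in screen_pairs(recs)) == 1

    def test_decoy_only_structure_is_empty_or_failing(self):
        st = generate_decoy_structure(0, 4, seed=1)
        recs = screen_pairs(enumerate_candidate_pairs(st))
        assert sum(r.pass_flag for r in recs) == 0

    def test_no_donors_gives_empty_collection(self):
        ring = plant_pair_fragment(PlantSpec(3.3, 10.0)).ring_residue
        st = Structure(models=[Model(1, [Chain("A", [ring])])])
        assert enumerate_candidate_pairs(st) == []

    def test_product_count_all_within_range(self):
        """3 donors and 2 rings all within 4.5 A give 6 records."""
        residues = []
        seq = 1
        for k in range(3):
            pair = plant_pair_fragment(
                PlantSpec(d_NM=3.0 + 0.2 * k, theta=10.0, azimuth=120.0 * k),
                donor_seqnum=seq,
                ring_seqnum=seq + 1,
            )
            d, r = pair.residues()
            residues.append(d)
            if k < 2:
                residues.append(r)
            seq += 2
        st = Structure(models=[Model(1, [Chain("A", residues)])])
        recs = enumerate_candidate_pairs(st)
        # every donor sits close to the shared origin-centred rings
        assert len(recs) == 6


def _collagen_residue(resname, seqnum, ca):
    atoms = [Atom(name="CA", element="C", serial=1, coords=ca)]
    return Residue(resname=resname, seqnum=seqnum, atoms=atoms)


def make_collagen(n_triplets=8, rise=2.86, stagger=None, sub=()):
    """Idealized staggered three-chain Gly-X-Y helix (CA trace only).

    ``sub`` entries are (chain_id, seqnum, resname) substitutions.
    leading chain A sits one residue rise ahead of B, B ahead of C.
    """
    stagger = {"A": 2, "B": 1, "C": 0} if stagger is None else stagger
    offsets = {"A": (0.0, 0.0), "B": (4.0, 0.0), "C": (2.0, 3.5)}
    chains = []
    for cid in ("A", "B", "C"):
        residues = []
        for i in range(3 * n_triplets):
            seqnum = i + 1
            resname = ("GLY", "PRO", "HYP")[i % 3]
            for c, s, rn in sub:
                if c == cid and s == seqnum:
                    resname = rn
            z = (i + stagger[cid]) * rise
            x, y = offsets[cid]
            residues.append(_collagen_residue(resname, seqnum, np.array([x, y, z])))
        chains.append(Chain(cid, residues))
    return Structure(models=[Model(1, chains)], id="COLL")


class TestCollagenRegister:
    def test_role_inference_from_stagger(self):
        st = make_collagen()
        roles = infer_chain_roles(st)
        assert roles == {"A": "leading", "B": "middle", "C": "trailing"}

    def test_axial_pair(self):
        # Y-position donor on the leading chain, X-position ring on the
        # *next* triplet of the middle chain
        st = make_collagen(sub=[("A", 12, "GLN"), ("B", 14, "PHE")])
        rec = _record(3.3, 8.4, 159.2, donor_chain="A", ring_chain="B",
                      donor=("GLN", 12, ""), ring=("PHE", 14, ""))
        assert classify_collagen_register(rec, st) == "axial"

    def test_lateral_pair(self):
        # same-triplet Y-X contact on the neighbouring chain
        st = make_collagen(sub=[("A", 12, "GLN"), ("B", 11, "PHE")])
        rec = _record(3.3, 8.4, 159.2, donor_chain="A", ring_chain="B",
                      donor=("GLN", 12, ""), ring=("PHE", 11, ""))
        assert classify_collagen_register(rec, st) == "lateral"

    def test_non_successor_chain_is_none(self):
        st = make_collagen(sub=[("C", 12, "GLN"), ("A", 14, "PHE")])
        rec = _record(3.3, 8.4, 159.2, donor_chain="C", ring_chain="A",
                      donor=("GLN", 12, ""), ring=("PHE", 14, ""))
        assert classify_collagen_register(rec, st) == "none"

    def test_globular_input_is_na(self):
        st = generate_decoy_structure(1, 0, seed=5)
        rec = _record(3.3, 8.4, 159.2, donor_chain="A", ring_chain="A",
                      donor=("GLN", 1, ""), ring=("PHE", 2, ""))
        assert classify_collagen_register(rec, st) == "n/a"

    def test_explicit_roles_override(self):
        st = make_collagen(sub=[("A", 12, "GLN"), ("B", 14, "PHE")])
        roles = {"A": "middle", "B": "trailing", "C": "leading"}
        rec = _record(3.3, 8.4, 159.2, donor_chain="A", ring_chain="B",
                      donor=("GLN", 12, ""), ring=("PHE", 14, ""))
        assert classify_collagen_register(rec, st, chain_roles=roles) == "axial"


class TestDatasetFilter:
    def test_published_crystal_is_rejected_on_chain_length(self):
        # a 1.385 A / R 0.167 entry with 27-residue chains fails only the
        # 40-residue minimum
        e = DatasetEntry("xtal", resolution=1.385, r_factor=0.167, min_chain_length=27)
        accepted, rejected = filter_dataset_entries([e])
        assert accepted == []
        assert "chain length" in rejected[0][1]

    def test_inclusive_bounds_accepted(self):
        e = DatasetEntry("edge", resolution=2.0, r_factor=0.25, min_chain_length=40)
        accepted, _ = filter_dataset_entries([e])
        assert accepted == [e]

    @pytest.mark.parametrize(
        "kwargs, phrase",
        [
            (dict(resolution=2.4, r_factor=0.20, min_chain_length=100), "resolution"),
            (dict(resolution=1.8, r_factor=0.30, min_chain_length=100), "R-factor"),
            (dict(resolution=1.8, r_factor=None, min_chain_length=100), "missing"),
            (dict(resolution=1.8, r_factor=0.2, min_chain_length=100,
                  experimental=False), "experimental"),
            (dict(resolution=1.8, r_factor=0.2, min_chain_length=100,
                  full_coordinates=False), "incomplete"),
        ],
    )
    def test_rejection_reasons(self, kwargs, phrase):
        _, rejected = filter_dataset_entries([DatasetEntry("x", **kwargs)])
        assert phrase in rejected[0][1]
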