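"""Ambient filtering, contact classification, S_rot, census, switching."""

import dataclasses

import numpy as np
import pytest

import chiralmem as cm
from chiralmem import contacts as ct
from chiralmem import geometry as geo
from chiralmem import synthetic as syn

from _oracles import contact_analysis
from conftest import random_cluster_frame


def lipid_at(lid, head, c2=None, tail=None):
    """Single-headed test lipid; unspecified atoms stack away from origin
    (i.e. away from the peptide, which the fixtures keep near the origin)."""
    head = np.atleast_2d(np.asarray(head, float))
    away = head[0] / max(np.linalg.norm(head[0]), 1e-9)
    c2 = np.asarray(c2 if c2 is not None else head[0] + 0.3 * away, float)
    tail = np.atleast_2d(np.asarray(tail, float)) if tail is not None \
        else (c2 + 0.4 * away)[None, :]
    return cm.LipidPseudo(lipid_id=lid, head_atoms=head, c2_atom=c2,
                          tail_atoms=tail, leaflet="upper")


def outward_radial(peptide, atom, residue):
    """Unit vector from the helix axis (+x through origin) out through an atom."""
    xyz = peptide.coords_of(atom, residue)
    radial = xyz - np.array([xyz[0], 0.0, 0.0])
    return radial / np.linalg.norm(radial)


class TestAmbientFilter:
    @pytest.mark.parametrize("offset,included", [(0.29, True), (0.31, False)])
    def test_boundary_distances(self, peptide_L, policy, offset, included):
        # anchor on the outermost atom of residue 1 so the stated offset is
        # the true nearest-atom distance
        anchor = peptide_L.coords_of("CB", 1)
        lipid = lipid_at(0, head=anchor + offset * outward_radial(
            peptide_L, "CB", 1))
        frame = cm.Frame(peptide=peptide_L, lipids=[lipid], box=None)
        result = ct.ambient_lipids(frame, policy)
        assert (0 in result) == included

    def test_empty_lipid_set_is_not_an_error(self, peptide_L, policy):
        frame = cm.Frame(peptide=peptide_L, lipids=[], box=None)
        assert ct.ambient_lipids(frame, policy) == []

    def test_graded_distances_match_brute_force(self, peptide_L, policy):
        rng = np.random.default_rng(5)
        lipids = [lipid_at(i, head=peptide_L.coords[3] + d * rng.normal(size=3)
                           / np.linalg.norm(rng.normal(size=3)))
                  for i, d in enumerate(np.linspace(0.1, 1.2, 10))]
        frame = cm.Frame(peptide=peptide_L, lipids=lipids, box=None)
        assert sorted(ct.ambient_lipids(frame, policy)) == \
            contact_analysis(frame, policy)["ambient"]


class TestCountContacts:
    def test_single_arg_head_contact_on_descending_side(self, peptide_L, policy):
        # head atom 0.4 nm radially out from Arg1's CB: only that residue
        # is within the 0.5 nm cutoff
        arg_cb = peptide_L.coords_of("CB", 1)
        u = outward_radial(peptide_L, "CB", 1)
        head = arg_cb + 0.4 * u
        lipid = lipid_at(0, head=head, c2=head + 1.0 * u, tail=head + 2.0 * u)
        sides = {0: geo.DESCENDING}
        frame = cm.Frame(peptide=peptide_L, lipids=[lipid], box=None)
        bd = ct.count_contacts(frame, sides, policy)
        assert (bd.n_dp, bd.n_dh, bd.n_ah, bd.n_ap) == (1, 0, 0, 0)
        assert bd.s_rot == policy.weights[0]

    def test_no_atoms_within_cutoff(self, peptide_L, policy):
        lipid = lipid_at(0, head=peptide_L.coords.mean(axis=0) + [0, 5.0, 0])
        frame = cm.Frame(peptide=peptide_L, lipids=[lipid], box=None)
        bd = ct.count_contacts(frame, {0: geo.ASCENDING}, policy)
        assert (bd.n_dp, bd.n_dh, bd.n_ah, bd.n_ap) == (0, 0, 0, 0)
        assert bd.s_rot == 0.0

    def test_score_linear_in_weights(self, policy):
        rng = np.random.default_rng(11)
        frame = random_cluster_frame(rng, 4)
        bd1 = ct.analyze_frame(frame, policy)
        doubled = dataclasses.replace(policy,
                                      weights=tuple(2 * w for w in policy.weights))
        bd2 = ct.analyze_frame(frame, doubled)
        assert bd2.s_rot == pytest.approx(2 * bd1.s_rot)

    def test_counts_monotone_in_cutoff(self, policy):
        rng = np.random.default_rng(13)
        for _ in range(10):
            frame = random_cluster_frame(rng, 4)
            helix = geo.helix_axis(frame.peptide.ca_coords())
            sides = ct.frame_sides(frame, policy, helix=helix,
                                   ambient=[l.lipid_id for l in frame.lipids])
            small = ct.count_contacts(frame, sides, policy)
            big_policy = dataclasses.replace(policy, contact_cutoff=0.8)
            big = ct.count_contacts(frame, sides, big_policy)
            total_small = small.n_dp + small.n_dh + small.n_ah + small.n_ap
            total_big = big.n_dp + big.n_dh + big.n_ah + big.n_ap
            assert total_big >= total_small

    def test_breakdown_matches_exhaustive_enumeration(self, policy):
        rng = np.random.default_rng(17)
        for _ in range(40):
            frame = random_cluster_frame(rng, int(rng.integers(1, 6)))
            oracle = contact_analysis(frame, policy)
            bd = ct.analyze_frame(frame, policy)
            assert (bd.n_dp, bd.n_dh, bd.n_ah, bd.n_ap) == (
                oracle["counts"]["dp"], oracle["counts"]["dh"],
                oracle["counts"]["ah"], oracle["counts"]["ap"])
            assert bd.s_rot == pytest.approx(oracle["s_rot"])
            assert bd.trp_head_contacts == oracle["trp_head"]
            assert (bd.n_des, bd.n_asc) == (oracle["n_des"], oracle["n_asc"])

    def test_strict_mode_drops_mixed_pairs(self, peptide_L):
        policy = ct.ContactPolicy(mixed_mode="strict")
        # nonpolar Leu2 touching a head atom: mixed pair, dropped in strict
        leu_cb = peptide_L.coords_of("CB", 2)
        u = outward_radial(peptide_L, "CB", 2)
        lipid = lipid_at(0, head=leu_cb + 0.45 * u, c2=leu_cb + 1.5 * u,
                         tail=leu_cb + 2.5 * u)
        frame = cm.Frame(peptide=peptide_L, lipids=[lipid], box=None)
        bd = ct.count_contacts(frame, {0: geo.DESCENDING}, policy)
        assert bd.n_dp + bd.n_dh + bd.n_ah + bd.n_ap == 0

    def test_mirror_breakdown_identical_after_system_mirror(self, policy):
        rng = np.random.default_rng(23)
        frame = random_cluster_frame(rng, 5, chirality="L")
        mirrored = syn.mirror_frame(frame)
        bd_l = ct.analyze_frame(frame, policy)
        bd_d = ct.analyze_frame(mirrored, policy)
        assert (bd_l.n_dp, bd_l.n_dh, bd_l.n_ah, bd_l.n_ap) == \
            (bd_d.n_dp, bd_d.n_dh, bd_d.n_ah, bd_d.n_ap)
        assert (bd_l.n_des, bd_l.n_asc) == (bd_d.n_des, bd_d.n_asc)


class TestTrpHeadContacts:
    def test_at_most_one_contact_per_lipid(self, peptide_L, policy):
        trp_cg = peptide_L.coords_of("CG", 10)
        heads = np.array([trp_cg + [0, 0, 0.2], trp_cg + [0, 0.2, 0.2],
                          trp_cg + [0.2, 0, 0.2]])
        lipid = lipid_at(0, head=heads, tail=trp_cg + [0, 0, 5.0])
        frame = cm.Frame(peptide=peptide_L, lipids=[lipid], box=None)
        assert ct.trp_head_contacts(frame, policy) == 1

    def test_heads_beyond_cutoff_do_not_count(self, peptide_L, policy):
        trp_cg = peptide_L.coords_of("CG", 10)
        u = outward_radial(peptide_L, "CG", 10)
        lipid = lipid_at(0, head=trp_cg + 0.6 * u)
        frame = cm.Frame(peptide=peptide_L, lipids=[lipid], box=None)
        assert ct.trp_head_contacts(frame, policy) == 0


class TestSideCensus:
    def test_counts_and_difference(self):
        sides = {i: geo.DESCENDING for i in range(3)}
        sides.update({3 + i: geo.ASCENDING for i in range(5)})
        assert ct.side_census(sides) == (3, 5, -2)

    def test_balanced_fixture_is_zero(self):
        sides = {0: geo.DESCENDING, 1: geo.ASCENDING}
        assert ct.side_census(sides)[2] == 0


class TestSwitchEvents:
    def test_persistent_change_counts_once(self):
        series = {0: ["des", "des", "asc", "asc", "asc"]}
        rep = ct.switch_events(series, debounce=2)
        assert rep.per_lipid[0] == 1
        assert rep.n_switching_lipids == 1

    def test_flicker_suppressed_by_debounce(self):
        series = {0: ["des", "asc"] * 10}
        rep = ct.switch_events(series, debounce=5)
        assert rep.per_lipid[0] == 0
        assert rep.n_switching_lipids == 0

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            ct.switch_events({0: ["des"] * 5, 1: ["asc"] * 4})

    def test_planted_hop_rates_order_the_switch_counts(self):
        rng = np.random.default_rng(31)

        def series(p_hop):
            out = {}
            for lid in range(30):
                labels = ["des"]
                for _ in range(299):
                    cur = labels[-1]
                    if rng.random() < p_hop:
                        cur = "asc" if cur == "des" else "des"
                    labels.append(cur)
                out[lid] = labels
            return out

        slow = ct.switch_events(series(0.001), debounce=5)
        fast = ct.switch_events(series(0.03), debounce=5)
        assert fast.n_switching_lipids > slow.n_switching_lipids
        assert ct.switch_difference(slow, fast) < 0


class TestLipidValidation:
    def test_missing_partition_is_named_error(self, peptide_L, policy):
        bad = cm.LipidPseudo(lipid_id=0, head_atoms=np.empty((0, 3)),
                             c2_atom=np.zeros(3),
                             tail_atoms=np.zeros((1, 3)), leaflet="upper")
        frame = cm.Frame(peptide=peptide_L, lipids=[bad], box=None)
        with pytest.raises(ct.LipidPartitionError):
            ct.ambient_lipids(frame, policy)

    def test_minimum_image_distances_with_box(self, peptide_L, policy):
        # lipid across the periodic boundary is a near neighbor
        box = np.array([6.0, 6.0, 6.0])
        anchor = peptide_L.coords[0]
        lipid = lipid_at(0, head=anchor + [5.9, 0, 0])
        frame = cm.Frame(peptide=peptide_L, lipids=[lipid], box=box)
        assert ct.ambient_lipids(frame, policy) == [0]
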