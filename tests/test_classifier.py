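"""Groove-site enumeration, configuration calls, arrows, match categories."""

import numpy as np
import pytest

import lhdock as L
from lhdock.classify import (
    ARROWS,
    alpha3_symbol,
    build_match_matrix,
    compare_configurations,
    element_contacts,
    viewing_frame,
)
from lhdock.geometry import RigidTransform, quat_from_axis_angle, random_quaternion
from lhdock.structures import CONTACT_ELEMENTS

C2 = RigidTransform(quat_from_axis_angle(np.array([1.0, 0, 0]), np.pi), np.zeros(3))


class TestGrooveSites:
    def test_expected_sites_for_default_fixture(self, sites):
        assert [s.index for s in sites] == [-3, -2, -1, 0, 1, 2, 3]

    def test_site_zero_unique_and_at_dyad(self, sites, nuc):
        zeros = [s for s in sites if s.index == 0]
        assert len(zeros) == 1
        assert np.linalg.norm(zeros[0].center - nuc.dyad_point) < 8.0

    def test_index_monotone_with_contour_distance(self, sites, nuc):
        tab = nuc.bp_table
        id_to_bp = {}
        for _, row in tab.iterrows():
            id_to_bp[int(row["p1"])] = int(row["bp"])
            id_to_bp[int(row["p2"])] = int(row["bp"])
        for side in (+1, -1):
            picked = [s for s in sites if np.sign(s.index) == side]
            picked.sort(key=lambda s: abs(s.index))
            prev = -1
            for s in picked:
                far = max(abs(id_to_bp[int(a)]) for a in s.member_atom_ids)
                assert far > prev
                prev = far

    def test_linker_sites_live_on_the_arms(self, sites):
        for s in sites:
            if abs(s.index) >= 2:
                assert s.segment.startswith("L-DNA")
            else:
                assert s.segment == "N-DNA"


class TestWorkedExamples:
    def test_on_dyad_configuration_string(self, lh, nuc):
        pose = L.place_reference_pose(lh, nuc, "on-dyad")
        cfg = L.classify(lh, pose, nuc)
        assert cfg.render() == "(-3↑, 0, +3)"
        assert cfg.dyad_mode == "on-dyad"

    def test_off_dyad_l1_all_negative(self, lh, nuc):
        pose = L.place_reference_pose(lh, nuc, "off-dyad-L1")
        cfg = L.classify(lh, pose, nuc)
        assert cfg.dyad_mode == "off-dyad-L-DNA1"
        assert cfg.contacted and all(k < 0 for k in cfg.contacted)

    def test_off_dyad_l2_all_positive(self, lh, nuc):
        pose = L.place_reference_pose(lh, nuc, "off-dyad-L2")
        cfg = L.classify(lh, pose, nuc)
        assert cfg.dyad_mode == "off-dyad-L-DNA2"
        assert cfg.contacted and all(k > 0 for k in cfg.contacted)

    def test_far_pose_has_no_contacts(self, lh, nuc, sites):
        pose = RigidTransform(translation=np.array([300.0, 0, 0]))
        contacts = element_contacts(lh, pose, sites, nuc)
        assert all(v == [] for v in contacts.values())
        assert L.classify(lh, pose, nuc).dyad_mode == "no-contact"

    def test_contact_cutoff_edge(self, lh, nuc, sites):
        # an atom at 4.9 Å from a site-0 phosphate counts at the 5.0 Å cutoff
        idx = {int(a): i for i, a in enumerate(nuc.solute.atom_ids)}
        site0 = next(s for s in sites if s.index == 0)
        p = nuc.solute.positions[idx[int(site0.member_atom_ids[0])]]
        mask = lh.element_atom_mask("alpha3")
        atom = lh.solute.reference_positions[mask][0]
        target = p + np.array([4.9, 0, 0])
        pose = RigidTransform(translation=target - atom)
        contacts = element_contacts(lh, pose, sites, nuc)
        assert 0 in contacts["alpha3"]


class TestBruteForceAgreement:
    def test_contacts_match_all_pairs_scan(self, lh, nuc, sites, rng):
        idx = {int(a): i for i, a in enumerate(nuc.solute.atom_ids)}
        coords = {
            s.index: nuc.solute.positions[[idx[int(a)] for a in s.member_atom_ids]]
            for s in sites
        }
        for _ in range(100):
            pose = RigidTransform(
                random_quaternion(rng), nuc.dyad_point + rng.uniform(-30, 30, 3)
            )
            world = pose.apply(lh.solute.reference_positions)
            fast = element_contacts(lh, pose, sites, nuc)
            for element in CONTACT_ELEMENTS:
                atoms = world[lh.element_atom_mask(element)]
                brute = sorted(
                    k for k, pc in coords.items()
                    if np.any(
                        np.linalg.norm(
                            atoms[:, None, :] - pc[None, :, :], axis=2
                        ) <= 5.0
                    )
                )
                assert fast[element] == brute


class TestAlpha3Symbol:
    def test_native_pose_points_up(self, lh, nuc):
        assert alpha3_symbol(lh, lh.solute.frame, nuc) == "↑"

    def test_vector_along_dyad_axis_is_x(self, lh, nuc):
        _, e2, n = viewing_frame(nuc)
        # rotate the whole LH so the alpha3 axis (e2 in the native pose)
        # aligns with the dyad axis
        axis = np.cross(e2, n)
        rot = RigidTransform(
            quat_from_axis_angle(axis, np.pi / 2), np.zeros(3)
        )
        pose = rot.compose(lh.solute.frame)
        assert alpha3_symbol(lh, pose, nuc) == "X"

    def test_rotation_about_dyad_axis_advances_arrow(self, lh, nuc):
        base = lh.solute.frame
        _, _, n = viewing_frame(nuc)
        start = ARROWS.index(alpha3_symbol(lh, base, nuc))
        for steps in range(1, 8):
            rot = RigidTransform(
                quat_from_axis_angle(n, steps * np.pi / 4), np.zeros(3)
            )
            sym = alpha3_symbol(lh, rot.compose(base), nuc)
            assert sym == ARROWS[(start + steps) % 8]

    def test_degenerate_vector_errors(self, lh, nuc):
        broken = lh.copy()
        broken.alpha3_c_terminus = broken.alpha3_n_terminus
        with pytest.raises(ValueError, match="zero-length"):
            alpha3_symbol(broken, lh.solute.frame, nuc)


class TestSymmetryAndInvariance:
    def test_dyad_mirror_negates_indices_and_swaps_arms(self, lh, nuc, rng):
        for _ in range(100):
            pose = RigidTransform(
                random_quaternion(rng), nuc.dyad_point + rng.uniform(-25, 25, 3)
            )
            c1 = L.classify(lh, pose, nuc)
            c2 = L.classify(lh, C2.compose(pose), nuc)
            for element in CONTACT_ELEMENTS:
                assert c2.contacts[element] == sorted(-k for k in c1.contacts[element])
            swap = {
                "off-dyad-L-DNA1": "off-dyad-L-DNA2",
                "off-dyad-L-DNA2": "off-dyad-L-DNA1",
            }
            assert c2.dyad_mode == swap.get(c1.dyad_mode, c1.dyad_mode)

    def test_invariant_under_global_rigid_transform(self, lh, nuc, rng):
        g = RigidTransform(random_quaternion(rng), rng.normal(size=3) * 40)
        moved = L.annotate_nucleosome(
            nuc.solute.with_frame(g), nuc.bp_table, dyad_bp=0,
            core_atom_ids=nuc.core_atom_ids,
        )
        for _ in range(10):
            pose = RigidTransform(
                random_quaternion(rng), nuc.dyad_point + rng.uniform(-20, 20, 3)
            )
            c1 = L.classify(lh, pose, nuc)
            c2 = L.classify(lh, g.compose(pose), moved)
            assert c1.contacts == c2.contacts
            assert c1.dyad_mode == c2.dyad_mode
            assert c1.alpha3_symbol == c2.alpha3_symbol


class TestComparison:
    def _config(self, a3, b1, l1):
        return L.Configuration({"alpha3": a3, "beta1": b1, "l1": l1}, "↑", "on-dyad")

    def test_identical(self):
        c = self._config([-3], [0], [3])
        assert compare_configurations(c, c) == "identical"

    def test_partial_when_one_or_two_differ(self):
        ref = self._config([-3], [0], [3])
        assert compare_configurations(self._config([-2], [0], [3]), ref) == "partial"
        assert compare_configurations(self._config([-2], [1], [3]), ref) == "partial"

    def test_different_when_all_differ(self):
        ref = self._config([-3], [0], [3])
        assert compare_configurations(self._config([-2], [1], [2]), ref) == "different"

    def test_match_matrix_with_planted_differences(self):
        wt = self._config([-3], [0], [3])
        shifted = self._config([-2], [1], [2])
        partial = self._config([-2], [0], [3])
        runs = {
            ("WT", "c0"): wt, ("WT", "c1"): wt,
            ("mutA", "c0"): wt, ("mutA", "c1"): shifted,
            ("mutB", "c0"): partial, ("mutB", "c1"): shifted,
        }
        matrix, shifts = build_match_matrix(runs)
        assert shifts == {"WT": 0, "mutA": 1, "mutB": 2}
        cell = matrix.loc[
            (matrix.variant == "mutA") & (matrix.conformer == "c1"), "category"
        ].iloc[0]
        assert cell == "different"

    def test_missing_wt_cell_is_undefined(self):
        runs = {("mutA", "c0"): self._config([-3], [0], [3])}
        matrix, shifts = build_match_matrix(runs)
        assert matrix["category"].iloc[0] == "undefined"
        assert shifts["mutA"] == 0
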