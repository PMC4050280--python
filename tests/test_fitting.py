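"""Atomic-model fitting: density synthesis, rigid and hinge-flexible
fitting, domain rotations, residue distances and bilayer placement."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from memtomo.core_io import AtomicModel, DomainAssignment
from memtomo.fitting import (
    GLU_CARBOXYLATE,
    LYS_AMINE,
    BilayerFit,
    NoBilayerError,
    domain_rotation_between,
    fit_bilayer_profile,
    hinge_flexible_fit,
    model_map_ccc,
    model_to_map,
    residue_pair_distance,
    rigid_fit,
)


from memtomo.synthetic import make_synthetic_chain as make_chain  # noqa: E402


@pytest.fixture()
def domains():
    return DomainAssignment(
        domains={"I": (1, 20), "II": (23, 40), "III": (43, 60)},
        hinges={"I-II": [21, 22], "I-III": [41, 42]},
    )


class TestModelToMap:
    def test_single_atom_blob_centred_on_atom(self):
        m = AtomicModel(serial=np.array([1]), element=["C"], atom_name=["CA"],
                        residue_name=["ALA"], residue_number=np.array([1]),
                        chain=["A"], xyz=np.array([[10.0, 12.0, 14.0]]),
                        mass=np.array([12.011]))
        dm = model_to_map(m, resolution=8.0, voxel_size=2.0)
        idx = np.unravel_index(np.argmin(dm.grid), dm.shape)
        centre = dm.origin + (np.array(idx) + 0.5) * 2.0
        assert centre == pytest.approx([10.0, 12.0, 14.0], abs=1.0)
        assert dm.grid.min() < 0

    def test_integral_proportional_to_mass(self):
        model = make_chain(20)
        doubled = AtomicModel(
            serial=np.r_[model.serial, model.serial + 1000],
            element=model.element * 2, atom_name=model.atom_name * 2,
            residue_name=model.residue_name * 2,
            residue_number=np.r_[model.residue_number,
                                 model.residue_number + 100],
            chain=model.chain * 2,
            xyz=np.vstack([model.xyz, model.xyz + 40.0]),
            mass=np.r_[model.mass, model.mass],
        )
        lo = model.xyz.min(axis=0) - 40
        shape = (80, 80, 104)
        a = model_to_map(model, 8.0, 2.0, origin=lo, shape=shape)
        b = model_to_map(doubled, 8.0, 2.0, origin=lo, shape=shape)
        assert b.grid.sum() == pytest.approx(2 * a.grid.sum(), rel=0.01)

    def test_resolution_below_sampling_limit_rejected(self):
        with pytest.raises(ValueError):
            model_to_map(make_chain(5), resolution=3.0, voxel_size=2.0)


class TestRigidFit:
    def test_self_fit_recovers_identity(self):
        model = make_chain(30)
        target = model_to_map(model, 12.0, 3.0)
        fit, fitted = rigid_fit(model, target, 12.0, ang_half=6.0,
                                ang_step=3.0, shift_half=3.0, shift_step=3.0)
        assert fit.ccc > 0.99
        np.testing.assert_allclose(fitted.xyz, model.xyz, atol=1.0)

    def test_planted_rotation_recovered_within_one_step(self):
        model = make_chain(30)
        centroid = model.xyz.mean(axis=0)
        R = Rotation.from_euler("ZYZ", [0, 10.0, 0], degrees=True).as_matrix()
        rotated = model.with_xyz((model.xyz - centroid) @ R.T + centroid)
        target = model_to_map(rotated, 12.0, 3.0)
        fit, fitted = rigid_fit(model, target, 12.0, ang_half=15.0,
                                ang_step=5.0, shift_half=0.0, shift_step=3.0)
        rms = np.sqrt(((fitted.xyz - rotated.xyz) ** 2).sum(axis=1).mean())
        assert rms < 3.0
        assert fit.ccc > 0.95

    def test_zero_search_evaluates_initial_pose(self):
        model = make_chain(20)
        target = model_to_map(model, 12.0, 3.0)
        fit, fitted = rigid_fit(model, target, 12.0, ang_half=0.0,
                                ang_step=1.0, shift_half=0.0, shift_step=1.0)
        np.testing.assert_allclose(fitted.xyz, model.xyz, atol=1e-9)
        assert fit.ccc > 0.99


class TestHingeFlexibleFit:
    def test_constructed_domain_rotations_recovered(self, domains):
        model = make_chain(60)
        target_model = model.with_xyz(model.xyz.copy())
        xyz = target_model.xyz
        for key, dom, angle in (("I-II", "II", 14.0), ("I-III", "III", -18.0)):
            from memtomo.fitting import _moving_mask, hinge_pivot
            pivot = hinge_pivot(model, domains, key)
            moving = _moving_mask(model, domains, dom, key)
            R = Rotation.from_rotvec([0, 0, angle], degrees=True).as_matrix()
            xyz[moving] = (xyz[moving] - pivot) @ R.T + pivot
        target = model_to_map(target_model.with_xyz(xyz), 10.0, 2.5)
        target = model_to_map(target_model.with_xyz(xyz), 10.0, 2.5)
        fit, fitted = hinge_flexible_fit(model, domains, target, 10.0,
                                         n_iterations=2, max_angle=25.0)
        assert fit.ccc > 0.97
        assert fit.hinge_rotations["I-II"] == pytest.approx(14.0, abs=2.0)
        assert fit.hinge_rotations["I-III"] == pytest.approx(18.0, abs=2.0)

    def test_zero_rotation_range_equals_rigid_result(self, domains):
        model = make_chain(60)
        target = model_to_map(model, 10.0, 2.5)
        rigid_ccc = model_map_ccc(model, target, 10.0)
        fit, fitted = hinge_flexible_fit(model, domains, target, 10.0,
                                         n_iterations=2, max_angle=0.0)
        np.testing.assert_allclose(fitted.xyz, model.xyz, atol=1e-9)
        assert fit.ccc == pytest.approx(rigid_ccc, abs=1e-9)

    def test_flexible_ccc_never_below_rigid(self, domains):
        model = make_chain(60)
        # target from a slightly different conformation
        xyz = model.xyz.copy()
        xyz[model.residue_number >= 43] += [2.0, -1.0, 0.5]
        target = model_to_map(model.with_xyz(xyz), 10.0, 2.5)
        rigid_ccc = model_map_ccc(model, target, 10.0)
        fit, _ = hinge_flexible_fit(model, domains, target, 10.0,
                                    n_iterations=1, max_angle=10.0,
                                    n_refine=2)
        assert fit.ccc >= rigid_ccc - 1e-9

    def test_unassigned_domains_rejected(self):
        model = make_chain(60)
        bad = DomainAssignment(domains={"I": (1, 30)}, hinges={})
        target = model_to_map(model, 10.0, 2.5)
        with pytest.raises(ValueError):
            hinge_flexible_fit(model, bad, target, 10.0)


class TestDomainRotationBetween:
    def test_identical_models_rotate_zero(self, domains):
        model = make_chain(60)
        assert domain_rotation_between(model, model, domains, "I", "II") == \
            pytest.approx(0.0, abs=1e-6)

    def test_constructed_25_degree_rotation(self, domains):
        model = make_chain(60)
        xyz = model.xyz.copy()
        moving = (model.residue_number >= 23) & (model.residue_number <= 40)
        pivot = xyz[moving].mean(axis=0)
        R = Rotation.from_rotvec([25.0, 0, 0], degrees=True).as_matrix()
        xyz[moving] = (xyz[moving] - pivot) @ R.T + pivot
        other = model.with_xyz(xyz)
        got = domain_rotation_between(model, other, domains, "I", "II")
        assert got == pytest.approx(25.0, abs=0.1)

    def test_symmetric_in_model_order(self, domains):
        model = make_chain(60)
        xyz = model.xyz.copy()
        moving = model.residue_number >= 43
        R = Rotation.from_rotvec([0, 12.0, 5.0], degrees=True).as_matrix()
        xyz[moving] = (xyz[moving] - xyz[moving].mean(0)) @ R.T \
            + xyz[moving].mean(0)
        other = model.with_xyz(xyz)
        ab = domain_rotation_between(model, other, domains, "I", "III")
        ba = domain_rotation_between(other, model, domains, "I", "III")
        assert ab == pytest.approx(ba, abs=1e-6)

    def test_invariant_to_global_rigid_motion(self, domains):
        model = make_chain(60)
        xyz = model.xyz.copy()
        moving = model.residue_number >= 43
        R = Rotation.from_rotvec([0, 0, 20.0], degrees=True).as_matrix()
        xyz[moving] = (xyz[moving] - xyz[moving].mean(0)) @ R.T \
            + xyz[moving].mean(0)
        other = model.with_xyz(xyz)
        ref = domain_rotation_between(model, other, domains, "I", "III")
        G = Rotation.from_euler("ZYZ", [40, 70, 10], degrees=True).as_matrix()
        other_moved = other.with_xyz(other.xyz @ G.T + np.array([30, -50, 10]))
        got = domain_rotation_between(model, other_moved, domains, "I", "III")
        assert got == pytest.approx(ref, abs=1e-6)

    def test_too_few_common_atoms_rejected(self, domains):
        model = make_chain(60)
        tiny = AtomicModel(
            serial=model.serial[:3], element=model.element[:3],
            atom_name=model.atom_name[:3], residue_name=model.residue_name[:3],
            residue_number=model.residue_number[:3], chain=model.chain[:3],
            xyz=model.xyz[:3], mass=model.mass[:3])
        with pytest.raises(ValueError):
            domain_rotation_between(model, tiny, domains, "I", "II")


class TestResiduePairDistance:
    @pytest.fixture()
    def salt_bridge_model(self):
        xyz = np.array([
            [0.0, 0.0, 0.0],   # GLU OE1
            [1.0, 0.0, 0.0],   # GLU OE2
            [4.0, 3.0, 0.0],   # LYS NZ: 5.0 from OE2's (1,0,0)? -> dist
        ])
        return AtomicModel(
            serial=np.array([1, 2, 3]), element=["O", "O", "N"],
            atom_name=["OE1", "OE2", "NZ"],
            residue_name=["GLU", "GLU", "LYS"],
            residue_number=np.array([245, 245, 400]),
            chain=["A", "A", "A"], xyz=xyz,
            mass=np.array([15.999, 15.999, 14.007]))

    def test_known_gap_recovered_exactly(self, salt_bridge_model):
        d = residue_pair_distance(
            salt_bridge_model, ("A", 245, GLU_CARBOXYLATE),
            ("A", 400, LYS_AMINE))
        # min over both oxygens: from OE2 at (1,0,0) to NZ at (4,3,0)
        assert d == pytest.approx(np.sqrt(9 + 9), abs=1e-12)

    def test_overlapping_sets_give_zero(self, salt_bridge_model):
        d = residue_pair_distance(
            salt_bridge_model, ("A", 245, ("OE1", "OE2")),
            ("A", 245, ("OE2",)))
        assert d == 0.0

    def test_missing_residue_named_in_error(self, salt_bridge_model):
        with pytest.raises(ValueError, match="999"):
            residue_pair_distance(
                salt_bridge_model, ("A", 245, GLU_CARBOXYLATE),
                ("A", 999, LYS_AMINE))

    def test_matches_exhaustive_minimum(self, salt_bridge_model):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 10, (4, 3))
        b = rng.uniform(5, 15, (3, 3))
        model = AtomicModel(
            serial=np.arange(7), element=["O"] * 4 + ["N"] * 3,
            atom_name=["OE1", "OE2", "OD1", "OD2", "NZ", "NH1", "NH2"],
            residue_name=["GLU"] * 4 + ["LYS"] * 3,
            residue_number=np.array([1] * 4 + [2] * 3),
            chain=["A"] * 7, xyz=np.vstack([a, b]),
            mass=np.ones(7) * 14)
        d = residue_pair_distance(
            model, ("A", 1, ("OE1", "OE2", "OD1", "OD2")),
            ("A", 2, ("NZ", "NH1", "NH2")))
        want = np.linalg.norm(a[:, None] - b[None], axis=-1).min()
        assert d == pytest.approx(want, abs=1e-12)


class TestBilayerFit:
    @staticmethod
    def _profile(r1, r2, a1=1.0, a2=1.0):
        r = np.linspace(150.0, 350.0, 120)
        prof = (-a1 * np.exp(-((r - r1) ** 2) / (2 * 9.0**2))
                - a2 * np.exp(-((r - r2) ** 2) / (2 * 9.0**2)))
        return r, prof

    def test_two_dips_recovered_within_1A(self):
        r, prof = self._profile(230.0, 270.0)
        fit = fit_bilayer_profile(r, prof)
        assert fit.leaflet_radii[0] == pytest.approx(230.0, abs=1.0)
        assert fit.leaflet_radii[1] == pytest.approx(270.0, abs=1.0)
        assert fit.separation == pytest.approx(40.0, abs=2.0)

    def test_single_dip_raises(self):
        r = np.linspace(150.0, 350.0, 120)
        prof = -np.exp(-((r - 250.0) ** 2) / (2 * 12.0**2))
        with pytest.raises(NoBilayerError):
            fit_bilayer_profile(r, prof)

    def test_symmetric_profile_gives_equal_amplitudes(self):
        r, prof = self._profile(235.0, 275.0, 0.8, 0.8)
        fit = fit_bilayer_profile(r, prof)
        assert fit.amplitudes[0] == pytest.approx(fit.amplitudes[1], rel=0.05)

    def test_rendered_bilayer_vesicle_resolved(self):
        from memtomo.core_io import ParticleTable, VesicleModel
        from memtomo.fitting import place_bilayer
        from memtomo.synthetic import (SceneTruth, make_protein_template,
                                       render_tomogram)
        tmpl = make_protein_template(130.0, (60, 40), 10.0, 4.0)
        v = VesicleModel(centre=np.full(3, 320.0), radius=200.0)
        m = render_tomogram(
            SceneTruth(vesicles=[v], particles=ParticleTable.empty()),
            tmpl, membrane_thickness=45.0, box_dims=(80, 80, 80),
            voxel_size=8.0, bilayer=True, leaflet_separation=35.0)
        fit = place_bilayer(m, v, window=60.0)
        assert fit.separation == pytest.approx(35.0, abs=6.0)
        mid = 0.5 * (fit.leaflet_radii[0] + fit.leaflet_radii[1])
        assert mid == pytest.approx(200.0, abs=5.0)
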