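"""Subvolume extraction, correlation scoring, alignment, selection,
splitting, averaging, FSC and classification."""

import numpy as np
import pytest
import scipy.fft as sfft

from memtomo.averaging import (
    AlignmentSchedule,
    DegenerateVarianceError,
    Resolution,
    UndefinedScoreError,
    align_particles,
    average_particles,
    box_origin,
    cc_score,
    compute_fsc,
    cylinder_mask,
    extract_subvolume,
    lowpass_by_fsc,
    masked_correlation,
    pca_classify,
    remove_duplicates,
    resolution_at,
    rotate_map,
    rotation_grid,
    select_above_mean,
    split_even_odd,
)
from memtomo.core_io import DensityMap, FSCCurve, ParticleTable


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


class TestExtractSubvolume:
    def test_integer_position_is_exact_crop(self, rng):
        tomo = DensityMap(rng.standard_normal((32, 32, 32)).astype(np.float32), 2.0)
        # centre voxel index 10 -> position of its centre
        pos = (np.array([10, 12, 14]) + 0.5) * 2.0
        sub = extract_subvolume(tomo, pos, 8)
        np.testing.assert_array_equal(
            sub.grid, tomo.grid[6:14, 8:16, 10:18])

    def test_subvoxel_shift_round_trip(self, rng):
        from scipy import ndimage as ndi
        smooth = ndi.gaussian_filter(
            rng.standard_normal((32, 32, 32)), 1.5).astype(np.float32)
        tomo = DensityMap(smooth, 2.0)
        base = (np.array([16, 16, 16]) + 0.5) * 2.0
        delta = np.array([0.6, -0.8, 0.4])
        a = extract_subvolume(tomo, base + delta, 12)
        b = extract_subvolume(tomo, base, 12)
        from scipy import ndimage
        shifted_back = ndimage.shift(a.grid, delta / 2.0, order=1)
        core = (slice(2, -2),) * 3
        assert np.corrcoef(shifted_back[core].ravel(),
                           b.grid[core].ravel())[0, 1] > 0.98

    def test_out_of_bounds_without_padding_raises(self, rng):
        tomo = DensityMap(rng.standard_normal((16, 16, 16)).astype(np.float32), 2.0)
        with pytest.raises(ValueError):
            extract_subvolume(tomo, np.array([1.0, 1.0, 1.0]), 8, pad=False)
        sub = extract_subvolume(tomo, np.array([1.0, 1.0, 1.0]), 8, pad=True)
        assert sub.shape == (8, 8, 8)

    def test_box_larger_than_tomogram_rejected(self, rng):
        tomo = DensityMap(rng.standard_normal((8, 8, 8)).astype(np.float32), 2.0)
        with pytest.raises(ValueError):
            extract_subvolume(tomo, np.full(3, 8.0), 16)


class TestCCScore:
    def test_self_correlation_is_one(self, rng):
        ref = DensityMap(rng.standard_normal((16, 16, 16)).astype(np.float32), 2.0)
        assert cc_score(ref, ref) == pytest.approx(1.0, abs=1e-5)

    def test_negation_gives_minus_one(self, rng):
        ref = DensityMap(rng.standard_normal((16, 16, 16)).astype(np.float32), 2.0)
        neg = DensityMap(-ref.grid, 2.0)
        assert cc_score(neg, ref) == pytest.approx(-1.0, abs=1e-5)

    def test_matches_direct_formula(self, rng):
        a = rng.standard_normal((16, 16, 16))
        b = rng.standard_normal((16, 16, 16))
        da, db = a - a.mean(), b - b.mean()
        want = (da * db).sum() / np.sqrt((da**2).sum() * (db**2).sum())
        got = masked_correlation(a, b)
        assert got == pytest.approx(want, abs=1e-12)

    def test_zero_variance_masked_region_raises(self):
        a = np.zeros((8, 8, 8))
        b = np.ones((8, 8, 8))
        with pytest.raises(UndefinedScoreError):
            masked_correlation(a, b)


class TestSelectionAndSplit:
    def test_strictly_above_mean(self):
        t = ParticleTable.from_arrays(np.zeros((4, 3)),
                                      cc=np.array([0.1, 0.2, 0.3, 0.4]))
        assert len(select_above_mean(t)) == 2

    def test_all_equal_scores_select_none(self):
        t = ParticleTable.from_arrays(np.zeros((5, 3)), cc=np.full(5, 0.5))
        assert len(select_above_mean(t)) == 0

    def test_unset_scores_rejected(self):
        t = ParticleTable.from_arrays(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            select_above_mean(t)

    def test_count_matches_oracle_on_1973_scores(self, rng):
        cc = rng.uniform(-1, 1, 1973)
        t = ParticleTable.from_arrays(rng.uniform(0, 100, (1973, 3)), cc=cc)
        assert len(select_above_mean(t)) == (cc > cc.mean()).sum()

    @pytest.mark.parametrize("n,even_n,odd_n", [(801, 401, 400), (2, 1, 1),
                                                (0, 0, 0)])
    def test_split_even_odd_by_record_index(self, n, even_n, odd_n, rng):
        t = ParticleTable.from_arrays(rng.uniform(0, 10, (n, 3))) if n else \
            ParticleTable.empty()
        even, odd = split_even_odd(t)
        assert (len(even), len(odd)) == (even_n, odd_n)
        if n > 2:
            assert list(even.df["id"]) == list(t.df["id"])[0::2]

    def test_remove_duplicates_keeps_higher_cc(self):
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0], [100.0, 0, 0]])
        t = ParticleTable.from_arrays(pos, cc=np.array([0.2, 0.9, 0.5]))
        out = remove_duplicates(t, 50.0)
        assert len(out) == 2
        assert 0.9 in out.df["cc"].values and 0.2 not in out.df["cc"].values


class TestAverageAndAlign:
    @pytest.fixture()
    def planted_tomo(self, rng):
        """Four copies of an asymmetric blob at known poses."""
        from memtomo.core_io import euler_to_matrix
        from scipy import ndimage
        tmpl = np.zeros((16, 16, 16), np.float32)
        tmpl[6:10, 7:9, 4:12] = -1.0
        tmpl[5:11, 5:11, 10:12] = -1.5
        tomo = np.zeros((64, 64, 64), np.float32)
        poses = [(0.0, 0.0, 0.0), (30.0, 20.0, 0.0), (120.0, 45.0, 10.0),
                 (250.0, 60.0, 90.0)]
        centres = [(np.array(c) + 0.5) * 4.0
                   for c in [(12, 12, 12), (40, 12, 14), (14, 44, 40),
                             (44, 44, 20)]]
        for pose, centre in zip(poses, centres):
            R = euler_to_matrix(*pose)
            rot = rotate_map(tmpl, np.linalg.inv(R), cval=0.0)
            ci = np.rint(centre / 4.0 - 0.5).astype(int)
            tomo[ci[0] - 8:ci[0] + 8, ci[1] - 8:ci[1] + 8,
                 ci[2] - 8:ci[2] + 8] += rot
        table = ParticleTable.from_arrays(np.array(centres), np.array(poses))
        return DensityMap(tomo, 4.0), table, tmpl

    def test_average_at_true_poses_recovers_template(self, planted_tomo):
        tomo, table, tmpl = planted_tomo
        avg = average_particles(table, tomo, 16)
        core = (slice(3, -3),) * 3
        cc = np.corrcoef(avg.grid[core].ravel(), tmpl[core].ravel())[0, 1]
        assert cc > 0.95

    def test_single_particle_average_is_its_rotated_subvolume(self, planted_tomo):
        tomo, table, tmpl = planted_tomo
        one = ParticleTable(table.df.iloc[[1]])
        avg = average_particles(one, tomo, 16)
        R = one.rotation_matrices()[0]
        sub = extract_subvolume(tomo, one.positions[0], 16)
        np.testing.assert_allclose(avg.grid, rotate_map(sub.grid, R),
                                   atol=1e-5)

    def test_alignment_recovers_planted_perturbations(self, planted_tomo):
        tomo, table, tmpl = planted_tomo
        ref = average_particles(table, tomo, 16)
        rng = np.random.default_rng(1)
        pert_eul = table.eulers + rng.uniform(-15, 15, (4, 3))
        pert_pos = table.positions + rng.uniform(-4, 4, (4, 3))
        bad = table.with_updates(positions=pert_pos, eulers=pert_eul)
        sched = AlignmentSchedule([20.0, 10.0, 5.0], [5.0, 2.5, 1.25],
                                  [8.0, 6.0, 4.0])
        out, log = align_particles(bad, tomo, ref, sched,
                                   update_reference=False)
        from memtomo.core_io import euler_to_matrix
        angs = []
        for i in range(4):
            R_t = euler_to_matrix(*table.eulers[i])
            R_r = euler_to_matrix(*out.eulers[i])
            angs.append(np.degrees(np.arccos(np.clip(
                ((R_t @ [0, 0, 1]) * (R_r @ [0, 0, 1])).sum(), -1, 1))))
            assert np.linalg.norm(out.positions[i] - table.positions[i]) <= 5.0
        # within the ring discretization of the grid for typical poses; the
        # blobby phantom leaves one pose with a flatter landscape
        # the blocky phantom's double-interpolation (planting + recovery)
        # shifts the correlation optimum a few degrees; sign or convention
        # errors would show up as tens of degrees
        assert np.median(angs) <= 6.5
        assert max(angs) <= 7.5
        assert log[-1]["mean_cc"] > 0.8

    def test_mean_cc_nondecreasing_on_planted_scene(self, planted_tomo):
        tomo, table, tmpl = planted_tomo
        ref = average_particles(table, tomo, 16)
        bad = table.with_updates(eulers=table.eulers + 8.0)
        sched = AlignmentSchedule([10.0] * 3, [2.5] * 3, [4.0] * 3)
        _, log = align_particles(bad, tomo, ref, sched,
                                 update_reference=False)
        ccs = [entry["mean_cc"] for entry in log]
        assert all(b >= a - 1e-6 for a, b in zip(ccs, ccs[1:]))

    def test_empty_particle_set_rejected(self, planted_tomo):
        tomo, _, _ = planted_tomo
        with pytest.raises(ValueError):
            align_particles(ParticleTable.empty(), tomo, None,
                            AlignmentSchedule([5.0], [2.5], [2.0]),
                            box_size=16)

    def test_average_snr_grows_as_sqrt_n(self, rng):
        """Averaging N noisy copies improves SNR with a log-log slope of
        one half."""
        tmpl = np.zeros((12, 12, 12), np.float32)
        tmpl[3:9, 4:8, 2:10] = -1.0
        sig = tmpl - tmpl.mean()
        ns = [2, 4, 8, 16, 32, 64]
        snrs = []
        for n in ns:
            acc = np.zeros_like(tmpl)
            for _ in range(n):
                acc += tmpl + rng.normal(0, 1.0, tmpl.shape).astype(np.float32)
            avg = acc / n
            resid = avg - tmpl
            snrs.append(sig.var() / resid.var())
        slope = np.polyfit(np.log(ns), 0.5 * np.log(snrs), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.1)


class TestScheduleInvariants:
    def test_half_ranges_must_not_increase(self):
        with pytest.raises(ValueError):
            AlignmentSchedule([10.0, 20.0], [5.0, 5.0], [4.0, 4.0])

    def test_cutoffs_must_not_decrease(self):
        with pytest.raises(ValueError):
            AlignmentSchedule([20.0, 10.0], [5.0, 5.0], [4.0, 4.0],
                              [0.5, 0.25])

    def test_rotation_grid_contains_identity_first(self):
        g = rotation_grid(20.0, 10.0)
        np.testing.assert_allclose(g[0], np.eye(3))
        assert len(g) > 10


class TestFSC:
    def test_map_with_itself_is_unity(self, rng):
        m = DensityMap(rng.standard_normal((32, 32, 32)).astype(np.float32), 4.0)
        curve = compute_fsc(m, m)
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-9)

    def test_independent_noise_decorrelates(self):
        r1, r2 = np.random.default_rng(1), np.random.default_rng(2)
        a = DensityMap(r1.standard_normal((64, 64, 64)).astype(np.float32), 4.0)
        b = DensityMap(r2.standard_normal((64, 64, 64)).astype(np.float32), 4.0)
        curve = compute_fsc(a, b)
        assert np.abs(curve.values[4:]).max() < 0.1

    def test_matches_brute_force_shell_sums(self, rng):
        a = rng.standard_normal((16, 16, 16))
        b = a + rng.standard_normal((16, 16, 16))
        ma = DensityMap(a.astype(np.float32), 2.0)
        mb = DensityMap(b.astype(np.float32), 2.0)
        curve = compute_fsc(ma, mb)
        fa, fb = sfft.fftn(ma.grid.astype(float)), sfft.fftn(mb.grid.astype(float))
        ix = sfft.fftfreq(16) * 16
        r = np.sqrt(ix[:, None, None] ** 2 + ix[None, :, None] ** 2
                    + ix[None, None, :] ** 2)
        for s in (2, 5, 7):
            sel = np.rint(r) == s
            want = ((fa[sel] * np.conj(fb[sel])).sum().real
                    / np.sqrt((np.abs(fa[sel]) ** 2).sum()
                              * (np.abs(fb[sel]) ** 2).sum()))
            assert curve.values[s] == pytest.approx(want, abs=1e-10)

    def test_dim_mismatch_rejected(self, rng):
        a = DensityMap(rng.standard_normal((16, 16, 16)).astype(np.float32), 2.0)
        b = DensityMap(rng.standard_normal((8, 8, 8)).astype(np.float32), 2.0)
        with pytest.raises(ValueError):
            compute_fsc(a, b)


class TestResolutionAt:
    def test_hand_interpolated_crossing(self):
        curve = FSCCurve([0.0, 0.01, 0.02, 0.03], [1.0, 0.9, 0.5, 0.1])
        res = resolution_at(curve, 0.5)
        assert res.crossed
        assert res.resolution == pytest.approx(50.0)

    def test_05_crossing_not_finer_than_0143(self):
        f = np.linspace(0, 0.06, 25)
        v = 1.0 / (1.0 + (f / 0.02) ** 3)
        curve = FSCCurve(f, v)
        r05 = resolution_at(curve, 0.5).resolution
        r0143 = resolution_at(curve, 0.143).resolution
        assert r05 >= r0143

    def test_no_crossing_returns_nyquist_with_flag(self):
        curve = FSCCurve([0.0, 0.02, 0.04], [1.0, 1.0, 1.0])
        res = resolution_at(curve, 0.5)
        assert not res.crossed
        assert res.resolution == pytest.approx(25.0)

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            resolution_at(FSCCurve([], []), 0.5)


class TestLowpassByFSC:
    def test_unity_curve_leaves_map_unchanged(self, rng):
        m = DensityMap(rng.standard_normal((24, 24, 24)).astype(np.float32), 4.0)
        f = np.linspace(0, 0.125, 13)
        out = lowpass_by_fsc(m, FSCCurve(f, np.ones_like(f)))
        np.testing.assert_array_equal(out.grid, m.grid)

    def test_impulse_becomes_gaussian_of_matching_width(self):
        n = 48
        g = np.zeros((n, n, n), np.float32)
        g[n // 2, n // 2, n // 2] = -1.0
        m = DensityMap(g, 2.0)
        sigma_f = 0.03
        f = np.linspace(0, 0.25, 30)
        curve = FSCCurve(f, np.exp(-(f**2) / (2 * sigma_f**2)))
        out = lowpass_by_fsc(m, curve)
        # real-space sigma of the Fourier pair: 1 / (2 pi sigma_f)
        want_sigma = 1.0 / (2 * np.pi * sigma_f)
        w = -out.grid
        ax = (np.arange(n) - n // 2) * 2.0
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        var = (w * (X**2)).sum() / w.sum()
        assert np.sqrt(var) == pytest.approx(want_sigma, rel=0.05)

    def test_power_ratio_matches_gaussian_squared(self, rng):
        m = DensityMap(rng.standard_normal((32, 32, 32)).astype(np.float32), 2.0)
        sigma_f = 0.05
        f = np.linspace(0, 0.25, 20)
        curve = FSCCurve(f, np.exp(-(f**2) / (2 * sigma_f**2)))
        out = lowpass_by_fsc(m, curve)
        fin = np.abs(sfft.rfftn(m.grid.astype(float))) ** 2
        fout = np.abs(sfft.rfftn(out.grid.astype(float))) ** 2
        fx = sfft.fftfreq(32, 2.0)
        fz = sfft.rfftfreq(32, 2.0)
        f2 = (fx[:, None, None] ** 2 + fx[None, :, None] ** 2
              + fz[None, None, :] ** 2)
        sel = (fin > 1e-6) & (f2 > 0) & (f2 < 0.02)
        ratio = fout[sel] / fin[sel]
        want = np.exp(-f2[sel] / (2 * sigma_f**2)) ** 2
        np.testing.assert_allclose(ratio, want, rtol=1e-3)


class TestPCAClassify:
    def test_two_phantom_populations_separate(self, rng):
        a = np.zeros((10, 10, 10)); a[2:8, 4:6, 2:8] = -1.0
        b = np.zeros((10, 10, 10)); b[2:8, 2:8, 4:6] = -1.0
        vols = []
        labels_true = []
        for i in range(100):
            base = a if i < 50 else b
            vols.append(base + rng.normal(0, 0.3, base.shape))
            labels_true.append(0 if i < 50 else 1)
        labels, counts = pca_classify(np.array(vols), None, n_components=4,
                                      k_classes=2, seed=0)
        labels_true = np.array(labels_true)
        purity = max((labels == labels_true).mean(),
                     (labels != labels_true).mean())
        assert purity >= 0.9
        assert sum(counts.values()) == 100

    def test_identical_inputs_rejected(self):
        vols = np.ones((5, 6, 6, 6))
        with pytest.raises(DegenerateVarianceError):
            pca_classify(vols, None, k_classes=2, seed=0)

    def test_more_classes_than_volumes_rejected(self, rng):
        vols = rng.standard_normal((3, 4, 4, 4))
        with pytest.raises(ValueError):
            pca_classify(vols, None, k_classes=5, seed=0)


class TestCylinderMask:
    def test_mask_soft_in_unit_interval(self):
        m = cylinder_mask(24, 4.0, radius=30.0, z_min=5.0, z_max=40.0,
                          edge_width=8.0)
        assert m.min() >= 0.0 and m.max() <= 1.0
        orig = box_origin(24, 4.0)
        centre_idx = 12
        zi = int(np.rint((20.0 - orig[2]) / 4.0 - 0.5))
        assert m[centre_idx, centre_idx, zi] == pytest.approx(1.0)
        assert m[0, 0, 0] == 0.0
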