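"""Denoising stages: motion screening, aCompCor, regression, filtering."""

import numpy as np
import pytest
from scipy import linalg

from thalafc.io_cohort import LabeledMaskSet
from thalafc.preprocess import (
    ROTATION_SPHERE_RADIUS_MM,
    ConfoundMatrix,
    FilterSpec,
    MotionTrace,
    acompcor_components,
    build_confound_matrix,
    detect_outlier_volumes,
    detrend_and_bandpass,
    exclusion_check,
    framewise_displacement,
    gaussian_smooth,
    preprocess_subject,
    regress_confounds,
)

from conftest import make_image


def trace_of(params):
    return MotionTrace(np.asarray(params, dtype=float))


class TestFramewiseDisplacement:
    def test_constant_trace_is_all_zero(self):
        fd = framewise_displacement(trace_of(np.ones((10, 6)) * 0.4))
        np.testing.assert_array_equal(fd, np.zeros(10))

    def test_translation_step_registers_at_step_volume(self):
        params = np.zeros((8, 6))
        params[4:, 0] = 0.2  # 0.2 mm x-translation from volume 4 on
        fd = framewise_displacement(trace_of(params))
        expected = np.zeros(8)
        expected[4] = 0.2
        np.testing.assert_allclose(fd, expected)

    def test_one_degree_rotation_is_arc_length_on_50mm_sphere(self):
        params = np.zeros((5, 6))
        params[2:, 3] = 1.0  # 1 degree rotation step
        fd = framewise_displacement(trace_of(params))
        assert fd[2] == pytest.approx(ROTATION_SPHERE_RADIUS_MM * np.pi / 180)
        assert fd[[0, 1, 3, 4]].max() == 0

    def test_volume_zero_always_zero(self):
        rng = np.random.default_rng(0)
        fd = framewise_displacement(trace_of(rng.normal(size=(20, 6))))
        assert fd[0] == 0.0
        assert np.all(fd >= 0)


class TestOutliers:
    def test_threshold_is_strict(self):
        assert list(detect_outlier_volumes(np.array([0, 0.05, 0.20]))) == [2]
        assert list(detect_outlier_volumes(np.array([0, 0.09, 0.05]))) == []
        assert list(detect_outlier_volumes(np.zeros(10))) == []

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            detect_outlier_volumes(np.zeros(3), threshold_mm=0.0)


class TestExclusion:
    @pytest.mark.parametrize(
        "column,value,verdict",
        [
            (0, 3.5, "exclude"),   # 3.5 mm translation
            (0, 2.9, "keep"),
            (3, -3.2, "exclude"),  # negative rotation, magnitude counts
            (3, 3.0, "keep"),      # exactly at the limit is kept
        ],
    )
    def test_limits(self, column, value, verdict):
        params = np.zeros((10, 6))
        params[5, column] = value
        assert exclusion_check(trace_of(params)) == verdict

    def test_all_zero_kept(self):
        assert exclusion_check(trace_of(np.zeros((5, 6)))) == "keep"


def noise_mask_set(grid, n_voxels):
    m = np.zeros(grid, dtype=bool)
    m.reshape(-1)[:n_voxels] = True
    return LabeledMaskSet(grid, {"WM": m}, kind="noise_compartment")


class TestACompCor:
    def test_rank_one_noise_recovers_shared_signal(self):
        rng = np.random.default_rng(3)
        T = 50
        s = rng.standard_normal(T)
        grid = (4, 4, 4)
        data = np.zeros(grid + (T,))
        masks = noise_mask_set(grid, 10)
        gains = 1.0 + rng.random(10)
        data.reshape(-1, T)[:10] = gains[:, None] * s
        img = make_image(data)
        comps = acompcor_components(img, masks, n_components=2)
        r = abs(np.corrcoef(comps[:, 0], s)[0, 1])
        assert r > 1 - 1e-10

    def test_components_span_known_orthogonal_signal_subspace(self):
        rng = np.random.default_rng(4)
        T = 60
        basis = linalg.orth(rng.standard_normal((T, 5)))  # 5 orthonormal signals
        grid = (4, 4, 4)
        n_vox = 40
        mixing = rng.standard_normal((n_vox, 5))
        data = np.zeros(grid + (T,))
        data.reshape(-1, T)[:n_vox] = mixing @ basis.T
        img = make_image(data)
        comps = acompcor_components(img, noise_mask_set(grid, n_vox), 5)
        # orthonormal columns
        np.testing.assert_allclose(comps.T @ comps, np.eye(5), atol=1e-10)
        # principal angles between spans ~ 0 (demeaning costs one direction
        # at most; the demeaned basis spans what the components must cover)
        basis_dm = basis - basis.mean(axis=0)
        sv = linalg.svdvals(comps.T @ linalg.orth(basis_dm))
        assert sv.min() > 1 - 1e-8

    def test_too_few_noise_voxels(self):
        img = make_image(np.random.default_rng(0).standard_normal((4, 4, 4, 20)))
        with pytest.raises(ValueError, match="too few"):
            acompcor_components(img, noise_mask_set((4, 4, 4), 3), 5)

    def test_zero_variance_noise_region(self):
        img = make_image(np.zeros((4, 4, 4, 20)))
        with pytest.raises(ValueError, match="zero-variance"):
            acompcor_components(img, noise_mask_set((4, 4, 4), 10), 5)


class TestRegressConfounds:
    def test_voxel_equal_to_confound_becomes_zero(self):
        rng = np.random.default_rng(5)
        T = 40
        c = rng.standard_normal(T)
        trace = trace_of(np.zeros((T, 6)))
        confounds = ConfoundMatrix(c[:, None], ["c"])
        data = np.zeros((2, 2, 2, T))
        data[0, 0, 0] = 3.0 * c + 1.0
        img = make_image(data)
        out = regress_confounds(img, confounds)
        np.testing.assert_allclose(out.data[0, 0, 0], 0.0, atol=1e-10)

    def test_orthogonal_confound_leaves_series_unchanged_up_to_mean(self):
        T = 40
        t = np.arange(T, dtype=float)
        voxel = np.sin(2 * np.pi * t / 10)
        c = np.cos(2 * np.pi * t / 10)  # orthogonal over full cycles
        confounds = ConfoundMatrix(c[:, None], ["c"])
        data = np.zeros((1, 1, 1, T))
        data[0, 0, 0] = voxel + 2.0
        out = regress_confounds(make_image(data), confounds)
        np.testing.assert_allclose(out.data[0, 0, 0], voxel, atol=1e-10)

    def test_residuals_orthogonal_to_all_columns(self):
        rng = np.random.default_rng(6)
        T = 60
        trace = trace_of(rng.normal(0, 0.01, (T, 6)))
        confounds = build_confound_matrix(
            trace, compcor=rng.standard_normal((T, 5)),
            outlier_indices=np.array([7, 23]),
        )
        img = make_image(rng.standard_normal((3, 3, 3, T)))
        out = regress_confounds(img, confounds)
        resid = out.data.reshape(-1, T)
        for j in range(confounds.values.shape[1]):
            col = confounds.values[:, j] - confounds.values[:, j].mean()
            denom = np.linalg.norm(col) * np.linalg.norm(resid, axis=1)
            corr = np.abs(resid @ col) / np.where(denom == 0, 1, denom)
            assert corr.max() < 1e-6

    def test_collinear_columns_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(7)
        T = 30
        c = rng.standard_normal(T)
        confounds = ConfoundMatrix(
            np.column_stack([c, 2 * c]), ["c", "c_twice"]
        )
        img = make_image(rng.standard_normal((2, 2, 2, T)))
        import logging

        with caplog.at_level(logging.WARNING, logger="thalafc.preprocess"):
            out = regress_confounds(img, confounds)
        assert "collinear" in caplog.text
        resid = out.data.reshape(-1, T)
        assert np.abs(resid @ c).max() < 1e-8

    def test_planted_compartment_leak_removed(self, spec16, geometry16):
        """Simulated WM/CSF signal leaked into brain voxels is gone after
        aCompCor-based confound regression."""
        from thalafc.synthetic import preset_coupling, simulate_subject

        cp = preset_coupling("null")
        subject = simulate_subject(
            spec16, cp, geometry16, ["awake"], set(), seed=77
        )
        img = subject.images["awake"]
        wm = img.data[geometry16.noise.union()].mean(axis=0)  # ≈ leak source
        comps = acompcor_components(img, geometry16.noise, 5)
        confounds = build_confound_matrix(
            MotionTrace.from_dataframe(subject.motion["awake"]), comps
        )
        out = regress_confounds(img, confounds)
        resid = out.data[img.brain_mask]
        wm_c = wm - wm.mean()
        resid_c = resid - resid.mean(axis=1, keepdims=True)
        corr = (resid_c @ wm_c) / (
            np.linalg.norm(resid_c, axis=1) * np.linalg.norm(wm_c)
        )
        assert np.abs(corr).mean() < 0.05


class TestDetrendBandpass:
    def test_linear_ramp_removed(self):
        T = 100
        data = np.tile(np.linspace(-3, 7, T), (2, 2, 2, 1))
        out = detrend_and_bandpass(make_image(data), FilterSpec())
        assert np.abs(out.data).max() < 1e-8

    def test_midband_sinusoid_preserved_within_ten_percent(self):
        T, tr = 200, 2.0
        f_mid = 0.04  # well inside 0.008-0.09 Hz
        t = np.arange(T) * tr
        data = np.zeros((1, 1, 1, T))
        data[0, 0, 0] = np.sin(2 * np.pi * f_mid * t)
        out = detrend_and_bandpass(make_image(data, tr=tr), FilterSpec())
        amp = out.data[0, 0, 0].std() / data[0, 0, 0].std()
        assert 0.9 < amp < 1.1

    def test_far_stopband_attenuated_tenfold(self):
        T, tr = 200, 0.5  # Nyquist 1 Hz, high cutoff 0.09: test 0.9 Hz
        t = np.arange(T) * tr
        data = np.zeros((1, 1, 1, T))
        data[0, 0, 0] = np.sin(2 * np.pi * 0.9 * t)
        out = detrend_and_bandpass(make_image(data, tr=tr), FilterSpec())
        assert out.data[0, 0, 0].std() < 0.1 * data[0, 0, 0].std()

    def test_passband_above_nyquist_rejected(self):
        img = make_image(np.zeros((1, 1, 1, 60)), tr=10.0)  # Nyquist 0.05 Hz
        with pytest.raises(ValueError, match="Nyquist"):
            detrend_and_bandpass(img, FilterSpec(high_cutoff_hz=0.09))

    def test_zero_phase_no_shift_of_midband_peak(self):
        T, tr = 256, 2.0
        t = np.arange(T) * tr
        sig = np.cos(2 * np.pi * 0.04 * t)
        data = np.zeros((1, 1, 1, T))
        data[0, 0, 0] = sig
        out = detrend_and_bandpass(make_image(data, tr=tr), FilterSpec())
        # cross-correlation peak at zero lag
        xc = np.correlate(out.data[0, 0, 0], sig, mode="full")
        assert abs(int(np.argmax(xc)) - (T - 1)) == 0


class TestGaussianSmooth:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(8)
        img = make_image(rng.standard_normal((5, 5, 5, 3)))
        out = gaussian_smooth(img, 0.0)
        np.testing.assert_array_equal(out.data, img.data)

    def test_impulse_response_matches_closed_form_kernel(self):
        shape = (15, 15, 15)
        data = np.zeros(shape + (1,))
        data[7, 7, 7, 0] = 1.0
        fwhm, vox = 6.0, 3.0
        out = gaussian_smooth(make_image(data, voxel_size=(vox,) * 3), fwhm)
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / vox
        # scipy's discrete kernel: sampled Gaussian, renormalized
        radius = int(4 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        center = k1[radius]
        offset1 = k1[radius + 1]
        assert out.data[7, 7, 7, 0] == pytest.approx(center**3, rel=1e-10)
        for neighbour in [(8, 7, 7), (6, 7, 7), (7, 8, 7), (7, 6, 7),
                          (7, 7, 8), (7, 7, 6)]:
            assert out.data[neighbour + (0,)] == pytest.approx(
                offset1 * center**2, rel=1e-10
            )

    def test_constant_volume_unchanged(self):
        img = make_image(np.full((6, 6, 6, 2), 3.5))
        out = gaussian_smooth(img, 6.0)
        np.testing.assert_allclose(out.data, 3.5, rtol=1e-12)


class TestDriver:
    def test_driver_drops_initial_volumes_and_reports_qc(self, spec16, geometry16):
        from thalafc.synthetic import preset_coupling, simulate_subject

        cp = preset_coupling("null")
        subject = simulate_subject(spec16, cp, geometry16, ["awake"], set(), seed=9)
        res = preprocess_subject(
            subject.images["awake"],
            MotionTrace.from_dataframe(subject.motion["awake"]),
            geometry16.noise,
        )
        assert res.image.n_volumes == spec16.n_volumes - 5
        assert res.n_dropped_initial == 5
        assert res.exclusion == "keep"
        assert res.confounds.n_volumes == res.image.n_volumes
        assert res.confounds.labels[:6] == [
            "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"
        ]

    def test_denoising_reduces_brain_variance(self, spec16, geometry16):
        """With planted compartment leak and drift, mean in-brain variance
        strictly decreases through the denoising driver."""
        from thalafc.synthetic import preset_coupling, simulate_subject

        cp = preset_coupling("null")
        subject = simulate_subject(spec16, cp, geometry16, ["awake"], set(), seed=10)
        raw = subject.images["awake"]
        res = preprocess_subject(
            raw, MotionTrace.from_dataframe(subject.motion["awake"]),
            geometry16.noise,
        )
        var_before = raw.data[raw.brain_mask][:, 5:].var(axis=1).mean()
        var_after = res.image.data[res.image.brain_mask].var(axis=1).mean()
        assert var_after < var_before
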