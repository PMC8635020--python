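"""Frequency-analysis pipeline: spectra, shell filter, Sratio, extraction."""

import numpy as np
import pytest
from scipy import ndimage

from myodisarray import (PhantomSpec, RunConfig, Volume, analyze_chunk,
                         analyze_volume, default_delta_f, dissect_chunks,
                         extract_orientation, make_isotropic_grating,
                         make_shell_filter, make_striated_volume,
                         normalize_sratio, pad_spectrum, preprocess_volume,
                         remove_outliers, rotate_and_extract_chunk,
                         smoothed_psds, sratio)
from myodisarray.phantoms import (PSF_SIGMA_XY_UM, PSF_SIGMA_Z_UM,
                                  angles_from_direction)

from conftest import make_field

PSF_BLUR = (PSF_SIGMA_Z_UM / 2.0, PSF_SIGMA_XY_UM / 0.44,
            PSF_SIGMA_XY_UM / 0.44)


def _grating_chunk(theta=0.0, phi=0.0, phase=0.0, blur=True):
    src = make_isotropic_grating(phase_um=phase)
    chunk = rotate_and_extract_chunk(src, theta, phi)
    if blur:
        chunk = ndimage.gaussian_filter(chunk, PSF_BLUR)
    return chunk


class TestChunkGrid:
    def test_grid_shape_is_floor_division(self):
        vol = Volume(np.zeros((40, 720, 720), dtype=np.uint8))
        grid = dissect_chunks(vol, np.ones(vol.data.shape, bool))
        assert grid.chunk_px == (8, 36, 36)
        assert grid.grid_shape == (5, 20, 20)
        assert grid.is_tissue.all()

    def test_tissue_fraction_threshold_is_inclusive(self):
        # 10x10x10-voxel chunks at unit voxel: 0.80 exactly is tissue
        vol = Volume(np.zeros((10, 10, 10), dtype=np.uint8),
                     voxel=(1.0, 1.0, 1.0))
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.ravel()[:800] = True
        grid = dissect_chunks(vol, mask, chunk_um=10.0)
        assert grid.tissue_fraction[0, 0, 0] == pytest.approx(0.80)
        assert grid.is_tissue[0, 0, 0]
        mask.ravel()[790:800] = False  # 0.79
        grid = dissect_chunks(vol, mask, chunk_um=10.0)
        assert not grid.is_tissue[0, 0, 0]

    def test_volume_smaller_than_chunk_raises(self):
        vol = Volume(np.zeros((4, 20, 20), dtype=np.uint8))
        with pytest.raises(ValueError):
            dissect_chunks(vol, np.ones(vol.data.shape, bool))


class TestPadSpectrum:
    def test_zero_chunk_gives_zero_spectrum(self):
        assert not pad_spectrum(np.zeros((8, 36, 36))).any()

    def test_only_central_planes_carry_information(self):
        rng = np.random.default_rng(3)
        chunk = rng.random((8, 36, 36))
        padded = pad_spectrum(chunk)
        spec = np.fft.fftshift(np.fft.fftn(chunk - chunk.mean()))
        np.testing.assert_allclose(padded[14:22], spec)
        assert not padded[:14].any() and not padded[22:].any()
        # energy preserved by the embedding
        assert np.sum(np.abs(padded) ** 2) == pytest.approx(
            np.sum(np.abs(spec) ** 2))

    def test_equivalent_to_sinc_interpolation_along_z(self):
        """Zero-padding the Z frequency axis == trigonometric
        interpolation of the chunk to isotropic 0.44-um sampling."""
        rng = np.random.default_rng(4)
        chunk = rng.random((8, 36, 36))
        padded = pad_spectrum(chunk)
        fine = np.fft.ifftn(np.fft.ifftshift(padded)) * (36 / 8)

        # independent oracle: evaluate the 8-term Fourier series of each
        # (y, x) profile at the 36 fine positions
        centred = chunk - chunk.mean()
        coeffs = np.fft.fft(centred, axis=0)           # k = 0..7
        k = np.fft.fftfreq(8, d=1.0) * 8               # -> -4..3 ordering
        n = np.arange(36)
        basis = np.exp(2j * np.pi * np.outer(n, k) / 36) / 8.0
        oracle = np.einsum("nk,kyx->nyx", basis, coeffs)
        np.testing.assert_allclose(fine, oracle, atol=1e-10)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            pad_spectrum(np.zeros((8, 36, 35)))


class TestShellFilter:
    def test_default_geometry(self, shell):
        assert shell.delta_f == pytest.approx(0.0631, abs=5e-5)
        assert (shell.rho_m, shell.rho, shell.rho_M) == (8, 9, 10)
        assert shell.mask[18, 27, 18]       # offset (0, +9, 0)
        assert not shell.mask[18, 23, 18]   # radius 5, inside the shell

    def test_mask_matches_lattice_enumeration(self, shell):
        count = 0
        for z in range(36):
            for y in range(36):
                for x in range(36):
                    r = np.sqrt((z - 18) ** 2 + (y - 18) ** 2 + (x - 18) ** 2)
                    if 8 <= r <= 10:
                        count += 1
        assert int(shell.mask.sum()) == count

    def test_center_symmetry(self, shell):
        # mirror about the centre voxel (18, 18, 18); index 0 of the even
        # grid has no mirror partner and is excluded
        m = shell.mask[1:, 1:, 1:]
        np.testing.assert_array_equal(m, m[::-1, ::-1, ::-1])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="period"):
            make_shell_filter((36,) * 3, 0.0631, (2.0, 1.6))
        with pytest.raises(ValueError, match="cubic"):
            make_shell_filter((36, 36, 8), 0.0631)


class TestSratio:
    def test_zero_spectrum_gives_zero_psds_and_nan_score(self, shell):
        sxx, sxxf = smoothed_psds(np.zeros((36,) * 3, complex), shell)
        assert not sxx.any() and not sxxf.any()
        assert np.isnan(sratio(sxx, sxxf))

    def test_smoothing_preserves_total_power(self, shell):
        rng = np.random.default_rng(5)
        padded = pad_spectrum(rng.random((8, 36, 36)))
        sxx, sxxf = smoothed_psds(padded, shell)
        raw = np.abs(padded) ** 2
        assert sxx.sum() == pytest.approx(raw.sum(), rel=1e-6)
        assert sxxf.sum() == pytest.approx(raw[shell.mask].sum(), rel=1e-6)

    def test_in_band_grating_scores_high(self, shell):
        chunk = _grating_chunk(blur=False)
        score, _, _ = analyze_chunk(chunk, shell)
        assert score >= 0.5

    def test_white_noise_scores_near_flat_expectation(self, shell):
        rng = np.random.default_rng(6)
        chunk = rng.normal(size=(8, 36, 36))
        sxx, sxxf = smoothed_psds(pad_spectrum(chunk), shell)
        score = sratio(sxx, sxxf)
        # flat spectrum lives on the 8 central planes only
        in_band = sum(1 for dz in range(-4, 4) for dy in range(-18, 18)
                      for dx in range(-18, 18)
                      if 8 <= np.sqrt(dz ** 2 + dy ** 2 + dx ** 2) <= 10)
        expected = in_band / (8 * 36 * 36 - 1)
        assert 0.5 * expected <= score <= 1.5 * expected

    def test_spectrum_entirely_inside_shell_scores_one(self, shell):
        padded = np.zeros((36,) * 3, complex)
        padded[shell.mask & (np.abs(np.indices((36,) * 3)[0] - 18) <= 3)] = 1.0
        sxx, sxxf = smoothed_psds(padded, shell)
        assert sratio(sxx, sxxf) == pytest.approx(1.0, abs=1e-9)


class TestNormalizeSratio:
    def test_min_max_scaling(self):
        field = make_field(np.tile([0, 1.0, 0], (3, 1)), (1, 1, 3))
        for rec, raw in zip(field.iter_records(), (0.1, 0.2, 0.3)):
            rec.sratio_raw = raw
        normalize_sratio(field)
        norms = [r.sratio_norm for r in field.iter_records()]
        assert norms == pytest.approx([0.0, 0.5, 1.0])

    def test_reliability_threshold_is_strict(self):
        field = make_field(np.tile([0, 1.0, 0], (3, 1)), (1, 1, 3))
        for rec, raw in zip(field.iter_records(), (0.0, 0.14, 1.0)):
            rec.sratio_raw = raw
        normalize_sratio(field, threshold=0.14)
        flags = [r.is_reliable for r in field.iter_records()]
        assert flags == [False, False, True]
        for rec, raw in zip(field.iter_records(), (0.0, 0.141, 1.0)):
            rec.sratio_raw = raw
        normalize_sratio(field, threshold=0.14)
        assert [r.is_reliable for r in field.iter_records()][1]

    def test_single_tissue_chunk_is_unreliable(self):
        field = make_field(np.array([[0, 1.0, 0]]), (1, 1, 1))
        field.records[0, 0, 0].sratio_raw = 0.7
        normalize_sratio(field)
        rec = field.records[0, 0, 0]
        assert rec.sratio_norm == 0.0 and not rec.is_reliable


class TestExtractOrientation:
    def test_y_grating_recovers_axis_and_period(self, shell):
        chunk = _grating_chunk(phase=0.3)
        _, direction, freq = analyze_chunk(chunk, shell)
        theta, phi = angles_from_direction(direction)
        assert abs(theta) <= 2.0 and abs(phi) <= 2.0
        assert 1.6 - shell.delta_f <= 1.0 / freq <= 2.0 + shell.delta_f

    def test_azimuth_recovered_within_reference_error(self, shell):
        chunk = _grating_chunk(phi=15.0, phase=0.5)
        _, direction, _ = analyze_chunk(chunk, shell)
        _, phi = angles_from_direction(direction)
        assert abs(phi - 15.0) <= 3.9

    def test_negative_vy_peak_is_flipped(self, shell):
        sxxf = np.zeros((36,) * 3)
        sxxf[18, 18 - 9, 18 + 2] = 1.0   # peak with vy < 0
        direction, _ = extract_orientation(sxxf, shell.delta_f)
        assert direction[1] > 0

    def test_all_zero_filtered_psd_returns_none(self, shell):
        assert extract_orientation(np.zeros((36,) * 3), shell.delta_f) is None

    def test_matches_bruteforce_band_energy_search(self, shell):
        """Centroid peak localization agrees within 2 degrees with an
        exhaustive 1-degree-grid search maximizing in-band energy on
        noiseless plane-wave gratings."""
        rng = np.random.default_rng(8)
        thetas = np.arange(-25.0, 26.0, 1.0)
        phis = np.arange(-25.0, 26.0, 1.0)
        tt, pp = np.meshgrid(thetas, phis, indexing="ij")
        th, ph = np.deg2rad(tt.ravel()), np.deg2rad(pp.ravel())
        dirs = np.stack([np.sin(th), np.cos(th) * np.cos(ph),
                         np.cos(th) * np.sin(ph)])          # (3, n)
        radii = np.arange(8.0, 10.01, 0.25)
        for i in range(30):
            theta0 = float(rng.uniform(-18, 18))
            phi0 = float(rng.uniform(-25, 25))
            spec = PhantomSpec(extent_um=(16.0, 16.0, 16.0),
                               theta_deg=theta0, phi_deg=phi0,
                               noise_sd=0.0, sigma_z_um=0.0,
                               sigma_xy_um=0.0, seed=i)
            chunk = make_striated_volume(spec)[0].data[:8, :36, :36]
            _, sxxf = smoothed_psds(pad_spectrum(chunk.astype(float)), shell)
            direction, _ = extract_orientation(sxxf, shell.delta_f)
            theta_est, phi_est = angles_from_direction(direction)
            # oracle: sample the filtered PSD along each candidate axis
            energy = np.zeros(dirs.shape[1])
            for r in radii:
                energy += ndimage.map_coordinates(sxxf, 18.0 + r * dirs,
                                                  order=1)
            best = int(np.argmax(energy))
            assert abs(theta_est - tt.ravel()[best]) <= 2.0
            assert abs(phi_est - pp.ravel()[best]) <= 2.0


class TestRemoveOutliers:
    @pytest.fixture()
    def uniform_field_with_deviant(self):
        def build(deviant_sratio):
            dirs = np.tile([0.0, 1.0, 0.0], (27, 1)).reshape(3, 3, 3, 3)
            field = make_field(dirs, (3, 3, 3), sratio_norm=0.5)
            rec = field.records[1, 1, 1]
            rec.direction = np.array([0.0, 0.0, 1.0])  # orthogonal
            rec.sratio_norm = deviant_sratio
            return field
        return build

    def test_weak_deviant_flagged(self, uniform_field_with_deviant):
        field = remove_outliers(uniform_field_with_deviant(0.2),
                                base_threshold=0.14)
        rec = field.records[1, 1, 1]
        assert rec.is_outlier and not rec.is_reliable

    def test_strong_deviant_kept(self, uniform_field_with_deviant):
        field = remove_outliers(uniform_field_with_deviant(0.9),
                                base_threshold=0.14)
        assert not field.records[1, 1, 1].is_outlier

    def test_uniform_field_has_no_outliers(self):
        dirs = np.tile([0.0, 1.0, 0.0], (27, 1)).reshape(3, 3, 3, 3)
        field = remove_outliers(make_field(dirs, (3, 3, 3)))
        assert not any(r.is_outlier for r in field.iter_records())


@pytest.fixture(scope="module")
def phantom_field():
    # striated strip along Y with background at the X borders,
    # segmented by the pipeline itself
    spec = PhantomSpec(extent_um=(32, 144, 144), seed=5)
    box = ((0, 32), (8, 136), (40, 104))
    volume, _, axis = make_striated_volume(spec, tissue_box_um=box)
    _, mask, masked = preprocess_volume(volume)
    field = analyze_volume(masked, mask.data)
    grid = dissect_chunks(masked, mask.data)
    return field, axis, grid


class TestAnalyzeVolume:
    def test_uniform_phantom_mostly_reliable(self, phantom_field):
        """Full-tissue chunks are reliable; discards concentrate at the
        strip borders, which the 80% tissue rule is designed to drop."""
        field, axis, grid = phantom_field
        full = [r for r in field.iter_records()
                if r.is_tissue and grid.tissue_fraction[r.index] >= 0.999]
        assert len(full) >= 20
        assert sum(r.is_reliable for r in full) >= 0.9 * len(full)
        mean_dir = field.reliable_directions().mean(axis=0)
        mean_dir /= np.linalg.norm(mean_dir)
        angle = np.degrees(np.arccos(np.clip(np.dot(mean_dir, axis), -1, 1)))
        assert angle <= 3.0

    def test_unreliable_chunks_sit_at_strip_borders(self, phantom_field):
        field, _, grid = phantom_field
        for rec in field.iter_records():
            if rec.is_tissue and not rec.is_reliable:
                assert grid.tissue_fraction[rec.index] < 0.999

    def test_reliable_directions_in_upper_hemisphere(self, phantom_field):
        field, _, _ = phantom_field
        assert (field.reliable_directions()[:, 1] >= 0).all()

    def test_periods_inside_filter_band(self, phantom_field):
        field, _, _ = phantom_field
        df = default_delta_f()
        for rec in field.iter_records():
            if rec.is_reliable:
                assert 1 / (1 / 1.6 + df) - 1e-6 <= rec.period
                assert rec.period <= 1 / (1 / 2.0 - df) + 1e-6

    def test_noise_volume_yields_no_reliable_chunks(self):
        rng = np.random.default_rng(9)
        noisy = Volume((20 + rng.normal(0, 8, (16, 120, 120)))
                       .clip(0, 255).astype(np.uint8))
        _, mask, masked = preprocess_volume(noisy)
        field = analyze_volume(masked, mask.data)
        assert field.n_reliable <= 0.2 * max(field.n_tissue, 1)

    def test_rerun_is_deterministic(self):
        spec = PhantomSpec(extent_um=(16, 80, 80), seed=6)
        volume, mask, _ = make_striated_volume(spec)
        f1 = analyze_volume(volume, mask)
        f2 = analyze_volume(volume, mask)
        for a, b in zip(f1.iter_records(), f2.iter_records()):
            np.testing.assert_array_equal(a.direction, b.direction)
            assert a.is_reliable == b.is_reliable
            assert (a.sratio_raw == b.sratio_raw
                    or (np.isnan(a.sratio_raw) and np.isnan(b.sratio_raw)))
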