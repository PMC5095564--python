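"""Basis rendering, angular-spectrum refocusing, compounding."""

import numpy as np
import pytest

from ssmholo import (
    BasisGeometry,
    FieldImage,
    InvalidArgumentError,
    PropagationParams,
    angular_compound,
    angular_spectrum_propagate,
    coeffs_to_field,
    field_to_coeffs,
    refocus_stack,
    sharpness,
    speckle_contrast,
)
from conftest import random_coeffs


def _dc_coeffs(geometry):
    c = np.zeros(geometry.n_modes, dtype=complex)
    c[(geometry.ny // 2) * geometry.nx + geometry.nx // 2] = 1.0
    return c


class TestBasisGeometry:
    def test_sensor_bookkeeping(self):
        # the 66x60-mode sensor: 5.28 x 4.00 mm FOV, 80 x 67 um spot
        g = BasisGeometry(nx=66, ny=60)
        assert g.n_modes == 3960
        assert g.spot_x * 1000 == pytest.approx(80.0)
        assert g.spot_y * 1000 == pytest.approx(66.7, abs=0.1)

    def test_invalid(self):
        with pytest.raises(InvalidArgumentError):
            BasisGeometry(nx=0, ny=4)
        with pytest.raises(InvalidArgumentError):
            BasisGeometry(nx=8, ny=8, grid_nx=4, grid_ny=16)


class TestBasisRendering:
    def test_dc_coefficient_gives_constant_field(self, small_geometry):
        field = coeffs_to_field(_dc_coeffs(small_geometry), small_geometry)
        assert np.allclose(field.values, field.values.flat[0], rtol=1e-12)

    def test_parseval_constant(self, small_geometry):
        ratios = [
            np.linalg.norm(coeffs_to_field(c, small_geometry).values) ** 2
            / np.linalg.norm(c) ** 2
            for c in (random_coeffs(small_geometry.n_modes, s) for s in range(20))
        ]
        assert np.allclose(ratios, ratios[0], rtol=1e-10)
        assert ratios[0] == pytest.approx(1.0)  # orthonormal synthesis: C = 1

    def test_roundtrip_identity(self, small_geometry):
        c = random_coeffs(small_geometry.n_modes, 9)
        back = field_to_coeffs(
            coeffs_to_field(c, small_geometry), small_geometry
        ).coefficients
        assert np.allclose(back, c, atol=1e-10)

    def test_constant_field_is_dc_only(self, small_geometry):
        g = small_geometry
        field = FieldImage(
            np.ones((g.grid_ny, g.grid_nx), dtype=complex),
            pitch_x=g.pitch_x, pitch_y=g.pitch_y, wavelength_nm=g.wavelength_nm,
        )
        coeffs = field_to_coeffs(field, g).coefficients
        dc_index = (g.ny // 2) * g.nx + g.nx // 2
        others = np.delete(np.abs(coeffs), dc_index)
        assert np.abs(coeffs[dc_index]) > 0
        assert others.max() < 1e-10 * np.abs(coeffs[dc_index])

    def test_projection_is_contraction(self, small_geometry, rng):
        g = small_geometry
        for _ in range(20):
            noise = rng.standard_normal((g.grid_ny, g.grid_nx)) + 1j * (
                rng.standard_normal((g.grid_ny, g.grid_nx))
            )
            field = FieldImage(noise, pitch_x=g.pitch_x, pitch_y=g.pitch_y,
                               wavelength_nm=g.wavelength_nm)
            coeffs = field_to_coeffs(field, g).coefficients
            assert np.linalg.norm(coeffs) <= np.linalg.norm(noise) * (1 + 1e-12)

    def test_length_mismatch(self, small_geometry):
        with pytest.raises(InvalidArgumentError):
            coeffs_to_field(np.ones(5), small_geometry)


def _bandlimited_field(seed=0, n=128, pitch=0.02, wavelength_nm=633.0):
    """Smooth random field, well inside the propagating band."""
    gen = np.random.default_rng(seed)
    spec = np.zeros((n, n), dtype=complex)
    lo = n // 2 - 6
    spec[lo : lo + 12, lo : lo + 12] = gen.standard_normal((12, 12)) + 1j * (
        gen.standard_normal((12, 12))
    )
    values = np.fft.ifft2(np.fft.ifftshift(spec), norm="ortho")
    return FieldImage(values, pitch_x=pitch, pitch_y=pitch,
                      wavelength_nm=wavelength_nm)


class TestAngularSpectrum:
    def test_zero_distance_identity(self):
        f = _bandlimited_field()
        out = angular_spectrum_propagate(f, 0.0)
        assert np.allclose(out.values, f.values, atol=1e-12)

    def test_forward_backward_roundtrip(self):
        f = _bandlimited_field(seed=1)
        out = angular_spectrum_propagate(
            angular_spectrum_propagate(f, 80.0), -80.0
        )
        assert np.linalg.norm(out.values - f.values) <= 1e-9 * np.linalg.norm(
            f.values
        )
        assert out.z_offset == pytest.approx(0.0)

    def test_composition_additivity(self):
        f = _bandlimited_field(seed=2)
        one = angular_spectrum_propagate(f, 37.0)
        two = angular_spectrum_propagate(
            angular_spectrum_propagate(f, 17.0), 20.0
        )
        assert np.linalg.norm(one.values - two.values) <= 1e-9 * np.linalg.norm(
            one.values
        )

    def test_energy_conserved_on_propagating_band(self):
        f = _bandlimited_field(seed=3)
        out = angular_spectrum_propagate(f, 150.0)
        assert np.linalg.norm(out.values) == pytest.approx(
            np.linalg.norm(f.values), rel=1e-9
        )

    def test_gaussian_beam_width_matches_analytic(self):
        # w(z) = w0 sqrt(1 + (z/z_R)^2), z_R = pi w0^2 / lambda
        w0, lam_nm, z = 0.5, 633.0, 200.0  # mm, nm, mm
        n, pitch = 256, 0.04
        coords = (np.arange(n) - n // 2) * pitch
        X, Y = np.meshgrid(coords, coords)
        beam = FieldImage(
            np.exp(-(X**2 + Y**2) / w0**2).astype(complex),
            pitch_x=pitch, pitch_y=pitch, wavelength_nm=lam_nm,
        )
        out = angular_spectrum_propagate(beam, z)
        intensity = np.abs(out.values) ** 2
        # 1/e^2 radius from the intensity second moment: <x^2> = w^2/4
        w_num = 2 * np.sqrt(np.sum(X**2 * intensity) / np.sum(intensity))
        z_r = np.pi * w0**2 / (lam_nm * 1e-6)
        w_analytic = w0 * np.sqrt(1 + (z / z_r) ** 2)
        assert w_num == pytest.approx(w_analytic, rel=0.01)

    def test_invalid_params(self):
        with pytest.raises(InvalidArgumentError):
            PropagationParams(z=np.inf)
        with pytest.raises(InvalidArgumentError):
            PropagationParams(z=1.0, evanescent_policy="reflect")


def _blob_object(center_x, seed, n=128, pitch=0.05):
    """Cluster of small smooth amplitude blobs around lateral center_x (mm)."""
    gen = np.random.default_rng(seed)
    coords = (np.arange(n) - n // 2) * pitch
    X, Y = np.meshgrid(coords, coords)
    a = np.zeros((n, n))
    for _ in range(6):
        x0 = center_x + gen.uniform(-0.8, 0.8)
        y0 = gen.uniform(-0.8, 0.8)
        a += np.exp(-((X - x0) ** 2 + (Y - y0) ** 2) / (2 * 0.08**2))
    return a.astype(complex)


def _two_plane_scene(z_sep=400.0):
    """Two smooth objects: one in focus at z=0 (left), one at z=z_sep (right)."""
    n, pitch, lam = 128, 0.05, 633.0
    f_left = FieldImage(_blob_object(-1.8, 1), pitch_x=pitch, pitch_y=pitch,
                        wavelength_nm=lam)
    f_right = FieldImage(_blob_object(+1.8, 2), pitch_x=pitch, pitch_y=pitch,
                         wavelength_nm=lam)
    # object B lives at +z_sep: back-propagate its field to the native plane
    f_right_native = angular_spectrum_propagate(f_right, -z_sep)
    return FieldImage(
        f_left.values + f_right_native.values,
        pitch_x=pitch, pitch_y=pitch, wavelength_nm=lam,
    )


class TestRefocusStack:
    def test_single_zero_plane(self):
        f = _bandlimited_field(seed=4)
        stack = refocus_stack(f, [0.0])
        assert len(stack) == 1
        assert np.allclose(stack[0].values, f.values, atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(InvalidArgumentError):
            refocus_stack(_bandlimited_field(), [])

    def test_sweep_range_from_original_plane(self):
        # the mirrored -350..+350 mm sweep: each plane from the native field
        f = _bandlimited_field(seed=5)
        zs = np.linspace(-350, 350, 8)
        stack = refocus_stack(f, zs)
        assert [s.z_offset for s in stack] == pytest.approx(list(zs))

    def test_two_plane_scene_sharpness_peaks(self):
        # each object is sharpest when the stack lands on its own plane
        scene = _two_plane_scene(z_sep=400.0)
        zs = np.linspace(-100.0, 500.0, 13)  # includes 0 and 400 exactly
        stack = refocus_stack(scene, zs)
        s_left = [sharpness(np.abs(f.values[:, :64])) for f in stack]
        s_right = [sharpness(np.abs(f.values[:, 64:])) for f in stack]
        assert zs[int(np.argmax(s_left))] == pytest.approx(0.0, abs=1e-9)
        assert zs[int(np.argmax(s_right))] == pytest.approx(400.0, abs=1e-9)


def _speckle_field(seed, n=128, pitch=0.02):
    gen = np.random.default_rng(seed)
    spec = np.zeros((n, n), dtype=complex)
    lo = n // 2 - 16
    spec[lo : lo + 32, lo : lo + 32] = gen.standard_normal((32, 32)) + 1j * (
        gen.standard_normal((32, 32))
    )
    return FieldImage(np.fft.ifft2(np.fft.ifftshift(spec), norm="ortho"),
                      pitch_x=pitch, pitch_y=pitch, wavelength_nm=633.0)


class TestAngularCompound:
    def test_single_hologram_is_its_amplitude(self):
        f = _speckle_field(1)
        out = angular_compound([f], z=25.0)
        expected = np.abs(angular_spectrum_propagate(f, 25.0).values)
        assert np.allclose(out, expected, atol=1e-12)

    def test_contrast_scales_inverse_sqrt_k(self):
        # fully developed speckle over a uniform object: contrast ~ 1/sqrt(K)
        fields = [_speckle_field(100 + k) for k in range(25)]
        c1 = speckle_contrast(angular_compound(fields[:1], z=10.0))
        for k in (4, 16, 25):
            ck = speckle_contrast(angular_compound(fields[:k], z=10.0))
            assert ck / c1 == pytest.approx(1 / np.sqrt(k), rel=0.20)

    def test_contrast_monotone_in_k(self):
        fields = [_speckle_field(200 + k) for k in range(25)]
        contrasts = [
            speckle_contrast(angular_compound(fields[:k], z=0.0))
            for k in (1, 4, 16, 25)
        ]
        assert np.all(np.diff(contrasts) < 0)

    def test_grid_mismatch(self):
        a = _speckle_field(1, n=64)
        b = _speckle_field(2, n=128)
        with pytest.raises(InvalidArgumentError):
            angular_compound([a, b])
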