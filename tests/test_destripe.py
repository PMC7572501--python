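import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from lspost.destripe import (
    FrequencyMask,
    PieFilterSpec,
    apply_frequency_filter,
    binary_wedge,
    build_pie_mask,
    destripe_plane,
    estimate_stripe_angle,
    filter_plane_real,
    stripe_band_energy,
)
from lspost.errors import FilterError
from lspost.phantom import PhantomSpec, generate_phantom


def direct_dft_filter(plane: np.ndarray, mask_values: np.ndarray) -> np.ndarray:
    """O(N^4) direct DFT -> mask -> inverse DFT, independent of numpy's FFT."""
    m, n = plane.shape
    x = plane.astype(np.complex128)
    em = np.exp(-2j * np.pi * np.outer(np.arange(m), np.arange(m)) / m)
    en = np.exp(-2j * np.pi * np.outer(np.arange(n), np.arange(n)) / n)
    spectrum = em @ x @ en  # F[k, l] = sum_mn x[m, n] w^(km) w^(ln)
    # centre the spectrum to align with the mask, multiply, un-centre
    centred = np.roll(np.roll(spectrum, m // 2, axis=0), n // 2, axis=1)
    centred *= mask_values
    uncentred = np.roll(np.roll(centred, -(m // 2), axis=0), -(n // 2), axis=1)
    inv = (em.conj() @ uncentred @ en.conj()) / (m * n)
    return inv.real


def spec_strategy():
    return st.builds(
        PieFilterSpec,
        alpha_deg=st.floats(0, 179.9),
        d1=st.floats(1, 5),
        d2=st.one_of(st.just("nyquist"), st.floats(8, 20)),
        w1=st.floats(0.5, 8),
        w2=st.floats(0.5, 30),
        edge_sigma=st.floats(0, 3),
        attenuation=st.floats(0, 1),
    )


class TestSpecValidation:
    def test_bad_alpha(self):
        with pytest.raises(FilterError):
            PieFilterSpec(alpha_deg=180.0)

    def test_bad_radii(self):
        with pytest.raises(FilterError):
            PieFilterSpec(alpha_deg=10, d1=5, d2=4)
        with pytest.raises(FilterError):
            PieFilterSpec(alpha_deg=10, d1=0.5)

    def test_bad_attenuation(self):
        with pytest.raises(FilterError):
            PieFilterSpec(alpha_deg=10, attenuation=1.5)


class TestBuildMask:
    def test_zero_attenuation_gives_all_ones(self):
        mask = build_pie_mask((32, 32), PieFilterSpec(alpha_deg=30, attenuation=0.0))
        np.testing.assert_array_equal(mask.values, np.ones((32, 32)))

    def test_wedge_axis_at_90_minus_alpha(self):
        # stripes at 30 degrees (spatial) -> wedge axis at 60 degrees (spectral)
        spec = PieFilterSpec(alpha_deg=30, d1=3, d2=14, w1=4, w2=6, edge_sigma=1)
        mask = build_pie_mask((65, 65), spec)
        c = 32

        def ray_min(theta_deg):
            vals = []
            for r in np.arange(4, 13, 0.5):
                u = int(round(r * np.sin(np.deg2rad(theta_deg))))
                v = int(round(r * np.cos(np.deg2rad(theta_deg))))
                vals.append(mask.values[c + u, c + v])
            return min(vals)

        assert ray_min(60) < ray_min(150)
        assert ray_min(60) < 0.5

    def test_point_symmetry_exhaustive(self):
        spec = PieFilterSpec(alpha_deg=73.0, d1=2, d2=12, w1=3, w2=8, edge_sigma=1.5)
        mask = build_pie_mask((33, 33), spec).values
        c = 16
        for u in range(-16, 17):
            for v in range(-16, 17):
                assert abs(mask[c + u, c + v] - mask[c - u, c - v]) < 1e-9

    def test_even_shape_symmetry(self):
        spec = PieFilterSpec(alpha_deg=25.0, d1=2, d2="nyquist", w1=4, w2=20)
        vals = build_pie_mask((32, 32), spec).values
        rows = (2 * 16 - np.arange(32)) % 32
        cols = (2 * 16 - np.arange(32)) % 32
        np.testing.assert_allclose(vals, vals[np.ix_(rows, cols)], atol=1e-9)

    def test_dc_gain_is_one(self):
        spec = PieFilterSpec(alpha_deg=10, d1=1, d2=10, w1=8, w2=8, attenuation=1.0)
        assert build_pie_mask((21, 21), spec).values[10, 10] == 1.0

    def test_d2_clamped_to_nyquist(self):
        spec = PieFilterSpec(alpha_deg=10, d1=2, d2=10_000, w1=3, w2=3)
        mask = build_pie_mask((16, 16), spec)
        assert mask.values.shape == (16, 16)

    def test_too_small_shape(self):
        with pytest.raises(FilterError):
            build_pie_mask((3, 3), PieFilterSpec(alpha_deg=10))

    @settings(max_examples=30, deadline=None)
    @given(spec=spec_strategy(), odd=st.booleans())
    def test_mask_properties_randomized(self, spec, odd):
        shape = (25, 25) if odd else (24, 24)
        vals = build_pie_mask(shape, spec).values
        assert vals.min() >= 0.0 and vals.max() <= 1.0
        assert vals[shape[0] // 2, shape[1] // 2] == 1.0
        rows = (2 * (shape[0] // 2) - np.arange(shape[0])) % shape[0]
        cols = (2 * (shape[1] // 2) - np.arange(shape[1])) % shape[1]
        np.testing.assert_allclose(vals, vals[np.ix_(rows, cols)], atol=1e-9)


class TestApplyFilter:
    def test_all_ones_mask_is_identity(self, random_plane_16):
        mask = FrequencyMask(values=np.ones((32, 32)), shape=(32, 32))
        out = apply_frequency_filter(random_plane_16, mask, "clip")
        np.testing.assert_array_equal(out, random_plane_16)

    @pytest.mark.parametrize("size", [16, 32])
    def test_matches_direct_dft_oracle(self, size, rng):
        plane = rng.integers(0, 65536, (size, size)).astype(np.uint16)
        spec = PieFilterSpec(alpha_deg=40.0, d1=2, d2=size // 2, w1=3, w2=8, edge_sigma=1)
        mask = build_pie_mask((size, size), spec)
        fast = filter_plane_real(plane, mask)
        slow = direct_dft_filter(plane, mask.values)
        scale = np.abs(slow).max()
        np.testing.assert_allclose(fast, slow, atol=1e-6 * scale)

    def test_grating_in_wedge_suppressed(self):
        # grating with wavevector centrally inside the wedge, attenuation 1
        n = 64
        u0, v0 = 10, 6  # spectral angle ~59 deg -> spatial alpha ~31 deg
        y, x = np.mgrid[0:n, 0:n]
        carrier = np.cos(2 * np.pi * (u0 * y + v0 * x) / n)
        plane = np.round(30000 + 10000 * carrier).astype(np.uint16)
        alpha = (90.0 - np.degrees(np.arctan2(u0, v0))) % 180
        spec = PieFilterSpec(
            alpha_deg=alpha, d1=6, d2=20, w1=8, w2=10, edge_sigma=1, attenuation=1.0
        )
        mask = build_pie_mask((n, n), spec)
        raw = filter_plane_real(plane, mask)
        amp_in = 2 * np.abs(np.vdot(carrier, plane.astype(float)) / np.vdot(carrier, carrier))
        amp_out = 2 * np.abs(np.vdot(carrier, raw) / np.vdot(carrier, carrier))
        assert amp_out <= 0.05 * amp_in

    def test_shape_mismatch(self, random_plane_16):
        mask = FrequencyMask(values=np.ones((16, 16)), shape=(16, 16))
        with pytest.raises(FilterError, match="shape"):
            apply_frequency_filter(random_plane_16, mask)

    def test_asymmetric_mask_rejected(self, random_plane_16):
        values = np.ones((32, 32))
        values[3, 7] = 0.0  # break point symmetry
        mask = FrequencyMask(values=values, shape=(32, 32))
        with pytest.raises(FilterError, match="residual"):
            apply_frequency_filter(random_plane_16, mask)

    def test_minmax_rescale_bounds(self, random_plane_16):
        spec = PieFilterSpec(alpha_deg=10.0, d1=2, d2=10, w1=3, w2=6)
        out = destripe_plane(random_plane_16, spec, rescale_mode="minmax")
        assert out.min() >= random_plane_16.min()
        assert out.max() <= random_plane_16.max()


class TestDestripePlane:
    def test_attenuation_zero_is_identity(self, random_plane_16):
        spec = PieFilterSpec(alpha_deg=30.0, d1=2, d2=10, w1=3, w2=6, attenuation=0.0)
        out = destripe_plane(random_plane_16, spec)
        np.testing.assert_array_equal(out, random_plane_16)

    def test_matched_destripe_cuts_band_energy(self, striped_phantom_pair):
        striped, _, _ = striped_phantom_pair
        plane = striped.planes[0]
        spec = PieFilterSpec(alpha_deg=25.0, d1=2, d2="nyquist", w1=8, w2=60, edge_sigma=2)
        out = destripe_plane(plane, spec)
        e_in = stripe_band_energy(plane, spec)
        e_out = stripe_band_energy(out, spec)
        assert e_out <= 0.10 * e_in
        # energy outside the band (hard wedge + its Gaussian transition zone)
        # changes by <= 5%
        band = ndimage.binary_dilation(
            binary_wedge(plane.shape, spec), iterations=int(np.ceil(4 * spec.edge_sigma))
        )
        band[plane.shape[0] // 2, plane.shape[1] // 2] = True  # DC not "outside"

        def outside_energy(p):
            s = np.abs(np.fft.fftshift(np.fft.fft2(p.astype(float)))) ** 2
            return s[~band].sum()

        before, after = outside_energy(plane), outside_energy(out)
        assert abs(after - before) <= 0.05 * before

    def test_stripe_free_plane_nearly_unchanged(self, striped_phantom_pair):
        _, twin, _ = striped_phantom_pair
        plane = twin.planes[0]
        spec = PieFilterSpec(alpha_deg=25.0, d1=3, d2="nyquist", w1=6, w2=40, edge_sigma=2)
        out = destripe_plane(plane, spec)
        rms = np.sqrt(np.mean((out.astype(float) - plane.astype(float)) ** 2))
        assert rms <= 0.02 * 65535


class TestBandEnergy:
    def test_constant_plane_zero(self):
        spec = PieFilterSpec(alpha_deg=45.0, d1=2, d2=10, w1=4, w2=8)
        plane = np.full((32, 32), 1000, np.uint16)
        assert stripe_band_energy(plane, spec) == 0.0

    def test_parseval_partition(self, random_plane_16):
        spec = PieFilterSpec(alpha_deg=70.0, d1=2, d2=12, w1=4, w2=10)
        plane = random_plane_16
        wedge = binary_wedge(plane.shape, spec)
        s = np.abs(np.fft.fftshift(np.fft.fft2(plane.astype(float)))) ** 2
        total = plane.size * np.sum(plane.astype(float) ** 2)  # Parseval, unnormalized DFT
        dc = s[16, 16]
        complement = s[~wedge].sum() - dc
        wedge_energy = stripe_band_energy(plane, spec)
        assert abs((wedge_energy + complement + dc) - total) <= 1e-9 * total

    def test_energy_conserved_with_zero_attenuation(self, random_plane_16):
        spec = PieFilterSpec(alpha_deg=20.0, d1=2, d2=12, w1=4, w2=10, attenuation=0.0)
        mask = build_pie_mask((32, 32), spec)
        raw = filter_plane_real(random_plane_16, mask)
        e_in = np.sum(random_plane_16.astype(float) ** 2)
        e_out = np.sum(raw**2)
        assert abs(e_out - e_in) <= 1e-9 * e_in

    def test_hard_wedge_energy_drops_after_full_suppression(self, striped_phantom_pair):
        striped, _, _ = striped_phantom_pair
        plane = striped.planes[1]
        spec = PieFilterSpec(
            alpha_deg=25.0, d1=3, d2=40, w1=4, w2=12, edge_sigma=0.0, attenuation=1.0
        )
        out = destripe_plane(plane, spec)
        assert stripe_band_energy(out, spec) < stripe_band_energy(plane, spec)


class TestEstimateAngle:
    @pytest.mark.parametrize("alpha", [0, 15, 30, 45, 60, 75, 90, 120, 150])
    def test_angle_recovery(self, alpha):
        stack, _ = generate_phantom(
            PhantomSpec(
                shape=(4, 128, 128),
                stripe_angle_deg=float(alpha),
                occluders_per_plane=15,
                shadow_attenuation=0.5,
                noise_sigma=50.0,
                seed=3,
            )
        )
        est = estimate_stripe_angle(list(stack.planes))
        err = abs(est.angle_deg - alpha) % 180
        err = min(err, 180 - err)
        assert err <= 1.0
        assert not est.low_confidence

    def test_white_noise_low_confidence(self, rng):
        plane = rng.integers(0, 65536, (128, 128)).astype(np.uint16)
        est = estimate_stripe_angle(plane)
        assert est.low_confidence

    def test_constant_plane_rejected(self):
        with pytest.raises(FilterError, match="no spectral energy"):
            estimate_stripe_angle(np.full((32, 32), 7, np.uint16))
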