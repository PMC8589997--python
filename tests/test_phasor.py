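import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phasorflim as pf
from phasorflim.synth import BiomarkerModel


def _single_channel(counts, **kwargs):
    m = pf.AcquisitionMeta(**kwargs)
    return pf.DecayStack(counts={"NADPH": counts}, meta={"NADPH": m})


class TestTransform:
    def test_delta_in_first_bin_on_unit_circle(self, meta):
        counts = np.zeros((2, 2, 24), dtype=np.uint16)
        counts[..., 0] = 100
        ph = pf.phasor_transform(_single_channel(counts))["NADPH"]
        phase = meta.omega * 0.26  # first bin midpoint at 0.26 ns
        assert ph.g[0, 0] == pytest.approx(np.cos(phase), abs=1e-12)
        assert ph.s[0, 0] == pytest.approx(np.sin(phase), abs=1e-12)

    def test_uniform_counts_at_origin(self):
        counts = np.full((3, 3, 24), 10, dtype=np.uint16)
        ph = pf.phasor_transform(_single_channel(counts))["NADPH"]
        np.testing.assert_allclose(ph.g, 0.0, atol=1e-12)
        np.testing.assert_allclose(ph.s, 0.0, atol=1e-12)

    def test_zero_intensity_flagged_invalid(self):
        counts = np.zeros((2, 2, 24), dtype=np.uint16)
        counts[0, 0, 0] = 5
        ph = pf.phasor_transform(_single_channel(counts))["NADPH"]
        assert ph.valid[0, 0] and not ph.valid[1, 1]
        assert np.isnan(ph.g[1, 1])

    @pytest.mark.parametrize("harmonic", [12, 13, 0])
    def test_aliasing_harmonic_rejected(self, harmonic):
        counts = np.ones((2, 2, 24), dtype=np.uint16)
        with pytest.raises(ValueError):
            pf.phasor_transform(_single_channel(counts), harmonic=harmonic)

    def test_linearity_of_mixtures(self):
        """Phasor of a summed stack is the intensity-weighted mean of the
        component phasors (exact, noiseless)."""
        a = pf.simulate_homogeneous(BiomarkerModel(tau_free=0.4),
                                    noiseless=True, photons=300, shape=(4, 4))
        b = pf.simulate_homogeneous(BiomarkerModel(tau_free=3.2),
                                    noiseless=True, photons=700, shape=(4, 4))
        summed = _single_channel(a.counts["NADPH"] + b.counts["NADPH"])
        za = pf.phasor_transform(a)["NADPH"].mean_phasor()
        zb = pf.phasor_transform(b)["NADPH"].mean_phasor()
        zs = pf.phasor_transform(summed)["NADPH"].mean_phasor()
        assert abs(zs - (0.3 * za + 0.7 * zb)) < 1e-12


class TestCalibration:
    def test_reference_already_at_theory_gives_identity(self, meta):
        z = pf.monoexp_phasor(4.0, meta.omega)
        ph = pf.PhasorImage(g=np.full((4, 4), z.real), s=np.full((4, 4), z.imag),
                            intensity=np.full((4, 4), 100.0), harmonic=1,
                            omega=meta.omega, channel="NADPH")
        tr = pf.fit_calibration(ph, known_tau=4.0)
        assert tr.phase_offset == pytest.approx(0.0, abs=1e-12)
        assert tr.modulation_factor == pytest.approx(1.0, abs=1e-12)

    def test_shg_reference_inverts_measured_phase(self, meta):
        phi0, m0 = 0.3, 0.9
        ph = pf.PhasorImage(
            g=np.full((4, 4), m0 * np.cos(phi0)),
            s=np.full((4, 4), m0 * np.sin(phi0)),
            intensity=np.ones((4, 4)), harmonic=1, omega=meta.omega)
        tr = pf.fit_calibration(ph, known_tau=0.0)
        assert tr.phase_offset == pytest.approx(-phi0, abs=1e-12)
        assert tr.modulation_factor == pytest.approx(1 / m0, abs=1e-12)

    def test_one_reference_corrects_all_lifetimes(self, shg_calibrator):
        """Calibrate with fluorescein, then a 0.4 ns stack reads 0.4 ns: the
        binning/IRF factor is lifetime-independent."""
        fl = pf.simulate_reference("fluorescein", noiseless=True, shape=(4, 4))
        cal = pf.PhasorCalibrator(known_tau=4.0).fit(
            pf.phasor_transform(fl)["NADPH"])
        st = pf.simulate_reference("free_NADPH", noiseless=True, shape=(4, 4))
        ph = cal.transform(pf.phasor_transform(st)["NADPH"])
        tau_phi, _ = pf.lifetimes_from_phasor(ph)
        assert np.nanmean(tau_phi) == pytest.approx(0.4, abs=1e-9)

    def test_calibration_idempotence(self, meta):
        st = pf.simulate_reference("SHG", noiseless=True, shape=(4, 4))
        ph = pf.phasor_transform(st)["NADPH"]
        cal = pf.PhasorCalibrator(known_tau=0.0).fit(ph)
        refit = pf.fit_calibration(cal.transform(ph), known_tau=0.0)
        assert abs(refit.phase_offset) < 1e-9
        assert abs(refit.modulation_factor - 1.0) < 1e-9

    def test_degenerate_reference_rejected(self, meta):
        counts = np.full((3, 3, 24), 10, dtype=np.uint16)  # uniform: |z| ~ 0
        ph = pf.phasor_transform(_single_channel(counts))["NADPH"]
        with pytest.raises(ValueError, match="degenerate"):
            pf.PhasorCalibrator(known_tau=0.0).fit(ph)

    def test_inhomogeneous_reference_rejected(self, meta, rng):
        g = rng.uniform(-1, 1, size=(16, 16))
        ph = pf.PhasorImage(g=g, s=g[::-1], intensity=np.ones((16, 16)),
                            harmonic=1, omega=meta.omega)
        with pytest.raises(ValueError, match="homogeneous"):
            pf.PhasorCalibrator(known_tau=0.0).fit(ph)


class TestSmoothing:
    def _image(self, g, meta):
        return pf.PhasorImage(g=g, s=g.copy(), intensity=np.ones(g.shape),
                              harmonic=1, omega=meta.omega)

    def test_constant_unchanged(self, meta):
        ph = self._image(np.full((8, 8), 0.4), meta)
        sm = pf.smooth_phasor(ph)
        np.testing.assert_allclose(sm.g, 0.4, atol=1e-15)

    def test_outlier_replaced_by_neighborhood_median(self, meta):
        g = np.full((7, 7), 0.2)
        g[3, 3] = 0.95
        sm = pf.smooth_phasor(self._image(g, meta))
        assert sm.g[3, 3] == pytest.approx(0.2)

    def test_intensity_untouched_and_kernel_validated(self, meta):
        ph = self._image(np.full((6, 6), 0.1), meta)
        assert pf.smooth_phasor(ph).intensity is ph.intensity
        with pytest.raises(ValueError):
            pf.smooth_phasor(ph, kernel=4)

    def test_filter_reduces_poisson_scatter(self, shg_calibrator):
        st = pf.simulate_homogeneous(
            BiomarkerModel(tau_free=0.4, tau_bound=3.2, f_bound=0.3),
            photons=300, shape=(48, 48), seed=21)
        ph = shg_calibrator.transform(pf.phasor_transform(st)["NADPH"])
        sm = pf.smooth_phasor(ph)
        assert np.std(sm.g) < np.std(ph.g)
        assert np.std(sm.s) < np.std(ph.s)


class TestLifetimes:
    def test_monoexponential_identity(self, shg_calibrator):
        st = pf.simulate_reference("fluorescein", noiseless=True, shape=(4, 4))
        ph = shg_calibrator.transform(pf.phasor_transform(st)["NADPH"])
        tau_phi, tau_mod = pf.lifetimes_from_phasor(ph)
        np.testing.assert_allclose(tau_phi, tau_mod, atol=1e-6)
        np.testing.assert_allclose(tau_phi, 4.0, atol=1e-6)

    def test_unit_circle_origin_is_zero_lifetime(self, meta):
        ph = pf.PhasorImage(g=np.ones((2, 2)), s=np.zeros((2, 2)),
                            intensity=np.ones((2, 2)), harmonic=1,
                            omega=meta.omega, calibrated=True)
        tau_phi, tau_mod = pf.lifetimes_from_phasor(ph)
        np.testing.assert_allclose(tau_phi, 0.0, atol=1e-12)
        np.testing.assert_allclose(tau_mod, 0.0, atol=1e-12)

    def test_mixture_phase_below_modulation_lifetime(self, meta):
        z = 0.5 * pf.monoexp_phasor(0.4, meta.omega) \
            + 0.5 * pf.monoexp_phasor(3.2, meta.omega)
        ph = pf.PhasorImage(g=np.full((2, 2), z.real), s=np.full((2, 2), z.imag),
                            intensity=np.ones((2, 2)), harmonic=1,
                            omega=meta.omega, calibrated=True)
        tau_phi, tau_mod = pf.lifetimes_from_phasor(ph)
        assert np.all(tau_phi < tau_mod)

    def test_uncalibrated_input_rejected(self, meta):
        ph = pf.PhasorImage(g=np.ones((2, 2)), s=np.zeros((2, 2)),
                            intensity=np.ones((2, 2)), harmonic=1,
                            omega=meta.omega, calibrated=False)
        with pytest.raises(ValueError):
            pf.lifetimes_from_phasor(ph)


class TestFractionBound:
    def _ph(self, z, meta):
        return pf.PhasorImage(g=np.full((1, 1), z.real),
                              s=np.full((1, 1), z.imag),
                              intensity=np.ones((1, 1)), harmonic=1,
                              omega=meta.omega, calibrated=True)

    @pytest.mark.parametrize("frac,expected", [(0.0, 0.0), (1.0, 1.0),
                                               (0.5, 0.5), (0.25, 0.25)])
    def test_points_on_chord(self, frac, expected, meta):
        a = pf.monoexp_phasor(0.4, meta.omega)
        b = pf.monoexp_phasor(3.2, meta.omega)
        z = (1 - frac) * a + frac * b
        f = pf.fraction_bound(self._ph(z, meta), a, b)
        assert f[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_off_chord_noise_projected_out(self, meta):
        a, b = complex(0.2, 0.2), complex(0.8, 0.2)
        z = complex(0.5, 0.35)  # displaced perpendicular to the chord
        assert pf.fraction_bound(self._ph(z, meta), a, b)[0, 0] == \
            pytest.approx(0.5, abs=1e-12)
        assert pf.fraction_bound(self._ph(z, meta), a, b, mode="distance")[0, 0] \
            > 0.5

    def test_coincident_anchors_rejected(self, meta):
        with pytest.raises(ValueError, match="coincide"):
            pf.fraction_bound(self._ph(0.5 + 0.2j, meta),
                              (0.3, 0.3), (0.3, 0.3))


class TestGeometry:
    @given(tau=st.floats(min_value=0.0, max_value=50.0,
                         allow_nan=False, allow_infinity=False))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_monoexp_on_universal_semicircle(self, tau):
        z = pf.monoexp_phasor(tau, 2 * np.pi / 12.48)
        assert abs(z - 0.5) == pytest.approx(0.5, abs=1e-12)

    def test_simulated_decays_inside_semicircle(self, shg_calibrator):
        for f in (0.0, 0.3, 0.7, 1.0):
            st_ = pf.simulate_homogeneous(
                BiomarkerModel(tau_free=0.4, tau_bound=3.2, f_bound=f),
                photons=2000, shape=(24, 24), seed=int(10 * f))
            ph = shg_calibrator.transform(pf.phasor_transform(st_)["NADPH"])
            ph = pf.smooth_phasor(ph)
            r2 = (ph.g - 0.5) ** 2 + ph.s ** 2
            assert np.nanmax(r2) <= 0.25 + 0.02  # tolerance shrinks with photons

    @given(lam=st.floats(min_value=1.0, max_value=5000.0, allow_nan=False))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_virtual_wavelength_identity(self, lam):
        assert pf.virtual_wavelength(lam, lam) == pytest.approx(lam, rel=1e-12)

    def test_virtual_wavelength_examples(self):
        assert pf.virtual_wavelength(800, 800) == pytest.approx(800.0)
        with pytest.raises(ValueError):
            pf.virtual_wavelength(-5, 700)
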