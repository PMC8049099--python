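"""Parametric signal model: axes, basis, synthesis, sampling, training sets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrsep.axes import SpectralAxis
from mrsep.basis import SUPPORTED_METABOLITES, MetaboliteBasis, build_default_basis
from mrsep.lineshape import measure_fwhm
from mrsep.params import (MM_POSITIONS_PPM, BoundedGaussian, ComponentParams,
                          default_distributions, sample_parameter_arrays,
                          sample_parameters)
from mrsep.seeds import rng_for
from mrsep.synth import (fids_to_real, generate_training_set, real_to_fids,
                         synthesize_fid)


class TestSpectralAxis:
    def test_dwell_and_conversions_are_consistent(self):
        ax = SpectralAxis(256, 2000.0, field_mhz=127.7, ref_ppm=4.7)
        assert ax.dwell == 1.0 / 2000.0
        assert ax.time[1] - ax.time[0] == pytest.approx(ax.dwell)
        # ppm <-> Hz is affine and invertible; water maps to 0 Hz
        assert ax.ppm_to_hz(4.7) == 0.0
        for ppm in (0.9, 2.01, 3.03):
            assert ax.hz_to_ppm(ax.ppm_to_hz(ppm)) == pytest.approx(ppm)
        # increasing ppm -> increasing frequency offset
        assert ax.ppm_to_hz(3.0) > ax.ppm_to_hz(2.0)

    def test_unitary_spectrum_preserves_noise_scale(self, rng):
        ax = SpectralAxis(512, 2000.0)
        noise = rng.normal(size=(200, 512)) + 1j * rng.normal(size=(200, 512))
        spec = ax.spectrum(noise)
        assert np.std(spec.real) == pytest.approx(np.std(noise.real), rel=0.02)

    def test_invalid_construction_rejected(self):
        with pytest.raises(ValueError):
            SpectralAxis(0, 2000.0)
        with pytest.raises(ValueError):
            SpectralAxis(64, -1.0)


class TestBasis:
    def test_unknown_metabolite_raises_with_supported_list(self, axis):
        with pytest.raises(ValueError, match="NAA"):
            build_default_basis(axis, ["NAA", "NotAMolecule"])

    def test_decay_free_basis_has_constant_modulus(self, axis):
        b = build_default_basis(axis, ["NAA"])
        # single-line part dominates; modulus at t=0 equals sum of amplitudes
        assert abs(b.fids[0, 0]) == pytest.approx(sum(a for _, a in b.lines["NAA"]))

    def test_t0_value_equals_amplitude_sum(self, axis):
        b = build_default_basis(axis)
        for i, name in enumerate(b.names):
            assert b.fids[i, 0] == pytest.approx(
                sum(a for _, a in b.lines[name]), rel=1e-12)

    def test_naa_spectrum_peaks_at_its_chemical_shift(self, full_axis):
        b = build_default_basis(full_axis, ["NAA"])
        spec = np.abs(full_axis.spectrum(b.fids[0], zero_fill=8))
        freqs = np.fft.fftshift(np.fft.fftfreq(full_axis.n_points * 8,
                                               d=full_axis.dwell))
        peak_hz = freqs[int(np.argmax(spec))]
        expected = full_axis.ppm_to_hz(2.008)
        assert abs(peak_hz - expected) <= full_axis.bandwidth / full_axis.n_points

    def test_determinism(self, axis):
        b1 = build_default_basis(axis)
        b2 = build_default_basis(axis)
        np.testing.assert_array_equal(b1.fids, b2.fids)


class TestSynthesis:
    def test_component_additivity_is_exact(self, full_axis, full_basis, dists):
        from mrsep.params import sample_parameter_batch
        p = sample_parameter_batch(dists, "both", rng_for(5, "t"), 1)[0]
        met = synthesize_fid(p, full_basis, full_axis, "metabolite")
        mm = synthesize_fid(p, full_basis, full_axis, "mm")
        both = synthesize_fid(p, full_basis, full_axis, "both")
        np.testing.assert_array_equal(met + mm, both)

    def test_gaussian_mm_fwhm_matches_linewidth(self, full_axis):
        for w in (10.0, 25.0, 50.0):
            p = ComponentParams(mm_amp=[1.0], mm_width_hz=[w],
                                mm_df_hz=[0.0], mm_phase=[0.0])
            fid = synthesize_fid(p, None, full_axis, "mm")
            bin_hz = full_axis.bandwidth / full_axis.n_points
            assert abs(measure_fwhm(fid, full_axis) - w) <= bin_hz

    def test_lorentzian_fwhm_is_inverse_pi_t2star(self, full_axis):
        flat = MetaboliteBasis(names=["X"], fids=np.ones((1, 512)), axis=full_axis)
        for t2 in (0.05, 0.1):
            p = ComponentParams(met_names=["X"], met_conc=[1.0], met_t2star=[t2],
                                met_df_hz=[0.0], met_phase=[0.0])
            fid = synthesize_fid(p, flat, full_axis, "metabolite")
            np.testing.assert_allclose(fid, np.exp(-full_axis.time / t2))
            bin_hz = full_axis.bandwidth / full_axis.n_points
            assert abs(measure_fwhm(fid, full_axis) - 1 / (np.pi * t2)) <= bin_hz

    @settings(deadline=None, max_examples=20)
    @given(alpha=st.floats(-np.pi, np.pi))
    def test_global_phase_rotates_fid_exactly(self, alpha):
        axis = SpectralAxis(64, 2000.0)
        p = ComponentParams(mm_amp=[1.0, 0.5], mm_width_hz=[20.0, 40.0],
                            mm_df_hz=[-100.0, 50.0], mm_phase=[0.1, -0.2])
        base = synthesize_fid(p, None, axis, "mm")
        rotated = synthesize_fid(p.with_phi0(alpha), None, axis, "mm")
        np.testing.assert_allclose(rotated, base * np.exp(1j * alpha),
                                   rtol=1e-12, atol=1e-12)

    def test_frequency_shift_moves_spectrum_by_delta(self, full_axis):
        delta = 125.0  # Hz, a whole number of bins away from an exact bin
        p0 = ComponentParams(mm_amp=[1.0], mm_width_hz=[20.0],
                             mm_df_hz=[-200.0], mm_phase=[0.0])
        p1 = ComponentParams(mm_amp=[1.0], mm_width_hz=[20.0],
                             mm_df_hz=[-200.0 + delta], mm_phase=[0.0])
        s0 = np.abs(full_axis.spectrum(synthesize_fid(p0, None, full_axis, "mm")))
        s1 = np.abs(full_axis.spectrum(synthesize_fid(p1, None, full_axis, "mm")))
        bin_hz = full_axis.bandwidth / full_axis.n_points
        k0, k1 = int(np.argmax(s0)), int(np.argmax(s1))
        assert abs((k1 - k0) * bin_hz - delta) <= bin_hz

    def test_zero_amplitudes_give_zero_fid(self, axis, basis):
        p = ComponentParams(met_names=list(basis.names),
                            met_conc=np.zeros(len(basis)),
                            met_t2star=np.full(len(basis), 0.05),
                            met_df_hz=np.zeros(len(basis)),
                            met_phase=np.zeros(len(basis)),
                            mm_amp=np.zeros(13), mm_width_hz=np.full(13, 20.0),
                            mm_df_hz=np.zeros(13), mm_phase=np.zeros(13))
        np.testing.assert_array_equal(synthesize_fid(p, basis, axis, "both"), 0)

    def test_nonfinite_parameters_rejected(self, axis, basis):
        with pytest.raises(ValueError):
            ComponentParams(mm_amp=[np.nan], mm_width_hz=[20.0],
                            mm_df_hz=[0.0], mm_phase=[0.0])


class TestSampling:
    def test_zero_std_returns_means(self, dists):
        import dataclasses
        d0 = dataclasses.replace(
            dists,
            met_conc={k: BoundedGaussian(v.mean, 0.0, v.lo, v.hi)
                      for k, v in dists.met_conc.items()},
            met_t2star=BoundedGaussian(0.06, 0.0, 0.005, 0.2),
            met_shift_hz=BoundedGaussian(0.0, 0.0, -10, 10),
            phi0_std_deg=0.0, met_phase_std_deg=0.0)
        p = sample_parameters(d0, "metabolite", 3)
        np.testing.assert_allclose(p.met_conc,
                                   [v.mean for v in dists.met_conc.values()])
        np.testing.assert_allclose(p.met_t2star, 0.06)
        assert p.phi0 == 0.0

    def test_bounds_respected_over_many_draws(self, dists):
        arr = sample_parameter_arrays(dists, "both", rng_for(7, "x"), 10_000)
        assert arr["met_t2star"].min() >= 0.005
        assert arr["met_t2star"].max() <= 0.200
        assert arr["met_conc"].min() >= 0.0
        assert arr["met_conc"].max() <= 2.0
        assert arr["mm_width_hz"].min() >= 5.0
        assert arr["mm_width_hz"].max() <= 70.0
        assert arr["mm_amp"].min() >= 0.0

    def test_phi0_distribution_matches_prescription(self, dists):
        arr = sample_parameter_arrays(dists, "macromolecule", rng_for(7, "y"),
                                      10_000)
        std_deg = np.rad2deg(arr["phi0"].std())
        se = 25.0 / np.sqrt(2 * 10_000)  # standard error of the sample std
        assert abs(std_deg - 25.0) < 3 * se

    def test_infeasible_bounds_error_after_attempt_cap(self):
        bad = BoundedGaussian(100.0, 0.01, 0.0, 1.0)
        with pytest.raises(RuntimeError, match="rejection"):
            bad.sample(np.random.default_rng(0), 100, max_tries=5)


class TestTrainingSet:
    def test_shape_normalization_and_roundtrip(self, axis, basis, dists):
        ts = generate_training_set(100, "metabolite", dists, basis, axis, 9)
        assert ts.samples.shape == (100, 2 * axis.n_points)
        assert np.abs(ts.samples).max() <= 1.0
        assert np.abs(ts.samples).max() == pytest.approx(1.0)
        # de-normalization reproduces the raw synthesis exactly
        np.testing.assert_array_equal(real_to_fids(fids_to_real(ts.fids())),
                                      ts.fids())

    def test_same_seed_is_bit_identical(self, axis, basis, dists):
        a = generate_training_set(50, "macromolecule", dists, None, axis, 4)
        b = generate_training_set(50, "macromolecule", dists, None, axis, 4)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert a.norm_scale == b.norm_scale

    def test_mm_set_uses_the_13_reported_positions(self, axis, dists):
        assert len(MM_POSITIONS_PPM) == 13
        assert MM_POSITIONS_PPM == (0.9, 1.21, 1.38, 1.63, 2.01, 2.09, 2.25,
                                    2.61, 2.96, 3.11, 3.67, 3.8, 3.96)
        arr = sample_parameter_arrays(dists, "macromolecule", rng_for(2, "z"),
                                      500, field_mhz=axis.field_mhz,
                                      ref_ppm=axis.ref_ppm)
        centers = arr["mm_df_hz"].mean(axis=0)
        expected = (np.asarray(MM_POSITIONS_PPM) - axis.ref_ppm) * axis.field_mhz
        np.testing.assert_allclose(centers, expected, atol=1.0)

    def test_metabolite_set_covers_nine_names(self, axis, basis, dists):
        assert tuple(basis.names) == SUPPORTED_METABOLITES
        assert len(basis.names) == 9
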