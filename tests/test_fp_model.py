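"""Forward optical model: phase, reflectance, spectra, thermal drift."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fpsense
from fpsense import (
    FPCavityParams,
    GridResolutionError,
    InvalidGeometryError,
    InvalidInputError,
    ResolutionWarning,
    ThermalParams,
)
from fpsense.fp_model import MIN_SAMPLES_PER_FRINGE

from conftest import odd_order_resonances


class TestPhase:
    def test_resonance_condition(self):
        # lam = 4 n d / (2k+1) makes the phase an odd multiple of pi
        p = FPCavityParams(d_um=200.0)
        for k in (0, 5, 400):
            lam = 4 * p.n * p.d_nm / (2 * k + 1)
            assert fpsense.phase(lam, p) == pytest.approx((2 * k + 1) * np.pi, rel=1e-12)

    def test_direct_substitution(self):
        p = FPCavityParams(d_um=300.0, n=1.0)
        assert fpsense.phase(1550.0, p) == pytest.approx(4 * np.pi * 3e5 / 1550.0)

    def test_phi0_additivity(self):
        p0 = FPCavityParams(d_um=300.0, phi0=0.0)
        p1 = FPCavityParams(d_um=300.0, phi0=np.pi)
        assert fpsense.phase(1550.0, p1) - fpsense.phase(1550.0, p0) == pytest.approx(np.pi)

    def test_rejects_nonpositive_wavelength(self):
        p = FPCavityParams(d_um=300.0)
        with pytest.raises(InvalidInputError):
            fpsense.phase(0.0, p)
        with pytest.raises(InvalidInputError):
            fpsense.phase(np.array([1550.0, -1.0]), p)


class TestReflectance:
    def test_single_surface_limit(self):
        # R2 = 0 removes the second beam: flat reflectance R1 at any phase
        p = FPCavityParams(d_um=300.0, r1=0.04, r2=0.0)
        deltas = np.linspace(0, 4 * np.pi, 17)
        assert fpsense.reflectance_at_phase(deltas, p) == pytest.approx(0.04)

    @pytest.mark.parametrize(
        "cos_sign, expected",
        [(-1.0, 0.9933221), (+1.0, 0.9850375)],
        ids=["antiphase_max", "inphase_min"],
    )
    def test_hand_evaluated_extrema(self, cos_sign, expected):
        # frozen from direct evaluation of the two-beam formula with
        # R1=0.04, R2=0.99, q=1: cross term 2*sqrt(0.0396)=0.39799497
        p = FPCavityParams(d_um=300.0, r1=0.04, r2=0.99, q=1.0)
        delta = np.pi if cos_sign < 0 else 2 * np.pi
        assert fpsense.reflectance_at_phase(delta, p) == pytest.approx(expected, abs=1e-7)

    def test_periodic_with_maxima_at_odd_pi(self):
        p = FPCavityParams(d_um=300.0)
        delta = np.linspace(0.0, 2 * np.pi, 10001)
        r = fpsense.reflectance_at_phase(delta, p)
        assert np.argmax(r) == pytest.approx(5000, abs=1)  # delta = pi
        assert r[0] == pytest.approx(r[-1], rel=1e-12)  # period 2 pi
        assert fpsense.reflectance_at_phase(np.pi, p) > fpsense.reflectance_at_phase(0.0, p)

    def test_physical_range(self):
        p = FPCavityParams(d_um=300.0)
        spec = fpsense.generate_spectrum(p)
        assert np.all(spec.intensities >= 0.0) and np.all(spec.intensities <= 1.0)


class TestGenerateSpectrum:
    def test_fringe_count_matches_odd_order_oracle(self, cavity_300, spectrum_300):
        oracle = odd_order_resonances(300.0)
        y = spectrum_300.intensities
        interior_maxima = np.sum((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]))
        assert interior_maxima == oracle.size == 20

    @given(st.integers(min_value=0, max_value=800))
    def test_fringe_count_oracle_equivalence_on_lattice(self, step):
        # d on a 0.5 um lattice over [100, 500] um
        d = 100.0 + 0.5 * step
        spec = fpsense.generate_spectrum(FPCavityParams(d_um=d))
        y = spec.intensities
        interior_maxima = int(np.sum((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])))
        assert interior_maxima == odd_order_resonances(d).size

    def test_subwavelength_cavity_single_fringe(self):
        spec = fpsense.generate_spectrum(FPCavityParams(d_um=0.3875))
        y = spec.intensities
        assert np.sum((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) <= 1

    def test_doubling_d_halves_fsr(self):
        # FSR ~ lam^2 / (2 n d) near 1550 nm
        for d in (150.0, 300.0):
            res = fpsense.resonance_wavelengths(FPCavityParams(d_um=d))
            mid = np.argmin(np.abs(res - 1550.0))
            fsr = res[mid + 1] - res[mid]
            assert fsr == pytest.approx(1550.0**2 / (2 * d * 1e3), rel=0.01)

    def test_coarse_grid_warns_then_errors(self):
        p = FPCavityParams(d_um=300.0)
        with pytest.warns(ResolutionWarning):
            fpsense.generate_spectrum(p, n_samples=300)
        with pytest.raises(GridResolutionError):
            fpsense.generate_spectrum(p, n_samples=300, on_coarse_grid="error")
        # fine grids stay silent
        fsr = 1510.0**2 / (2 * 300e3)
        needed = int(80.0 / fsr * MIN_SAMPLES_PER_FRINGE) + 2
        fpsense.generate_spectrum(p, n_samples=max(needed, 2000))


class TestThermal:
    THERMAL = ThermalParams(gauge_length_mm=6.0, alpha_expander=15e-6, alpha_fiber=5.5e-7)

    def test_mismatch_model_value(self):
        sens = fpsense.temperature_sensitivity(self.THERMAL, 300.0)
        assert round(sens, 3) == 0.087

    def test_linear_in_coefficients_and_increasing_in_d(self):
        t2 = ThermalParams(6.0, 30e-6, 11e-7)
        assert fpsense.temperature_sensitivity(t2, 300.0) == pytest.approx(
            2 * fpsense.temperature_sensitivity(self.THERMAL, 300.0)
        )
        s = [fpsense.temperature_sensitivity(self.THERMAL, d) for d in (100.0, 300.0, 500.0)]
        assert s[0] < s[1] < s[2]

    def test_limits(self):
        # matched CTEs with zero cavity: no net drift
        matched = ThermalParams(6.0, 1e-6, 1e-6)
        assert fpsense.temperature_sensitivity(matched, 0.0) == pytest.approx(0.0)
        # cavity approaching the gauge length: expander term only
        near = fpsense.temperature_sensitivity(self.THERMAL, 5999.999)
        assert near == pytest.approx(6000.0 * 15e-6, rel=1e-4)

    def test_invalid_geometry(self):
        with pytest.raises(InvalidGeometryError):
            fpsense.temperature_sensitivity(self.THERMAL, 6000.0)

    def test_apply_temperature(self):
        assert fpsense.apply_temperature(300.0, 0.0, self.THERMAL) == 300.0
        drifted = fpsense.apply_temperature(300.0, 20.0, self.THERMAL)
        assert drifted - 300.0 == pytest.approx(20 * 0.086865, abs=1e-6)
        # empirically fitted oven sensitivity used directly
        emp = fpsense.apply_temperature(300.0, 20.0, sensitivity_um_per_c=0.1081)
        assert emp - 300.0 == pytest.approx(2.162)

    def test_apply_temperature_needs_a_sensitivity(self):
        with pytest.raises(InvalidInputError):
            fpsense.apply_temperature(300.0, 5.0)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"d_um": -1.0},
            {"d_um": 300.0, "r1": 1.5},
            {"d_um": 300.0, "r2": -0.1},
            {"d_um": 300.0, "q": 0.0},
            {"d_um": 300.0, "n": 0.5},
        ],
    )
    def test_bad_cavity_params(self, kwargs):
        with pytest.raises(InvalidInputError):
            FPCavityParams(**kwargs)

    def test_spectrum_invariants(self):
        with pytest.raises(InvalidInputError):
            fpsense.ReflectionSpectrum(np.array([1550.0, 1540.0]), np.array([0.5, 0.5]))
        with pytest.raises(InvalidInputError):
            fpsense.ReflectionSpectrum(np.array([1540.0, 1550.0]), np.array([0.5, np.nan]))
        with pytest.raises(InvalidInputError):
            fpsense.ReflectionSpectrum(np.array([1540.0, 1550.0]), np.array([0.5, -0.1]))
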