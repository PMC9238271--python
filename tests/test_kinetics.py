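"""Formation, permeability, and biexponential-exposure estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from entfkit.kinetics import (
    BiexpProfile,
    TimeCourse,
    cumulative_amounts,
    exposure,
    exposure_ratio,
    fit_biexponential,
    fit_formation,
    fit_papp,
)

GRID = (0.0, 5.0, 10.0, 30.0, 60.0, 120.0, 180.0)


def formation_tc(f_inf, k, times=GRID):
    t = np.asarray(times)
    return TimeCourse(tuple(t), tuple(f_inf * (1 - np.exp(-k * t))),
                      unit="percent_formed")


class TestFormation:
    @pytest.mark.parametrize("k, rate", [(0.0171, 1.71), (0.0011, 0.11)])
    def test_noiseless_recovery_of_initial_rate(self, k, rate):
        fit = fit_formation(formation_tc(100.0, k))
        assert fit.rate == pytest.approx(rate, rel=1e-6)
        assert fit.k == pytest.approx(k, rel=1e-6)

    def test_all_zero_series_degenerates_to_zero_rate(self):
        tc = TimeCourse(GRID, (0,) * 7, unit="percent_formed")
        fit = fit_formation(tc)
        assert fit.k == 0.0 and fit.rate == 0.0

    def test_negative_responses_rejected(self):
        with pytest.raises(ValueError):
            fit_formation(TimeCourse((0, 5, 10, 30), (0, -1, 2, 3)))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_formation(TimeCourse((0, 5, 10), (0, 1, 2)))

    def test_scale_equivariance(self):
        tc = formation_tc(100.0, 0.0171)
        scaled = TimeCourse(tc.times, tuple(3.0 * y for y in tc.responses))
        assert fit_formation(scaled).rate == pytest.approx(
            3.0 * fit_formation(tc).rate, rel=1e-6
        )


class TestTimeCourse:
    @pytest.mark.parametrize("times", [(0, 5, 5), (5, 0), (-1, 2)])
    def test_bad_time_axes_rejected(self, times):
        with pytest.raises(ValueError):
            TimeCourse(times, tuple(range(len(times))))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            TimeCourse((0, 1), (1,))


class TestPapp:
    AREA, C0 = 1.12, 1e-9  # cm^2, mol/cm^3

    def test_noiseless_amounts_invert_definition(self):
        papp = 3.67e-9
        slope = papp * self.AREA * self.C0  # mol/s
        t = np.array([30.0, 60.0, 90.0, 120.0])
        tc = TimeCourse(tuple(t), tuple(slope * t * 60.0), unit="amount_mol")
        fit = fit_papp(tc, area_cm2=self.AREA, c0_mol_per_cm3=self.C0)
        assert fit.papp == pytest.approx(papp, rel=1e-9)

    def test_zero_slope_gives_zero_papp(self):
        tc = TimeCourse((30, 60, 90, 120), (1e-15,) * 4, unit="amount_mol")
        assert fit_papp(tc).papp == pytest.approx(0.0, abs=1e-18)

    def test_sampling_correction_recovers_linear_transport(self):
        """Receiver concentrations diluted by replaced aliquots rebuild
        the exact cumulative amounts."""
        slope, vr, vs = 4e-18, 1500.0, 300.0  # mol/s, uL, uL
        t = np.array([30.0, 60.0, 90.0, 120.0])
        conc, amount, prev = [], 0.0, 0.0
        for tk in t:
            amount += slope * (tk - prev) * 60.0
            conc.append(amount / vr)
            amount *= 1 - vs / vr
            prev = tk
        q = cumulative_amounts(conc, vr, vs)
        assert np.allclose(q, slope * t * 60.0, rtol=1e-12)
        tc = TimeCourse(tuple(t), tuple(conc), unit="receiver_conc_mol_per_ul")
        fit = fit_papp(tc, area_cm2=self.AREA, c0_mol_per_cm3=self.C0,
                       sample_volume_ul=vs, receiver_volume_ul=vr)
        assert fit.papp == pytest.approx(slope / (self.AREA * self.C0), rel=1e-9)

    @pytest.mark.parametrize("kwargs", [
        {"area_cm2": 0.0}, {"c0_mol_per_cm3": -1e-9},
    ])
    def test_bad_geometry_rejected(self, kwargs):
        tc = TimeCourse((30, 60, 90, 120), (1, 2, 3, 4), unit="amount_mol")
        with pytest.raises(ValueError):
            fit_papp(tc, **kwargs)

    def test_scale_equivariance(self):
        t = np.array([30.0, 60.0, 90.0, 120.0])
        tc = TimeCourse(tuple(t), tuple(2e-18 * t), unit="amount_mol")
        scaled = TimeCourse(tc.times, tuple(5 * y for y in tc.responses),
                            unit="amount_mol")
        assert fit_papp(scaled).papp == pytest.approx(5 * fit_papp(tc).papp,
                                                      rel=1e-9)


def biexp_tc(profile, times):
    t = np.asarray(times, dtype=float)
    c = np.where(t <= profile.breakpoint,
                 profile.A * np.exp(-profile.alpha * t),
                 profile.B * np.exp(-profile.beta * t))
    return TimeCourse(tuple(t), tuple(c), unit="nM")


class TestBiexponential:
    TIMES = (5, 10, 15, 20, 25, 30, 45, 60, 90, 120, 150, 180)

    def test_noiseless_exact_recovery(self):
        true = BiexpProfile(A=100.0, alpha=0.05, B=60.0, beta=0.01)
        fit = fit_biexponential(biexp_tc(true, self.TIMES))
        for attr in ("A", "alpha", "B", "beta"):
            assert getattr(fit, attr) == pytest.approx(getattr(true, attr),
                                                       rel=1e-9)

    def test_single_phase_data_gives_equal_decay_constants(self):
        mono = BiexpProfile(A=50.0, alpha=0.02, B=50.0, beta=0.02)
        fit = fit_biexponential(biexp_tc(mono, self.TIMES))
        assert fit.alpha == pytest.approx(fit.beta, rel=1e-9)

    def test_noisy_recovery_within_ten_percent(self):
        true = BiexpProfile(A=100.0, alpha=0.05, B=60.0, beta=0.01)
        rng = np.random.default_rng(3)
        tc0 = biexp_tc(true, (5, 10, 20, 30, 60, 90, 120, 180))
        noisy = TimeCourse(
            tc0.times,
            tuple(y * math.exp(rng.normal(0, 0.02)) for y in tc0.responses),
            unit="nM",
        )
        fit = fit_biexponential(noisy)
        for attr in ("A", "alpha", "B", "beta"):
            assert getattr(fit, attr) == pytest.approx(getattr(true, attr),
                                                       rel=0.10)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            fit_biexponential(TimeCourse((5, 10, 40, 80), (1.0, 0.0, 2.0, 1.0)))

    def test_too_few_points_per_phase_rejected(self):
        with pytest.raises(ValueError):
            fit_biexponential(TimeCourse((5, 10, 20, 60), (4, 3, 2, 1)))


class TestExposure:
    def test_zero_amplitudes_give_zero_exposure(self):
        prof = BiexpProfile(A=0.0, alpha=0.05, B=0.0, beta=0.01)
        assert exposure(prof, 1440.0) == 0.0

    def test_matches_quadrature_oracle(self):
        prof = BiexpProfile(A=100.0, alpha=0.05, B=60.0, beta=0.01)
        val = exposure(prof, 1440.0)
        ref = (
            quad(lambda t: prof.A * math.exp(-prof.alpha * t), 0, 30)[0]
            + quad(lambda t: prof.B * math.exp(-prof.beta * t), 30, 1440)[0]
        )
        assert val == pytest.approx(ref, rel=1e-10)
        assert val == pytest.approx(5998.6, abs=0.5)

    def test_window_at_breakpoint_keeps_first_phase_only(self):
        prof = BiexpProfile(A=80.0, alpha=0.04, B=50.0, beta=0.02)
        first = prof.A / prof.alpha * (1 - math.exp(-30 * prof.alpha))
        assert exposure(prof, 30.0 + 1e-12) == pytest.approx(first, rel=1e-9)

    @pytest.mark.parametrize("alpha, beta", [(0.0, 0.01), (0.05, -0.1)])
    def test_nonpositive_decay_rejected(self, alpha, beta):
        with pytest.raises(ValueError):
            exposure(BiexpProfile(A=1, alpha=alpha, B=1, beta=beta), 1440)

    def test_window_before_breakpoint_rejected(self):
        with pytest.raises(ValueError):
            exposure(BiexpProfile(A=1, alpha=0.1, B=1, beta=0.01), 10.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_monotonicity_in_parameters(self, seed):
        """Exposure grows with x, A, B and shrinks with alpha, beta."""
        rng = np.random.default_rng(seed)
        A, B = rng.uniform(1, 200, size=2)
        alpha = rng.uniform(0.01, 0.2)
        beta = rng.uniform(0.001, alpha)
        x = rng.uniform(60, 2000)
        base = BiexpProfile(A=A, alpha=alpha, B=B, beta=beta)
        e0 = exposure(base, x)
        # strictly increasing in x until the terminal tail has fully
        # decayed to floating-point saturation
        if beta * x < 20:
            assert exposure(base, x * 1.5) > e0
        else:
            assert exposure(base, x * 1.5) >= e0
        assert exposure(BiexpProfile(A=A * 1.1, alpha=alpha, B=B, beta=beta), x) > e0
        assert exposure(BiexpProfile(A=A, alpha=alpha, B=B * 1.1, beta=beta), x) > e0
        assert exposure(BiexpProfile(A=A, alpha=alpha * 1.1, B=B, beta=beta), x) < e0
        assert exposure(BiexpProfile(A=A, alpha=alpha, B=B, beta=beta * 1.1), x) < e0


class TestExposureRatio:
    def test_unit_ratio(self):
        # profile whose 0-1440 exposure equals 1440 nM*min
        prof = BiexpProfile(A=0.0, alpha=0.05, B=0.0, beta=0.01)
        prof2 = BiexpProfile(A=prof.A, alpha=prof.alpha,
                             B=1440.0 / (
                                 (math.exp(-0.01 * 30) - math.exp(-0.01 * 1440))
                                 / 0.01),
                             beta=0.01)
        assert exposure_ratio(prof2, 1.0) == pytest.approx(1.0, rel=1e-9)

    def test_zero_endogenous_rejected(self):
        prof = BiexpProfile(A=1, alpha=0.05, B=1, beta=0.01)
        with pytest.raises(ValueError):
            exposure_ratio(prof, 0.0)
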