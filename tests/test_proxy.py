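"""d11B -> pH conversion: calibration, borate equation, Monte-Carlo envelope."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boronph.exceptions import InvalidInputError, UninvertibleError
from boronph.proxy import (
    CalibrationModel,
    ProxyParams,
    borate_from_skeletal,
    delta11B_borate_from_ph,
    measurement_2sigma,
    ph_deterministic,
    ph_from_borate,
    reconstruct,
    seawater_d11b_summary,
    skeletal_from_borate,
)
from boronph.synthetic import coverage_records


class TestMeasurementError:
    def test_printed_formula_values(self):
        """2s = 1.61 exp(-0.22 B) + 0.17 exp(-0.002 B): 1.78 at B=0, 0.183 at B=20."""
        assert measurement_2sigma(0.0) == pytest.approx(1.78, abs=1e-12)
        assert measurement_2sigma(20.0) == pytest.approx(0.18310, abs=1e-4)

    def test_strictly_decreasing(self):
        b = np.linspace(0.0, 60.0, 200)
        assert np.all(np.diff(measurement_2sigma(b)) < 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            measurement_2sigma(-1.0)


class TestCalibration:
    def test_worked_inversion(self):
        assert borate_from_skeletal(28.7) == pytest.approx((28.7 - 6.91) / 1.46, rel=1e-12)
        assert borate_from_skeletal(28.7) == pytest.approx(14.92, abs=0.01)

    def test_zero_point_and_identity(self):
        assert borate_from_skeletal(6.91) == pytest.approx(0.0, abs=1e-12)
        ident = CalibrationModel(slope=1.0, slope_2sigma=0.0, intercept=0.0, intercept_2sigma=0.0)
        assert borate_from_skeletal(23.4, ident) == 23.4

    def test_forward_inverse_pair(self):
        assert skeletal_from_borate(borate_from_skeletal(28.7)) == pytest.approx(28.7, abs=1e-12)


class TestBorateEquation:
    def test_worked_example_ph(self):
        """28.7 permil skeletal d11B with pKB* 8.82 gives seawater pH 7.87."""
        ph = ph_deterministic(28.7, 8.82)
        assert ph == pytest.approx(7.87, abs=0.01)

    def test_analytic_fixed_point(self):
        """At the borate value making the log argument 1, pH equals pKB*."""
        p = ProxyParams()
        db = (2 * p.d11B_sw - 1000 * (p.alpha_B - 1)) / (1 + p.alpha_B)
        assert ph_from_borate(db, 8.82, p) == pytest.approx(8.82, abs=1e-12)

    def test_uninvertible_low_d11b(self):
        with pytest.raises(UninvertibleError):
            ph_from_borate(5.0, 8.82)
        out = ph_from_borate(np.array([5.0, 15.0]), 8.82, invalid="nan")
        assert np.isnan(out[0]) and np.isfinite(out[1])

    def test_strictly_increasing_in_borate(self):
        db = np.linspace(13.0, 25.0, 100)
        assert np.all(np.diff(ph_from_borate(db, 8.82)) > 0)

    @given(ph=st.floats(7.0, 8.6), pkb=st.floats(8.6, 9.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_property(self, ph, pkb):
        """Forward/inverse round trip through the borate equation to < 1e-10."""
        db = delta11B_borate_from_ph(ph, pkb)
        assert ph_from_borate(db, pkb) == pytest.approx(ph, abs=1e-10)


def test_table_mean_and_spread_of_seawater_d11b():
    """Local seawater d11B: mean 39.73 permil, 2-sigma 0.08 permil."""
    mean, two_sigma = seawater_d11b_summary()
    assert mean == pytest.approx(39.73, abs=5e-3)
    assert two_sigma == pytest.approx(0.08, abs=5e-3)


def _single_record(d11b=27.5, b=20.0, year=2000):
    bands = pd.DataFrame({
        "specimen_id": ["X"], "year_ce": [year], "d11B_permil": [d11b],
        "B_ngg": [b], "BCa_umolmol": [np.nan],
    })
    env = pd.DataFrame({"year_ce": [year], "T_C": [9.0], "S_psu": [30.3]})
    return bands, env


class TestReconstruct:
    def test_degenerate_all_sigma_zero(self):
        """With every error source at zero the envelope collapses onto the
        deterministic estimate."""
        bands, env = _single_record()
        params = ProxyParams(d11B_sw_sd=0.0, T_sd=0.0, S_sd=0.0)
        cal = CalibrationModel(slope_2sigma=0.0, intercept_2sigma=0.0)
        out = reconstruct(bands, env, params, cal, n_draws=64, seed=0,
                          measurement_sigma_scale=0.0)
        from boronph.carbonate import pkb_star
        expected = ph_deterministic(27.5, pkb_star(9.0, 30.3), params, cal)
        assert out.loc[0, "pH_median"] == pytest.approx(expected, abs=1e-12)
        assert out.loc[0, "ci95_hi"] - out.loc[0, "ci95_lo"] == 0.0

    def test_bit_stable_given_seed(self):
        bands, env = _single_record()
        a = reconstruct(bands, env, n_draws=500, seed=11)
        b = reconstruct(bands, env, n_draws=500, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_median_converges_to_deterministic(self):
        """MC median approaches the central estimate within 0.005 pH at 1e4 draws."""
        bands, env = _single_record()
        out = reconstruct(bands, env, n_draws=10_000, seed=3)
        from boronph.carbonate import pkb_star
        det = ph_deterministic(27.5, pkb_star(9.0, 30.3))
        assert out.loc[0, "pH_median"] == pytest.approx(det, abs=0.005)

    def test_envelope_grows_as_boron_falls(self):
        widths = []
        for b in (40.0, 10.0, 4.0):
            bands, env = _single_record(b=b)
            out = reconstruct(bands, env, n_draws=4000, seed=5)
            widths.append(out.loc[0, "ci68_hi"] - out.loc[0, "ci68_lo"])
        assert widths[0] < widths[1] < widths[2]

    def test_small_noise_envelope_matches_linear_propagation(self):
        """In the small-noise limit the MC 68% half-width matches first-order
        analytic error propagation within 15%."""
        from boronph.carbonate import pkb_star

        scale = 0.2  # shrink every sigma into the linear regime
        d11b, b_conc, t0, s0 = 27.5, 20.0, 9.0, 30.3
        params = ProxyParams(d11B_sw_sd=0.1 * scale, T_sd=scale, S_sd=scale)
        cal = CalibrationModel(slope_2sigma=0.06 * scale, intercept_2sigma=0.72 * scale)

        def model(d11b_, slope, intercept, dsw, T, S):
            p = ProxyParams(d11B_sw=dsw)
            c = CalibrationModel(slope=slope, intercept=intercept)
            return ph_deterministic(d11b_, pkb_star(T, S), p, c)

        x0 = (d11b, 1.46, 6.91, 39.73, t0, s0)
        sig_meas = scale * measurement_2sigma(b_conc) / 2
        sigmas = (sig_meas, 0.06 * scale / 2, 0.72 * scale / 2, 0.1 * scale, scale, scale)
        var = 0.0
        for i, s in enumerate(sigmas):
            hi = list(x0); lo = list(x0)
            eps = max(1e-6, 1e-4 * abs(x0[i]))
            hi[i] += eps; lo[i] -= eps
            grad = (model(*hi) - model(*lo)) / (2 * eps)
            var += (grad * s) ** 2
        analytic = np.sqrt(var)

        bands, env = _single_record(d11b=d11b, b=b_conc)
        out = reconstruct(bands, env, params, cal, n_draws=50_000, seed=9,
                          measurement_sigma_scale=scale)
        mc_half = (out.loc[0, "ci68_hi"] - out.loc[0, "ci68_lo"]) / 2
        assert mc_half == pytest.approx(analytic, rel=0.15)

    def test_mostly_uninvertible_record_excluded_with_warning(self):
        bands, env = _single_record(d11b=24.0)  # below the invertibility limit
        with pytest.warns(UserWarning, match="uninvertible"):
            out = reconstruct(bands, env, n_draws=500, seed=2)
        assert len(out) == 0

    def test_missing_env_year_rejected(self):
        bands, env = _single_record()
        with pytest.raises(InvalidInputError, match="missing years"):
            reconstruct(bands, env.assign(year_ce=[1900]), n_draws=10)

    def test_coverage_near_nominal(self):
        """68% envelopes cover the truth for ~68% of records generated from
        the full error model."""
        bands, env, truth = coverage_records(200, seed=3)
        rec = reconstruct(bands, env, n_draws=2000, seed=7)
        cov = float(((truth >= rec["ci68_lo"]) & (truth <= rec["ci68_hi"])).mean())
        assert 0.63 <= cov <= 0.73
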