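"""Carbonate-system constants and solvers, checked against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boronph.carbonate import (
    alk_change_for_ph_step,
    alk_from_ph_dic,
    compute_constants,
    dic_from_ph_alk,
    dic_from_ph_pco2,
    pco2_from_ph_dic,
    pH_from_alk_dic,
    pkb_star,
    solve_state,
)
from boronph.exceptions import InvalidInputError, LowSalinityWarning, NoSolutionError


def oracle_alkalinity(ph, dic_umol, c):
    """Independent speciation: alkalinity (umol/kg) at given pH and DIC.

    Written from the equilibrium expressions directly, separate from the
    implementation's residual function.
    """
    h = 10.0**-ph
    alpha_hco3 = 1.0 / (h / c.K1 + 1.0 + c.K2 / h)
    alpha_co3 = 1.0 / (h**2 / (c.K1 * c.K2) + h / c.K2 + 1.0)
    borate = c.BT * c.KB / (c.KB + h)
    return dic_umol * (alpha_hco3 + 2 * alpha_co3) + borate + (c.Kw / h - h) * 1e6


def oracle_ph_scan(alk, dic, c):
    """Brute-force pH grid scan at 1e-5 resolution (coarse bracket + fine scan)."""
    coarse = np.arange(2.0, 12.0, 0.01)
    resid = oracle_alkalinity(coarse, dic, c) - alk
    i = int(np.argmin(np.abs(resid)))
    fine = np.arange(coarse[i] - 0.02, coarse[i] + 0.02, 1e-5)
    resid_f = oracle_alkalinity(fine, dic, c) - alk
    return float(fine[np.argmin(np.abs(resid_f))])


class TestConstants:
    def test_lueker_pk1_warming_shift(self):
        """pK1 moves from 6.03 at 8 degC to 6.00 at 11 degC (S = 32)."""
        pk1_cold = -np.log10(compute_constants(8.0, 32.0).K1)
        pk1_warm = -np.log10(compute_constants(11.0, 32.0).K1)
        assert pk1_cold == pytest.approx(6.03, abs=0.01)
        assert pk1_warm == pytest.approx(6.00, abs=0.01)

    def test_total_boron_scales_with_salinity(self):
        assert compute_constants(10.0, 0.0).BT == 0.0
        c35 = compute_constants(10.0, 35.0)
        c17 = compute_constants(10.0, 17.5)
        assert c35.BT == pytest.approx(2 * c17.BT, rel=1e-12)
        assert c35.BT == pytest.approx(415.7, rel=1e-3)

    def test_constant_invariants(self):
        c = compute_constants(10.0, 33.0)
        assert all(v > 0 for v in (c.K0, c.K1, c.K2, c.KB, c.Kw, c.BT))
        assert c.K1 > c.K2
        # pK1 decreases as T rises at fixed S
        pk1 = [-np.log10(compute_constants(t, 33.0).K1) for t in (5, 10, 15, 20)]
        assert np.all(np.diff(pk1) < 0)

    def test_pkb_average_matches_study_constant(self):
        """Mean pKB* over 6-11 degC at S = 30.3 is the 8.82 proxy constant."""
        mean = np.mean([pkb_star(t, 30.3) for t in range(6, 12)])
        assert mean == pytest.approx(8.82, abs=0.02)

    def test_pkb_point_value_and_monotonicity(self):
        # closed-form hand evaluation of the Dickson expression at (10, 30.3)
        assert pkb_star(10.0, 30.3) == pytest.approx(8.8058, abs=1e-3)
        vals = [pkb_star(t, 30.3) for t in (6, 8, 10, 12)]
        assert np.all(np.diff(vals) < 0)

    def test_low_salinity_warns_not_errors(self):
        with pytest.warns(LowSalinityWarning):
            c = compute_constants(10.0, 15.0)
        assert c.K1 > 0

    @pytest.mark.parametrize("T,S", [(-1, 33), (45, 33), (10, -1), (10, 50), (np.nan, 33)])
    def test_out_of_range_inputs_rejected(self, T, S):
        with pytest.raises(InvalidInputError):
            compute_constants(T, S)


class TestSolver:
    def test_reference_state(self):
        """The 20% WSW / 80% LSW mixture water solves to pH 8.05."""
        c = compute_constants(11.0, 34.5)
        # frozen from the independent grid-scan oracle
        assert pH_from_alk_dic(2235.0, 2050.0, c) == pytest.approx(8.0495, abs=1e-3)

    def test_unmixed_gulf_seawater_is_ph_8(self):
        c = compute_constants(10.0, 33.0)
        assert pH_from_alk_dic(2200.0, 2050.0, c) == pytest.approx(8.0, abs=0.01)

    def test_agrees_with_grid_scan_oracle(self, rng):
        """Brent solution matches a 1e-5 pH grid scan within 1e-4 over 1000 states."""
        n = 1000
        T = rng.uniform(0.0, 25.0, n)
        S = rng.uniform(20.0, 38.0, n)
        dic = rng.uniform(1500.0, 2300.0, n)
        alk = dic * rng.uniform(1.02, 1.15, n)
        for i in range(n):
            c = compute_constants(T[i], S[i])
            ph = pH_from_alk_dic(alk[i], dic[i], c)
            assert abs(ph - oracle_ph_scan(alk[i], dic[i], c)) < 1e-4

    def test_monotonic_in_alk_and_dic(self):
        c = compute_constants(10.0, 33.0)
        ph_alk = [pH_from_alk_dic(a, 2050.0, c) for a in np.linspace(2150, 2400, 11)]
        assert np.all(np.diff(ph_alk) > 0)
        ph_dic = [pH_from_alk_dic(2250.0, d, c) for d in np.linspace(1900, 2200, 11)]
        assert np.all(np.diff(ph_dic) < 0)

    def test_residual_below_hundredth_umol(self):
        c = compute_constants(11.0, 34.5)
        ph = pH_from_alk_dic(2235.0, 2050.0, c)
        assert abs(alk_from_ph_dic(ph, 2050.0, c) - 2235.0) < 0.01

    def test_unphysical_pair_raises(self):
        c = compute_constants(10.0, 33.0)
        with pytest.raises(NoSolutionError):
            pH_from_alk_dic(50000.0, 1.0, c)

    @given(
        alk=st.floats(2000.0, 2400.0),
        ratio=st.floats(0.85, 0.98),
        T=st.floats(2.0, 25.0),
        S=st.floats(20.0, 38.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_property(self, alk, ratio, T, S):
        """alk_from_ph_dic inverts pH_from_alk_dic to < 0.01 umol/kg."""
        c = compute_constants(T, S)
        dic = alk * ratio
        ph = pH_from_alk_dic(alk, dic, c)
        assert alk_from_ph_dic(ph, dic, c) == pytest.approx(alk, abs=0.01)


class TestCompanionSolvers:
    def test_dic_from_ph_pco2_speciation(self):
        c = compute_constants(10.0, 33.0)
        # higher pH at fixed pCO2 holds more DIC
        dics = [dic_from_ph_pco2(ph, 400.0, c) for ph in (7.6, 7.9, 8.2)]
        assert np.all(np.diff(dics) > 0)
        # round trip through pco2_from_ph_dic
        assert pco2_from_ph_dic(8.0, dic_from_ph_pco2(8.0, 400.0, c), c) == pytest.approx(400.0, rel=1e-10)

    def test_dic_from_ph_alk_round_trip(self):
        c = compute_constants(10.0, 33.0)
        dic = dic_from_ph_alk(8.0, 2200.0, c)
        assert pH_from_alk_dic(2200.0, dic, c) == pytest.approx(8.0, abs=1e-6)

    def test_freshwater_limit_river_dic(self):
        """At ALK = 230 and river pH 7.2 the extrapolated constants give ~260 umol/kg DIC."""
        with pytest.warns(LowSalinityWarning):
            c = compute_constants(10.0, 0.0)
        assert dic_from_ph_alk(7.2, 230.0, c) == pytest.approx(261.0, rel=0.05)

    def test_dic_to_zero_limit(self):
        """As DIC -> 0 alkalinity reduces to borate + water terms."""
        c = compute_constants(10.0, 33.0)
        h = 10.0**-8.0
        borate_water = (c.BT * 1e-6 * c.KB / (c.KB + h) + c.Kw / h - h) * 1e6
        assert alk_from_ph_dic(8.0, 1e-9, c) == pytest.approx(borate_water, abs=1e-6)

    def test_alk_step_scenarios(self):
        """ALK increase for pH 7.7 -> 7.9: ~60 umol/kg at fixed DIC (hand-derived)."""
        d_fixed_dic = alk_change_for_ph_step(7.7, 7.9, 10.0, 30.3, DIC=2050.0)
        assert d_fixed_dic == pytest.approx(59.7, abs=1.0)
        # fixed-pCO2 framing answers a different question and is much larger
        d_fixed_pco2 = alk_change_for_ph_step(7.7, 7.9, 10.0, 30.3, pCO2=400.0)
        assert d_fixed_pco2 > d_fixed_dic

    def test_solve_state_pairs_consistent(self):
        st1 = solve_state(10.0, 33.0, ALK=2200.0, DIC=2050.0)
        st2 = solve_state(10.0, 33.0, pH=st1.pH, DIC=2050.0)
        st3 = solve_state(10.0, 33.0, pH=st1.pH, pCO2=st1.pCO2)
        st4 = solve_state(10.0, 33.0, ALK=2200.0, pCO2=st1.pCO2)
        assert st2.ALK == pytest.approx(2200.0, abs=0.01)
        assert st3.DIC == pytest.approx(2050.0, rel=1e-6)
        assert st4.pH == pytest.approx(st1.pH, abs=1e-6)
        with pytest.raises(InvalidInputError):
            solve_state(10.0, 33.0, DIC=2050.0, pCO2=400.0)


def test_cross_check_established_package():
    """Optional cross-validation against an established carbonate-chemistry package."""
    PyCO2SYS = pytest.importorskip("PyCO2SYS")
    res = PyCO2SYS.sys(
        par1=2235.0, par2=2050.0, par1_type=1, par2_type=2,
        temperature=11.0, salinity=34.5,
        opt_k_carbonic=10, opt_pH_scale=1, opt_total_borate=1,
    )
    c = compute_constants(11.0, 34.5)
    assert pH_from_alk_dic(2235.0, 2050.0, c) == pytest.approx(float(res["pH"]), abs=0.005)
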