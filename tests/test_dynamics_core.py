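"""Growth laws, within-step chemistry, and the coupled deterministic model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from commsel import (ChemState, deterministic_trajectory, h_inhibition_factor,
                     integrate_chem_step, mankad_bungay_rate, monod_rate)
from commsel.params import PREADAPTED_GROWTH


class TestGrowthLaws:
    @pytest.mark.parametrize(
        "R, g_max, aff, expected",
        [
            (1.0, 0.25, 1.0, 0.125),  # half-saturation: R = K
            (0.2, 0.3, 5.0, 0.15),
            (0.0, 0.7, 3.0, 0.0),
            (5.0, 0.7, 0.0, 0.0),  # null affinity: K -> infinity
        ],
    )
    def test_monod_values(self, R, g_max, aff, expected):
        assert monod_rate(R, g_max, aff) == pytest.approx(expected)

    def test_monod_rejects_negative(self):
        with pytest.raises(ValueError):
            monod_rate(-0.1, 0.25, 1.0)

    def test_mankad_bungay_half_rate_at_unit_saturation(self):
        # R_M = B_M = 1 gives exactly g_max/2
        g = mankad_bungay_rate(1 / 3, 100 / 3, 0.7, 3.0, 0.03)
        assert g == pytest.approx(0.35)

    def test_mankad_bungay_monod_limit_in_excess_byproduct(self):
        # B_M -> inf recovers monosubstrate Monod kinetics in R
        RM = 0.8
        g_lim = mankad_bungay_rate(RM / 3.0, 1e9, 0.7, 3.0, 0.03)
        assert g_lim == pytest.approx(0.7 * RM / (RM + 1.0), rel=1e-6)

    @pytest.mark.parametrize("R,B", [(0.0, 10.0), (1.0, 0.0)])
    def test_mankad_bungay_zero_without_either_substrate(self, R, B):
        assert mankad_bungay_rate(R, B, 0.7, 3.0, 0.03) == 0.0

    @settings(max_examples=60, deadline=None)
    @given(R=st.floats(0.0, 10.0), B=st.floats(0.0, 1000.0),
           dR=st.floats(0.0, 5.0))
    def test_mankad_bungay_bounded_and_monod_like_when_other_saturating(
            self, R, B, dR):
        """The rate is bounded by g_max and, with the partner substrate
        saturating, increases Monod-like in the varied substrate.  (Away
        from saturation the rate is *not* monotone in each substrate —
        that non-monotonicity is the affinity anomaly tested below.)
        """
        g0 = mankad_bungay_rate(R, B, 0.7, 3.0, 0.03)
        assert 0.0 <= g0 <= 0.7
        g_sat = mankad_bungay_rate(R, 1e9, 0.7, 3.0, 0.03)
        g_sat2 = mankad_bungay_rate(R + dR, 1e9, 0.7, 3.0, 0.03)
        assert g_sat2 >= g_sat - 1e-12

    def test_inhibition_factor(self):
        assert h_inhibition_factor(0.0, 50.0) == 1.0
        assert h_inhibition_factor(50.0, 50.0) == pytest.approx(np.exp(-1))
        assert h_inhibition_factor(1e6, None) == 1.0  # commensal model

    def test_affinity_anomaly_signs(self):
        """dg_M/dK_MR changes sign between substrate-limitation regimes.

        When Resource is abundant and Byproduct scarce, lowering the
        affinity for the abundant Resource *increases* the growth rate;
        in the opposite regime the usual sign holds.  Checked by finite
        differences in K_MR at R_M = 100, B_M = 0.01 and vice versa.
        """
        g_max, K0, eps = 0.7, 1.0 / 3.0, 1e-6

        def g_of_K(K_MR, RM0, BM0):
            # actual substrate amounts fixed; K_MR varies around K0
            R = RM0 * K0
            B = BM0 / 0.03
            return mankad_bungay_rate(R, B, g_max, 1.0 / K_MR, 0.03)

        # abundant R, scarce B: dg/dK > 0 (lower affinity helps)
        d_abundant = g_of_K(K0 + eps, 100.0, 0.01) - g_of_K(K0 - eps, 100.0, 0.01)
        assert d_abundant > 0
        # scarce R, abundant B: dg/dK < 0 (the familiar Monod case)
        d_scarce = g_of_K(K0 + eps, 0.01, 100.0) - g_of_K(K0 - eps, 0.01, 100.0)
        assert d_scarce < 0


class TestChemStep:
    def _groups(self, growth, Hb, Mb):
        return ((np.array([Hb]), np.array([growth.g_Hmax]), np.array([growth.aff_HR])),
                (np.array([Mb]), np.array([growth.g_Mmax]), np.array([growth.aff_MR]),
                 np.array([growth.aff_MB])))

    def test_no_cells_leaves_chemicals_unchanged(self, growth, fixed, fresh_chem):
        h, m = self._groups(growth, 0.0, 0.0)
        chem, IH, IM = integrate_chem_step(fresh_chem, h, m, 0.05, fixed)
        assert chem.R == fresh_chem.R and chem.B == fresh_chem.B
        assert IH[0] == 0.0 and IM[0] == 0.0

    def test_helper_only_mass_balance(self, growth, fixed, fresh_chem):
        """With M = 0, Byproduct released equals Resource consumed / c_RH."""
        h, m = self._groups(growth, 50.0, 0.0)
        chem, IH, IM = integrate_chem_step(fresh_chem, h, m, 1.0, fixed)
        dB = chem.B - fresh_chem.B
        dR = fresh_chem.R - chem.R
        assert dB == pytest.approx(dR / fixed.c_RH, rel=1e-6)

    def test_agrees_with_fine_euler_oracle(self, growth, fixed, fresh_chem):
        """Independent forward-Euler integration at tiny steps matches."""
        Hb, Mb = 40.0, 60.0
        chem = fresh_chem.replace(B=0.05)
        h, m = self._groups(growth, Hb, Mb)
        out, IH, IM = integrate_chem_step(chem, h, m, 0.5, fixed)
        # oracle
        R, B = chem.R, chem.B
        ih = im = 0.0
        n = 200_000
        dt = 0.5 / n
        for _ in range(n):
            gh = monod_rate(R, growth.g_Hmax, growth.aff_HR)
            gm = mankad_bungay_rate(R, B, growth.g_Mmax, growth.aff_MR,
                                    growth.aff_MB)
            R += dt * (-fixed.c_RM * gm * Mb - fixed.c_RH * gh * Hb)
            B += dt * (gh * Hb - fixed.c_BM * gm * Mb)
            ih += gh * dt
            im += gm * dt
        assert out.R == pytest.approx(R, rel=1e-4)
        assert out.B == pytest.approx(B, rel=1e-4)
        assert IH[0] == pytest.approx(ih, rel=1e-4)
        assert IM[0] == pytest.approx(im, rel=1e-4)

    def test_solver_convergence_in_tolerance(self, growth, fixed, fresh_chem):
        h, m = self._groups(growth, 1000.0, 2000.0)
        tol = 1e-6
        a, _, _ = integrate_chem_step(fresh_chem, h, m, 0.05, fixed, rtol=tol)
        b, _, _ = integrate_chem_step(fresh_chem, h, m, 0.05, fixed, rtol=tol / 10)
        assert abs(a.R - b.R) <= 10 * tol * max(a.R, 1e-9)
        assert abs(a.B - b.B) <= 10 * tol * max(a.B, 1e-9)


class TestDeterministicTrajectory:
    def test_zero_cost_makes_no_product(self, growth, fixed):
        traj = deterministic_trajectory((40, 60, ChemState(R=1)), growth,
                                        fixed, 0.0, 17.0)
        assert traj.P[-1] == pytest.approx(0.0, abs=1e-12)

    def test_states_remain_nonnegative(self, growth, fixed):
        traj = deterministic_trajectory((40, 60, ChemState(R=1)), growth,
                                        fixed, 0.41, 30.0)
        for arr in (traj.H_total, traj.M_total, traj.R, traj.B, traj.P):
            assert np.all(np.asarray(arr) >= 0)
        assert np.all(np.diff(traj.P) >= -1e-9)  # Product non-decreasing

    def test_resource_budget_identity_without_death(self, growth, no_death):
        """R consumed = c_RH dH + c_RM dM/(1-f_P) when death is off."""
        f_P = 0.3
        traj = deterministic_trajectory((40, 60, ChemState(R=1)), growth,
                                        no_death, f_P, 17.0, rtol=1e-9,
                                        atol=1e-12)
        dH = traj.H_total[-1] - traj.H_total[0]
        dM = traj.M_total[-1] - traj.M_total[0]
        consumed = traj.R[0] - traj.R[-1]
        predicted = no_death.c_RH * dH + no_death.c_RM * dM / (1 - f_P)
        assert consumed == pytest.approx(predicted, rel=1e-6)

    def test_byproduct_balance_identity_without_death(self, growth, no_death):
        """B(T) = dH - c_BM dM/(1-f_P) when death is off."""
        f_P = 0.3
        traj = deterministic_trajectory((40, 60, ChemState(R=1)), growth,
                                        no_death, f_P, 17.0, rtol=1e-9,
                                        atol=1e-12)
        dH = traj.H_total[-1] - traj.H_total[0]
        dM = traj.M_total[-1] - traj.M_total[0]
        predicted = dH - no_death.c_BM * dM / (1 - f_P)
        assert traj.B[-1] == pytest.approx(predicted, rel=1e-5, abs=1e-6)

    def test_mutualistic_inhibition_slows_helper(self, growth, fixed):
        inhibited = fixed.replace(B0=2 * (1 / PREADAPTED_GROWTH.aff_MB))
        base = deterministic_trajectory((40, 60, ChemState(R=1)), growth,
                                        fixed, 0.13, 17.0)
        mut = deterministic_trajectory((40, 60, ChemState(R=1)), growth,
                                       inhibited, 0.13, 17.0)
        assert mut.H_total[-1] < base.H_total[-1]
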