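"""Forward broken-and-intact-cell model: groups, branches, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sfex.bic import (BICParameters, ExtractionCurve, ExtractionSystem,
                      dimensionless_time, extraction_fraction, h_k,
                      psi_k, simulate_curve, transfer_groups,
                      yield_percent)

valid_G = st.floats(1e-3, 1.0 - 1e-3)
valid_Z = st.floats(0.05, 20.0)
valid_Y = st.floats(0.05, 20.0)


def make_system(**over):
    base = dict(N=0.023, x0=0.003, ys=1e-3, Q=1e-4, eps=0.53,
                rho_s=1400.0, rho_f=857.2, d_p=220e-6)
    base.update(over)
    return ExtractionSystem(**base)


class TestDimensionlessTime:
    def test_direct_arithmetic(self):
        sys = make_system()
        # 3600 * 1e-4 * 1e-3 / (0.023 * 0.003)
        assert dimensionless_time(3600.0, sys) == pytest.approx(
            5.2173913043, rel=1e-9)

    def test_linear_and_homogeneous(self):
        sys = make_system()
        assert dimensionless_time(0.0, sys) == 0.0
        assert dimensionless_time(2 * 777.0, sys) == pytest.approx(
            2 * dimensionless_time(777.0, sys))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            dimensionless_time(-1.0, make_system())


class TestTransferGroups:
    def test_direct_arithmetic(self):
        sys = make_system(Q=1.67e-4, eps=0.53, rho_f=857.2, rho_s=1400.0)
        params = BICParameters(G=0.5, ksa0=1e-5, kfa0=0.02)
        Z, Y = transfer_groups(sys, params)
        assert Z == pytest.approx(
            0.023 * 0.02 * 857.2 / (1.67e-4 * 0.47 * 1400.0), rel=1e-12)
        assert Y == pytest.approx(
            0.023 * 1e-5 * 0.003 / (1.67e-4 * 0.47 * 1e-3), rel=1e-12)

    def test_scale_inverse_in_flow(self):
        params = BICParameters(G=0.5, ksa0=1e-5, kfa0=1e-3)
        Z1, Y1 = transfer_groups(make_system(Q=1e-4), params)
        Z2, Y2 = transfer_groups(make_system(Q=2e-4), params)
        assert Z2 == pytest.approx(Z1 / 2) and Y2 == pytest.approx(Y1 / 2)

    def test_degenerate_kfa0_rejected_by_invariant(self):
        with pytest.raises(ValueError):
            BICParameters(G=0.5, ksa0=1e-5, kfa0=0.0)


class TestPsiKAndHk:
    def test_closed_forms(self):
        assert psi_k(0.0, 2.0, 3.0) == 0.0
        # G=1: psi_k = 1/Z + (1/Y)*ln(e^Y) = 1/Z + 1
        assert psi_k(1.0, 2.0, 3.0) == pytest.approx(1.5, rel=1e-12)
        # G=1, Y=2, psi-G/Z=0.5: h_k = ln(1 + (e-1))/2 = 0.5
        assert h_k(1.0 / 2.0 + 0.5, 1.0, 2.0, 2.0) == pytest.approx(
            0.5, rel=1e-12)

    @given(G=valid_G, Z=valid_Z, Y=valid_Y)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_boundary_identities(self, G, Z, Y):
        pk = psi_k(G, Z, Y)
        assert pk >= G / Z
        assert h_k(G / Z, G, Z, Y) == pytest.approx(0.0, abs=1e-12)
        assert h_k(pk, G, Z, Y) == pytest.approx(1.0, abs=1e-12)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            h_k(0.0, 0.5, 2.0, 3.0)  # below G/Z
        with pytest.raises(ValueError):
            h_k(0.3, 0.0, 2.0, 3.0)  # G=0 divides by G


class TestExtractionFraction:
    def test_zero_and_asymptote(self):
        assert extraction_fraction(0.0, 0.5, 3.0, 2.0) == 0.0
        pk = psi_k(0.5, 3.0, 2.0)
        assert extraction_fraction(pk + 50 / 2.0, 0.5, 3.0, 2.0) == \
            pytest.approx(1.0, abs=1e-10)

    def test_branches_agree_at_boundaries(self):
        G, Z, Y = 0.5, 3.0, 2.0
        lo, pk = G / Z, psi_k(G, Z, Y)
        for b in (lo, pk):
            below = extraction_fraction(np.nextafter(b, 0.0), G, Z, Y)
            assert extraction_fraction(b, G, Z, Y) == pytest.approx(
                below, abs=1e-10)

    @given(G=valid_G, Z=valid_Z, Y=valid_Y)
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_continuity_monotonicity_bounds(self, G, Z, Y):
        lo, pk = G / Z, psi_k(G, Z, Y)
        psi = np.sort(np.concatenate([
            np.linspace(0.0, pk + 10 / Y, 50),
            [np.nextafter(lo, 0), lo, np.nextafter(pk, 0), pk]]))
        e = extraction_fraction(psi, G, Z, Y)
        assert np.all(np.diff(e) >= -1e-10)
        assert np.all((e >= -1e-12) & (e <= 1.0 + 1e-12))
        i_lo = np.searchsorted(psi, lo)
        i_pk = np.searchsorted(psi, pk)
        assert abs(e[i_lo] - e[i_lo - 1]) < 1e-10
        assert abs(e[i_pk] - e[i_pk - 1]) < 1e-10

    def test_early_slope_equals_film_limit(self):
        # de/dpsi -> 1 - e^{-Z} for psi << G/Z
        G, Z, Y = 0.6, 2.5, 1.5
        h = 1e-7 * G / Z
        slope = (extraction_fraction(2 * h, G, Z, Y)
                 - extraction_fraction(h, G, Z, Y)) / h
        assert slope == pytest.approx(1 - np.exp(-Z), rel=1e-6)

    def test_G_edge_cases(self):
        # G=1: no intact-cell period before psi_k; G->0: immediate
        # diffusion-limited regime
        assert psi_k(1.0, 2.0, 1.0) == pytest.approx(1.5)
        e_small_G = extraction_fraction(0.5, 1e-12, 2.0, 1.0)
        e_zero_G = extraction_fraction(0.5, 0.0, 2.0, 1.0)
        assert e_small_G == pytest.approx(e_zero_G, abs=1e-9)

    def test_extreme_groups_do_not_overflow(self):
        e = extraction_fraction(np.linspace(0, 5000.0, 7), 0.9, 0.01,
                                600.0)
        assert np.all(np.isfinite(e))


class TestSimulateCurve:
    def test_zero_grid_and_monotone(self, exp2_system, exp2_params):
        c = simulate_curve([0.0], exp2_system, exp2_params)
        assert c.masses[0] == 0.0 and c.provenance == "simulated"
        t = np.linspace(0, 8 * 3600, 17)
        c = simulate_curve(t, exp2_system, exp2_params)
        assert np.all(np.diff(c.masses) >= 0)
        assert c.masses[-1] <= exp2_system.N * exp2_system.x0

    def test_asymptote_is_total_oil(self, exp2_system, exp2_params):
        c = simulate_curve([1e9], exp2_system, exp2_params)
        assert c.masses[-1] == pytest.approx(
            exp2_system.N * exp2_system.x0, rel=1e-10)

    def test_bad_grid_rejected(self, exp2_system, exp2_params):
        for grid in ([], [3.0, 2.0], [-1.0, 2.0]):
            with pytest.raises(ValueError):
                simulate_curve(grid, exp2_system, exp2_params)


class TestYieldPercent:
    def test_values(self):
        assert yield_percent(0.0, 23.0) == 0.0
        assert yield_percent(23.0, 23.0) == 100.0
        # highest-yield run: 65.55 mg extract from 23 g of leaves
        assert yield_percent(0.0655, 23.0) == pytest.approx(0.285,
                                                            abs=5e-4)

    def test_invalid_masses_rejected(self):
        with pytest.raises(ValueError):
            yield_percent(1.0, 0.0)
        with pytest.raises(ValueError):
            yield_percent(-1.0, 23.0)


class TestExtractionCurveInvariants:
    def test_validation(self, exp2_system):
        with pytest.raises(ValueError):
            ExtractionCurve(times=[0, 1], masses=[1], system=exp2_system)
        with pytest.raises(ValueError):
            ExtractionCurve(times=[1, 0], masses=[0, 0],
                            system=exp2_system)
        with pytest.raises(ValueError):
            ExtractionCurve(times=[0, 1], masses=[0, -1],
                            system=exp2_system)
        with pytest.raises(ValueError):
            ExtractionCurve(times=[0, 1], masses=[1e-3, 9e-4],
                            system=exp2_system, provenance="simulated")

    def test_fractions(self, exp2_system):
        c = ExtractionCurve(times=[0, 1], masses=[0, 6.555e-5],
                            system=exp2_system, provenance="synthetic")
        assert c.fractions[-1] == pytest.approx(1.0)
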