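"""Unit and property tests for the dimer-gel free-energy model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dimergel.model_core import (
    BulkComposition,
    ModelParams,
    bonded_sticker_concentration,
    chemical_potentials,
    dimer_concentration,
    excluded_volume_coefficients,
    free_energy_dimer,
    free_energy_excluded,
    free_energy_independent,
    free_energy_noninteracting,
    free_energy_total,
    nm3_to_per_uM,
    per_uM_to_nm3,
)

conc = st.floats(min_value=1e-3, max_value=1e3)


def pairing_oracle(a, b, K):
    """Independent root-finding oracle for A + B <-> AB mass action."""
    roots = np.roots([1.0, -(a + b + K), a * b])
    roots = roots[(roots.real >= -1e-12) & (np.abs(roots.imag) < 1e-12)].real
    return float(min(r for r in roots if r <= min(a, b) + 1e-9))


class TestExcludedVolumes:
    def test_printed_coefficients(self):
        # reference values at the 0.01 nm^3 precision they are usually quoted to
        # (the cross coefficient evaluates to 179.594, quoted as 179.60)
        v_R, v_E, v_ER = excluded_volume_coefficients(10.0, 1.0)
        assert v_R == pytest.approx(261.80, abs=0.01)
        assert v_E == pytest.approx(16.76, abs=0.01)
        assert v_ER == pytest.approx(179.60, abs=0.01)

    def test_unit_sphere_case(self):
        # d_R = 2 makes v_R half of 4/3 pi (the one-eighth share times four)
        v_R, _, _ = excluded_volume_coefficients(2.0, 1.0)
        assert v_R == pytest.approx(0.5 * (4.0 / 3.0) * math.pi, rel=1e-12)

    @pytest.mark.parametrize("d_R,R_g", [(0.0, 1.0), (10.0, -1.0)])
    def test_nonpositive_sizes_rejected(self, d_R, R_g):
        with pytest.raises(ValueError):
            excluded_volume_coefficients(d_R, R_g)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_unit_conversion_round_trip(self, v):
        assert per_uM_to_nm3(nm3_to_per_uM(v)) == pytest.approx(v, rel=1e-14)


class TestIdealAndExcludedTerms:
    def test_noninteracting_examples(self, params):
        assert free_energy_noninteracting(BulkComposition(1.0, 0.0), params) == pytest.approx(-1.0)
        assert free_energy_noninteracting(BulkComposition(0.0, 0.0), params) == 0.0
        expected = 2 * math.log(2 / math.e) + 3 * math.log(3 / math.e)
        assert free_energy_noninteracting(BulkComposition(2.0, 3.0), params) == pytest.approx(expected)

    def test_excluded_zero_at_origin(self, params):
        assert free_energy_excluded(BulkComposition(0.0, 0.0), params) == 0.0

    def test_excluded_arithmetic_oracle(self, params):
        # independent re-derivation at rho_R = rho_E = 150 uM (sticker conc 1200/750)
        got = free_energy_excluded(BulkComposition(150.0, 150.0), params)
        expected = 0.602214e-6 * (
            261.79938779914943 * 1200**2
            + 16.755160819145562 * 750**2
            + 179.59438003021648 * 750 * 1200
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            BulkComposition(-1.0, 1.0)


class TestPairingConcentrations:
    def test_dimer_quadratic_oracle(self):
        assert dimer_concentration(1.0, 1.0, 0.029) == pytest.approx(
            pairing_oracle(1.0, 1.0, 0.029), rel=1e-10
        )
        assert dimer_concentration(1.0, 1.0, 0.029) == pytest.approx(0.84359, abs=5e-6)

    def test_limits(self):
        assert dimer_concentration(1.0, 1.0, 1e12) == pytest.approx(0.0, abs=1e-9)
        assert dimer_concentration(0.3, 2.0, 1e-12) == pytest.approx(0.3, rel=1e-9)
        assert bonded_sticker_concentration(0.0, 5.0, 60.0) == 0.0
        assert bonded_sticker_concentration(4.0, 2.5, 1e-12) == pytest.approx(2.5, rel=1e-9)

    def test_bonded_sticker_dense_value(self):
        assert bonded_sticker_concentration(1200.0, 750.0, 60.0) == pytest.approx(
            pairing_oracle(1200.0, 750.0, 60.0), rel=1e-10
        )
        assert bonded_sticker_concentration(1200.0, 750.0, 60.0) == pytest.approx(673.30, abs=5e-3)

    def test_invalid_constant(self):
        with pytest.raises(ValueError):
            dimer_concentration(1.0, 1.0, 0.0)

    @given(conc, conc, st.floats(min_value=1e-3, max_value=1e4))
    @settings(max_examples=100, deadline=None)
    def test_mass_action_back_substitution(self, a, b, K):
        x = dimer_concentration(a, b, K)
        if x > 1e-12 and min(a, b) - x > 1e-12:
            assert (a - x) * (b - x) == pytest.approx(K * x, rel=1e-9)


class TestSpecificFreeEnergies:
    def test_dimer_zero_cases(self, params):
        assert free_energy_dimer(BulkComposition(0.0, 1.0), params) == 0.0
        assert free_energy_dimer(BulkComposition(1.0, 0.0), params) == 0.0
        weak = ModelParams(K_d=1e9)
        assert free_energy_dimer(BulkComposition(1.0, 1.0), weak) == pytest.approx(0.0, abs=1e-6)

    def test_dimer_term_by_term_oracle(self, params):
        rho_d = 0.8435863  # root of the pairing quadratic at (1, 1, 0.029)
        def xle(x):
            return x * math.log(x / math.e)
        expected = (
            rho_d * math.log(0.029)
            + xle(rho_d)
            + 2 * xle(1.0 - rho_d)
            - 2 * xle(1.0)
        )
        got = free_energy_dimer(BulkComposition(1.0, 1.0), params)
        assert got == pytest.approx(expected, abs=1e-5)

    def test_independent_zero_cases(self, params):
        assert free_energy_independent(BulkComposition(0.0, 10.0), params) == 0.0
        weak = ModelParams(K_b=1e12)
        assert free_energy_independent(BulkComposition(150.0, 150.0), weak) == pytest.approx(
            0.0, abs=1e-4
        )

    def test_independent_arithmetic_oracle(self, params):
        c_b = 673.2988  # pairing root at (1200, 750, 60)
        def xle(x):
            return x * math.log(x / math.e)
        expected = (
            c_b * math.log(60.0)
            + xle(c_b)
            + xle(1200.0 - c_b)
            + xle(750.0 - c_b)
            - xle(750.0)
            - xle(1200.0)
        )
        got = free_energy_independent(BulkComposition(150.0, 150.0), params)
        assert got == pytest.approx(expected, rel=1e-5)

    def test_dimer_branch_weakens_with_K_d(self, params):
        comp = BulkComposition(1.0, 1.0)
        values = [
            free_energy_dimer(comp, ModelParams(K_d=K)) for K in (1e-3, 1e-1, 1e1, 1e3, 1e6)
        ]
        assert all(a < b for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(0.0, abs=1e-3)

    @given(st.floats(min_value=1e-6, max_value=10.0))
    @settings(max_examples=30, deadline=None)
    def test_continuity_toward_empty_axis(self, eps):
        # every term stays finite and vanishes as either species disappears
        b = free_energy_total(BulkComposition(eps * 1e-6, 1.0), ModelParams())
        assert np.isfinite(b.f_total)
        assert abs(b.f_dim) < 10.0


class TestTotalFreeEnergy:
    def test_dense_point_prefers_independent_stickers(self, params):
        b = free_energy_total(BulkComposition(150.0, 150.0), params)
        assert b.branch == "independent"
        assert b.f_s == b.f_ind
        assert b.f_total == pytest.approx(b.f_ni + b.f_ex + b.f_s)

    def test_dilute_point_prefers_dimers(self, params):
        b = free_energy_total(BulkComposition(0.5, 0.5), params)
        assert b.branch == "dimer"
        assert b.f_s == min(b.f_dim, b.f_ind)

    def test_empty_composition(self, params):
        b = free_energy_total(BulkComposition(0.0, 0.0), params)
        assert b.f_total == 0.0 and b.rho_d == 0.0 and b.c_b == 0.0

    def test_branch_dominance_exponents(self, params):
        """Free-energy gap per molecule at the two reference coexistence densities."""
        dense = free_energy_total(BulkComposition(150.0, 150.0), params)
        assert (dense.f_dim - dense.f_ind) / 150.0 == pytest.approx(6.0, abs=1.5)
        dilute = free_energy_total(BulkComposition(0.5, 0.5), params)
        assert (dilute.f_ind - dilute.f_dim) / 0.5 == pytest.approx(2.0, abs=1.5)

    def test_pairing_bounds(self, params):
        b = free_energy_total(BulkComposition(2.0, 7.0), params)
        assert 0.0 <= b.rho_d <= 2.0
        assert 0.0 <= b.c_b <= params.L_R * 2.0


class TestChemicalPotentials:
    def test_near_ideal_limit(self):
        # vanishing excluded volume and binding: mu_R -> ln rho_R
        p = ModelParams(K_d=1e9, K_b=1e12, d_R=1e-3, R_g=1e-4)
        mu_R, mu_E, grand = chemical_potentials(BulkComposition(2.0, 3.0), p)
        assert mu_R == pytest.approx(math.log(2.0), abs=1e-4)
        assert mu_E == pytest.approx(math.log(3.0), abs=1e-4)
        # ideal grand potential: F - sum(rho (ln rho - 1 + 1)) ... = -(rho_R + rho_E)
        assert grand == pytest.approx(-5.0, rel=1e-3)

    def test_swap_symmetry(self):
        # v_R == v_E when R_g = d_R/4, and L_R == L_E makes sticker counts match
        p = ModelParams(L_R=5, L_E=5, K_d=0.1, K_b=10.0, d_R=4.0, R_g=1.0)
        mu_R, mu_E, _ = chemical_potentials(BulkComposition(3.0, 3.0), p)
        assert mu_R == pytest.approx(mu_E, rel=1e-12)

    @pytest.mark.parametrize("branch", ["dimer", "independent"])
    @pytest.mark.parametrize("point", [(1.0, 1.0), (0.3, 2.0), (150.0, 120.0)])
    def test_analytic_matches_finite_difference(self, params, branch, point):
        comp = BulkComposition(*point)
        mu_a = chemical_potentials(comp, params, branch=branch, method="analytic")
        mu_f = chemical_potentials(comp, params, branch=branch, method="fd")
        for a, f in zip(mu_a[:2], mu_f[:2]):
            assert f == pytest.approx(a, rel=1e-4)

    def test_axis_composition_rejected(self, params):
        with pytest.raises(ValueError):
            chemical_potentials(BulkComposition(0.0, 1.0), params)
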