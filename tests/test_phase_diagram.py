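"""Tests for the coexistence solver: binodal, tie lines, classification, predictions."""

import math

import numpy as np
import pytest

from dimergel.model_core import BulkComposition, ModelParams, chemical_potentials
from dimergel.phase_diagram import (
    Binodal,
    TieLineError,
    classify_bulk_point,
    compute_binodal,
    detect_instability,
    diffusion_vs_ratio_table,
    epyc1_monomer_fraction,
    predict_dilute_diffusion,
    refine_tie_line,
    scan_free_energy,
)

WEAK = ModelParams(K_d=1e6, K_b=1e6)  # effectively no specific binding


class TestSurfaceScan:
    def test_grid_shape(self, params):
        surf = scan_free_energy(params, ((0.1, 10, 2), (0.1, 10, 2)))
        assert len(surf) == 4
        assert set(surf.columns) == {"rho_R", "rho_E", "f_total", "branch"}

    def test_positive_bounds_required(self, params):
        with pytest.raises(ValueError):
            scan_free_energy(params, ((0.0, 10, 5), (0.1, 10, 5)))

    def test_dense_region_is_independent_branch(self, params):
        surf = scan_free_energy(params, ((100, 1e4, 10), (100, 1e4, 10)))
        assert (surf["branch"] == "independent").all()

    def test_deterministic(self, params):
        a = scan_free_energy(params, ((1e-2, 1e2, 10), (1e-2, 1e2, 10)))
        b = scan_free_energy(params, ((1e-2, 1e2, 10), (1e-2, 1e2, 10)))
        assert a.equals(b)


class TestInstabilityDetection:
    def test_convex_surface_has_no_spanning_facets(self):
        surf = scan_free_energy(WEAK, ((1e-2, 1e2, 30), (1e-2, 1e2, 30)))
        assert detect_instability(surf) == []

    def test_defaults_flag_dilute_to_dense_facets(self, params):
        surf = scan_free_energy(params, ((1e-4, 1e4, 60), (1e-4, 1e4, 60)))
        pairs = detect_instability(surf)
        assert pairs
        spans = [
            (den.rho_R + den.rho_E) / (dil.rho_R + dil.rho_E) for dil, den in pairs
        ]
        assert max(spans) > 50  # micromolar-scale to 10^2-micromolar-scale

    def test_refinement_stable_under_grid_doubling(self, params):
        def region(n):
            pairs = detect_instability(
                scan_free_energy(params, ((1e-4, 1e4, n), (1e-4, 1e4, n)))
            )
            dense = np.array([[d.rho_R, d.rho_E] for _, d in pairs])
            return np.log10(dense.sum(axis=1)).mean()

        assert region(60) == pytest.approx(region(120), abs=0.35)


class TestTieLineRefinement:
    def test_equal_fields_at_endpoints(self, params, binodal):
        tie = binodal.tie_lines[len(binodal) // 2]
        mu_d = chemical_potentials(tie.dilute, params, branch="dimer")
        mu_D = chemical_potentials(tie.dense, params, branch="independent")
        for a, b in zip(mu_d, mu_D):
            assert abs(a - b) / max(1.0, abs(b)) < 1e-6

    def test_guess_perturbation_returns_same_tie(self, params, binodal):
        tie = binodal.tie_lines[len(binodal) // 2]
        dil0 = BulkComposition(tie.dilute.rho_R * 1.05, tie.dilute.rho_E * 0.95)
        den0 = BulkComposition(tie.dense.rho_R * 1.05, tie.dense.rho_E * 1.05)
        again = refine_tie_line(dil0, den0, params, angle=tie.angle)
        assert again.dilute.rho_R == pytest.approx(tie.dilute.rho_R, rel=1e-6)
        assert again.dense.rho_E == pytest.approx(tie.dense.rho_E, rel=1e-6)

    def test_symmetric_parameters_give_symmetric_tie(self):
        # v_R == v_E (R_g = d_R/4) and equal sticker counts: the model is invariant
        # under exchanging the species, so the equal-ray tie line is symmetric.
        p = ModelParams(L_R=5, L_E=5, K_d=0.029, K_b=60.0, d_R=4.0, R_g=1.0)
        bn = compute_binodal(p, n_tie_lines=21)
        if bn.is_empty:
            pytest.skip("symmetric toy parameters do not phase separate")
        mid = min(bn.tie_lines, key=lambda t: abs(t.angle - math.pi / 4))
        assert mid.dilute.rho_R == pytest.approx(mid.dilute.rho_E, rel=1e-4)
        assert mid.dense.rho_R == pytest.approx(mid.dense.rho_E, rel=1e-4)

    def test_bad_guess_raises(self, params):
        with pytest.raises(TieLineError):
            refine_tie_line(
                BulkComposition(1e-4, 1e-4), BulkComposition(2e-4, 2e-4), params
            )


class TestBinodal:
    def test_no_interactions_no_two_phase_region(self):
        assert compute_binodal(WEAK).is_empty

    def test_equal_ray_coexistence_densities(self, binodal):
        dense = binodal.branch_intersection_equal_ray("dense")
        dilute = binodal.branch_intersection_equal_ray("dilute")
        # reference coexistence scale: ~0.5 uM dilute, ~150 uM dense
        assert 150.0 / 1.5 <= dense <= 150.0 * 1.5
        assert 0.5 / 1.5 <= dilute <= 0.5 * 1.5

    def test_dense_branch_rubisco_ceiling(self, binodal):
        assert binodal.dense_branch[:, 0].max() <= 600.0

    def test_branches_are_simple_polylines(self, binodal):
        poly = binodal.region_polygon()
        assert poly.is_valid and poly.is_simple

    def test_high_epyc1_to_rubisco_asymmetry(self, params, binodal):
        # two-phase bulk compositions exist with [EPYC1]/[Rubisco] far above 40
        ratios = [
            E / R
            for R in np.logspace(-2.5, 0.5, 25)
            for E in np.logspace(-1.0, 1.2, 25)
            if classify_bulk_point(BulkComposition(R, E), binodal, params).n_phases == 2
        ]
        assert max(ratios) > 40.0


class TestClassification:
    def test_deep_dilute_is_one_phase(self, params, binodal):
        res = classify_bulk_point(BulkComposition(1e-3, 1e-3), binodal, params)
        assert res.n_phases == 1 and res.tie is None

    def test_experimental_mixture_is_two_phase(self, params, binodal):
        res = classify_bulk_point(BulkComposition(0.5, 2.0), binodal, params)
        assert res.n_phases == 2

    def test_lever_rule_identity(self, params, binodal):
        bulk = BulkComposition(0.5, 2.0)
        res = classify_bulk_point(bulk, binodal, params)
        lam, tie = res.lever_fraction, res.tie
        rec_R = (1 - lam) * tie.dilute.rho_R + lam * tie.dense.rho_R
        rec_E = (1 - lam) * tie.dilute.rho_E + lam * tie.dense.rho_E
        assert rec_R == pytest.approx(bulk.rho_R, rel=1e-6)
        assert rec_E == pytest.approx(bulk.rho_E, rel=1e-6)

    def test_empty_binodal_classifies_one_phase(self, params):
        res = classify_bulk_point(BulkComposition(1.0, 1.0), Binodal([]), params)
        assert res.n_phases == 1


class TestDiluteObservables:
    def test_monomer_fraction_limits(self):
        strong = ModelParams(K_d=1e-9)
        assert epyc1_monomer_fraction(BulkComposition(1.0, 1.0), strong) == pytest.approx(
            0.0, abs=1e-4
        )
        assert epyc1_monomer_fraction(BulkComposition(0.0, 1.0), strong) == 1.0
        assert epyc1_monomer_fraction(BulkComposition(1.0, 2.0), strong) == pytest.approx(
            0.5, abs=1e-4
        )
        with pytest.raises(ValueError):
            epyc1_monomer_fraction(BulkComposition(1.0, 0.0), strong)

    def test_diffusion_prediction_anchors(self):
        assert predict_dilute_diffusion(1.0) == 62.0
        assert predict_dilute_diffusion(0.0) == 42.0
        assert predict_dilute_diffusion(0.5) == 52.0
        with pytest.raises(ValueError):
            predict_dilute_diffusion(1.2)

    def test_ratio_table_monotone_and_spans_anchors(self, params, binodal):
        points = [
            BulkComposition(R, E)
            for E in (1.0, 2.0, 3.0, 4.0)
            for R in (0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0)
        ]
        table = diffusion_vs_ratio_table(points, params, binodal)
        assert table["two_phase"].all()
        d = table["D_pred_um2_s"].to_numpy()
        r = table["ratio"].to_numpy()
        # D_pred is strictly non-increasing in ratio along each fixed-EPYC1 sweep
        # (sweeps at different EPYC1 interleave within ~1% at equal ratio)
        for _, sweep in table.groupby("rho_E_uM"):
            sweep = sweep.sort_values("ratio")
            assert (np.diff(sweep["D_pred_um2_s"].to_numpy()) <= 1e-9).all()
        assert d[r <= 0.1].min() > 57.0  # near the free-monomer anchor
        assert d[r >= 1.0].max() < 45.0  # near the heterodimer anchor
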