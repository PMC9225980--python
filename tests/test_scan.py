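"""Gradient sweeps, branch tracking and bifurcation detection."""

import numpy as np
import pytest

from crsens import (
    AttractorOutcome,
    BifurcationNotFoundError,
    GradientSpec,
    UnsupportedVariantError,
    attractor_probe,
    closed_form_equilibria,
    detect_fold,
    detect_global,
    detect_hopf,
    detect_transcritical,
    numeric_equilibria_rms,
    sweep,
    transcritical_closed_form,
)


class TestGradientSpec:
    def test_defaults_follow_packaged_ranges(self):
        gk = GradientSpec.default("K")
        gf = GradientSpec.default("F")
        assert (gk.lo, gk.hi) == (0.0, 10.0)
        assert (gf.lo, gf.hi) == (0.0, 0.3)

    def test_invalid_specs_rejected(self):
        from crsens import ConfigurationError

        with pytest.raises(ConfigurationError):
            GradientSpec("K", 1.0, 1.0)
        with pytest.raises(ConfigurationError):
            GradientSpec("Q", 0.0, 1.0)


class TestSweep:
    def test_lvv_resource_equilibrium_independent_of_k(self, table1):
        tab = sweep("LVV", table1, GradientSpec("K", 0.0, 10.0, 200))
        live = tab[tab.regime != "absent"]
        # above the invasion threshold A* is pinned at m/(e g)
        assert np.allclose(live.A_star, 0.625)
        # consumer biomass takes up the enrichment
        assert live.Z_star.is_monotonic_increasing

    def test_rm_lvv_is_stable_with_no_hopf(self, table1):
        grad = GradientSpec("K", 0.0, 10.0, 200)
        tab = sweep("RM_LVV", table1, grad)
        live = tab[tab.regime != "absent"]
        assert (live.re_lambda < 0).all()
        with pytest.raises(BifurcationNotFoundError):
            detect_hopf("RM_LVV", table1, grad)

    def test_rms_branch_count_goes_1_3_1(self, table1):
        tab = sweep("RMS", table1, GradientSpec("F", 0.0, 0.3, 300))
        counts = tab[tab.regime != "absent"].groupby("param").size()
        # the bistable window sits strictly inside the gradient
        assert counts.iloc[0] == 1 and counts.iloc[-1] == 1
        assert counts.max() == 3
        window = counts[counts == 3].index
        assert 0.07 < window.min() < 0.08 and 0.23 < window.max() < 0.25

    def test_rms_branches_are_continuous(self, table1):
        tab = sweep("RMS", table1, GradientSpec("F", 0.0, 0.3, 300))
        live = tab[tab.regime != "absent"]
        for _, branch in live.groupby("branch"):
            jumps = branch.A_star.diff().abs().dropna()
            assert (jumps < 0.1 * 1.5 * table1.K).all()

    def test_rows_flagged_below_invasion_threshold(self, table1):
        tab = sweep("LVV", table1, GradientSpec("K", 0.0, 0.5, 50))
        assert (tab.regime == "absent").all()


class TestTranscritical:
    def test_lvv_threshold(self, table1, grad_K):
        ev = detect_transcritical("LVV", table1, grad_K)
        assert round(ev.param_value, 2) == 0.64

    def test_agrees_with_closed_form_to_1e8(self, table1, grad_K):
        for variant in ("LVV", "LVV_LV", "RM", "RM_LV", "RM_LVV"):
            ev = detect_transcritical(variant, table1, grad_K, refinement_tol=1e-9)
            want = transcritical_closed_form(variant, table1)
            assert ev.param_value == pytest.approx(want, abs=1e-8)

    def test_linearized_coincides_with_parent(self, table1, grad_K):
        parent = detect_transcritical("LVV", table1, grad_K).param_value
        lin = detect_transcritical("LVV_LV", table1, grad_K).param_value
        assert lin == pytest.approx(parent, abs=1e-6)

    def test_rms_family_unsupported(self, table1, grad_K):
        with pytest.raises(UnsupportedVariantError):
            detect_transcritical("RMS", table1, grad_K)

    def test_no_sign_change_signalled(self, table1):
        with pytest.raises(BifurcationNotFoundError):
            detect_transcritical("LVV", table1, GradientSpec("K", 2.0, 10.0, 50))


class TestHopfAndFold:
    def test_rm_hopf_near_paradox_of_enrichment(self, table1, grad_K):
        ev = detect_hopf("RM", table1, grad_K)
        assert round(ev.param_value, 2) == 2.65

    def test_grid_refinement_does_not_move_events(self, table1):
        coarse = detect_hopf("RM", table1, GradientSpec("K", 0.0, 10.0, 1000))
        fine = detect_hopf("RM", table1, GradientSpec("K", 0.0, 10.0, 2000))
        assert abs(coarse.param_value - fine.param_value) <= coarse.refinement_tol

    def test_fully_linear_variants_have_no_hopf_or_fold(self, table1, grad_K, grad_F):
        for variant, grad in [("LVV_LV", grad_K), ("RM_LV", grad_K), ("RMS_LV", grad_F)]:
            with pytest.raises(BifurcationNotFoundError):
                detect_hopf(variant, table1, grad)
            assert detect_fold(variant, table1, grad) == []

    def test_rms_fold_pair(self, table1):
        events = detect_fold("RMS", table1, GradientSpec("F", 0.0, 0.3, 400))
        assert len(events) == 2
        lower, upper = (e.param_value for e in events)
        assert 0.07 < lower < 0.08 and 0.235 < upper < 0.245

    def test_fold_refinement_is_grid_stable(self, table1):
        e1 = detect_fold("RMS", table1, GradientSpec("F", 0.05, 0.1, 100))
        e2 = detect_fold("RMS", table1, GradientSpec("F", 0.05, 0.1, 200))
        assert len(e1) == len(e2) == 1
        assert abs(e1[0].param_value - e2[0].param_value) <= e1[0].refinement_tol


class TestAttractorProbe:
    def test_rm_limit_cycle_beyond_enrichment_hopf(self, table1):
        p = table1.replace(K=5.0)
        eq = closed_form_equilibria("RM", p)[0]
        assert attractor_probe("RM", p, eq) is AttractorOutcome.LIMIT_CYCLE

    def test_rm_settles_below_hopf(self, table1):
        p = table1.replace(K=2.0)
        eq = closed_form_equilibria("RM", p)[0]
        assert attractor_probe("RM", p, eq) is AttractorOutcome.SETTLES_TO_EQ

    def test_rms_escapes_inside_homoclinic_window(self, table1):
        p = table1.replace(K=10.0, F=0.15)
        eq = numeric_equilibria_rms("RMS", p)[0]
        assert attractor_probe("RMS", p, eq) is AttractorOutcome.OTHER_ATTRACTOR

    def test_boundary_equilibrium_rejected(self, table1):
        from crsens import ConfigurationError
        from crsens.models import boundary_equilibrium_rms

        with pytest.raises(ConfigurationError):
            attractor_probe("RMS", table1, boundary_equilibrium_rms(table1))


class TestGlobal:
    def test_variants_without_folds_are_rejected(self, table1, grad_F):
        with pytest.raises(BifurcationNotFoundError):
            detect_global(table1, grad_F, variant="RMS_LVV")
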