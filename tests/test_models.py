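"""Right-hand sides, equilibria and analytic Jacobians of all ten variants."""

import numpy as np
import pytest

from crsens import (
    DomainError,
    Equilibrium,
    ModelVariant,
    StaleEquilibriumError,
    UnsupportedVariantError,
    closed_form_equilibria,
    equilibria,
    jacobian,
    linearize,
    numeric_equilibria_rms,
    rhs,
)
from crsens.models import boundary_equilibrium_rms, make_rhs

from conftest import LINEARIZED, NONLINEAR, random_params


class TestRhs:
    def test_lv_interior_equilibrium_vanishes(self, table1):
        dA, dZ = rhs("LV", table1, (0.625, 1.225))
        assert max(abs(dA), abs(dZ)) < 1e-12

    def test_lv_origin_is_fixed_point(self, table1):
        assert rhs("LV", table1, (0.0, 0.0)) == (0.0, 0.0)

    def test_rms_origin_keeps_chemostat_influx(self, table1):
        p = table1.replace(K=10.0, F=0.0)
        dA, dZ = rhs("RMS", p, (0.0, 0.0))
        assert dA == pytest.approx(p.l * p.K)  # 0.1
        assert dZ == 0.0

    def test_negative_state_rejected(self, table1):
        with pytest.raises(DomainError):
            rhs("LV", table1, (-0.1, 1.0))

    def test_unknown_variant_rejected(self, table1):
        from crsens import ConfigurationError

        with pytest.raises(ConfigurationError):
            rhs("LW", table1, (1.0, 1.0))

    @pytest.mark.parametrize("variant", NONLINEAR)
    def test_rhs_vanishes_at_every_interior_equilibrium(self, variant):
        rng = np.random.default_rng(42)
        for _ in range(25):
            p, eqs = random_params(rng, variant)
            for eq in eqs:
                dA, dZ = rhs(variant, p, (eq.A_star, eq.Z_star))
                scale = max(1.0, eq.A_star, eq.Z_star)
                assert max(abs(dA), abs(dZ)) < 1e-10 * scale


class TestClosedFormEquilibria:
    def test_lv_interior(self, table1):
        eq = closed_form_equilibria("LV", table1)[0]
        assert eq.A_star == pytest.approx(0.625)
        assert eq.Z_star == pytest.approx(1.225)
        assert eq.interior

    def test_rm_interior_at_k5(self, table1):
        eq = closed_form_equilibria("RM", table1.replace(K=5.0))[0]
        assert eq.A_star == pytest.approx(1.0)
        assert eq.Z_star == pytest.approx(1.56)

    def test_lvv_below_invasion_threshold_flagged_infeasible(self, table1):
        eq = closed_form_equilibria("LVV", table1.replace(K=0.5))[0]
        assert eq.interior and eq.Z_star < 0 and not eq.feasible

    def test_boundary_equilibrium_is_consumer_free(self, table1):
        p = table1.replace(K=5.0)
        for variant in ("LVV", "RM"):
            bd = closed_form_equilibria(variant, p)[1]
            assert bd.Z_star == 0.0 and not bd.interior
            dA, dZ = rhs(variant, p, (bd.A_star, bd.Z_star))
            assert abs(dA) < 1e-12 and dZ == 0.0

    def test_rms_family_refused(self, table1):
        with pytest.raises(UnsupportedVariantError):
            closed_form_equilibria("RMS", table1)


class TestNumericEquilibriaRMS:
    @pytest.mark.parametrize(
        "F, expected",
        [(0.0, 1), (0.15, 3), (0.29, 1)],
        ids=["below-folds", "bistable-window", "above-folds"],
    )
    def test_interior_count_across_the_fold_window(self, table1, F, expected):
        eqs = numeric_equilibria_rms("RMS", table1.replace(K=10.0, F=F))
        assert len(eqs) == expected
        assert [e.branch_id for e in eqs] == list(range(expected))
        assert all(a.A_star < b.A_star for a, b in zip(eqs, eqs[1:]))

    def test_residual_vanishes_at_each_root(self, table1):
        p = table1.replace(K=10.0, F=0.15)
        for eq in numeric_equilibria_rms("RMS", p):
            dA, dZ = rhs("RMS", p, (eq.A_star, eq.Z_star))
            assert max(abs(dA), abs(dZ)) < 1e-10 * max(1.0, eq.A_star, eq.Z_star)

    def test_reduces_to_rm_closed_form_without_influx_and_f(self, table1):
        p = table1.replace(K=5.0, F=0.0)
        got = numeric_equilibria_rms("RMS", p, influx=False)
        want = closed_form_equilibria("RM", p)[0]
        assert len(got) == 1
        assert got[0].A_star == pytest.approx(want.A_star, abs=1e-8)
        assert got[0].Z_star == pytest.approx(want.Z_star, abs=1e-8)

    def test_boundary_state_excluded_but_exact(self, table1):
        p = table1.replace(K=10.0, F=0.15)
        bd = boundary_equilibrium_rms(p)
        assert bd.A_star == p.K and bd.Z_star == 0.0
        dA, dZ = rhs("RMS", p, (bd.A_star, bd.Z_star))
        assert dA == 0.0 and dZ == 0.0
        assert all(e.Z_star > 0 for e in numeric_equilibria_rms("RMS", p))


class TestJacobian:
    def test_lv_interior_matrix(self, table1):
        eq = closed_form_equilibria("LV", table1)[0]
        J = jacobian("LV", table1, eq)
        assert J.J11 == 0.0 and J.J22 == 0.0
        assert J.J12 == pytest.approx(-table1.m / table1.e)  # -0.25
        assert J.J21 == pytest.approx(table1.e * (table1.r - table1.l))  # 0.294

    def test_lv_trace_zero_det_positive(self, table1):
        eq = closed_form_equilibria("LV", table1)[0]
        J = jacobian("LV", table1, eq)
        assert J.trace == 0.0
        assert J.det == pytest.approx(table1.m * (table1.r - table1.l))

    def test_stale_equilibrium_rejected(self, table1):
        with pytest.raises(StaleEquilibriumError):
            jacobian("LV", table1, Equilibrium(0.7, 1.3, interior=True))

    @pytest.mark.parametrize("variant", NONLINEAR + LINEARIZED)
    def test_matches_finite_difference_oracle(self, variant):
        """Analytic entries vs central differences at 100 random draws."""
        rng = np.random.default_rng(int(np.sum(list(variant.value.encode()))))
        h, done = 1e-6, 0
        while done < 100:
            p, eqs = random_params(rng, variant)
            for eq in eqs:
                if variant.is_nonlinear:
                    sys_params = p
                else:
                    sys_params = linearize(variant.parent, p, eq, variant.target_dynamics)
                J = jacobian(variant, sys_params, eq)
                f = make_rhs(variant, sys_params)
                A, Z = eq.A_star, eq.Z_star
                fd = np.empty((2, 2))
                fd[:, 0] = (np.array(f(0, (A + h, Z))) - f(0, (A - h, Z))) / (2 * h)
                fd[:, 1] = (np.array(f(0, (A, Z + h))) - f(0, (A, Z - h))) / (2 * h)
                np.testing.assert_allclose(J.as_array(), fd, rtol=1e-5, atol=1e-6)
                done += 1

    def test_structural_zeros_of_fully_linear_systems(self, table1):
        """Per-capita growth vanishes at interior equilibria: exact zeros."""
        p = table1.replace(K=5.0)
        for parent, target in [("LVV", "LV"), ("RM", "LV")]:
            eq = closed_form_equilibria(parent, p)[0]
            lin = linearize(parent, p, eq, target)
            J = jacobian(lin.variant, lin, eq)
            assert J.J11 == 0.0 and J.J22 == 0.0


def test_equilibria_dispatches_per_family(table1):
    assert len(equilibria("LVV", table1.replace(K=5.0))) == 1
    assert len(equilibria("RMS", table1.replace(K=10.0, F=0.15))) == 3
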