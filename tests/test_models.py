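"""Settling-model evaluation: trivial identities, oracle equivalence, domains."""

import numpy as np
import pytest

import phytosed as ps
from phytosed.models import drag_riazi, evaluate_structure
from phytosed.traits import volume_from_nominal_diameter

from conftest import oracle_omega, random_in_domain_inputs


def make_traits(d_n, s_f, rho, specimen_id="t"):
    v = volume_from_nominal_diameter(d_n)
    c = (s_f * np.sqrt(v)) ** (2.0 / 3.0)
    ab = v / c
    return ps.ParticleTraits(
        specimen_id, volume=v, wet_weight=rho * v, morphology="direct_axes",
        axes=(np.sqrt(ab), np.sqrt(ab), c),
    )


class TestGeneralVelocity:
    def test_zero_at_neutral_buoyancy(self, median_medium):
        assert ps.general_velocity(median_medium.rho_sw, median_medium, 0.02, 1.0) == 0.0

    def test_unit_combination(self):
        # (rho/rho_sw - 1) g d = 1 and C_D = 4/3 -> omega = 1
        m = ps.override_properties(1000.0, 1e-6, g=1.0)
        assert ps.general_velocity(2000.0, m, 1.0, 4.0 / 3.0) == pytest.approx(1.0)

    def test_floating_particle_raises_buoyancy_error(self, median_medium):
        with pytest.raises(ps.BuoyancyError):
            ps.general_velocity(900.0, median_medium, 0.02, 1.0)

    def test_nonpositive_drag_rejected(self, median_medium):
        with pytest.raises(ps.DomainError):
            ps.general_velocity(1100.0, median_medium, 0.02, 0.0)


class TestRiaziForm:
    def test_reduces_to_general_at_spherical_shape(self, median_medium):
        t = make_traits(0.02, 1.0, 1104.44)
        v1 = ps.riazi_velocity(t, median_medium, c_d=2.0)
        v2 = ps.general_velocity(t.rho, median_medium, t.d_n, 2.0)
        assert v1 == pytest.approx(v2, rel=1e-14)

    def test_shape_scaling_exponent(self, median_medium):
        # S_f = 0.001 cuts omega by 0.001^(1/3) = 0.1 vs S_f = 1
        lo = ps.riazi_velocity(make_traits(0.02, 0.001, 1104.44), median_medium, 2.0)
        hi = ps.riazi_velocity(make_traits(0.02, 1.0, 1104.44), median_medium, 2.0)
        assert lo / hi == pytest.approx(0.1, rel=1e-10)


class TestDragRiazi:
    def test_constant_limits(self, median_medium):
        t = make_traits(0.02, 0.01, 1104.44)
        assert drag_riazi(t, median_medium, x1=7.0, x2=0.0, x3=1.0) == pytest.approx(1.0)
        lin = drag_riazi(t, median_medium, x1=1.0, x2=5.0, x3=0.0)
        expected = 5.0 * median_medium.nu / (t.d_n**1.5 * median_medium.g**0.5)
        assert lin == pytest.approx(expected, rel=1e-12)

    def test_dimensional_invariance(self):
        # (nu, d_n) -> (k nu, k^(2/3) d_n) leaves the drag group unchanged
        rng = np.random.default_rng(42)
        for _ in range(20):
            k = float(rng.uniform(0.2, 5.0))
            d_n, nu = 0.02, 1.1e-6
            t1 = make_traits(d_n, 0.01, 1104.44)
            t2 = make_traits(d_n * k ** (2.0 / 3.0), 0.01, 1104.44)
            m1 = ps.override_properties(1009.45, nu)
            m2 = ps.override_properties(1009.45, nu * k)
            c1 = drag_riazi(t1, m1, 5.57, 4146.0, 0.89)
            c2 = drag_riazi(t2, m2, 5.57, 4146.0, 0.89)
            assert c2 == pytest.approx(c1, rel=1e-10)

    def test_negative_base_refused(self, median_medium):
        t = make_traits(0.02, 0.01, 1104.44)
        with pytest.raises(ps.DomainError, match="base"):
            drag_riazi(t, median_medium, x1=2.0, x2=1.0, x3=-1.0)


class TestPresetModels:
    def test_all_models_zero_at_neutral_buoyancy(self, median_medium):
        t = make_traits(0.02, 0.01, median_medium.rho_sw)
        for f in (ps.model_a, ps.model_b, ps.model_c):
            assert f(t, median_medium).omega == 0.0

    def test_model_a_scales_linearly_with_dn(self, median_medium):
        # C_D ~ 1/d_n makes omega ~ d_n under the square root
        w1 = ps.model_a(make_traits(0.01, 0.01, 1104.44), median_medium).omega
        w2 = ps.model_a(make_traits(0.02, 0.01, 1104.44), median_medium).omega
        assert w2 / w1 == pytest.approx(2.0, rel=1e-10)

    def test_model_b_sf_halving_scales_by_cbrt_half(self, median_medium):
        w1 = ps.model_b(make_traits(0.02, 0.02, 1104.44), median_medium).omega
        w2 = ps.model_b(make_traits(0.02, 0.01, 1104.44), median_medium).omega
        assert w2 / w1 == pytest.approx(0.5 ** (1.0 / 3.0), rel=1e-10)

    @pytest.mark.parametrize("structure", ["A", "B", "C"])
    def test_median_condition_evaluations_match_oracle(self, structure, median_medium):
        t = make_traits(0.02, 0.01, 1104.44)
        w = ps.predict(ps.preset(structure), t, median_medium).omega
        expected = oracle_omega(
            structure, ps.preset(structure).constants,
            t.d_n, t.s_f, t.rho, median_medium.rho_sw, median_medium.nu, median_medium.g,
        )
        assert w == pytest.approx(expected, rel=1e-10)

    def test_high_power_shape_term_underflows_cleanly(self):
        # S_f^52.04557 underflows to a value < 1e-15 for all s_f <= 0.5
        s = np.array([0.00029, 0.01, 0.069, 0.5])
        with np.errstate(under="ignore"):
            term = np.exp(52.04557 * np.log(s))
        assert np.all(term < 1e-15)

    def test_buoyant_particle_distinct_error(self, median_medium):
        t = make_traits(0.02, 0.01, 900.0)
        with pytest.raises(ps.BuoyancyError):
            ps.model_c(t, median_medium)


class TestOracleEquivalence:
    @pytest.mark.parametrize("structure", ["A", "B", "C"])
    def test_random_inputs_match_log_domain_oracle(self, structure):
        rng = np.random.default_rng(123)
        rows = random_in_domain_inputs(rng, 300, structure=structure)
        spec = ps.preset(structure)
        for d_n, s_f, rho, rho_sw, nu, g in rows:
            w, _, ok = evaluate_structure(
                structure, np.asarray(spec.constants),
                np.array([d_n]), np.array([s_f]), np.array([rho]), rho_sw, nu, g,
            )
            expected = oracle_omega(structure, spec.constants, d_n, s_f, rho, rho_sw, nu, g)
            assert ok[0] and expected is not None
            assert w[0] == pytest.approx(expected, rel=1e-12)


class TestPredictionSurface:
    def test_single_cell_equals_scalar_evaluation(self, median_medium):
        t = make_traits(0.02, 0.01, 1104.44)
        omega, ok = ps.prediction_surface(
            ps.MODEL_C, median_medium, 1104.44, [0.02], [0.01]
        )
        assert ok.shape == (1, 1) and ok[0, 0]
        assert omega[0, 0] == pytest.approx(ps.model_c(t, median_medium).omega, rel=1e-12)

    def test_out_of_domain_cells_masked_not_raised(self, median_medium):
        omega, ok = ps.prediction_surface(
            ps.MODEL_C, median_medium, 1104.44, [0.02], [0.01, 1.0]
        )
        assert ok[0, 0] and not ok[1, 0]
        assert np.isnan(omega[1, 0])

    def test_empty_or_nonpositive_grid_rejected(self, median_medium):
        with pytest.raises(ps.ValidityError):
            ps.prediction_surface(ps.MODEL_C, median_medium, 1104.44, [], [0.01])
        with pytest.raises(ps.ValidityError):
            ps.prediction_surface(ps.MODEL_C, median_medium, 1104.44, [0.0], [0.01])
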