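import numpy as np
import pytest
from dataclasses import replace

from stemopt.fields import FieldResult, StaticSolver
from stemopt.loading import daily_activity_cases
from stemopt.mesh_fe import build_mesh
from stemopt.metrics import (
    cortical_evaluation_set,
    format_percent,
    percent_difference,
    shielding_metrics,
    strain_energy_change_rate,
    stress_objective,
)
from tests.conftest import make_strip


def _fake_result(name, energies, stresses=None):
    n = len(energies)
    stresses = np.zeros((n, 4)) if stresses is None else np.asarray(stresses, float)
    return FieldResult(name, np.zeros((1, 2)), np.asarray(energies, float),
                       stresses, 0.0)


@pytest.fixture()
def unit_cancellous_model():
    return build_mesh(make_strip(1, 1, label=2, rho=0.5))


class TestStrainEnergyChangeRate:
    def test_identical_fields_give_zero(self, unit_cancellous_model):
        m = unit_cancellous_model
        res = [_fake_result("a", [2.0])]
        g, n_inc, n_exc = strain_energy_change_rate(m, res, m, res, [1.0])
        assert g == 0.0
        assert (n_inc, n_exc) == (1, 0)

    def test_single_element_half_drop_is_fifty_percent(self, unit_cancellous_model):
        m = unit_cancellous_model
        g, _, _ = strain_energy_change_rate(
            m, [_fake_result("a", [2.0])], m, [_fake_result("a", [1.0])], [1.0])
        assert g == pytest.approx(50.0)

    def test_three_case_weighted_average(self, unit_cancellous_model):
        """Per-case rates (10%, 20%, 30%) at weights (0.6, 0.2, 0.2) -> 16%."""
        m = unit_cancellous_model
        pre = [_fake_result(c, [1.0]) for c in "abc"]
        post = [_fake_result("a", [0.9]), _fake_result("b", [0.8]),
                _fake_result("c", [0.7])]
        g, _, _ = strain_energy_change_rate(m, pre, m, post, [0.6, 0.2, 0.2])
        assert g == pytest.approx(16.0)

    def test_energy_gain_contributes_negatively(self, unit_cancellous_model):
        m = unit_cancellous_model
        g, _, _ = strain_energy_change_rate(
            m, [_fake_result("a", [1.0])], m, [_fake_result("a", [3.0])], [1.0])
        assert g == pytest.approx(-200.0)
        g_abs, _, _ = strain_energy_change_rate(
            m, [_fake_result("a", [1.0])], m, [_fake_result("a", [3.0])], [1.0],
            absolute=True)
        assert g_abs == pytest.approx(200.0)

    def test_floor_excludes_unloaded_elements(self):
        m = build_mesh(make_strip(1, 2, label=2, rho=0.5))
        pre = [_fake_result("a", [1.0, 1e-15])]
        post = [_fake_result("a", [0.5, 42.0])]
        g, n_inc, n_exc = strain_energy_change_rate(m, pre, m, post, [1.0])
        assert g == pytest.approx(50.0)
        assert (n_inc, n_exc) == (1, 1)

    def test_marrow_elements_are_not_part_of_the_shielding_set(self):
        img = make_strip(1, 2, label=2, rho=0.5)
        img.density[0, 1] = 0.01  # marrow
        m = build_mesh(img)
        pre = [_fake_result("a", [1.0, 1.0])]
        post = [_fake_result("a", [0.5, 100.0])]
        g, n_inc, _ = strain_energy_change_rate(m, pre, m, post, [1.0])
        assert g == pytest.approx(50.0)
        assert n_inc == 1

    def test_weights_must_sum_to_one(self, unit_cancellous_model):
        m = unit_cancellous_model
        with pytest.raises(ValueError):
            strain_energy_change_rate(m, [_fake_result("a", [1.0])],
                                      m, [_fake_result("a", [1.0])], [0.5])

    def test_g_is_invariant_under_uniform_load_scaling(self, coarse_evaluator):
        """Doubling every load quadruples energies; the ratios cancel."""
        ev = coarse_evaluator
        model, results = ev.fields_at(90.0)
        scaled_pre = [replace(r, element_strain_energy=4 * r.element_strain_energy)
                      for r in ev.pre_results]
        scaled_post = [replace(r, element_strain_energy=4 * r.element_strain_energy)
                       for r in results]
        g1, _, _ = strain_energy_change_rate(ev.pre_model, ev.pre_results,
                                             model, results, ev.weights)
        g2, _, _ = strain_energy_change_rate(ev.pre_model, scaled_pre,
                                             model, scaled_post, ev.weights)
        assert g1 == pytest.approx(g2, rel=1e-12)


class TestStressObjective:
    def test_single_cortical_element_sums_its_corners(self):
        m = build_mesh(make_strip(1, 1, label=1))
        res = [_fake_result("a", [0.0], [[1.0, 2.0, 3.0, 4.0]])]
        assert stress_objective(m, res, [1.0]) == pytest.approx(10.0)

    def test_equal_fields_under_split_weights_match_single_case(self):
        m = build_mesh(make_strip(1, 1, label=1))
        r = _fake_result("a", [0.0], [[1.0, 2.0, 3.0, 4.0]])
        single = stress_objective(m, [r], [1.0])
        double = stress_objective(m, [r, r], [0.5, 0.5])
        assert double == pytest.approx(single)

    def test_matches_brute_force_triple_loop(self, coarse_evaluator):
        ev = coarse_evaluator
        model, results = ev.fields_at(95.0)
        keep = cortical_evaluation_set(model)
        total = 0.0
        for ck, res in zip(ev.weights, results):
            for e in np.nonzero(keep)[0]:
                for c in range(4):
                    total += ck * res.nodal_stress[e, c]
        assert stress_objective(model, results, ev.weights) == pytest.approx(
            total, rel=1e-9)

    def test_f_scales_linearly_with_load(self):
        m = build_mesh(make_strip(1, 1, label=1))
        r1 = _fake_result("a", [0.0], [[1.0, 2.0, 3.0, 4.0]])
        r2 = _fake_result("a", [0.0], [[2.0, 4.0, 6.0, 8.0]])
        assert stress_objective(m, [r2], [1.0]) == pytest.approx(
            2 * stress_objective(m, [r1], [1.0]))

    def test_max_mode_takes_weighted_per_case_maximum(self):
        m = build_mesh(make_strip(1, 1, label=1))
        r = _fake_result("a", [0.0], [[1.0, 2.0, 3.0, 4.0]])
        assert stress_objective(m, [r], [1.0], mode="max") == pytest.approx(4.0)


class TestPercentDifference:
    @pytest.mark.parametrize("cand, ref, display", [
        (9.4028, 27.079, "-65.3%"),
        (32.127, 27.079, "+18.6%"),
        (115.84, 101.17, "+14.5%"),
        (108.28, 101.17, "+7.03%"),
    ])
    def test_table_convention_round_trips(self, cand, ref, display):
        assert format_percent(percent_difference(cand, ref)) == display

    def test_identity_is_zero(self):
        assert percent_difference(3.5, 3.5) == 0.0

    def test_zero_reference_is_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(1.0, 0.0)


def test_shielding_metrics_aggregates_consistently(coarse_evaluator):
    ev = coarse_evaluator
    model, results = ev.fields_at(100.0)
    m = shielding_metrics(ev.pre_model, ev.pre_results, model, results, ev.weights)
    g, n_inc, n_exc = strain_energy_change_rate(
        ev.pre_model, ev.pre_results, model, results, ev.weights)
    assert m.g_percent == pytest.approx(g)
    assert m.f_objective == pytest.approx(
        stress_objective(model, results, ev.weights))
    assert set(m.max_stress_per_case) == {c.name for c in daily_activity_cases()}
    w = ev.weights
    expected_weighted = sum(wk * m.max_stress_per_case[c.name]
                            for wk, c in zip(w, daily_activity_cases()))
    assert m.max_stress_weighted == pytest.approx(expected_weighted)
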