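import itertools

import numpy as np
import pytest

from restraintopt.injury_risk import (RiskVector, ScalingModel,
                                      anthropometric_scale,
                                      joint_risk, joint_risk_gradient_batch,
                                      measure_to_risk, risk_from_measures,
                                      risks_batch)
from restraintopt.population import OccupantCovariates, midsize_male_reference
from restraintopt.simulator import InjuryMeasures

REF = midsize_male_reference()


def test_head_risk_curve_values():
    # Phi((ln 1000 - 7.45231)/0.73998)
    assert measure_to_risk("head", 1000.0) == pytest.approx(0.2309, abs=1e-4)
    assert measure_to_risk("head", 1e-6) < 1e-12
    # scale is ignored for the head
    assert measure_to_risk("head", 1000.0, 2.0) == measure_to_risk("head", 1000.0)


def test_femur_risk_logistic_midpoint():
    # logistic midpoint at F = 5.795 / 0.5196 = 11.1528... kN
    assert measure_to_risk("lower_ext", 5.795 / 0.5196, 1.0) == pytest.approx(
        0.5, abs=1e-12)
    # the 4-decimal rounding of the midpoint sits within 1e-5 of 0.5
    assert measure_to_risk("lower_ext", 11.1528, 1.0) == pytest.approx(0.5, abs=1e-5)
    assert measure_to_risk("lower_ext", 0.0) == pytest.approx(
        1 / (1 + np.exp(5.795)), abs=1e-12)


def test_chest_risk_floor_and_monotonicity():
    floor = measure_to_risk("chest", 0.0)
    assert 0 < floor < 1e-4
    risks = [measure_to_risk("chest", d) for d in (10, 30, 60, 90)]
    assert all(a < b for a, b in zip(risks, risks[1:]))
    # larger anthropometric scale lowers the risk at a fixed measure
    assert measure_to_risk("chest", 40.0, 1.2) < measure_to_risk("chest", 40.0, 1.0)


def test_joint_risk_hand_values():
    assert joint_risk(0.0, 0.0, 0.0) == 0.0
    assert joint_risk(1.0, 0.5, 0.2) == pytest.approx(1.0)
    assert joint_risk(0.1, 0.1, 0.1) == pytest.approx(0.271)


def test_joint_risk_matches_inclusion_exclusion_on_grid():
    # brute-force union probability over the 0.1-grid of region risks
    grid = np.round(np.arange(0.0, 1.0001, 0.1), 10)
    for a, b, c in itertools.product(grid, repeat=3):
        expected = (a + b + c - a * b - a * c - b * c + a * b * c)
        assert joint_risk(a, b, c) == pytest.approx(expected, abs=1e-12)
        # symmetry
        assert joint_risk(c, a, b) == pytest.approx(joint_risk(a, b, c))


def test_joint_risk_rejects_out_of_range():
    with pytest.raises(ValueError):
        joint_risk(-0.1, 0.5, 0.5)
    with pytest.raises(ValueError):
        joint_risk(0.1, 1.5, 0.5)


def test_all_risks_within_unit_interval_random_sweep():
    rng = np.random.default_rng(0)
    n = 10_000
    S = np.column_stack([
        rng.integers(0, 2, n).astype(float),
        rng.uniform(150, 186, n),
        rng.uniform(19.5, 42.5, n),
    ])
    Y = np.column_stack([
        rng.uniform(0, 3000, n), rng.uniform(0, 90, n), rng.uniform(0, 25, n)
    ])
    R = risks_batch(S, Y)
    assert ((R >= 0) & (R <= 1)).all()
    assert (R[:, 3] >= R[:, :3].max(axis=1) - 1e-12).all()


def test_anthropometric_scale_identity_at_reference():
    assert anthropometric_scale(REF) == pytest.approx((1.0, 1.0))


def test_anthropometric_scale_grows_with_bmi():
    cs_hi, fs_hi = anthropometric_scale(OccupantCovariates("male", 175.0, 35.6))
    assert cs_hi > 1.0 and fs_hi > 1.0


def test_scale_ratio_equals_predicted_depth_ratio():
    model = ScalingModel()
    s1 = OccupantCovariates("female", 160.0, 30.0)
    s2 = OccupantCovariates("male", 180.0, 24.0)
    cs1, _ = anthropometric_scale(s1, model)
    cs2, _ = anthropometric_scale(s2, model)
    d1 = model.chest_depth(1.0, 160.0, 30.0)
    d2 = model.chest_depth(0.0, 180.0, 24.0)
    assert cs1 / cs2 == pytest.approx(float(d1 / d2))


def test_risk_from_measures_composition():
    y = InjuryMeasures(800.0, 45.0, 8.0)
    s = OccupantCovariates("female", 155.0, 38.0)
    rv = risk_from_measures(s, y)
    cs, fs = anthropometric_scale(s)
    assert rv.p_head == pytest.approx(measure_to_risk("head", 800.0))
    assert rv.p_chest == pytest.approx(measure_to_risk("chest", 45.0, cs))
    assert rv.p_lower_ext == pytest.approx(measure_to_risk("lower_ext", 8.0, fs))
    assert rv.p_joint == pytest.approx(
        joint_risk(rv.p_head, rv.p_chest, rv.p_lower_ext))
    assert rv.p_joint >= rv.p_chest
    # zero measures: head ~ 0, chest ~ 0, small positive femur logistic floor
    rv0 = risk_from_measures(s, InjuryMeasures(0.0, 0.0, 0.0))
    assert rv0.p_head == 0.0
    assert rv0.p_lower_ext == pytest.approx(1 / (1 + np.exp(5.795)), rel=1e-9)


def test_scale_one_is_identity_on_risks():
    for m, region in ((900.0, "head"), (40.0, "chest"), (9.0, "lower_ext")):
        assert measure_to_risk(region, m, 1.0) == measure_to_risk(region, m)


def test_joint_risk_gradient_matches_finite_differences():
    rng = np.random.default_rng(2)
    S = np.column_stack([
        rng.integers(0, 2, 6).astype(float),
        rng.uniform(155, 185, 6), rng.uniform(20, 40, 6)])
    Y = np.column_stack([
        rng.uniform(200, 1500, 6), rng.uniform(10, 60, 6), rng.uniform(1, 15, 6)])
    pj, G = joint_risk_gradient_batch(S, Y)
    assert pj == pytest.approx(risks_batch(S, Y)[:, 3])
    for m in range(3):
        h = 1e-5 * Y[:, m].mean()
        Yp, Ym = Y.copy(), Y.copy()
        Yp[:, m] += h
        Ym[:, m] -= h
        num = (risks_batch(S, Yp)[:, 3] - risks_batch(S, Ym)[:, 3]) / (2 * h)
        assert np.allclose(num, G[:, m], rtol=1e-5, atol=1e-10)


def test_invalid_measure_or_scale_rejected():
    with pytest.raises(ValueError):
        measure_to_risk("chest", -1.0)
    with pytest.raises(ValueError):
        measure_to_risk("chest", 10.0, 0.0)
    with pytest.raises(ValueError):
        RiskVector(0.2, 0.3, 1.2, 0.5)
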