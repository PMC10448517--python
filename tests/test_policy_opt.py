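import numpy as np
import pytest

import restraintopt as ro
from restraintopt.injury_risk import risk_from_measures
from restraintopt.population import (CovariateBox, OccupantCovariates,
                                     midsize_male_reference,
                                     population_numeric, sample_population)
from restraintopt.policy_opt import (DesignPolicy, ObjectiveSpec,
                                     PolicyFeatureMap, TruthPredictor,
                                     constant_policy, default_mc_sample,
                                     evaluate_policy, optimize_constant,
                                     optimize_policy, population_objective)
from restraintopt.simulator import (DESIGN_VARS, InjuryMeasures,
                                    SimulatorConfig, design_to_unit,
                                    optimal_unit_design_batch, sedan_config,
                                    true_optimal_design)

CFG = sedan_config()
BOX = CovariateBox()


class StubPredictor:
    """Returns fixed measures regardless of the design."""

    def __init__(self, Y):
        self.Y = np.atleast_2d(np.asarray(Y, dtype=float))

    def predict(self, S_num, D_phys):
        assert len(S_num) == len(self.Y)
        return self.Y

    def predict_with_grad(self, S_num, D_phys):
        return self.predict(S_num, D_phys), np.zeros((len(S_num), 3, 7))


def test_order_one_policy_is_constant_in_covariates():
    fmap = PolicyFeatureMap(1, BOX)
    policy = DesignPolicy(fmap, np.zeros((1, 7)))
    ds = {evaluate_policy(policy, s).as_array().tobytes()
          for s in sample_population(BOX, 10, seed=0)}
    assert len(ds) == 1


def test_polynomial_feature_arithmetic_identity_squash():
    # b1 + b2 * s~ with b1=0.2, b2=0.5 at standardized bmi 0.6 -> raw 0.5
    fmap = PolicyFeatureMap(2, BOX)
    W = np.zeros((len(fmap.names), 7))
    W[fmap.names.index("1"), 0] = 0.2
    W[fmap.names.index("bmi^1"), 0] = 0.5
    policy = DesignPolicy(fmap, W, squash="identity")
    b_lo, b_hi = BOX.union_bmi()
    bmi = b_lo + 0.8 * (b_hi - b_lo)          # standardized bmi = +0.6
    s = OccupantCovariates("male", 175.0, bmi)
    assert policy.raw_batch(s.as_numeric()[None, :])[0, 0] == pytest.approx(0.5)


def test_sex_feature_deduplication():
    # even sex powers are constant, odd ones duplicate the linear term
    names = PolicyFeatureMap(4, BOX).names
    assert names.count("sex") == 1
    assert "stature^3" in names and "bmi^3" in names


def test_sigmoid_squash_keeps_output_strictly_inside_box():
    fmap = PolicyFeatureMap(1, BOX)
    wild = DesignPolicy(fmap, 100.0 * np.ones((1, 7)))
    d = evaluate_policy(wild, midsize_male_reference())
    u = design_to_unit(d.as_array())
    assert ((u > 0) & (u < 1)).all()


def test_population_objective_matches_brute_force_loop():
    sample = sample_population(BOX, 6, seed=1)
    Y = np.abs(np.random.default_rng(0).normal(
        [600, 30, 4], [100, 5, 1], size=(6, 3)))
    spec = ObjectiveSpec(sample, StubPredictor(Y))
    d = true_optimal_design(midsize_male_reference(), CFG)
    got = population_objective(d, spec)
    expected = np.mean([
        risk_from_measures(s, InjuryMeasures(*y)).p_joint
        for s, y in zip(sample, Y)
    ])
    assert got == pytest.approx(expected, abs=1e-12)


def test_population_objective_constant_stub_risk():
    sample = sample_population(BOX, 4, seed=2)
    Y = np.tile([600.0, 30.0, 4.0], (4, 1))
    spec = ObjectiveSpec(sample, StubPredictor(Y))
    fmap = PolicyFeatureMap(2, BOX)
    p1 = DesignPolicy(fmap, np.zeros((len(fmap.names), 7)))
    p2 = DesignPolicy(fmap, np.ones((len(fmap.names), 7)))
    assert population_objective(p1, spec) == pytest.approx(
        population_objective(p2, spec))


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        ObjectiveSpec([], StubPredictor(np.ones((1, 3))))


def test_midsize_constant_recovers_reference_optimum():
    spec = ObjectiveSpec(default_mc_sample(n=16, seed=3), TruthPredictor(CFG))
    d = optimize_constant(spec, "midsize_male", seed=0, steps=1200)
    u = design_to_unit(d.as_array())
    u_star = design_to_unit(
        true_optimal_design(midsize_male_reference(), CFG).as_array())
    assert np.abs(u - u_star).max() < 0.05


def test_symmetric_two_occupant_population_optimum_is_midpoint():
    # equal baselines (covariate slopes zeroed) and optima symmetric about
    # the box center: the population-optimal constant is the midpoint
    cfg = SimulatorConfig(bmi_slope=(0, 0, 0), stature_slope=(0, 0, 0),
                          female_chest_offset=0.0)
    b_lo, b_hi = BOX.male_bmi
    mid_st = 175.0
    s1 = OccupantCovariates("male", mid_st, 25.0)
    s2 = OccupantCovariates("male", mid_st, 2 * (19.5 + 42.5) / 2 - 25.0)
    spec = ObjectiveSpec([s1, s2], TruthPredictor(cfg))
    d = optimize_constant(spec, "population", seed=0, steps=1500)
    S = population_numeric([s1, s2])
    u_mid = optimal_unit_design_batch(S, cfg).mean(axis=0)
    assert np.abs(design_to_unit(d.as_array()) - u_mid).max() < 0.05


def test_returned_objective_never_exceeds_warm_start():
    sample = default_mc_sample(n=64, seed=4)
    spec = ObjectiveSpec(sample, TruthPredictor(CFG))
    d0 = ro.true_optimal_design(midsize_male_reference(), CFG)
    w0 = constant_policy(d0, BOX).W
    j0 = population_objective(constant_policy(d0, BOX), spec)
    policy = optimize_policy(spec, m=2, seed=0, steps=400, restarts=1,
                             warm_starts=[w0])
    assert population_objective(policy, spec) <= j0 + 1e-12


def test_order_nesting_and_constant_equivalence():
    sample = default_mc_sample(n=64, seed=5)
    spec = ObjectiveSpec(sample, TruthPredictor(CFG))
    d_pop = optimize_constant(spec, "population", seed=0, steps=1200)
    w_pop = constant_policy(d_pop, BOX).W
    p1 = optimize_policy(spec, m=1, seed=0, steps=800, restarts=1,
                         warm_starts=[w_pop])
    p2 = optimize_policy(spec, m=2, seed=0, steps=800, restarts=1,
                         warm_starts=[p1.W])
    j_const = population_objective(d_pop, spec)
    j1 = population_objective(p1, spec)
    j2 = population_objective(p2, spec)
    # m=1 searches the same space as the constant optimization
    assert j1 == pytest.approx(j_const, abs=1e-4)
    # larger model class can only improve (warm-started)
    assert j2 <= j1 + 1e-6


def test_frozen_variables_stay_at_base_design():
    sample = default_mc_sample(n=32, seed=6)
    spec = ObjectiveSpec(sample, TruthPredictor(CFG))
    base = true_optimal_design(midsize_male_reference(), CFG)
    frozen = [v for v in DESIGN_VARS if v != "f_ll"]
    policy = optimize_policy(spec, m=2, seed=0, steps=300, restarts=1,
                             frozen_vars=frozen, base_design=base)
    S = population_numeric(sample)
    D = policy.design_batch(S)
    base_arr = base.as_array()
    for v in frozen:
        idx = DESIGN_VARS.index(v)
        assert D[:, idx] == pytest.approx(base_arr[idx], rel=1e-6)
    # the free variable does adapt
    assert np.ptp(D[:, DESIGN_VARS.index("f_ll")]) > 1.0


def test_policy_json_round_trip(tmp_path):
    fmap = PolicyFeatureMap(2, BOX)
    rng = np.random.default_rng(0)
    policy = DesignPolicy(fmap, rng.normal(size=(len(fmap.names), 7)))
    path = tmp_path / "policy.json"
    policy.to_json(path)
    back = DesignPolicy.from_json(path)
    S = population_numeric(sample_population(BOX, 5, seed=0))
    assert back.design_batch(S) == pytest.approx(policy.design_batch(S))
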