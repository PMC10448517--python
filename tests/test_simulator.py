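import numpy as np
import pytest

import restraintopt as ro
from restraintopt.injury_risk import risks_batch
from restraintopt.population import (OccupantCovariates, population_numeric,
                                     sample_population)
from restraintopt.simulator import (DesignVector,
                                    config_from_yaml, config_to_yaml,
                                    constant_optimum_config, design_from_unit,
                                    generate_dataset,
                                    optimal_unit_design_batch, sedan_config,
                                    simulate_batch, simulate_gradient_batch,
                                    simulate_measures, suv_config,
                                    true_optimal_design)

CFG = sedan_config()
REF = ro.midsize_male_reference()


def occupants(n=5, seed=0):
    return sample_population(CFG.box, n, seed)


def test_measures_at_true_optimum_equal_baseline():
    # the quadratic bowl vanishes exactly at d*(s)
    for s in occupants(6, seed=2):
        y = simulate_measures(s, true_optimal_design(s, CFG), CFG, noisy=False)
        base = simulate_batch(s.as_numeric()[None, :],
                              true_optimal_design(s, CFG).as_array()[None, :],
                              CFG)[0]
        assert y.as_array() == pytest.approx(base)
    y_ref = simulate_measures(REF, true_optimal_design(REF, CFG), CFG, noisy=False)
    assert y_ref.as_array() == pytest.approx([600.0, 30.0, 4.0])


def test_measures_increase_with_bmi_at_fixed_design():
    d = DesignVector.from_array(design_from_unit(np.full(7, 0.3)))
    lo = simulate_measures(OccupantCovariates("male", 175.0, 22.0), d, CFG)
    hi = simulate_measures(OccupantCovariates("male", 175.0, 35.0), d, CFG)
    assert (hi.as_array() > lo.as_array()).all()


def test_grid_search_argmin_matches_true_optimum():
    # per-coordinate 11-point grid with other variables held at the optimum
    s = OccupantCovariates("male", 182.0, 33.0)
    S = s.as_numeric()[None, :]
    u_star = optimal_unit_design_batch(S, CFG)[0]
    grid = np.linspace(0, 1, 11)
    w = np.asarray(CFG.bowl_weights)
    for l in range(7):
        if w[:, l].sum() == 0:
            continue  # flat coordinate for every measure
        U = np.tile(u_star, (11, 1))
        U[:, l] = grid
        Y = simulate_batch(np.tile(S, (11, 1)), design_from_unit(U), CFG)
        # total (summed) response is the bowl in coordinate l
        argmin = grid[np.argmin(Y.sum(axis=1))]
        assert abs(argmin - u_star[l]) <= 0.1 + 1e-12


def test_true_optimum_trends_and_projection():
    lo = true_optimal_design(OccupantCovariates("male", 175.0, 21.0), CFG)
    hi = true_optimal_design(OccupantCovariates("male", 175.0, 39.0), CFG)
    assert hi.f_ll > lo.f_ll       # more belt force for obese occupants
    assert hi.mf < lo.mf           # softer airbag for obese occupants
    # constant map when all covariate slopes are zero
    c_cfg = constant_optimum_config()
    ds = {true_optimal_design(s, c_cfg).as_array().tobytes()
          for s in occupants(10, seed=1)}
    assert len(ds) == 1
    # projection keeps 1000 optima inside the physical box
    S = population_numeric(occupants(1000, seed=5))
    U = optimal_unit_design_batch(S, CFG)
    assert ((U >= 0) & (U <= 1)).all()


def test_dataset_generation_contract():
    pairs = [(s, true_optimal_design(s, CFG)) for s in occupants(5, seed=3)]
    recs = generate_dataset(pairs, CFG, seed=11)
    assert len(recs) == 5
    assert [(r.s, r.d) for r in recs] == pairs
    recs2 = generate_dataset(pairs, CFG, seed=11)
    assert all(r1.y == r2.y for r1, r2 in zip(recs, recs2))
    # noise-off path equals the noiseless response
    quiet = generate_dataset(pairs, CFG, seed=11, noisy=False)
    for r, (s, d) in zip(quiet, pairs):
        assert r.y.as_array() == pytest.approx(
            simulate_measures(s, d, CFG, noisy=False).as_array())
    with pytest.raises(ValueError):
        generate_dataset([], CFG, seed=0)


def test_out_of_box_inputs_rejected():
    with pytest.raises(ValueError):
        DesignVector(0.08, 0.05, 1.0, 0.25, 2000.0, 0.0, 0.0)  # d0_ll too big
    giant = OccupantCovariates("male", 230.0, 25.0)
    d = true_optimal_design(REF, CFG)
    with pytest.raises(ValueError):
        simulate_measures(giant, d, CFG)


def test_adaptive_oracle_beats_any_constant_design():
    # the premise of adaptive design: with occupant-dependent optima, every
    # constant setting carries excess population risk over the oracle rule
    S = population_numeric(occupants(200, seed=9))
    U_star = optimal_unit_design_batch(S, CFG)
    y_opt = simulate_batch(S, design_from_unit(U_star), CFG)
    pj_opt = risks_batch(S, y_opt)[:, 3].mean()
    rng = np.random.default_rng(0)
    for _ in range(20):
        u_const = rng.uniform(size=7)
        y_c = simulate_batch(S, np.tile(design_from_unit(u_const), (len(S), 1)), CFG)
        assert risks_batch(S, y_c)[:, 3].mean() > pj_opt


def test_design_gradient_matches_finite_differences():
    S = population_numeric(occupants(4, seed=13))
    rng = np.random.default_rng(1)
    D = design_from_unit(rng.uniform(0.1, 0.9, size=(4, 7)))
    G = simulate_gradient_batch(S, D, CFG)
    for l in range(7):
        h = 1e-6 * (design_from_unit(np.ones(7)) - design_from_unit(np.zeros(7)))[l]
        Dp, Dm = D.copy(), D.copy()
        Dp[:, l] += h
        Dm[:, l] -= h
        num = (simulate_batch(S, Dp, CFG) - simulate_batch(S, Dm, CFG)) / (2 * h)
        assert np.allclose(num, G[:, :, l], rtol=1e-4, atol=1e-7)


def test_presets_differ_and_noise_is_lognormal_multiplicative():
    assert suv_config().baselines != sedan_config().baselines
    s, d = REF, true_optimal_design(REF, CFG)
    rng = np.random.default_rng(42)
    noisy = np.array([
        simulate_measures(s, d, CFG, noisy=True, rng=rng).as_array()
        for _ in range(400)
    ])
    clean = simulate_measures(s, d, CFG, noisy=False).as_array()
    assert (noisy > 0).all()
    rel = noisy / clean
    assert np.std(np.log(rel), axis=0) == pytest.approx(
        np.sqrt(np.log1p(CFG.noise_rel_sd ** 2)), rel=0.25)


def test_config_yaml_round_trip(tmp_path):
    path = tmp_path / "cfg.yaml"
    config_to_yaml(suv_config(), path)
    assert config_from_yaml(path) == suv_config()
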