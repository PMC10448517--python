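"""Seedable synthetic stand-in for the crash-simulation campaign.

Maps (occupant covariates, restraint design) to the three injury measures
HIC15, chest deflection (mm) and femur force (kN).  The response has a
documented ground-truth structure so that end-to-end optimization can be
checked against a closed-form oracle:

    y_m(s, d) = baseline_m(s) * (1 + sum_l w_ml * (u_l - u*_l(s))^2) * noise

where u is the design standardized to the unit cube of the design box,
u*(s) — the ground-truth optimal setting — is linear in standardized
covariates (clipped into the box), baseline_m(s) grows exponentially in BMI
and stature (with an optional female offset on chest deflection), and the
noise is multiplicative lognormal.  The noiseless response is therefore
minimized over d exactly at u*(s), the globally optimal adaptive rule is
linear in s, and higher-BMI/taller occupants carry a higher floor of risk —
the qualitative features a restraint-design study needs from its simulator.

The default ground-truth map encodes the physically expected adaptation:
higher retractor belt force (f_ll) and lower airbag mass flow (mf) for
high-BMI occupants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .population import CovariateBox, OccupantCovariates, population_numeric

#: design-variable order used throughout the package
DESIGN_VARS = ("d0_ll", "d1_ll", "dab", "dabstrap", "f_ll", "mf", "stiff")

#: physical box for the seven restraint design variables
DESIGN_BOUNDS: dict[str, tuple[float, float]] = {
    "d0_ll": (0.03, 0.05),        # load-limiter belt payout D0, m
    "d1_ll": (0.01, 0.11),        # load-limiter belt payout D1, m
    "dab": (0.96, 1.12),          # airbag cushion diameter, m
    "dabstrap": (0.2032, 0.3048), # airbag tether length, m
    "f_ll": (1000.0, 4000.0),     # retractor belt force, N
    "mf": (-0.15, 0.15),          # airbag mass-flow adjustment, fraction
    "stiff": (-0.40, 0.40),       # knee-bolster stiffness adjustment, fraction
}

DESIGN_LO = np.array([DESIGN_BOUNDS[v][0] for v in DESIGN_VARS])
DESIGN_HI = np.array([DESIGN_BOUNDS[v][1] for v in DESIGN_VARS])
DESIGN_SPAN = DESIGN_HI - DESIGN_LO

MEASURES = ("hic15", "chest_d_mm", "femur_f_kn")


def design_to_unit(d_phys: np.ndarray) -> np.ndarray:
    """Standardize physical design values to the unit cube."""
    return (np.asarray(d_phys) - DESIGN_LO) / DESIGN_SPAN


def design_from_unit(u: np.ndarray) -> np.ndarray:
    return DESIGN_LO + np.asarray(u) * DESIGN_SPAN


@dataclass(frozen=True)
class DesignVector:
    """One restraint setting; every component inside its physical range."""

    d0_ll: float
    d1_ll: float
    dab: float
    dabstrap: float
    f_ll: float
    mf: float
    stiff: float

    def __post_init__(self) -> None:
        for name in DESIGN_VARS:
            lo, hi = DESIGN_BOUNDS[name]
            v = getattr(self, name)
            if not (lo - 1e-9 <= v <= hi + 1e-9):
                raise ValueError(
                    f"{name}={v} outside its range [{lo}, {hi}]"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, v) for v in DESIGN_VARS])

    @staticmethod
    def from_array(a: Sequence[float]) -> "DesignVector":
        return DesignVector(*(float(x) for x in a))


@dataclass(frozen=True)
class InjuryMeasures:
    """HIC15 (dimensionless), chest deflection (mm), femur force (kN)."""

    hic15: float
    chest_d_mm: float
    femur_f_kn: float

    def __post_init__(self) -> None:
        vals = (self.hic15, self.chest_d_mm, self.femur_f_kn)
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise ValueError("injury measures must be finite and non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.hic15, self.chest_d_mm, self.femur_f_kn])


@dataclass(frozen=True)
class SimulationRecord:
    s: OccupantCovariates
    d: DesignVector
    y: InjuryMeasures


def _std_covariates(S_num: np.ndarray, box: CovariateBox) -> np.ndarray:
    """Map [sex01, stature, bmi] rows to [-1, 1] per covariate.

    Sex: male -> -1, female -> +1.  Stature/BMI use the union range across
    sexes so the map is continuous in the numeric covariates.
    """
    st_lo, st_hi = box.union_stature()
    b_lo, b_hi = box.union_bmi()
    out = np.empty_like(S_num, dtype=float)
    out[:, 0] = 2.0 * S_num[:, 0] - 1.0
    out[:, 1] = 2.0 * (S_num[:, 1] - st_lo) / (st_hi - st_lo) - 1.0
    out[:, 2] = 2.0 * (S_num[:, 2] - b_lo) / (b_hi - b_lo) - 1.0
    return out


@dataclass(frozen=True)
class SimulatorConfig:
    """Ground-truth structure of the synthetic crash response.

    baselines: measure level at the midsize-male reference.
    slopes: per-measure (bmi, stature) log-linear baseline sensitivities
        (per kg/m^2 and per cm); chosen so a (+10 BMI, +10 cm) occupant has
        roughly 50% higher baselines.
    female_chest_offset: log-offset added to the chest baseline for females.
    bowl_weights: (3, 7) non-negative curvature of each measure in each
        standardized design coordinate.
    opt_map: (7, 4) coefficients [intercept, sex, stature, bmi] of the
        ground-truth optimal unit-scaled setting, linear in standardized
        covariates, clipped to [0, 1].
    noise_rel_sd: relative sd of the multiplicative lognormal noise.
    """

    baselines: tuple[float, float, float] = (600.0, 30.0, 4.0)
    bmi_slope: tuple[float, float, float] = (0.030, 0.030, 0.030)
    stature_slope: tuple[float, float, float] = (0.012, 0.012, 0.012)
    female_chest_offset: float = 0.08
    bowl_weights: tuple[tuple[float, ...], ...] = (
        # d0_ll d1_ll dab  dabstrap f_ll  mf   stiff
        (0.00, 0.00, 0.60, 0.30, 0.40, 0.50, 0.00),  # hic15
        (0.40, 0.30, 0.00, 0.00, 0.60, 0.40, 0.00),  # chest deflection
        (0.00, 0.00, 0.00, 0.20, 0.00, 0.30, 0.70),  # femur force
    )
    opt_map: tuple[tuple[float, float, float, float], ...] = (
        # intercept, sex(-1/+1), stature, bmi     (standardized covariates)
        (0.50, 0.00, 0.10, 0.00),   # d0_ll
        (0.50, 0.00, 0.00, 0.08),   # d1_ll
        (0.50, 0.00, 0.15, 0.00),   # dab
        (0.50, 0.05, 0.00, 0.00),   # dabstrap
        (0.50, 0.00, 0.03, 0.25),   # f_ll: more belt force for obese
        (0.50, 0.00, -0.03, -0.25), # mf: softer airbag for obese
        (0.50, 0.00, 0.00, 0.10),   # stiff
    )
    noise_rel_sd: float = 0.02
    box: CovariateBox = field(default_factory=CovariateBox)

    def __post_init__(self) -> None:
        w = np.asarray(self.bowl_weights)
        if w.shape != (3, 7) or (w < 0).any():
            raise ValueError("bowl_weights must be (3, 7) and non-negative")
        if np.asarray(self.opt_map).shape != (7, 4):
            raise ValueError("opt_map must be (7, 4)")
        if self.noise_rel_sd < 0:
            raise ValueError("noise_rel_sd must be >= 0")


def sedan_config() -> SimulatorConfig:
    """Default preset (mid-size sedan compartment, structurally)."""
    return SimulatorConfig()


def suv_config() -> SimulatorConfig:
    """Second preset with different baselines and bowl curvature."""
    return SimulatorConfig(
        baselines=(450.0, 28.0, 3.5),
        bowl_weights=(
            (0.00, 0.00, 0.40, 0.40, 0.30, 0.40, 0.00),
            (0.50, 0.20, 0.00, 0.00, 0.50, 0.30, 0.00),
            (0.00, 0.00, 0.00, 0.10, 0.00, 0.20, 0.80),
        ),
    )


def single_active_config(variable: str = "f_ll") -> SimulatorConfig:
    """Config whose ground-truth optimum depends on covariates through one
    design variable only — used to test sensitivity attribution."""
    idx = DESIGN_VARS.index(variable)
    base = SimulatorConfig()
    opt = np.asarray(base.opt_map, dtype=float).copy()
    opt[:, 1:] = 0.0
    opt[idx] = [0.50, 0.0, 0.03, 0.30]
    return replace(base, opt_map=tuple(map(tuple, opt)))


def constant_optimum_config() -> SimulatorConfig:
    """Config whose optimal setting is the same for every occupant."""
    base = SimulatorConfig()
    opt = np.asarray(base.opt_map, dtype=float).copy()
    opt[:, 1:] = 0.0
    return replace(base, opt_map=tuple(map(tuple, opt)))


# ---------------------------------------------------------------------------
# vectorized core

def baseline_batch(S_num: np.ndarray, config: SimulatorConfig) -> np.ndarray:
    """(n, 3) baseline measures: exponential in BMI/stature around the
    midsize-male reference, female offset on chest deflection."""
    base = np.asarray(config.baselines)
    bs = np.asarray(config.bmi_slope)
    ss = np.asarray(config.stature_slope)
    d_bmi = S_num[:, 2:3] - 25.6
    d_st = S_num[:, 1:2] - 175.0
    log_fac = d_bmi * bs + d_st * ss
    log_fac[:, 1] += config.female_chest_offset * S_num[:, 0]
    return base * np.exp(log_fac)


def optimal_unit_design_batch(
    S_num: np.ndarray, config: SimulatorConfig
) -> np.ndarray:
    """(n, 7) ground-truth optimal settings on the unit design cube."""
    X = _std_covariates(S_num, config.box)
    feats = np.column_stack([np.ones(len(X)), X])   # [1, sex, stature, bmi]
    u = feats @ np.asarray(config.opt_map).T
    return np.clip(u, 0.0, 1.0)


def simulate_batch(
    S_num: np.ndarray,
    D_phys: np.ndarray,
    config: SimulatorConfig,
    noisy: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """(n, 3) injury measures for paired covariate/design rows."""
    S_num = np.atleast_2d(np.asarray(S_num, dtype=float))
    D_phys = np.atleast_2d(np.asarray(D_phys, dtype=float))
    u = design_to_unit(D_phys)
    u_star = optimal_unit_design_batch(S_num, config)
    w = np.asarray(config.bowl_weights)                     # (3, 7)
    dev2 = (u - u_star) ** 2                                # (n, 7)
    bowl = 1.0 + dev2 @ w.T                                 # (n, 3)
    y = baseline_batch(S_num, config) * bowl
    if noisy and config.noise_rel_sd > 0:
        if rng is None:
            raise ValueError("noisy simulation requires an rng")
        sigma = np.sqrt(np.log1p(config.noise_rel_sd ** 2))
        y = y * np.exp(sigma * rng.standard_normal(y.shape))
    return y


def simulate_gradient_batch(
    S_num: np.ndarray, D_phys: np.ndarray, config: SimulatorConfig
) -> np.ndarray:
    """(n, 3, 7) gradient of the noiseless measures w.r.t. physical design."""
    S_num = np.atleast_2d(np.asarray(S_num, dtype=float))
    D_phys = np.atleast_2d(np.asarray(D_phys, dtype=float))
    u = design_to_unit(D_phys)
    u_star = optimal_unit_design_batch(S_num, config)
    w = np.asarray(config.bowl_weights)
    base = baseline_batch(S_num, config)
    # dy_m/du_l = baseline_m * 2 w_ml (u_l - u*_l); du/dD = 1/span
    grad_u = 2.0 * base[:, :, None] * w[None, :, :] * (u - u_star)[:, None, :]
    return grad_u / DESIGN_SPAN[None, None, :]


# ---------------------------------------------------------------------------
# scalar / record interface

def _check_inputs(s: OccupantCovariates, d: DesignVector,
                  config: SimulatorConfig) -> None:
    if not config.box.contains(s):
        raise ValueError(f"occupant {s} outside the covariate box")
    # DesignVector validates its own box on construction
    _ = d.as_array()


def simulate_measures(
    s: OccupantCovariates,
    d: DesignVector,
    config: SimulatorConfig,
    noisy: bool = False,
    rng: np.random.Generator | None = None,
) -> InjuryMeasures:
    """Run one synthetic crash; deterministic given (inputs, rng state)."""
    _check_inputs(s, d, config)
    y = simulate_batch(s.as_numeric()[None, :], d.as_array()[None, :],
                       config, noisy=noisy, rng=rng)[0]
    return InjuryMeasures(*(float(v) for v in y))


def true_optimal_design(
    s: OccupantCovariates, config: SimulatorConfig
) -> DesignVector:
    """Ground-truth optimal setting d*(s), projected into the design box."""
    if not config.box.contains(s):
        raise ValueError(f"occupant {s} outside the covariate box")
    u = optimal_unit_design_batch(s.as_numeric()[None, :], config)[0]
    return DesignVector.from_array(design_from_unit(u))


def generate_dataset(
    design_matrix: Sequence[tuple[OccupantCovariates, DesignVector]],
    config: SimulatorConfig,
    seed: int,
    noisy: bool = True,
) -> list[SimulationRecord]:
    """One simulation record per (s, d) row; reproducible under the seed."""
    if len(design_matrix) == 0:
        raise ValueError("design matrix must be non-empty")
    rng = np.random.default_rng(seed)
    S_num = population_numeric([s for s, _ in design_matrix])
    D = np.array([d.as_array() for _, d in design_matrix])
    Y = simulate_batch(S_num, D, config, noisy=noisy, rng=rng)
    return [
        SimulationRecord(s, d, InjuryMeasures(*(float(v) for v in y)))
        for (s, d), y in zip(design_matrix, Y)
    ]


def records_to_frame(records: Iterable[SimulationRecord]) -> pd.DataFrame:
    """Dataset CSV schema: covariates, design variables, injury measures."""
    rows = []
    for r in records:
        rows.append(
            (r.s.sex, r.s.stature_cm, r.s.bmi, *r.d.as_array(), *r.y.as_array())
        )
    cols = ["sex", "stature_cm", "bmi", *DESIGN_VARS, *MEASURES]
    return pd.DataFrame(rows, columns=cols)


def records_from_frame(df: pd.DataFrame) -> list[SimulationRecord]:
    out = []
    for r in df.itertuples(index=False):
        s = OccupantCovariates(str(r.sex), float(r.stature_cm), float(r.bmi))
        d = DesignVector.from_array([getattr(r, v) for v in DESIGN_VARS])
        y = InjuryMeasures(float(r.hic15), float(r.chest_d_mm),
                           float(r.femur_f_kn))
        out.append(SimulationRecord(s, d, y))
    return out


def config_to_yaml(config: SimulatorConfig, path: str) -> None:
    data = {
        "baselines": list(config.baselines),
        "bmi_slope": list(config.bmi_slope),
        "stature_slope": list(config.stature_slope),
        "female_chest_offset": config.female_chest_offset,
        "bowl_weights": [list(r) for r in config.bowl_weights],
        "opt_map": [list(r) for r in config.opt_map],
        "noise_rel_sd": config.noise_rel_sd,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def config_from_yaml(path: str) -> SimulatorConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["baselines"] = tuple(data["baselines"])
    data["bmi_slope"] = tuple(data["bmi_slope"])
    data["stature_slope"] = tuple(data["stature_slope"])
    data["bowl_weights"] = tuple(map(tuple, data["bowl_weights"]))
    data["opt_map"] = tuple(map(tuple, data["opt_map"]))
    return SimulatorConfig(**data)
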