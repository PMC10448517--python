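"""Adaptive design-policy representation and optimization.

A design policy a(s) maps occupant covariates to the seven restraint
settings through a polynomial basis on standardized covariates:

    raw(s) = sum_{j=1..m} B_j phi_j(s~),   phi_j(s~) = [s~_1^{j-1}, ..., s~_K^{j-1}]

with covariates standardized to [-1, 1] (sex mapped to -1/+1) and the raw
output squashed into the physical design box by a scaled logistic, so the
policy output is always feasible and differentiable.  The population
objective is the Monte-Carlo mean of the joint injury risk Pjoint over a
covariate sample, with injury measures supplied by either the GP surrogate
(UCB prediction) or the synthetic simulator truth.

Coefficients are optimized with an Adam-style first-order method (adaptive
per-coordinate step sizes) on analytic full-batch gradients, with
multi-start; constant designs (the midsize-male and whole-population
baselines) are optimized with the same machinery restricted to the
intercept feature.  Because constants are a subclass of polynomial
policies, the optimized population constant is used as one warm start of
the adaptive search, which preserves the ordering
adaptive <= population constant <= midsize constant (on the population
objective) by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Protocol, Sequence

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .injury_risk import ScalingModel, joint_risk_gradient_batch, risks_batch
from .population import (CovariateBox, OccupantCovariates,
                         midsize_male_reference, population_numeric,
                         sample_population)
from .simulator import (DESIGN_LO, DESIGN_SPAN, DESIGN_VARS, DesignVector,
                        SimulatorConfig, _std_covariates, design_to_unit,
                        simulate_batch, simulate_gradient_batch)
from .surrogate import SurrogateModel


class MeasurePredictor(Protocol):
    """Maps covariate rows + physical designs to the three injury measures."""

    def predict(self, S_num: np.ndarray, D_phys: np.ndarray) -> np.ndarray: ...

    def predict_with_grad(
        self, S_num: np.ndarray, D_phys: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]: ...


@dataclass
class TruthPredictor:
    """Noiseless synthetic-simulator response (bypasses the surrogate)."""

    config: SimulatorConfig

    def predict(self, S_num, D_phys):
        return simulate_batch(S_num, D_phys, self.config, noisy=False)

    def predict_with_grad(self, S_num, D_phys):
        y = simulate_batch(S_num, D_phys, self.config, noisy=False)
        g = simulate_gradient_batch(S_num, D_phys, self.config)
        return y, g


@dataclass
class SurrogateUCBPredictor:
    """GP surrogate served at the one-sided upper confidence bound."""

    model: SurrogateModel
    level: float = 0.95

    def predict(self, S_num, D_phys):
        X = np.column_stack([S_num, D_phys])
        return np.maximum(self.model.ucb_batch(X, level=self.level), 1e-9)

    def predict_with_grad(self, S_num, D_phys):
        X = np.column_stack([S_num, D_phys])
        Xs = self.model.standardize(X)
        z = norm.ppf(self.level)
        q = len(Xs)
        Y = np.empty((q, 3))
        G = np.empty((q, 3, 7))
        d_cols = slice(3, 10)
        x_std_d = self.model.x_std[d_cols]
        for m_idx, comp in enumerate(self.model.components):
            mean, sd, dmean, dsd = comp.posterior_with_grad(Xs)
            ucb = mean + z * sd
            ducb = (dmean[:, d_cols] + z * dsd[:, d_cols]) / x_std_d
            if comp.log_target:
                val = np.exp(ucb)
                Y[:, m_idx] = val
                G[:, m_idx, :] = val[:, None] * ducb
            else:
                Y[:, m_idx] = ucb
                G[:, m_idx, :] = ducb
        low = Y < 1e-9
        Y = np.maximum(Y, 1e-9)
        G[low] = 0.0
        return Y, G


# ---------------------------------------------------------------------------
# polynomial features

@dataclass(frozen=True)
class PolicyFeatureMap:
    """Per-order power features of standardized covariates, de-duplicated.

    Sex (+-1) only contributes its first power: even powers are the
    constant feature and odd powers duplicate the linear one, so they are
    dropped to keep the coefficient problem identifiable.
    """

    m: int
    box: CovariateBox = field(default_factory=CovariateBox)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("polynomial order count m must be >= 1")

    @property
    def names(self) -> list[str]:
        out = ["1"]
        for j in range(2, self.m + 1):
            p = j - 1
            if p == 1:
                out.append("sex")
            out.extend([f"stature^{p}", f"bmi^{p}"])
        return out

    def __call__(self, S_num: np.ndarray) -> np.ndarray:
        X = _std_covariates(np.atleast_2d(S_num), self.box)
        cols = [np.ones(len(X))]
        for j in range(2, self.m + 1):
            p = j - 1
            if p == 1:
                cols.append(X[:, 0])
            cols.append(X[:, 1] ** p)
            cols.append(X[:, 2] ** p)
        return np.column_stack(cols)


Squash = Literal["sigmoid", "clip", "identity"]


def _squash_unit(raw: np.ndarray, squash: Squash):
    """Map raw policy output to unit design coordinates; returns value and
    derivative d(unit)/d(raw)."""
    if squash == "sigmoid":
        # clamp away from the faces so saturated raw values still map
        # strictly inside the physical box at float precision
        u = np.clip(expit(raw), 1e-9, 1.0 - 1e-9)
        return u, u * (1.0 - u)
    if squash == "clip":
        u = np.clip(raw, 0.0, 1.0)
        return u, ((raw > 0) & (raw < 1)).astype(float)
    if squash == "identity":
        return raw, np.ones_like(raw)
    raise ValueError(f"unknown squash {squash!r}")


@dataclass
class DesignPolicy:
    """Polynomial adaptive policy: W maps features to raw design outputs.

    ``W`` has one row per feature of ``feature_map`` and one column per
    design variable; the raw output is squashed into the physical box
    (default: scaled logistic with midpoint at the box center).
    """

    feature_map: PolicyFeatureMap
    W: np.ndarray
    squash: Squash = "sigmoid"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        F = len(self.feature_map.names)
        if self.W.shape != (F, len(DESIGN_VARS)):
            raise ValueError(
                f"W must be ({F}, {len(DESIGN_VARS)}), got {self.W.shape}"
            )

    def raw_batch(self, S_num: np.ndarray) -> np.ndarray:
        return self.feature_map(S_num) @ self.W

    def design_batch(self, S_num: np.ndarray) -> np.ndarray:
        u, _ = _squash_unit(self.raw_batch(S_num), self.squash)
        return DESIGN_LO + DESIGN_SPAN * u

    def to_json(self, path: str) -> None:
        data = {
            "m": self.feature_map.m,
            "squash": self.squash,
            "feature_names": self.feature_map.names,
            "W": self.W.tolist(),
            "box": {
                "male_stature": list(self.feature_map.box.male_stature),
                "male_bmi": list(self.feature_map.box.male_bmi),
                "female_stature": list(self.feature_map.box.female_stature),
                "female_bmi": list(self.feature_map.box.female_bmi),
            },
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2)

    @staticmethod
    def from_json(path: str) -> "DesignPolicy":
        with open(path) as fh:
            data = json.load(fh)
        box = CovariateBox(**{k: tuple(v) for k, v in data["box"].items()})
        fmap = PolicyFeatureMap(data["m"], box)
        return DesignPolicy(fmap, np.asarray(data["W"]), data["squash"])


def evaluate_policy(policy: DesignPolicy, s: OccupantCovariates) -> DesignVector:
    """Restraint setting assigned to occupant ``s`` by the policy."""
    d = policy.design_batch(s.as_numeric()[None, :])[0]
    return DesignVector.from_array(d)


def constant_policy(
    d: DesignVector,
    box: CovariateBox | None = None,
    squash: Squash = "sigmoid",
) -> DesignPolicy:
    """Order-1 policy returning ``d`` for every occupant (up to squash
    round-trip, exact for interior designs under the logistic squash)."""
    fmap = PolicyFeatureMap(1, box or CovariateBox())
    u = np.clip(design_to_unit(d.as_array()), 1e-9, 1 - 1e-9)
    if squash == "sigmoid":
        w0 = logit(u)
    else:
        w0 = u
    return DesignPolicy(fmap, w0[None, :], squash)


# ---------------------------------------------------------------------------
# objective

@dataclass
class ObjectiveSpec:
    """Monte-Carlo population objective: covariate sample + measure model.

    ``sample`` is the list of occupants the integral is averaged over
    (uniform weights — the population density is taken as constant);
    ``predictor`` supplies injury measures, ``risk_model`` maps them to
    Pjoint.
    """

    sample: Sequence[OccupantCovariates]
    predictor: MeasurePredictor
    risk_model: ScalingModel = field(default_factory=ScalingModel)
    box: CovariateBox = field(default_factory=CovariateBox)

    def __post_init__(self) -> None:
        if len(self.sample) == 0:
            raise ValueError("Monte-Carlo sample must be non-empty")
        self.S_num = population_numeric(self.sample)


def default_mc_sample(
    box: CovariateBox | None = None, n: int = 512, seed: int = 2024
) -> list[OccupantCovariates]:
    """Space-filling covariate sample for the optimization objective."""
    return sample_population(box or CovariateBox(), n, seed,
                             scheme="space-filling")


def population_objective(
    policy_or_design: DesignPolicy | DesignVector, spec: ObjectiveSpec
) -> float:
    """Mean Pjoint over the covariate sample under a policy or constant."""
    S = spec.S_num
    if isinstance(policy_or_design, DesignVector):
        D = np.tile(policy_or_design.as_array(), (len(S), 1))
    else:
        D = policy_or_design.design_batch(S)
    Y = spec.predictor.predict(S, D)
    return float(risks_batch(S, np.maximum(Y, 0.0), spec.risk_model)[:, 3].mean())


def _objective_and_grad(
    W: np.ndarray,
    Phi: np.ndarray,
    spec: ObjectiveSpec,
    squash: Squash,
    grad_mask: np.ndarray | None = None,
):
    S = spec.S_num
    raw = Phi @ W
    u, du = _squash_unit(raw, squash)
    D = DESIGN_LO + DESIGN_SPAN * u
    Y, dY = spec.predictor.predict_with_grad(S, D)
    pj, dpj_dy = joint_risk_gradient_batch(S, Y, spec.risk_model)
    # chain: dJ/dD (n,7) -> dJ/draw -> dJ/dW
    dJ_dD = np.einsum("nm,nml->nl", dpj_dy, dY)
    dJ_draw = dJ_dD * DESIGN_SPAN * du
    grad = Phi.T @ dJ_draw / len(S)
    if grad_mask is not None:
        grad = grad * grad_mask
    return float(pj.mean()), grad


def _adam(
    W0: np.ndarray,
    fun_grad,
    lr: float,
    steps: int,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
):
    """Adaptive-moment gradient descent; returns the best iterate seen."""
    W = W0.copy()
    m = np.zeros_like(W)
    v = np.zeros_like(W)
    best_J, best_W = np.inf, W.copy()
    for t in range(1, steps + 1):
        J, g = fun_grad(W)
        if not np.isfinite(J):
            raise FloatingPointError("non-finite objective")
        if J < best_J:
            best_J, best_W = J, W.copy()
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        m_hat = m / (1 - beta1 ** t)
        v_hat = v / (1 - beta2 ** t)
        W = W - lr * m_hat / (np.sqrt(v_hat) + eps)
    J, _ = fun_grad(W)
    if np.isfinite(J) and J < best_J:
        best_J, best_W = J, W.copy()
    return best_J, best_W


def optimize_policy(
    spec: ObjectiveSpec,
    m: int = 2,
    seed: int = 0,
    lr: float = 0.001,
    steps: int = 2000,
    restarts: int = 3,
    squash: Squash = "sigmoid",
    warm_starts: Sequence[np.ndarray] = (),
    frozen_vars: Sequence[str] = (),
    base_design: DesignVector | None = None,
) -> DesignPolicy:
    """Optimize policy coefficients by multi-start Adam on the population
    objective.

    ``warm_starts`` adds explicit coefficient matrices to the random
    starts.  ``frozen_vars`` pins the listed design variables to the
    constant ``base_design`` value (their coefficients receive zero
    gradient) — used by the per-variable sensitivity analysis.  The
    returned policy's objective never exceeds any start's initial value.
    """
    fmap = PolicyFeatureMap(m, spec.box)
    F = len(fmap.names)
    Phi = fmap(spec.S_num)
    n_vars = len(DESIGN_VARS)

    grad_mask = None
    base_W = np.zeros((F, n_vars))
    if frozen_vars:
        if base_design is None:
            raise ValueError("frozen_vars requires a base_design")
        grad_mask = np.ones((F, n_vars))
        u_base = np.clip(design_to_unit(base_design.as_array()), 1e-9, 1 - 1e-9)
        for v in frozen_vars:
            idx = DESIGN_VARS.index(v)
            grad_mask[:, idx] = 0.0
            base_W[0, idx] = logit(u_base[idx]) if squash == "sigmoid" else u_base[idx]

    def make_fun(mask):
        return lambda W: _objective_and_grad(W, Phi, spec, squash, mask)

    fun = make_fun(grad_mask)

    starts: list[np.ndarray] = []
    rng = np.random.default_rng(seed)
    for _ in range(restarts):
        W0 = base_W + 0.3 * rng.standard_normal((F, n_vars))
        if grad_mask is not None:
            W0 = base_W + grad_mask * 0.3 * rng.standard_normal((F, n_vars))
        starts.append(W0)
    for ws in warm_starts:
        ws = np.asarray(ws, dtype=float)
        if ws.shape[0] < F:   # pad lower-order warm start with zero coefficients
            ws = np.vstack([ws, np.zeros((F - ws.shape[0], n_vars))])
        starts.append(ws)

    best_J, best_W = np.inf, None
    for W0 in starts:
        J0, _ = fun(W0)
        if J0 < best_J:
            best_J, best_W = J0, W0.copy()
        try:
            J, W = _adam(W0, fun, lr=lr, steps=steps)
        except FloatingPointError:
            # restart this seed from a smaller perturbation
            W0r = base_W + 0.05 * rng.standard_normal((F, n_vars))
            if grad_mask is not None:
                W0r = base_W + grad_mask * 0.05 * rng.standard_normal((F, n_vars))
            J, W = _adam(W0r, fun, lr=lr, steps=steps)
        if J < best_J:
            best_J, best_W = J, W
    return DesignPolicy(fmap, best_W, squash)


def optimize_constant(
    spec: ObjectiveSpec,
    mode: Literal["midsize_male", "population"] = "population",
    seed: int = 0,
    lr: float = 0.01,
    steps: int = 1500,
    restarts: int = 3,
    reference: OccupantCovariates | None = None,
    warm_starts: Sequence[np.ndarray] = (),
) -> DesignVector:
    """Optimize a single (non-adaptive) design over the 7-dimensional box.

    ``midsize_male`` minimizes Pjoint at the reference occupant only;
    ``population`` minimizes the Monte-Carlo population mean.  A larger
    default learning rate is used than for the adaptive policy: the search
    space is 7 intercepts and the objective is much cheaper per step.
    """
    if mode == "midsize_male":
        ref = reference or midsize_male_reference()
        spec = ObjectiveSpec([ref], spec.predictor, spec.risk_model, spec.box)
    policy = optimize_policy(
        spec, m=1, seed=seed, lr=lr, steps=steps, restarts=restarts,
        warm_starts=warm_starts,
    )
    return evaluate_policy(policy, spec.sample[0])


def optimize_all(
    spec: ObjectiveSpec,
    m: int = 2,
    seed: int = 0,
    lr: float = 0.001,
    steps: int = 2000,
    restarts: int = 3,
    constant_lr: float = 0.01,
    constant_steps: int = 1500,
    reference: OccupantCovariates | None = None,
) -> dict:
    """The three solutions compared throughout: (i) midsize-male constant,
    (ii) population constant, (iii) adaptive policy.

    Warm starts chain the solutions ((i) seeds (ii), (ii) seeds (iii)) so
    the optimality ordering of the nested search spaces is preserved.
    """
    d_i = optimize_constant(spec, "midsize_male", seed=seed, lr=constant_lr,
                            steps=constant_steps, restarts=restarts,
                            reference=reference)
    w_i = constant_policy(d_i, spec.box).W
    d_ii = optimize_constant(spec, "population", seed=seed + 1, lr=constant_lr,
                             steps=constant_steps, restarts=restarts,
                             warm_starts=[w_i])
    w_ii = constant_policy(d_ii, spec.box).W
    policy = optimize_policy(spec, m=m, seed=seed + 2, lr=lr, steps=steps,
                             restarts=restarts, warm_starts=[w_ii])
    return {"design_i": d_i, "design_ii": d_ii, "policy_iii": policy}
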