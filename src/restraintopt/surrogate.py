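"""Gaussian-process surrogates of the injury measures.

One independent GP per measure (constant mean, squared-exponential kernel
with per-dimension lengthscales, observation-noise variance) over the
10-dimensional standardized input (sex, stature, BMI, 7 design variables).
Hyperparameters are estimated by maximum marginal likelihood with a fixed
multi-start.  HIC15 is modeled on the log scale.

Prediction serves the one-sided upper confidence bound (UCB)
mean + z * posterior sd — a conservative, worst-case-leaning estimate of
the injury measure; for HIC15 the bound is taken on the log scale and
back-transformed (the UCB commutes with a monotone transform).  The fitted
kernel is also exposed in closed form so the policy optimizer can use
analytic gradients of the UCB with respect to the design variables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_solve
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import KFold

from .simulator import MEASURES, SimulationRecord, records_to_frame

JITTER = 1e-6
N_INPUT = 10


def _records_to_xy(records: Sequence[SimulationRecord]):
    df = records_to_frame(records)
    df = df.assign(sex=(df["sex"] == "female").astype(float))
    X = df.iloc[:, :N_INPUT].to_numpy(dtype=float)
    Y = df[list(MEASURES)].to_numpy(dtype=float)
    return X, Y


@dataclass
class GPComponent:
    """Fitted GP for one measure, in closed form for fast linear algebra.

    Holds everything needed to reproduce the posterior: standardized
    training inputs, kernel hyperparameters (signal variance ``c``,
    per-dimension lengthscales ``ell``, noise variance ``white``), the
    weight vector alpha = K^-1 y_norm, the inverse kernel matrix, and the
    target normalization.  ``log_target`` marks measures fitted on the log
    scale.
    """

    name: str
    log_target: bool
    c: float
    ell: np.ndarray
    white: float
    X: np.ndarray          # (n, N_INPUT) standardized training inputs
    alpha: np.ndarray      # (n,)
    K_inv: np.ndarray      # (n, n)
    y_mean: float
    y_std: float

    def _k_trans(self, Xs: np.ndarray) -> np.ndarray:
        d = (Xs[:, None, :] - self.X[None, :, :]) / self.ell
        return self.c * np.exp(-0.5 * np.sum(d * d, axis=2))

    def posterior(self, Xs: np.ndarray):
        """Posterior mean and sd on the modeling scale (log for HIC15)."""
        K = self._k_trans(Xs)
        mean = self.y_mean + self.y_std * (K @ self.alpha)
        U = K @ self.K_inv
        var = np.maximum(self.c + self.white - np.sum(U * K, axis=1), 0.0)
        return mean, self.y_std * np.sqrt(var)

    def posterior_with_grad(self, Xs: np.ndarray):
        """Posterior (mean, sd) plus gradients w.r.t. standardized inputs.

        Returns mean (q,), sd (q,), dmean (q, p), dsd (q, p).
        """
        K = self._k_trans(Xs)                                  # (q, n)
        diff = Xs[:, None, :] - self.X[None, :, :]             # (q, n, p)
        dK = -K[:, :, None] * diff / (self.ell ** 2)           # (q, n, p)
        mean = self.y_mean + self.y_std * (K @ self.alpha)
        dmean = self.y_std * np.einsum("qnp,n->qp", dK, self.alpha)
        U = K @ self.K_inv                                     # (q, n)
        var = np.maximum(self.c + self.white - np.sum(U * K, axis=1), 0.0)
        sd_norm = np.sqrt(np.maximum(var, 1e-18))
        dvar = -2.0 * np.einsum("qnp,qn->qp", dK, U)
        dsd = self.y_std * dvar / (2.0 * sd_norm[:, None])
        return mean, self.y_std * sd_norm, dmean, dsd


@dataclass
class SurrogateModel:
    """Per-measure GPs plus the input standardization used at fit time."""

    components: list[GPComponent]
    x_mean: np.ndarray
    x_std: np.ndarray
    seed: int

    def standardize(self, X_raw: np.ndarray) -> np.ndarray:
        return (np.asarray(X_raw, dtype=float) - self.x_mean) / self.x_std

    def ucb_batch(self, X_raw: np.ndarray, level: float = 0.95) -> np.ndarray:
        """(q, 3) UCB-predicted measures on their natural scales."""
        if not 0.0 < level < 1.0:
            raise ValueError("level must be in (0, 1)")
        z = norm.ppf(level)
        Xs = self.standardize(X_raw)
        cols = []
        for comp in self.components:
            mean, sd = comp.posterior(Xs)
            ucb = mean + z * sd
            cols.append(np.exp(ucb) if comp.log_target else ucb)
        return np.column_stack(cols)

    def mean_batch(self, X_raw: np.ndarray) -> np.ndarray:
        return self.ucb_batch(X_raw, level=0.5)


def fit_gp(
    records: Sequence[SimulationRecord],
    seed: int = 0,
    n_restarts: int = 2,
) -> SurrogateModel:
    """Fit per-measure GPs by maximum marginal likelihood.

    Requires at least 10 records.  HIC15 is log-transformed before
    fitting.  A zero-variance (constant) target degrades gracefully to a
    constant-mean fit through target normalization.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records to fit a surrogate")
    X_raw, Y = _records_to_xy(records)
    x_mean = X_raw.mean(axis=0)
    x_std = X_raw.std(axis=0)
    x_std[x_std == 0] = 1.0
    Xs = (X_raw - x_mean) / x_std

    components = []
    for m_idx, name in enumerate(MEASURES):
        log_target = name == "hic15"
        y = np.log(np.maximum(Y[:, m_idx], 1e-12)) if log_target else Y[:, m_idx]
        kernel = (
            ConstantKernel(1.0, (1e-3, 1e3))
            * RBF(np.ones(N_INPUT), (1e-2, 1e2))
            + WhiteKernel(1e-6, (1e-12, 1e-1))
        )
        gpr = GaussianProcessRegressor(
            kernel=kernel,
            alpha=JITTER,
            normalize_y=True,
            n_restarts_optimizer=n_restarts,
            random_state=seed + m_idx,
        )
        with warnings.catch_warnings():
            # near-noiseless targets routinely push the noise level to its
            # lower bound and inert dimensions to long lengthscales; both
            # are benign here
            warnings.simplefilter("ignore")
            gpr.fit(Xs, y)
        k = gpr.kernel_
        n = len(y)
        K_inv = cho_solve((gpr.L_, True), np.eye(n))
        components.append(
            GPComponent(
                name=name,
                log_target=log_target,
                c=float(k.k1.k1.constant_value),
                ell=np.atleast_1d(np.asarray(k.k1.k2.length_scale, float)),
                white=float(k.k2.noise_level),
                X=np.asarray(gpr.X_train_, float),
                alpha=np.asarray(gpr.alpha_, float).ravel(),
                K_inv=K_inv,
                y_mean=float(np.ravel(gpr._y_train_mean)[0]),
                y_std=float(np.ravel(gpr._y_train_std)[0]),
            )
        )
    return SurrogateModel(components, x_mean, x_std, seed)


def predict_ucb(model: SurrogateModel, s, d, level: float = 0.95):
    """UCB-predicted injury measures for one occupant/design pair.

    At level 0.5 the bound coincides with the posterior mean; at the
    default 0.95 the one-sided normal quantile z = 1.645 is applied to the
    posterior sd.
    """
    from .simulator import InjuryMeasures

    x = np.concatenate([s.as_numeric(), d.as_array()])[None, :]
    y = model.ucb_batch(x, level=level)[0]
    return InjuryMeasures(*(float(max(v, 0.0)) for v in y))


@dataclass
class CvReport:
    """Out-of-fold predictions and per-measure R^2 from k-fold CV."""

    oof_predictions: np.ndarray    # (n, 3) posterior-mean predictions
    truths: np.ndarray             # (n, 3)
    r2: dict[str, float]
    k: int
    seed: int


def cross_validate(
    records: Sequence[SimulationRecord],
    k: int = 10,
    seed: int = 0,
    n_restarts: int = 0,
) -> CvReport:
    """k-fold cross-validation of the posterior-mean predictions.

    R^2 = 1 - SS_res/SS_tot per measure, computed on the natural measure
    scale (HIC15 predictions are back-transformed from the log scale).
    """
    n = len(records)
    if k < 2 or k > n:
        raise ValueError("need 2 <= k <= n folds")
    X_raw, Y = _records_to_xy(records)
    oof = np.full_like(Y, np.nan, dtype=float)
    records = list(records)
    for fold_idx, (tr, te) in enumerate(
        KFold(n_splits=k, shuffle=True, random_state=seed).split(X_raw)
    ):
        model = fit_gp([records[i] for i in tr], seed=seed + fold_idx,
                       n_restarts=n_restarts)
        oof[te] = model.mean_batch(X_raw[te])
    r2 = {}
    for m_idx, name in enumerate(MEASURES):
        resid = Y[:, m_idx] - oof[:, m_idx]
        ss_tot = np.sum((Y[:, m_idx] - Y[:, m_idx].mean()) ** 2)
        r2[name] = float(1.0 - np.sum(resid ** 2) / ss_tot)
    return CvReport(oof, Y, r2, k, seed)


# ---------------------------------------------------------------------------
# persistence

def save_model(model: SurrogateModel, path: str) -> None:
    """Persist hyperparameters, training data and standardization as JSON."""
    data = {
        "seed": model.seed,
        "x_mean": model.x_mean.tolist(),
        "x_std": model.x_std.tolist(),
        "components": [
            {
                "name": c.name,
                "log_target": c.log_target,
                "c": c.c,
                "ell": c.ell.tolist(),
                "white": c.white,
                "X": c.X.tolist(),
                "alpha": c.alpha.tolist(),
                "K_inv": c.K_inv.tolist(),
                "y_mean": c.y_mean,
                "y_std": c.y_std,
            }
            for c in model.components
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def load_model(path: str) -> SurrogateModel:
    with open(path) as fh:
        data = json.load(fh)
    comps = [
        GPComponent(
            name=c["name"],
            log_target=c["log_target"],
            c=c["c"],
            ell=np.asarray(c["ell"]),
            white=c["white"],
            X=np.asarray(c["X"]),
            alpha=np.asarray(c["alpha"]),
            K_inv=np.asarray(c["K_inv"]),
            y_mean=c["y_mean"],
            y_std=c["y_std"],
        )
        for c in data["components"]
    ]
    return SurrogateModel(
        comps, np.asarray(data["x_mean"]), np.asarray(data["x_std"]),
        data["seed"],
    )
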