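"""Maximum-projection (MaxPro) space-filling designs.

The simulation campaign explores a 10-dimensional input space (3 occupant
covariates + 7 design variables).  A MaxPro design minimizes

    psi(D) = [ (1/C(n,2)) * sum_{i<j} prod_l (x_il - x_jl)^(-2) ]^(1/p)

over Latin hypercubes, which rewards good space-filling in *every*
projection of the factors (any pair sharing a coordinate in any column
drives psi to infinity).  Construction: random Latin hypercube start,
then simulated-annealing coordinate exchange — swapping two entries
within one column, which preserves the Latin-hypercube structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np

from .population import CovariateBox, OccupantCovariates
from .simulator import DESIGN_BOUNDS, DESIGN_VARS, DesignVector

#: column layout of the full simulation-campaign design
CAMPAIGN_COLUMNS = ("sex", "stature_cm", "bmi", *DESIGN_VARS)


@dataclass
class ColumnMeta:
    """Physical interpretation of one unit-scaled design column."""

    name: str
    kind: str                     # "continuous" or "binary"
    low: float = 0.0
    high: float = 1.0


@dataclass
class DesignMatrix:
    """n x p matrix of unit-cube coordinates plus column metadata."""

    unit: np.ndarray
    columns: list[ColumnMeta]
    psi_initial: float | None = None
    psi_final: float | None = None

    def __post_init__(self) -> None:
        self.unit = np.asarray(self.unit, dtype=float)
        if self.unit.ndim != 2:
            raise ValueError("design must be a 2-D array")
        if ((self.unit < 0) | (self.unit > 1)).any():
            raise ValueError("all design entries must lie in [0, 1]")
        if len(self.columns) != self.unit.shape[1]:
            raise ValueError("column metadata does not match design width")

    @property
    def n(self) -> int:
        return self.unit.shape[0]

    @property
    def p(self) -> int:
        return self.unit.shape[1]

    def save(self, csv_path: str, meta_path: str) -> None:
        header = ",".join(c.name for c in self.columns)
        np.savetxt(csv_path, self.unit, delimiter=",", header=header,
                   comments="")
        with open(meta_path, "w") as fh:
            json.dump([c.__dict__ for c in self.columns], fh, indent=2)


def maxpro_criterion(design: DesignMatrix | np.ndarray) -> float:
    """MaxPro criterion psi; lower is better, +inf on any shared coordinate."""
    X = design.unit if isinstance(design, DesignMatrix) else np.asarray(design, float)
    n, p = X.shape
    if n < 2:
        raise ValueError("criterion needs at least 2 rows")
    diff = X[:, None, :] - X[None, :, :]
    iu = np.triu_indices(n, k=1)
    prod_sq = np.prod(diff[iu] ** 2, axis=1)
    if (prod_sq == 0).any():
        return float("inf")
    s = np.sum(1.0 / prod_sq) / comb(n, 2)
    return float(s ** (1.0 / p))


def _random_lhs(n: int, p: int, rng: np.random.Generator) -> np.ndarray:
    """Latin hypercube with one point uniform inside each of the n cells."""
    perms = np.array([rng.permutation(n) for _ in range(p)]).T
    return (perms + rng.uniform(size=(n, p))) / n


def _pair_inverse_products(X: np.ndarray) -> np.ndarray:
    """(n, n) symmetric matrix P_ij = prod_l (x_il - x_jl)^(-2), diag 0."""
    n = X.shape[0]
    diff = X[:, None, :] - X[None, :, :]
    with np.errstate(divide="ignore"):
        P = 1.0 / np.prod(diff ** 2 + np.eye(n)[:, :, None], axis=2)
    np.fill_diagonal(P, 0.0)
    return P


def generate_maxpro_design(
    n: int,
    p: int,
    seed: int = 0,
    iterations: int = 10_000,
    t0: float = 0.1,
    cooling: float = 0.999,
) -> DesignMatrix:
    """Build a MaxPro Latin hypercube by annealed coordinate exchange.

    Starts from a random LHS and proposes swaps of two entries within one
    column; improvements are always accepted, deteriorations with the
    annealing probability exp(-relative increase / T) under geometric
    cooling.  The best design visited is returned, so the final criterion
    never exceeds the initial one.
    """
    if n < 2 or p < 1:
        raise ValueError("need n >= 2 rows and p >= 1 columns")
    rng = np.random.default_rng(seed)
    X = _random_lhs(n, p, rng)
    P = _pair_inverse_products(X)
    npairs = comb(n, 2)
    total = P[np.triu_indices(n, k=1)].sum()
    psi0 = float((total / npairs) ** (1.0 / p))

    best_X, best_total = X.copy(), total
    T = t0
    rows_idx = np.arange(n)
    for _ in range(iterations):
        col = int(rng.integers(p))
        i, j = rng.choice(n, size=2, replace=False)
        xi_old, xj_old = X[i, col], X[j, col]
        # swapping entries within a column touches only pairs involving i or j
        others = rows_idx[(rows_idx != i) & (rows_idx != j)]
        ratio_i = ((X[others, col] - xi_old) / (X[others, col] - xj_old)) ** 2
        ratio_j = ((X[others, col] - xj_old) / (X[others, col] - xi_old)) ** 2
        new_Pi = P[i, others] * ratio_i
        new_Pj = P[j, others] * ratio_j
        delta = (new_Pi.sum() - P[i, others].sum()
                 + new_Pj.sum() - P[j, others].sum())
        accept = delta < 0 or rng.uniform() < np.exp(
            -delta / (T * max(total, 1e-300))
        )
        if accept:
            X[i, col], X[j, col] = xj_old, xi_old
            P[i, others] = new_Pi
            P[others, i] = new_Pi
            P[j, others] = new_Pj
            P[others, j] = new_Pj
            total += delta
            if total < best_total:
                best_total = total
                best_X = X.copy()
        T *= cooling

    psi_final = float((best_total / npairs) ** (1.0 / p))
    cols = [ColumnMeta(f"x{k}", "continuous") for k in range(p)]
    return DesignMatrix(best_X, cols, psi_initial=psi0,
                        psi_final=min(psi0, psi_final))


def campaign_metadata(box: CovariateBox | None = None) -> list[ColumnMeta]:
    """Column metadata for the 10-column simulation campaign.

    Sex is carried as a continuous unit column (the MaxPro criterion works
    on the continuous relaxation) and binarized at 0.5 during scaling; the
    stature/BMI ranges then follow the assigned sex.
    """
    box = box or CovariateBox()
    cols = [ColumnMeta("sex", "binary"),
            ColumnMeta("stature_cm", "continuous"),
            ColumnMeta("bmi", "continuous")]
    for v in DESIGN_VARS:
        lo, hi = DESIGN_BOUNDS[v]
        cols.append(ColumnMeta(v, "continuous", lo, hi))
    return cols


def scale_design(
    design: DesignMatrix,
    metadata: Sequence[ColumnMeta] | None = None,
    box: CovariateBox | None = None,
) -> list[tuple[OccupantCovariates, DesignVector]]:
    """Map a unit-cube campaign design to physical (occupant, design) pairs."""
    box = box or CovariateBox()
    meta = list(metadata) if metadata is not None else campaign_metadata(box)
    names = [c.name for c in meta]
    if len(meta) != design.p or names != list(CAMPAIGN_COLUMNS):
        raise ValueError(
            f"metadata must cover campaign columns {CAMPAIGN_COLUMNS}, got {names}"
        )
    out = []
    for row in design.unit:
        sex = "male" if row[0] < 0.5 else "female"
        st_lo, st_hi = box.stature_range(sex)
        b_lo, b_hi = box.bmi_range(sex)
        s = OccupantCovariates(
            sex,
            float(st_lo + (st_hi - st_lo) * row[1]),
            float(b_lo + (b_hi - b_lo) * row[2]),
        )
        d_vals = [
            m.low + (m.high - m.low) * u for m, u in zip(meta[3:], row[3:])
        ]
        out.append((s, DesignVector.from_array(d_vals)))
    return out


def campaign_design(
    n: int, seed: int = 0, iterations: int = 10_000,
    box: CovariateBox | None = None,
) -> DesignMatrix:
    """MaxPro design over the full 10-column campaign space."""
    dm = generate_maxpro_design(n, len(CAMPAIGN_COLUMNS), seed=seed,
                                iterations=iterations)
    dm.columns = campaign_metadata(box)
    return dm
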