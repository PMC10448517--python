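"""Injury-risk curves, anthropometric scaling and the joint risk Pjoint.

Injury measures map to body-region AIS3+ risks through standard
frontal-impact curves:

* head:       P = Phi((ln HIC15 - 7.45231) / 0.73998)        (lognormal)
* chest:      P = 1 / (1 + exp(10.5456 - 1.568 * D^0.4612)), D in mm
* lower ext.: P = 1 / (1 + exp(5.795 - 0.5196 * F)),         F in kN

Chest and lower-extremity risks are scaled to the occupant's anthropometry
by stretching the curve abscissa: the effective measure is the observed
measure divided by the ratio of the occupant's predicted chest depth (or
femur cross-sectional area) to the midsize-male reference.  A linear
regression stand-in predicts those quantities from (sex, stature, BMI).
Head risk is not anthropometrically scaled.

The joint risk combines regions under independence:
Pjoint = 1 - (1-p_head)(1-p_chest)(1-p_lower_ext).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import norm

HEAD_LN_MU = 7.45231
HEAD_LN_SIGMA = 0.73998
CHEST_A = 10.5456
CHEST_B = 1.568
CHEST_POW = 0.4612
FEMUR_A = 5.795
FEMUR_B = 0.5196

Region = Literal["head", "chest", "lower_ext"]


@dataclass(frozen=True)
class RiskVector:
    p_head: float
    p_chest: float
    p_lower_ext: float
    p_joint: float

    def __post_init__(self) -> None:
        vals = (self.p_head, self.p_chest, self.p_lower_ext, self.p_joint)
        if not all(0.0 <= v <= 1.0 for v in vals):
            raise ValueError("risks must lie in [0, 1]")


@dataclass(frozen=True)
class ScalingModel:
    """Linear predictors of chest depth (mm) and femur area (mm^2).

    Coefficients are stand-ins with the expected signs (depth and area grow
    with BMI and stature, smaller for females); the reference values are the
    predictions at the midsize-male occupant (male, 175 cm, BMI 25.6), so
    the scale factors are exactly 1 there.
    """

    chest_intercept: float = 230.0
    chest_bmi: float = 2.2
    chest_stature: float = 0.3
    chest_female: float = -10.0
    femur_intercept: float = 600.0
    femur_bmi: float = 6.0
    femur_stature: float = 3.0
    femur_female: float = -60.0
    ref_chest_depth: float = 230.0
    ref_femur_area: float = 600.0

    def chest_depth(self, sex_code, stature_cm, bmi):
        return (self.chest_intercept + self.chest_bmi * (np.asarray(bmi) - 25.6)
                + self.chest_stature * (np.asarray(stature_cm) - 175.0)
                + self.chest_female * np.asarray(sex_code))

    def femur_area(self, sex_code, stature_cm, bmi):
        return (self.femur_intercept + self.femur_bmi * (np.asarray(bmi) - 25.6)
                + self.femur_stature * (np.asarray(stature_cm) - 175.0)
                + self.femur_female * np.asarray(sex_code))


def anthropometric_scale(s, model: ScalingModel | None = None):
    """(chest_scale, femur_scale) for occupant ``s`` — ratios of predicted
    chest depth / femur area to the midsize-male reference; both 1.0 there."""
    model = model or ScalingModel()
    sex_code, stature, bmi = s.as_numeric()
    depth = float(model.chest_depth(sex_code, stature, bmi))
    area = float(model.femur_area(sex_code, stature, bmi))
    if depth <= 0 or area <= 0:
        raise ValueError("predicted chest depth / femur area must be positive")
    return depth / model.ref_chest_depth, area / model.ref_femur_area


def head_risk(hic15):
    hic15 = np.asarray(hic15, dtype=float)
    safe = np.maximum(hic15, np.finfo(float).tiny)
    p = norm.cdf((np.log(safe) - HEAD_LN_MU) / HEAD_LN_SIGMA)
    return np.where(hic15 > 0, p, 0.0)


def chest_risk(chest_d_mm, scale=1.0):
    d_eff = np.asarray(chest_d_mm, dtype=float) / scale
    return 1.0 / (1.0 + np.exp(CHEST_A - CHEST_B * d_eff ** CHEST_POW))


def lower_ext_risk(femur_f_kn, scale=1.0):
    f_eff = np.asarray(femur_f_kn, dtype=float) / scale
    return 1.0 / (1.0 + np.exp(FEMUR_A - FEMUR_B * f_eff))


def measure_to_risk(region: Region, measure: float, scale: float = 1.0) -> float:
    """Region injury probability for one measure value.

    ``scale`` stretches the curve abscissa (ignored for the head, whose
    risk curve is not anthropometrically scaled); risk is monotone
    increasing in the measure and decreasing in the scale.
    """
    if measure < 0:
        raise ValueError("injury measure must be non-negative")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if region == "head":
        return float(head_risk(measure))
    if region == "chest":
        return float(chest_risk(measure, scale))
    if region == "lower_ext":
        return float(lower_ext_risk(measure, scale))
    raise ValueError(f"unknown region {region!r}")


def joint_risk(p_head: float, p_chest: float, p_lower_ext: float) -> float:
    """Combined injury probability assuming region independence."""
    for p in (p_head, p_chest, p_lower_ext):
        if not 0.0 <= p <= 1.0:
            raise ValueError("region risks must lie in [0, 1]")
    return 1.0 - (1.0 - p_head) * (1.0 - p_chest) * (1.0 - p_lower_ext)


def risk_from_measures(s, y, model: ScalingModel | None = None) -> RiskVector:
    """Full risk vector for occupant ``s`` with injury measures ``y``."""
    model = model or ScalingModel()
    cs, fs = anthropometric_scale(s, model)
    ph = measure_to_risk("head", y.hic15)
    pc = measure_to_risk("chest", y.chest_d_mm, cs)
    pl = measure_to_risk("lower_ext", y.femur_f_kn, fs)
    return RiskVector(ph, pc, pl, joint_risk(ph, pc, pl))


# ---------------------------------------------------------------------------
# vectorized forms used by the optimizer and evaluation tables

def scales_batch(S_num: np.ndarray, model: ScalingModel | None = None):
    """(n,) chest and femur scale factors for covariate rows."""
    model = model or ScalingModel()
    sex, st, bmi = S_num[:, 0], S_num[:, 1], S_num[:, 2]
    cs = model.chest_depth(sex, st, bmi) / model.ref_chest_depth
    fs = model.femur_area(sex, st, bmi) / model.ref_femur_area
    if (cs <= 0).any() or (fs <= 0).any():
        raise ValueError("non-positive anthropometric scale")
    return cs, fs


def risks_batch(S_num: np.ndarray, Y: np.ndarray,
                model: ScalingModel | None = None) -> np.ndarray:
    """(n, 4) array [p_head, p_chest, p_lower_ext, p_joint]."""
    cs, fs = scales_batch(S_num, model)
    ph = head_risk(Y[:, 0])
    pc = chest_risk(Y[:, 1], cs)
    pl = lower_ext_risk(Y[:, 2], fs)
    pj = 1.0 - (1.0 - ph) * (1.0 - pc) * (1.0 - pl)
    return np.column_stack([ph, pc, pl, pj])


def joint_risk_gradient_batch(
    S_num: np.ndarray, Y: np.ndarray, model: ScalingModel | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pjoint and its gradient w.r.t. the three measures, vectorized.

    Returns (pjoint (n,), dPjoint/dY (n, 3)).  Uses the closed-form chain:
    dPjoint/dy_m = prod_{r != m} (1 - p_r) * dp_m/dy_m.
    """
    model = model or ScalingModel()
    cs, fs = scales_batch(S_num, model)
    hic = np.maximum(Y[:, 0], 1e-9)
    d_eff = np.maximum(Y[:, 1], 1e-9) / cs
    f_eff = Y[:, 2] / fs

    z = (np.log(hic) - HEAD_LN_MU) / HEAD_LN_SIGMA
    ph = norm.cdf(z)
    dph = norm.pdf(z) / (HEAD_LN_SIGMA * hic)

    pc = 1.0 / (1.0 + np.exp(CHEST_A - CHEST_B * d_eff ** CHEST_POW))
    dpc = pc * (1 - pc) * CHEST_B * CHEST_POW * d_eff ** (CHEST_POW - 1) / cs

    pl = 1.0 / (1.0 + np.exp(FEMUR_A - FEMUR_B * f_eff))
    dpl = pl * (1 - pl) * FEMUR_B / fs

    qh, qc, ql = 1 - ph, 1 - pc, 1 - pl
    pj = 1.0 - qh * qc * ql
    grad = np.column_stack([dph * qc * ql, qh * dpc * ql, qh * qc * dpl])
    return pj, grad
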