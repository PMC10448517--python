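# Methods

This note documents the models, numerical choices and limitations behind
`restraintopt`, in the package's own terms.

## Problem setting

An occupant is described by covariates **s** = (sex, stature, BMI); a
restraint configuration by seven design variables **d** inside a fixed
physical box:

| variable | meaning | range |
|---|---|---|
| `d0_ll` | load-limiter belt payout D0 (m) | 0.03 – 0.05 |
| `d1_ll` | load-limiter belt payout D1 (m) | 0.01 – 0.11 |
| `dab` | airbag cushion diameter (m) | 0.96 – 1.12 |
| `dabstrap` | airbag tether length (m) | 0.2032 – 0.3048 |
| `f_ll` | retractor belt force (N) | 1 000 – 4 000 |
| `mf` | airbag mass-flow adjustment (fraction) | −0.15 – +0.15 |
| `stiff` | knee-bolster stiffness adjustment (fraction) | −0.40 – +0.40 |

A crash at fixed severity produces three injury measures
**y** = (HIC15, chest deflection in mm, femur force in kN), which map to
region injury probabilities and to the joint risk
P_joint = 1 − (1−p_head)(1−p_chest)(1−p_femur). The target of inference is
a design policy **a**(**s**) minimizing E_s[P_joint(s, a(s))] over the
population, with the occupant density taken uniform over per-sex
5th–95th-percentile covariate boxes (constant weighting).

## Population model

Default per-sex boxes (configurable stand-ins for survey percentiles, not
fitted to any survey): male stature 163–186 cm, BMI 20.5–39.5; female
stature 150–172 cm, BMI 19.5–42.5. Sampling is uniform (or Latin-hypercube
space-filling) within the per-sex box with a 50/50 sex split, ties to
male. The midsize-male reference is (male, 175 cm, BMI 25.6). Vulnerable
subgroups use strict thresholds: tall obese males (BMI > 30.5 and stature
> 181.7 cm) and short obese females (BMI > 37.3 and stature < 157 cm).
Stature and BMI are sampled independently; real stature–BMI correlation is
not modeled.

## Synthetic simulator

The real injury-generating models are proprietary multibody crash
simulations; the package ships a synthetic stand-in whose structure makes
correctness provable rather than biofidelic:

    y_m(s, d) = baseline_m(s) · (1 + Σ_l w_ml (u_l − u*_l(s))²) · ε

* `u` is the design standardized to the unit cube of the box above.
* `u*(s)`, the ground-truth optimal setting, is **linear** in standardized
  covariates (sex → ±1, stature/BMI affinely to [−1, 1] over the union
  range), clipped to [0, 1]. The default map moves `f_ll` up (+0.25 per
  standardized BMI unit) and `mf` down (−0.25) for high-BMI occupants —
  the tighter-belt/softer-airbag adaptation expected physically.
* `baseline_m(s) = b_m · exp(0.030·ΔBMI + 0.012·Δstature [+ 0.08·female
  for chest])` with b = (600, 30 mm, 4 kN) at the midsize male, so a
  (+10 BMI, +10 cm) occupant has ≈ 52% higher baselines. Magnitudes are
  stand-ins chosen once for plausibility.
* Bowl weights w (3 × 7, non-negative) give each measure curvature in a
  subset of variables; every variable is active in at least one measure.
* ε is multiplicative lognormal noise, relative sd 2% by default
  (median-preserving), keeping measures positive.

Because the bowls share the same minimizer, the noiseless response is
minimized over **d** exactly at `u*(s)`; the globally optimal adaptive
policy is linear and known in closed form, and the excess risk of any
constant design is strictly positive. Two presets ("sedan", "suv") differ
in baselines and bowl weights to mirror two vehicle compartments
structurally, not numerically. What passing tests show is therefore that
the *method* recovers a recoverable truth — not that the stand-in predicts
real crash responses.

## Design of experiments

Campaign inputs come from a MaxPro Latin hypercube over the 10 columns
(sex carried as a continuous column, binarized at 0.5 during scaling;
stature/BMI scaled per the assigned sex). The criterion
ψ(D) = [(1/C(n,2)) Σ_{i<j} Π_l (x_il − x_jl)^{−2}]^{1/p} is minimized by
simulated-annealing coordinate exchange: swaps of two entries within one
column (preserving the LHS), geometric cooling (T₀ = 0.1, ratio 0.999),
10 000 proposals by default, incremental O(n) criterion updates, best
design retained — so the final ψ never exceeds the initial. Coincident
coordinates report ψ = ∞ rather than raising.

## Surrogate

One GP per measure over the standardized 10-dimensional input: constant
mean (via target normalization), anisotropic squared-exponential kernel,
white-noise term, diagonal jitter 1e−6, hyperparameters by maximum
marginal likelihood with 3 starts (scikit-learn backend). HIC15 is fitted
on the log scale; the upper confidence bound exp(μ + z σ) back-transforms
it, using that a one-sided bound commutes with a monotone map. "95% upper
confidence bound" is read as one-sided, z = 1.645 (configurable level).
Cross-validation reports per-measure R² of out-of-fold posterior-mean
predictions on the natural measure scale.

The campaign used for policy optimization keeps the simulator's 2%
observation noise. This matters numerically: on a noiseless campaign the
GP near-interpolates, and the posterior-sd field of the UCB objective
becomes a rugged "bed of nails" whose gradient swamps the smooth
mean-gradient signal and stalls first-order optimization. A fitted noise
floor keeps σ(x) smooth and the UCB gradient well aligned with the true
risk gradient. Cross-validation quality is still assessed on a noiseless
replicate, where R² per measure exceeds 0.999 at n = 300.

## Policy representation and optimization

Features per order j are φ_j(s̃) = [s̃₁^{j−1}, s̃₂^{j−1}, s̃₃^{j−1}] on
covariates standardized to [−1, 1]; because sex is ±1, its even powers
duplicate the constant feature and odd powers the linear one, so only the
first sex power is kept (identifiability). Default order count m = 2 — a
linear policy; m is configurable 1–4. The raw output is squashed into the
design box by a scaled logistic with midpoint at the box center (gradients
exist everywhere; outputs clamped 1e−9 from the faces so saturated
coefficients still map strictly inside the box at float precision); hard
clipping and identity squashes are available for testing.

The Monte-Carlo objective averages P_joint over a 512-point space-filling
covariate sample by default (uniform weights). Gradients are analytic
end-to-end: risk-curve derivatives × measure-gradient (closed-form for the
simulator; kernel-derivative algebra for the GP mean and sd) × logistic
squash × feature matrix. Optimization is Adam (β₁ = 0.9, β₂ = 0.999),
learning rate 0.001 for policies, 5 random multi-starts by default, best
iterate retained; non-finite objectives restart the seed from a smaller
perturbation. Constant designs reuse the same machinery restricted to the
intercept feature (learning rate 0.01 — a 7-parameter search on a cheaper
objective). `optimize_all` chains warm starts — midsize constant →
population constant → adaptive policy — so the nested-class ordering
J(adaptive) ≤ J(population constant) ≤ J(midsize constant) holds by
construction, not luck. The reduced sizes used in tests and the acceptance
script (300-run campaigns, 256-point optimization samples, 600–2 500 Adam
steps, 2 restarts, 2 048-point evaluation samples) were chosen as the
smallest at which the recovered policies are stable across seeds.

## Injury-risk model

Standard frontal-impact AIS3+ curve forms with fixed coefficients:
head Φ((ln HIC − 7.45231)/0.73998) (not anthropometrically scaled);
chest 1/(1 + exp(10.5456 − 1.568·D^0.4612)), D in mm;
femur 1/(1 + exp(5.795 − 0.5196·F)), F in kN. Chest and femur measures
are divided by occupant scale factors before curve evaluation —
equivalent to stretching the curve abscissa. Scale factors are ratios of
predicted chest depth / femur cross-sectional area to their midsize-male
references, from linear stand-in regressions on (sex, stature, BMI) with
positive BMI/stature coefficients and female offsets; both equal 1 at the
reference occupant by construction. P_joint combines regions under
independence; whether the original joint risk used exactly this
combination is not documented, and population averages cannot
disambiguate it, so independence is adopted as the default reading.

## Evaluation

Risk tables report, per solution, population means of the three region
risks and P_joint over a 2 048-point space-filling evaluation sample
(seeded separately from the optimization sample), plus P_joint at the
midsize-male reference. Relative reductions are 100·(base − new)/base,
computed from full-precision means and reported to 2 decimals. The
sensitivity analysis re-optimizes, for each design variable, a policy in
which only that variable's coefficients are free (the others pinned to the
population-constant design via gradient masking), warm-started at that
constant; its reduction against the constant isolates the variable's
adaptive benefit and is bounded above by the full-policy reduction.

## Known limitations

* The simulator encodes only the qualitative trends the method needs
  (monotone baselines, occupant-dependent optima, smoothness); absolute
  risk levels and published table entries are not reproduced, since they
  derive from proprietary vehicle models.
* Independent per-measure GPs; no cross-measure covariance, no
  heteroscedastic noise, no sparse approximations (campaigns here are
  ≤ a few thousand runs).
* A logistic-squashed linear policy cannot exactly represent a linear map
  in design units; over the default map's range the residual is ≪ 0.05
  standardized units, but steeper ground-truth maps would saturate.
* One crash severity, driver position only; no neck or submarining
  injuries; no seat/posture geometry.
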