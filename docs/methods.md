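# Methods

## Model

The toolkit implements the isometric, rigid-tendon specialization of
Hill-type muscle contraction dynamics. A muscle–tendon unit (MTU) of
length `l_mt` consists of a fiber pennated at angle α in series with a
tendon fixed at its slack length `l_sla_t` (rigid-tendon assumption: all
MTU length change is absorbed by the fiber). Under the constant-thickness
pennation model the fiber endpoints slide along the tendon line of action
while the perpendicular distance `h = l_opt_f · sin α_opt` stays constant,
giving

    fiber² = (l_mt − l_sla_t)² + h²           (≡ E3)
    α(l_mt) = atan2(h, l_mt − l_sla_t)
    l_norm  = √E3 / l_opt_f

and the force

    F = F_iso_max · cos α(l_mt) · (f_pe(l_norm) + a · f_ce(l_norm)) · v(·)

with activation `a ∈ [0, 1]` and the force–velocity multiplier `v` fixed
at 1 (`mts.core.VELOCITY_MULTIPLIER`, the documented hook for a velocity
term). The normalized fiber length is always computed from the geometric
(√E3) form, which stays defined where the algebraically equivalent
projection form `(l_mt − l_sla_t)/(l_opt_f cos α)` degenerates
(α → 90°); the two agree to 1e-12 relative wherever both exist (tested).
A fiber with zero pennation and `l_mt ≤ l_sla_t` has no defined length;
this raises `DegenerateFiberError` rather than clamping, and the
calibrator keeps the search feasible by construction instead of relying on
clamped evaluations.

The tendon-side quantity is parameterized by `l_opt_mt`, the MTU length at
the optimal joint position; the slack length is always its dependent
value, `l_sla_t = l_opt_mt − l_opt_f · cos α_opt`. In modeling terms the
slack length is a phase shift that selects the joint position at which the
fiber reaches optimal length, not an anatomical tendon measurement — which
is exactly why force estimation is so sensitive to it.

## Characteristic curves

Curves are pluggable; any object with `active_fl`, `passive_fl` and their
analytic first derivatives can be injected. Defaults
(`mts.curves.CharacteristicCurves`):

| parameter      | default | meaning                                        |
| -------------- | ------- | ---------------------------------------------- |
| `gamma`        | 0.45    | width of the Gaussian active curve             |
| `slack_strain` | 0.0     | strain where passive force begins              |
| `strain_max`   | 0.7     | strain where passive force reaches `F_iso_max` |
| `k_passive`    | 4.0     | passive exponential shape factor               |

Active: `f_ce(l) = exp(−(l−1)²/γ)` — peak of 1 at optimal length with zero
slope. Passive: zero at or below the slack strain, then

    f_pe = (exp(k·x) − 1 − k·x − (k·x)²/2) / (exp(k) − 1 − k − k²/2),
    x = (l − 1 − slack_strain)/(strain_max − slack_strain),

anchored at the conventional defaults (onset at strain 0, maximal
isometric value at strain 0.7). The linear and quadratic Taylor terms are
subtracted so the curve is C² at the slack point. This is a deliberate
numerical choice: with the default `slack_strain = 0` the passive onset
coincides with the optimal length, where both the sensitivity analysis and
its central finite-difference oracle are evaluated; a curve that is only
C⁰ or C¹ there makes the oracle one-sided (O(h) error against a vanishing
true derivative) and the analytic/numeric agreement unverifiable at that
point. The C² onset is slightly flatter at low strain and slightly steeper
near `strain_max` than the plain exponential; all stated anchors and the
monotonicity invariant are preserved.

## Parameter derivation

Raw architecture measurements are taken at an arbitrary fixation position;
the model needs values at the fiber's optimal (maximal active force)
state. The derivation pipeline (`mts.derivation`) makes each adjustment an
explicit, logged step:

- **Fiber length**: sarcomeres act in series, so fiber length scales
  linearly with sarcomere length; `l_opt_f = l_f_raw · l_s_opt / l_s_raw`.
  Default optimal sarcomere length 2.7 µm (the value adopted by the major
  cadaveric and MRI datasets; human estimates cluster at 2.6–2.8 µm),
  configurable within [2.2, 3.2] µm. Records without a sarcomere
  measurement pass through unscaled and are logged as carrying the
  optimal-at-rest simplification.
- **Pennation**: under constant thickness `fiber·sin α` is invariant and
  fiber tracks sarcomere length, so
  `α_opt = asin(l_s_raw · sin α_raw / l_s_opt)`. An argument above 1 means
  the constant-thickness model cannot hold for the inputs and is an error.
- **PCSA**: conventional `V/l_opt_f` or projected `(V/l_opt_f)·cos α_opt`.
  Which definition belongs in the force formula is genuinely unsettled for
  strongly pennated muscles; both are exposed and neither declared
  correct. When projected PCSA is combined with sarcomere scaling, the
  *scaled* pennation angle is used by default (the legacy behavior of
  keeping the raw angle — the fixed-pennation-angle simplification — is
  available behind `legacy_fixed_pennation_pcsa` for auditing). When both
  a reported PCSA and a volume are present, the volume-based recomputation
  wins and the discrepancy is logged.
- **Force capacity**: `F_iso_max = σ · A_PCS`. Specific tension is a
  per-record column, never a global constant, so non-uniform tensions are
  expressible; `rescale_specific_tension` gives the σ consistent with a
  fiber-length rescaling (σ′ = σ · ratio), e.g. 61 → 78 N/cm² under a
  2.8/2.2 rescale.
- **Tendon**: `l_sla_t = l_opt_mt − l_opt_f·cos α_opt` from a supplied
  optimal-position MTU length; alternatively (`tendon_mode="measured"`) a
  directly measured tendon length from an optional `tendon_slack_mm`
  column, logged as the slack-at-rest simplification.

Units at file boundaries follow the datasets (mm, µm, degrees, cm³,
N/cm²); everything internal is SI (m, N, rad).

## Sensitivity analysis

Closed-form partial derivatives of F with respect to each parameter share
the intermediates `E1 = f_pe + a·f_ce`, `E2 = ∂f_pe/∂l_norm +
a·∂f_ce/∂l_norm`, `E3` above, under the convention that `l_opt_mt` is the
free tendon-side parameter (slack length re-derived). Two variants exist
for optimal fiber length: holding `F_iso_max` fixed (independent PCSA) and
propagating `F_iso_max = σV/l_opt_f` (volume-coupled PCSA). Every
expression was derived and verified symbolically and is continuously
checked against a central finite-difference oracle (default step 1e-7 ×
parameter magnitude) over a stratified grid of pennation (0–30°),
tendon-to-fiber ratio (3–10), activation (0–1) and fiber length
(0.5–1.4 optimal); the assignment of the two tendon-side/pennation
expressions follows the oracle, with the sin α_opt-prefactored form being
∂F/∂α_opt (zero at α_opt = 0 by symmetry) and the unprefactored form
∂F/∂l_opt_mt (reducing to −F_iso_max·E2/l_opt_f for unpennated fibers).

Normalized sensitivity `(∂F/∂θ)·θ/F_iso_max` measures the fractional
change of force capacity per fractional parameter change and is the scale
on which parameters are compared (sweeps, heatmaps, ranking). On every
grid configuration the peak normalized sensitivities order as tendon-side
> optimal fiber length (fixed PCSA) > pennation angle.

Parameter-variation sweeps evaluate force–length curve families on a fixed
MTU-length grid (baseline normalized fiber lengths 0.35–1.50, 200 points,
full activation) against ±10 %/±20 % force-capacity reference bands. Sweep
variations hold the baseline's geometric primitives (`F_iso_max`,
`l_opt_f`, `α_opt`, `l_sla_t`) fixed while one quantity moves; the
tendon-side variation moves `l_opt_mt` (a one-to-one shift of `l_sla_t`).
Holding `l_sla_t` — rather than `l_opt_mt` — fixed while varying the
pennation angle is what isolates the pennation effect: the alternative
silently adds a tendon-side shift, which would dominate the panel. The
gradient convention (l_opt_mt free, slack dependent) and the sweep
convention therefore differ deliberately; the former answers "what does a
calibration step do", the latter "what does this one parameter contribute".

## Calibration

`calibrate` minimizes the weighted mean squared force residual
`L = (1/n) Σ wᵢ (F(l_mtᵢ, aᵢ; θ) − F_obs,ᵢ)²` over a chosen free subset of
{F_iso_max, l_opt_f, α_opt, l_opt_mt} using scipy's L-BFGS-B (bounded
quasi-Newton with line search) with the analytic derivatives as the exact
gradient. The mean runs over observations with multiplicative weights, so
rescaling all weights rescales the loss without moving the minimizer.
Positive parameters are optimized in log space (positivity structural,
multiplicative default bounds of 3× around the start); the pennation angle
is box-bounded in radians, default [0°, 45°] — a plain box rather than a
logit transform so that α_opt = 0 remains admissible. Tendon slack length
is never free directly; `l_opt_mt` is optimized and the slack follows.
Where a line-search trial leaves the region where the force model is
defined (`l_opt_mt` below the projected fiber length), a smooth finite
penalty with an informative gradient steers the search back. The reported
result is the better of the initial point and the optimizer exit (monotone
descent contract); hitting the iteration cap yields a non-converged
result, not an exception.

Diagnostics are deliberately honest: observations spanning less than 0.1
in normalized fiber length flag a near-singular warning, and free
parameters whose normalized force gradient is flat across all observations
(e.g. active-curve parameters under passive-only data) are listed as
unidentifiable.

## Provenance audit

Nine derivation simplifications are encoded as deterministic rules over
explicit metadata (schema v1): optimal-at-rest for fiber length, pennation
and tendon (three distinct findings), uniform optimal sarcomere length,
fixed pennation angle in projected PCSA, inherited fiber length (cohort
mix in PCSA), inherited and uniform specific tension, and slack-at-rest.
Grades use closed vocabularies (uncertainty: small/considerable/large;
impact: neglectable/considerable/severe). Verbal qualifiers are quantified
with configurable thresholds echoed in every report: "large pennation" ⇔
raw angle > 20° (beyond the small-angle cosine regime), "sarcomere much
different from optimal" ⇔ |1 − l_s_opt/raw| > 10 % (the spread of
plausible optimal sarcomere lengths). A missing raw measurement makes the
audit err on the cautious side (qualifier treated as holding). The
tendon-side rules grade severe regardless of qualifier because a slack
length error shifts the entire expressed force–length curve. The
`examples/provenance/` pack ships illustrative per-lineage metadata files;
they are summaries for demonstration, not authoritative records, and the
report's scope note states that findings concern contraction-dynamics
uncertainty only, never overall simulation accuracy.

## Synthetic data

`synth_architecture` draws ground-truth parameters first — fiber length
0.04–0.12 m, pennation 0–30°, raw sarcomere 2.0–3.2 µm, volume
100–900 cm³, specific tension 25–61 N/cm², tendon-to-fiber ratio 3–10,
matching the ranges reported across lower-limb architecture datasets — and
constructs the raw records by *inverse* scaling, so the derivation
pipeline must recover the truth exactly (an end-to-end oracle).
`synth_force_observations` places observations on an even normalized-length
grid (default 0.5–1.4, n = 50) with seeded mean-zero multiplicative noise
of chosen coefficient of variation. What the generator does *not* emulate:
measurement-position mismatch between quantities, within-muscle sarcomere
heterogeneity, correlated errors across muscles, or activation-estimation
error. Passing recovery tests therefore show the estimator is correct and
well-conditioned under the model's own assumptions, not that real cadaveric
or MRI data are this benign.

## Numerical choices and limitations

- Finite-difference oracle: central, default h = 1e-7 × parameter
  magnitude; one step reduction on infeasibility, then error. Comparisons
  against it use a relative tolerance plus an absolute floor at the fd
  roundoff level (~eps·F/h), the resolution limit where the true
  derivative vanishes.
- Problem sizes: oracle grids of 4×3×3 configurations × 5 lengths,
  20-replicate recovery experiments with n = 50 observations, 200-point
  sweeps — chosen so the whole suite and the analysis scripts run in
  seconds on a single core while still exercising every stratum.
- The force–velocity term, compliant-tendon equilibrium, activation
  dynamics, muscle paths and moment arms are out of scope; calibration to
  joint moments (which needs moment arms) is likewise excluded.
- Figure-level reproduction of published sweep/heatmap plots is
  qualitative only: the original curve parameterizations are not printed,
  so only curve-independent quantities (worked examples, ranking order,
  peak-scaling identities, cosine bounds) are asserted exactly.
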