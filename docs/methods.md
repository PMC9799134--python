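# Methods

## The paradigm

`reachprime` simulates and analyzes a two-session reaching experiment on
workspace redundancy. In each session a priming phase (7 blocks × 60
reaches) presents targets 15 cm from a home position at one of three
locations (0°, ±30° from straight ahead) whose shape leaves one spatial
dimension task-irrelevant: an 8 cm **arc** centred on home permits
variability in movement *direction*, an 8 cm **radial line** permits
variability in movement *extent*. One-dimensional endpoint feedback is
shown on 25% of priming reaches (15 per block). A test phase common to
both sessions then probes single-trial visuomotor adaptation with dot
targets: 90 mini-blocks of 3–5 reaches to one location, with endpoint
cursor feedback only on the penultimate ("perturbed") reach — a rotation
of ±8.53° or ±5.71° about home (extent veridical) or a radial gain change
of ±0.15 or ±0.10 (direction veridical) — and adaptation read out as the
behavioral change on the final ("test") reach.

Coordinates: home at the origin, straight ahead = +y, bearings in degrees
from +y with clockwise positive. Rotations and gains are matched through
the orthogonal-displacement equivalence at the 15 cm target radius,
`15·tan(θ)` ↔ `15·Δg`, giving ±2.25 and ±1.50 cm for the four magnitudes;
`tan` rather than arc length is used because it reproduces those printed
displacements exactly (`atan(0.15) = 8.53°`, `atan(0.10) = 5.71°`).

### Schedule constraints

The 90 test mini-blocks are arranged as 9 cycles of 10, each cycle a
shuffled permutation of the 8 perturbations plus 2 veridical mini-blocks,
so a perturbation never repeats within a cycle. Mini-block lengths (3/4/5)
are exactly balanced against perturbation (3 per perturbation per length,
6 veridical) and, independently, target locations against length (10 per
location per length; 30 per location overall). The joint
perturbation × location design is not additionally constrained — only the
stated marginals are. Lengths are assigned before perturbation order;
both draws are seeded. A subject's mini-block order is drawn once and
reused in both sessions; priming location order is drawn per block (20
per location per block) with 15 feedback trials per block, i.e. the 25%
feedback fraction is enforced exactly per block.

## The generative agent

The agent maintains, per target location, a planned aim point expressed as
offsets from the target centre in two dimensions: direction (degrees) and
extent (cm). On every reach

```
endpoint_d = aim_d + plan_d + exec_d,        plan_d ~ N(0, σ_plan_d),
aim_d     ← (aim_d + plan_d) · (1 − λ_d),    exec_d ~ N(0, σ_exec_d),
```

i.e. planning noise is absorbed into the next aim and then corrected
toward the target by a gain λ_d. With λ = 0 the aim performs a random
walk (the planned-aim-point-correction account of endpoint drift along
redundant dimensions: the direction series is then exactly the cumulative
sum of the planning draws, and an AR(1) process with coefficient 1 − λ in
the stationary regime). During priming, λ is `lambda_redundant` (default
0.15) along the target's redundant dimension and `lambda_constrained`
(default 0.8) along the constrained one; during test, the baseline gains
(0.8) are relaxed toward `lambda_redundant` by the fraction `carryover` in
the dimension that was redundant during that session's priming, modelling
the persistence of priming effects on variability into the test phase.

On a perturbed reach with feedback error ε (cm at the nominal 15 cm
radius: `15·tan(θ)` for rotations, `15·Δg` for gains) the aim in the
perturbed dimension shifts by `−B_d·ε`, with

```
B_d = b0_d + kappa · [dimension d was redundant during this session's priming].
```

Direction-dimension learning is applied in the tangential (cm-equivalent)
coordinate — `tan(aim°)` space — so that on noiseless data the regression
of cm-scale response changes on the signed cm perturbation recovers −B_d
exactly; `kappa` is the priming-dependent learning increment whose
recovery the acceptance suite checks, switchable off for null studies.

### Parameter defaults

Noise defaults were derived analytically from the endpoint-variability
levels the paradigm is designed to produce, via the stationary variance of
the aim process, `var(endpoint) = (1 + w)σ_plan² + σ_exec²` with
`w = (1−λ)²/(1−(1−λ)²)`, and `IQR = 1.349·SD` for Gaussian endpoints:

| parameter | default | role |
|---|---|---|
| σ_plan_dir, σ_exec_dir | 1.6°, 1.6° | direction planning/execution noise |
| σ_plan_ext, σ_exec_ext | 0.7, 0.62 cm | extent planning/execution noise |
| λ_redundant / λ_constrained | 0.15 / 0.8 | priming-phase aim-correction gains |
| λ_dir, λ_ext (test) | 0.8 | baseline test-phase gains |
| carryover | 0.65 | priming after-effect on test-phase gains |
| b0_dir, b0_ext | 0.2 | baseline single-trial learning rates |
| kappa | 0.15 | priming-dependent learning increment |
| location scale (plan, dir) | 1.25 / 0.92 / 0.92 | workspace anisotropy (−30/0/+30°) |
| location scale (plan, ext) | 0.85 / 1.06 / 1.06 | idem, extent |
| RT | 483.8 ms, −23 ms on test trials, SD 40 | response-time generator |

With λ_redundant = 0.15 these give priming-phase direction IQRs of ≈4.7°
(arc) vs ≈3.1° (line) and extent IQRs of ≈2.0 cm (line) vs ≈1.2–1.35 cm
(arc); `carryover = 0.65` solves the same stationary-variance equation for
the smaller test-phase contrast (≈3.7° vs ≈3.2°, ≈1.45 vs ≈1.28 cm). The
left (−30°) location gets elevated direction planning noise and reduced
extent noise, emulating the workspace anisotropy of planning noise.

Cohort simulation adds between-subject heterogeneity: independent
lognormal factors (SD 0.2) on each dimension's noise, Gaussian jitter
(SD 0.08) on the learning rates, and a lognormal "exploration propensity"
(SD 0.25) that scales planning noise and `kappa` together — the latter
induces the positive interindividual coupling between priming effects on
variability and on learning. At these values the coupling is weak
relative to single-target coefficient noise, so the induced correlations
are small and positive on average rather than reliably significant.

Trajectories are minimum-jerk paths from home to the endpoint sampled at
200 Hz, with 0.002 cm positional jitter on moving samples and a 60 ms
stationary tail. Durations are drawn via a nominal speed of U(22, 36)
cm/s (≈420–680 ms for a 15 cm reach); because the offset rule trims the
slow head and tail of the bell-shaped speed profile, measured mean speeds
run ~25–30% above nominal, so slow-artifact reaches use U(10, 15) cm/s to
stay safely under the 20 cm/s error-sound threshold. Curved artifacts add
a lateral half-sine detour of 2.5–3.5 cm (zero at both ends); gross
outliers displace the endpoint 10.5–14 cm from the target.

### What the generator does not emulate

Within-movement feedback control is absent: paths are straight apart from
jitter, so direction at peak velocity essentially equals endpoint
direction and analyses contrasting the two movement stages are
null-distributed on simulated data. There is no reaction-time/strategy
coupling (ΔRT is independent of correction magnitude by construction), no
use-dependent or perceptual carry-over mechanism, and endpoint noise is
Gaussian within cells. Passing tests therefore validate the analysis
chain and the stated generative mechanisms, not these additional features
of real reaching data.

## Kinematics

* **Onset**: first sample farther than 0.5 cm from home. **Offset**: the
  first post-onset sample followed by at least 33.3 ms with no detectable
  coordinate change. At 200 Hz, 33.3 ms spans 6.67 inter-sample
  intervals, so the first duration meeting "at least 33.3 ms" is 7
  consecutive stationary intervals; "no detectable change" is a
  displacement below 0.01 cm (tablet-quantization scale). If no such run
  exists the last sample is used and the trial flagged.
* **Mean speed**: path length onset→offset over duration; the slow flag
  uses a strict `< 20 cm/s` comparison.
* **Direction/extent**: bearing of the endpoint about home relative to
  the target bearing (clockwise positive, wrapped to (−180°, 180°]);
  Euclidean distance from home.
* **Curvature**: maximum normal distance from the home→endpoint segment.
* **Peak-velocity direction**: speed is the magnitude of a second-order
  Savitzky-Golay first derivative (31 samples = 155 ms), evaluated only
  where the full window fits; the direction reported is the bearing of
  the stylus *position* at the in-movement speed maximum (consistent with
  the endpoint definition); the velocity-vector bearing is available as
  an option. The filter is exact on quadratic position signals.

## Exclusion

Three flags, computed independently on all trials (not sequentially) and
combined by union: slow (< 20 cm/s), curved (max deviation > 2 cm), and
outlier — within each subject × session × phase × target-location cell,
endpoints farther than 8 × IQR of the endpoint-to-median Euclidean
distances from the componentwise-median endpoint. Quantiles use linear
interpolation; cells with fewer than 4 trials skip the outlier rule with
a warning. The 2-D median is the marginal (componentwise) median, and the
8×IQR rule is applied to the scalar distances. Exclusion is masking:
downstream statistics on the masked table are identical to dropping rows.

## Variability

IQR of direction (deg) and extent (cm) per target location, averaged
(unweighted) across the three locations to remove target-specific spatial
biases, then re-expressed as **explored variability**:
`100 · IQR / 30.56°` for direction and `100 · IQR / 8 cm` for extent,
where 30.56° is the printed central angle of the arc target (equal to
`deg(8/15 rad) = 30.5577°` to two decimals; the printed value is
hard-coded so percent conversions match tabled values, and the geometric
derivation is kept as a test). 100% means the IQR spans the full
redundant extent of the priming targets. Test-phase variability drops
each mini-block's final reach, whose position reflects the correction to
the preceding feedback. Direction variability is computed both at the
endpoint and at peak velocity; angles are treated linearly (spreads are
≪ 360°, so circular statistics are unnecessary). Angular IQRs assume the
same per-target averaging at both movement stages.

## Adaptation regression

Each non-veridical mini-block whose perturbed and test reaches both
survive exclusion contributes one observation: the change (test −
perturbed) in the perturbation's dimension only — direction for
rotations, extent for gains. Veridical mini-blocks are excluded by
default (their dimension is undefined); a flag includes them as
zero-perturbation observations in both dimensions. Direction deltas are
kept in degrees for the dimension-wise models (a cm-equivalent `15·tan`
column is also provided); the combined model uses responses standardized
per subject × dimension, which makes the two dimensions' scales
comparable — the stated purpose of standardization — whereas a single
pooled z across dimensions would mix degree and cm units and leave the
direction dimension dominant.

Per subject, ordinary least squares:

* **combined** — standardized delta on signed perturbation (cm), priming
  (arc = 1, line = 0), dimension (direction = 1, extent = 0), all two-way
  interactions and the three-way interaction (8 terms);
* **dimension-wise** — native-unit delta on perturbation, priming and
  their interaction (4 terms), per dimension;
* **null / perturbation-only** — for adaptation-evidence gating: a
  subject is flagged a non-adapter if *either* ΔBIC or ΔAIC favors the
  intercept-only model.

The OLS engine is a lean numpy implementation (validated against
statsmodels' coefficients, R², AIC and BIC in the test suite) because the
Monte-Carlo recovery studies fit tens of thousands of small models.
Coefficients are tested at the group level with two-tailed one-sample t
tests against zero; the R² gate re-tests the three-way coefficient in the
subjects whose combined-model R² meets each threshold (0.05–0.2), and
per-target fits repeat the combined model per location with Bonferroni ×3.
The perturbation predictor is signed by cursor displacement (clockwise /
overshoot positive), so adaptive slopes are negative and the hypothesized
three-way effect (stronger learning along the previously redundant
dimension) appears as a negative interaction coefficient.

## Group statistics

2×2 repeated-measures ANOVA from the within-subject decomposition in
contrast form — each 1-df effect's F equals the squared paired t of its
per-subject contrast, with partial-η² = SS_effect/(SS_effect + SS_error) =
t²/(t² + df) (cross-checked against pingouin). Paired and one-sample t
tests are two-tailed with Cohen's d = mean/SD of differences and
Bonferroni correction `min(1, m·p)`; families mirror the analysis plan
(2 for the variability planned comparisons, 3 for per-target tests, 2 for
dimension-wise follow-ups, 2 for the correlation panel). Between-subject
Pearson correlations use the t transform for p values; within-subject
correlation tests Fisher-z-transform per-subject r and test the z against
zero. The response-time analysis compares per-subject mean RTs on
perturbed vs test reaches (constant RTs yield t = 0 by convention) and
correlates ΔRT with correction magnitude per subject and dimension.

## Numerical choices and degenerate inputs

Quantiles: linear interpolation throughout. Angular subtraction wraps to
(−180°, 180°]. Zero-variance difference vectors raise (except the RT
convention above). A degenerate outlier cell with IQR = 0 flags any
endpoint distinct from the median. Trials whose trajectory never leaves
the home region raise; trajectories shorter than the 31-sample window
return a flagged missing peak-velocity direction. Schedules are validated
after construction and raise on any violated marginal. The exact
noiseless learning identities hold when aim correction is complete
(λ = 1); with partial correction, residual aim decays across mini-blocks,
which leaves slope estimates unbiased but not trial-wise exact.

## Problem sizes

The default study replication uses n = 33 subjects × 2 sessions × 780
reaches. Monte-Carlo suites use endpoint-level simulation (no
trajectories): 200 cohorts of n = 33 for power of the three-way test
under `kappa > 0` and 500 cohorts under `kappa = 0` for the type-I rate;
the exclusion-rate study uses ≈11,000 trials; random-walk checks use 400
replicate 60-trial series plus a 10,000-trial series against the exact
cumulative-sum oracle. Trajectory-level end-to-end runs are exercised at
small cohort sizes (4–5 subjects) since per-reach kinematics are
identical per trial regardless of cohort size.

## Known limitations

Single-subject fits assume homoscedastic Gaussian residuals; no
mixed-effects alternative is provided (summary-statistics inference
only). The simulator's priming effects transfer to the test phase through
a single scalar (`carryover`); richer dynamics (slow drift of λ, trial
index effects) are not modelled. The per-target correlation analyses are
underpowered at realistic coupling strengths, as in the paradigm itself.
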