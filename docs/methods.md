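# Methods

## The model

`cvpop` implements a small lumped-parameter model of the human
circulation built around Guyton's equilibrium between venous return and
cardiac output. Four submodels interact through fifteen algebraic and
differential relations:

- **Autoregulation.** Tissue blood flow feeds back on peripheral
  resistance: the autoregulated resistance target is a sigmoid in
  cardiac output (floor 0, ceiling `A_auto` = 0.0453 mmHg·min/mL,
  half-max at `S_auto` = 5126 mL/min), approached first-order with rate
  `k_auto` = 0.00048 min⁻¹. Mean arterial pressure is the product
  MAP = CO · TPR, with TPR = R_auto · SNA.
- **Baroreceptor reflex.** The afferent arm senses the deficit of MAP
  below a slowly adapting reference pressure `p_adapt` (rate `k_adapt` =
  0.0007 min⁻¹, a one-day half-time). Afferent activity is a sigmoid in
  that deficit (ceiling `A_aff` = 2.067, half-max at 39.235 mmHg of
  deficit); the efferent arm maps it onto a single sympathetic
  multiplier bounded in [0.9333, 1.9374] that scales resistance, venous
  elastance, and renal excretion.
- **Renal volume control.** Urine output is exponential in MAP
  (slope constant 0.05 mmHg⁻¹) and suppressed by sympathetic tone:
  UO = intake · exp(k_uo (MAP − P_renal · SNA)). Because excretion must
  balance intake in the long run, the kidney is an infinite-gain
  controller that pins steady-state MAP to the SNA-modulated renal set
  point. Extracellular fluid volume integrates intake − UO − hemorrhage,
  and is partitioned into blood volume by a sigmoid bounded by
  `BV_max` = 7900 mL.
- **Cardiac integration.** Blood volume above the unstressed volume
  (`V0` = 3500 mL) generates mean circulatory filling pressure
  MCFP = SV · E(SNA) with elastance affine in sympathetic tone
  (E = 0.002408·SNA + 0.004543 mmHg/mL; the tabulated "compliance"
  coefficients are interpreted as elastance because 1500 mL of stressed
  volume × 0.004543 gives the observed ~6.8 mmHg, whereas the
  mL/mmHg reading yields absurd pressures). Venous return flows down the
  MCFP→RAP gradient against the resistance to venous return
  RVR = 0.0296·TPR + 0.000839, and cardiac output follows the Starling
  curve, a sigmoid in RAP saturating at `CO_max` = 15 230 mL/min.

At every instant the fast circulation satisfies CO = VR. Venous return
is bounded below by zero and **bounded above by venous collapse**: when
RAP falls to the collapse pressure `p_vc` (default −2.2 mmHg) the great
veins flatten and the venous-return curve plateaus at (MCFP − p_vc)/RVR.
This upper bound is what makes circulatory collapse possible at all —
without it, an arbitrarily negative atrial pressure could always pull
enough venous return to match demand and no virtual patient would ever
decompensate.

## Equation transcription and its constants

Every saturating response is the logistic
`low + (high − low)/(1 + exp(−m (x − S)/w))`, half-maximal at the set
point `S` with tabulated sensitivity `m`. The tabulated coefficients do
not fix the input scale `w` of each curve, so these widths are
transcription constants of this implementation, identified once from
the model's published operating point and never varied thereafter:

| constant | value | anchored by |
| --- | --- | --- |
| `w_auto` | `S_auto` (relative form) | autoregulation acting over ±tens of % of resting flow |
| `w_aff` | 90 mmHg | a baroreflex that buffers 10–40 mmHg falls, maximal effectiveness over roughly ±50 mmHg of deficit |
| `w_sna` | 0.3 | the sympathetic floor 0.9333 being attained as afferent activity vanishes |
| `w_starling` | 10 mmHg | baseline RAP ≈ −1.5 mmHg at resting output, hence MCFP ≈ 6.3 mmHg |
| `w_BV` | 9000 mL | a ~520 mL blood loss for a 750 mL extracellular deficit |
| `p_vc` | −2.2 mmHg | venous collapse at small negative RAP; a ~43% compensator fraction under the standard hemorrhage |

The renal set-point scale `P_renal` is back-solved at start-up so the
best-fit patient's steady state sits at 100 mmHg (a normotensive adult
male, the population the target density describes); with the
multiplicative SNA modulation this makes steady MAP = P_renal · SNA
exactly, independent of intake.

## Solving the model

**Instantaneous equilibrium.** Given the three slow states (ECFV,
adapted pressure, delayed resistance), the residual VR − CO changes sign
exactly once as the operating point sweeps from zero flow to `CO_max`.
Because MAP = CO · R_auto · SNA(MAP) makes CO explicit as a function of
MAP, the fixed point is found by one bracketed Brent root solve in MAP,
converged to |CO − VR|/CO ≤ 1e−8. Exhausted stressed volume (MCFP
clamped at 0) and a collapsed venous inlet (RAP at `p_vc`) are flagged
on the result. The solver is validated against a dense scan over CO
candidates that recomposes the whole peripheral chain independently.

**Slow states.** ECFV, `p_adapt` and `r_auto` are integrated with a
classical Runge-Kutta scheme under step-doubling error control (local
relative error ≤ 1e−6 per component), landing exactly on every
requested sample time and drain-schedule breakpoint so output is
deterministic bit-for-bit.

**Steady state.** At steady state the baroreceptor deficit is zero and
excretion balances intake, which closes the system algebraically: SNA
and MAP are explicit, one 1-D root solve gives CO, and the cardiac
cascade yields RAP, MCFP, stressed volume, BV and ECFV. The result is
verified against the equilibrium solver (and |intake − UO| ≤ 1e−6
mL/min); a literal 200-day integration is the fallback. Parameter sets
with no admissible steady state (e.g. requiring blood volume beyond
`BV_max`) signal rejection, which the calibration treats as likelihood
zero.

## Population calibration

The target is a Gaussian-product kernel density over steady-state
(CO, TPR), with one Silverman bandwidth per coordinate. By default it
is fitted to 1000 draws from a surrogate normotensive-male cohort
(CO log-normal, median 5126 mL/min, CV 15%; MAP normal 100 ± 8 mmHg
truncated to [70, 130]; TPR = MAP/CO); measured (CO, TPR) pairs can be
supplied instead as two-column delimited text.

A modified Metropolis walk perturbs ten calibrated parameters with
component-wise Gaussian jumps (SD = 5% of the best fit; where a
published jump SD matches such a value, the printed number is used),
solves each proposal's steady state and accepts with probability
L_new/L_old. Each of 15 chains restarts from the best fit with its own
sub-seed, runs 20 burn-in iterations and then records the current state
at each of 20 further iterations — 300 virtual patients. Eight of the
ten calibrated parameters are fixed by matching printed jump SDs to 5%
of a tabulated coefficient (`k_adapt`, `BV_max`, `m_BV`, `S_auto`,
`A_aff`, `m_sna`, `sna_max`, `S_sna`); the remaining two slots are
filled by the one-at-a-time sensitivity screen's ranking (`sna_min`,
`m_aff`). Note that parameters which do not move the steady-state
(CO, TPR) — `k_adapt` and the blood-volume partition among them —
random-walk freely under the flat likelihood; their population spread
is what produces the wide blood-loss distribution downstream.

The sensitivity screen perturbs one parameter at a time over ±5%
uniform draws, estimates d(CO)/dθ and d(TPR)/dθ by least squares,
normalises each by the pooled across-draw SD of that output, and ranks
parameters by the Euclidean magnitude of the two normalised
derivatives.

**Matching the target.** The sampled cloud is compared with the target
sample by two-sample Kolmogorov-Smirnov tests per marginal. The 20
retained states of one chain are strongly autocorrelated (the walk's
relaxation time is comparable to the chain length), so a nominal-n test
on the pooled 300 states overstates its own sample size and rejects
spuriously; the formal check therefore uses near-independent draws, one
final retained state per chain, and the pooled nominal-n p-values are
recorded in the run manifest as a diagnostic.

## Hemorrhage protocol and classification

Each patient is bled by an ECFV drain of 37.5 mL/min for 20 minutes
(750 mL) and observed for 40 minutes. ΔMAP is baseline minus MAP at the
end of the drain (the nadir over the horizon is also recorded);
decompensation is ΔMAP > 15 mmHg, strictly. Blood loss is the blood
volume decrement at the end of the drain; because the BV–ECFV partition
has slope < 1 everywhere, blood bears only part of the fluid deficit.

Classification uses maximum-margin linear SVMs (unit cost parameter)
with features standardized to zero mean and unit SD on the training
fold only; features are all ten calibrated parameters plus the baseline
equilibrium variables (CO, TPR, MAP, RAP, MCFP, BV, stressed volume,
SNA, afferent activity, UO, elastance, its reciprocal compliance, ECFV
and the SNA-to-maximal-SNA ratio). One hundred random 225/75 splits
give the accuracy distribution, with a binomial confidence interval
over the pooled held-out predictions.

The maximally effective rubric (MER) search is inductive: single-feature
classifiers are kept when they beat the majority-class (naive)
classifier on the held-out fold; each later stage extends every
retained set by one feature and keeps extensions whose held-out accuracy
improves by at least the acquisition cost (default 0.01); at most 50
candidate sets survive a stage (the search is what makes the
combinatorial problem tractable). The best set wins, ties broken by
fewer features then lexicographic order. The ensemble repeats the
search on 37 independent splits and reports feature frequencies, mean
rubric size and mean held-out accuracy.

## What the synthetic target does and does not emulate

The surrogate cohort reproduces the location and spread of resting
cardiac output and arterial pressure in healthy adult males, and the
reciprocal CO–TPR dependence that follows from a common pressure. It
does not carry any of the covariance structure a measured cohort would
(age, fitness, autonomic tone), so passing tests demonstrate that the
calibration machinery recovers a specified joint density through the
model — not that the resulting parameter distributions are those of any
real population. Statistics that are ratios of within-population
variances (for instance the blood-loss/pressure-loss correlation) are
particularly sensitive to transcription constants that printed
coefficients do not pin down.

## Numerical choices and degenerate inputs

- Fixed-point tolerance 1e−8 (relative), integrator tolerance 1e−6,
  steady-state balance 1e−6 mL/min — all tighter than any statistic
  reported.
- Sigmoid exponents are clipped at ±500 before exponentiation; the
  curves saturate exactly at their bounds in that regime.
- MCFP clamps at zero when stressed volume is exhausted; the
  equilibrium then sits on the venous-return floor and is flagged
  `collapsed`.
- Proposals with non-positive parameters, invariant violations
  (e.g. `V0 ≥ BV_max`) or no admissible steady state have likelihood 0.
- An all-equal feature column is reported as constant (r = 0, flagged)
  rather than NaN; a single-class training fold is redrawn, and a
  single-class population is a hard error.
- Seed hierarchy: the master seed spawns per-stage `SeedSequence`
  children (target draw, chains, analysis splits), so stages re-run
  independently and every run is reproducible byte-for-byte.

## Known limitations

- No heart rate, regional circulations, respiratory or hormonal
  systems; autoregulation is uniform across the body.
- The baroreceptor adaptation constant `k_adapt` is calibrated but has
  almost no leverage over a 40-minute protocol (its half-time is a
  day); it matters only through its population spread.
- The blood-loss/pressure-loss correlation comes out near 0.65–0.8,
  higher than the ~0.35 a measured cohort shows: with collapse gated by
  the stressed-volume reserve, the reserve's population spread (itself
  bounded by the baseline RAP envelope) is too narrow to decouple the
  two. A transcription with a wider Starling curve lowers the
  correlation but pushes mean baseline RAP below its own envelope.
- Population statistics carry noticeable seed-to-seed variance
  (compensator fraction SD ≈ 10 percentage points across master seeds)
  because 15 short chains contribute strongly correlated samples; this
  is a property of the restart protocol, not of the sample size alone.
- Problem sizes used throughout: 300 patients (15 × 20), a
  1000-draw surrogate target, 100 SVM trials, 37 rubric repeats —
  the protocol's own scale.
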