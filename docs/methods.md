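# Methods

## Model structure

The model is a cohort state-transition model over a discrete grid of
four-week cycles (13 per year, configuration `CycleGrid`), horizon 65 cycles
(five years). Health states are sub-threshold depression (SUB), major
depressive episode (MDE) and recovered (REC). Transitions per cycle:

- SUB → MDE_1 with the per-cycle incidence probability; otherwise stay SUB.
  There is no remission from sub-threshold depression, so SUB mass can only
  decrease.
- MDE_k → REC_1 with recovery probability *r*(*k*), otherwise MDE_{k+1}.
- REC_j → MDE_1 with relapse probability *s*(*j*), otherwise REC_{j+1}.

Relapse and recurrence are pooled into a single relapse process. Prior
episode history does not modify relapse risk. There is no mortality and the
cohort is closed, so occupancy sums to one at every cycle (checked to 1e-9).

**Duration dependence.** *r* and *s* depend on time already spent in state,
which is semi-Markov behaviour. It is expressed exactly by expanding MDE and
REC into tunnel states indexed by duration 1..26 (two years) plus one tail
bucket. The tail rule is configurable per curve: `hold_last` (default)
continues the final per-cycle probability indefinitely — the conservative
continuation when a curve simply stops being reported — while `zero`
switches the hazard off. A person entering MDE_1 at cycle *t* can first
recover at cycle *t*+1 with *r*(1); there are no same-cycle double
transitions. State membership is counted at cycle start and no half-cycle
correction is applied (the convention is simple, explicit, and symmetric
between scenarios, so increments are unaffected to first order).

**Intervention mechanism.** Minimal contact psychotherapy acts only by
lowering the one-year SUB→MDE probability (control arm 21/111, treated arm
14/109, i.e. an incidence rate ratio of about 0.66) and by switching the
per-cycle sub-threshold cost to the intervention-arm value, both for exactly
13 cycles. After one year both scenarios share all parameters.

**Probability transform.** One-year probabilities convert to per-cycle
probabilities under a constant hazard: p_cycle = 1 − (1 − p_year)^(1/13),
giving 1.6%/cycle (reference) and 1.1%/cycle (intervention). The transform
and its inverse are exposed and tested as an exact round trip.

## Outcomes

**DALYs.** Disability weights: 0.46 (MDE), 0.097 (SUB), recovered set equal
to sub-threshold. DALYs accrue as occupancy × weight × 1/13 year per cycle,
discounted at 1.5%/yr. With no mortality the DALY stream is entirely
years-lived-with-disability, so one undiscounted person-year in MDE is
exactly 0.46 DALYs.

**Costs.** Per-cycle state costs in euro (health-care / societal):
SUB 132/439 (reference) and 139/384 (intervention year), MDE 268/615,
REC tied to reference SUB. The societal column *includes* health care, so
each perspective reads a single column; perspectives are never summed.
Costs are discounted at 4%/yr. Discounting uses exact fractional-year
exponents (1+ρ)^(−t/13) per cycle rather than annual step functions —
smooth and order-independent. One-off cascade costs (screening €5/person
screened, diagnostic interview €119/participant, intervention €423/treated
person) fall at t=0 undiscounted.

**Cascade.** Expected counts: 7.2e6 × 0.725 (screened) × 0.266 (positive)
× 0.357 (interviewed) × 0.595 (included). Counts are kept as real expected
values; every count and one-off cost is linear in the target population,
which is why the ICER is invariant to the screened fraction (tested to 1e-9
relative). The one-off totals implied by these unit costs and fractions are
about €85 M (screening) and €125 M (intervention); these are the package's
internally consistent figures and are reported as such.

**ICER.** Ratio of mean incremental costs to mean incremental DALYs averted
(reference minus intervention, positive = health gain). Labels: "cost
saving" when mean Δcost < 0 and mean ΔDALYs > 0, "dominated" for the
opposite corner, NaN (undefined, not an exception) at exactly zero effect.

## Probabilistic sensitivity analysis

5000 runs by default. Per run, each uncertain input is drawn once,
independently (only marginal distributions are available):

| input | distribution |
|---|---|
| screening participation | beta(3826, 1452) |
| screened → interview (pooled positive × participation) | beta(364, 3463) |
| interviewed → treated | beta(217, 148) |
| one-year incidence, reference / intervention | beta(21, 90) / beta(14, 95) |
| six per-cycle costs | gamma by method of moments from mean + 95% CI |
| sub-threshold quality of life | beta(106, 11) |

Incidence is sampled on the one-year scale and transformed per draw
(transform-after-sample). The drawn cascade fractions feed both counts and
one-off costs within a draw, so each run is an internally consistent world.
The sub-threshold disability weight enters as 1 − QoL draw; the MDE weight
is fixed at 0.46 (no published distribution).

The published gamma (shape, scale) pairs for several cost rows do not
reproduce their published means under either a shape/scale or shape/rate
reading (e.g. (33, 258) vs a mean of 439), presumably because of an
unquantified price-indexing step. The package therefore rebuilds every cost
gamma from the published mean and 95% CI by method of moments
(sd = CI half-width / 1.96, assuming symmetric normal-approximation CIs,
since no CI construction method is documented), keeping the printed pairs
as provenance strings only. Means are preserved exactly by construction.

Similarly, the sub-threshold disability weight is printed as 0.097 in text
while the QoL row implies 1 − 0.906 = 0.094 (and a footnote gives utility
0.903). The pipeline resolves this by always deriving the weight from the
QoL input: the deterministic base case is defined as the PSA with every
distribution collapsed to its sampling-scale mean (beta a/(a+b), gamma
shape×scale), so a degenerate PSA reproduces the deterministic run exactly
— a property the tests assert bit-for-bit. The documented 0.097 remains the
default of the standalone `DisabilityWeights` type used for unit-level DALY
accounting.

Seeding: one master seed spawns one `SeedSequence` child per draw, so any
single draw is replayable without rerunning the rest. Draws that would
leave the parameter support are rejected and redrawn with a logged count
(impossible for beta/gamma inputs; the guard protects user-supplied specs).

Outputs: cost-effectiveness plane quadrant fractions (boundary convention:
Δcost = 0 counts as the cost-saving side, Δeffect = 0 as the no-gain side —
probability-zero events for continuous draws, fixed for reproducibility) and
acceptability curves via the net-monetary-benefit indicator
P(λ·ΔE − ΔC ≥ 0), which handles negative-effect draws correctly. The ICER
uses the ratio-of-means estimator.

## Synthetic inputs

The recovery and relapse probability curves were estimated elsewhere from
Dutch (NEMESIS) and Australian data and published only as figures. The
`synthetic` module generates stand-ins with the documented qualitative
structure: non-increasing per-cycle probabilities over a 26-cycle (two-year)
span. Defaults (explicitly synthetic, configuration rather than constants):

- recovery: 0.25 · exp(−0.10 (k−1)) — median episode length ≈ 3–4 cycles,
  consistent with short median depressive episodes;
- relapse: 0.04 · exp(−0.08 (j−1)) — low and slowly declining.

Consequences: structural properties (conservation, microsimulation
agreement, scale invariance, collapse identities, CEAC behaviour) and all
unit/cascade anchors hold regardless of the curves, but population-scale
magnitudes — total DALYs averted, total downstream costs, hence the euro
value of the ICER and the CEAC heights — depend on the curves and should be
read as illustrative, not as estimates for any real population. With the
synthetic defaults the base case averts about 3,600 discounted DALYs and is
cost-saving societally while costing about €218 M net from the health-care
perspective. Passing tests therefore demonstrate correctness of the
machinery, not calibration to real epidemiology.

The module also generates pseudo-trial binomial event counts (control arm
n=111, treated n=109, treated risk 1 − (1 − p)^RR with RR = 0.66) whose
beta(events, non-events) refit recovers the generating one-year incidence —
the parameter-recovery property the tests check by CI coverage.

## Validation oracle

`microsim_oracle` is an individual-level stochastic re-implementation of the
identical transition rules (vectorised Bernoulli draws over duration-indexed
hazards). At 200,000 individuals its occupancy agrees with the cohort
recursion within 0.01 at every cycle and state, certifying that the
tunnel-state expansion realises the intended semi-Markov process.

## Numerical and engineering choices

- All cohort arithmetic is closed-form linear algebra on occupancy vectors;
  no iterative solvers, hence no tolerances beyond float64 rounding.
  Conservation error over 65 cycles stays below 1e-12 in practice.
- The PSA is vectorised across draws (occupancy arrays of shape
  n_draws × duration buckets), so 5000 runs × 2 scenarios × 65 cycles take
  well under a second; the microsimulation oracle at 200k individuals takes
  a few seconds. Default problem sizes are the study sizes (5000 runs,
  65 cycles); tests use smaller run counts only where a property does not
  need Monte-Carlo precision.
- Parameter files are YAML with curves in sibling two-column CSVs; floats
  round-trip bit-equal (repr-based serialisation).
- Report rounding mirrors conventional presentation (€ millions, DALYs in
  thousands, ICER to two significant figures) with full precision retained
  in the machine-readable JSON.

## Known limitations

- No mortality, so cost-effectiveness is understated for an intervention
  that prevents a condition with excess mortality.
- No age structure, no time-varying background incidence, no repeat
  screening, no dependence of relapse on episode history.
- The one-year effect duration and the no-remission assumption for
  sub-threshold depression are structural assumptions, not estimates.
- Synthetic curves (above): population-scale magnitudes are illustrative.
- All PSA inputs are sampled independently; any real correlation (e.g.
  between arm-specific costs) is ignored for lack of joint information.
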