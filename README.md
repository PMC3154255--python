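# depscreen

A health-economic decision model of **opportunistic screening for
sub-threshold depression in primary care, followed by minimal contact
psychotherapy (MCP)** — a self-help manual with brief telephone support based
on Lewinsohn's *Coping with Depression* course — compared with care as usual.
It is written for health economists and epidemiological modellers who want a
tested, scriptable implementation of this class of screen-and-treat
cost-effectiveness analyses.

## The model

A closed cohort of people with sub-threshold (minor) depression is simulated
over 13 four-week cycles per year for five years through three health states:

- **SUB** — sub-threshold depression (no remission: people stay at risk),
- **MDE** — major depressive episode,
- **REC** — recovered from a major depressive episode.

Per cycle, a person in SUB develops an MDE with probability *p* = 1 − (1 −
*P*₁ᵧᵣ)^(1/13) (constant-hazard transform of the one-year risk *P*₁ᵧᵣ; 1.6%
under usual care, 1.1% under MCP, the effect lasting one year). Recovery
probability *r*(*k*) declines with episode duration *k* and relapse
probability *s*(*j*) declines with time since recovery *j*, both over a
two-year span; these duration-dependent (semi-Markov) hazards are expressed
exactly through tunnel states. There is no mortality.

Outcomes per scenario are discounted DALYs (time in state × disability
weight: 0.46 for MDE, 0.097 for SUB and REC; effects discounted at 1.5%/yr)
and discounted costs from a health-care and a societal perspective (per-cycle
state costs; costs discounted at 4%/yr), plus one-off screening and
intervention outlays at t=0 driven by the screening cascade
(7.2 M GP visitors × 72.5% screened × 26.6% positive × 35.7% interviewed ×
59.5% included; unit costs €5, €119, €423). The incremental
cost-effectiveness ratio is the ratio of mean incremental costs to mean
incremental DALYs averted. A probabilistic sensitivity analysis (5000 runs)
propagates beta/gamma parameter uncertainty into cost-effectiveness planes
and acceptability curves (net-monetary-benefit rule).

The recovery and relapse curves were published only as figures; the package
ships clearly-labelled **synthetic** exponential-decay stand-ins with the
same qualitative shape (see `docs/methods.md`), so population-scale cost and
DALY magnitudes are illustrative while all structural results and
unit/cascade anchors are exact.

## Worked example

```python
import depscreen as ds

params = ds.default_paramset()          # published inputs + synthetic curves
det = ds.deterministic_run(params)      # point-estimate base case
print(f"screen-positive: {det.counts.n_positive/1e6:.2f} M")
print(f"treated:         {det.counts.n_treated/1e6:.2f} M")
print(f"ICER (health care): EUR {det.icer_hc:.0f} per DALY")
print(f"ICER (societal):    {det.icer_soc}")
```

prints

```
screen-positive: 1.39 M
treated:         0.30 M
ICER (health care): EUR 60327 per DALY
ICER (societal):    cost saving
```

Of 7.2 million GP visitors, 1.39 million screen positive and 0.30 million
(4%) receive MCP, costing €210 M up front. From the societal perspective the
downstream savings (mostly avoided productivity losses) outweigh the
programme cost, so the intervention is cost-saving; from the health-care
perspective it buys DALYs at a positive price (the euro figure depends on the
synthetic curves). The same pipeline is available from the shell:

```sh
depscreen make-fixtures --out fixtures
depscreen validate fixtures/params.yaml
depscreen run --params fixtures/params.yaml --out results --n-runs 5000 --seed 1
```

which writes `report.csv`, `psa_samples.csv`, `quadrants.csv`, `ceac.csv`
and `summary.json`.

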