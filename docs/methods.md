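# Methods

## Evidence base and trial categorisation

The arm-level table carries, for each retained randomised arm of the seven
published adjuvant-trastuzumab analyses, the proxy-survival (DDFS or DFS),
overall-survival and symptomatic-cardiac event counts, the sample size,
follow-up and person-years. Node labels encode the treatment category
(duration × timing of administration relative to taxane × endpoint family)
and are treated as *data*, not inferred: the categorisation is expert
judgement, and the code validates its consistency (a connected outcome
network may not mix DDFS- and DFS-reporting arms) rather than re-deriving
it. Three arms are deliberately absent from the table (a vinorelbine
subgroup not recommended in the UK, a 2-year arm, and a 12-month sequential
arm without a joint-analysis counterpart); these are one-off exclusion
decisions, so no exclusion engine exists. Fractional event counts (a 0.5
cardiac event from an even split of unattributed events) are carried as
reals and never rounded.

Connected components of the node-sharing graph form the candidate evidence
networks; with the full table this yields four components of 2, 2, 3 and 4
nodes. The 4-node DDFS component (the 9-week trial and the three-arm
12-month trial) is the only one with more than one non-zero duration under
compatible randomisation, so it feeds the economic model; its two 12-month
arms are pooled into one node (their survival did not differ significantly
in the source trial), conserving events, person-years and sample sizes
exactly.

## Network meta-analysis

Rate-based contrasts: for each non-baseline arm of each trial,
`y = log((d_a/e_a)/(d_b/e_b))` with `var(y) = 1/d_a + 1/d_b` — the normal
approximation for Poisson rates, matching contrast-based multivariate
meta-analysis at these event counts. Any count below 1 receives a +0.5
continuity correction before the variance is formed (without it, `1/d` is
explosive for the half-event). Multi-arm trials contribute a
shared-baseline covariance `1/d_b`. The consistency model (contrasts as
differences of per-node basic parameters versus the zero-trastuzumab
reference) is fitted by GLS; a method-of-moments common-τ² random-effects
variant exists but the default is fixed effects, because no comparison here
has more than two trials and τ² is degenerate. Rankings are obtained by
drawing (default 100,000; 200,000 in the acceptance script) basic-parameter
vectors from the fitted multivariate normal and ranking nodes by relative
log event rate, fewest events best; SUCRA equals `(a − mean rank)/(a − 1)`.

This likelihood reproduces the published 3-node ranking table almost
exactly (e.g. DDFS prob-best for 9 weeks ≈ 96% vs 95.9% printed). The
published 4-node cardiac table is *not* reproducible from the printed
counts: the original analysis's software settings (augmentation scheme,
effects model) are unreported, and its printed ranking even inverts the
direct zero-vs-12-month cardiac evidence. The package therefore asserts
only the rank *ordering* for that network (6 months first — the
face-validity failure that motivates excluding the late-randomising trial)
and reports its honestly computed probability (~59%).

The transitivity probe refits both networks and reports, alongside the
orderings, whether the added node seizes rank 1 and how far the shared
nodes' prob-best values shift; the implausible cardiac advantage of the
6-month arm (randomised only after surviving 6 months of trastuzumab) is
the signal that its trial population is not exchangeable with the others.

## Indirect hazard-ratio comparison

The adjusted indirect comparison runs on the trial teams' *modelled* hazard
ratios, not on crude rate ratios from the arm table — published HRs adjust
for follow-up and censoring in ways aggregate counts cannot reproduce.
Standard errors are back-calculated from 95% CIs with z = 1.959964 (a 1.96
variant is accepted; sub-rounding matters when checking 2-d.p. outputs).
The packaged HR fixture uses the published per-arm DDFS/OS hazard ratios;
one subgroup OS interval is not printed in any accessible source and was
back-derived from the indirect results it must reproduce — it is flagged
`reconstructed` in the provenance manifest.

## Cost-effectiveness model

**Structure.** Years 0–5: decision tree. At time zero the strategy's
trastuzumab schedule cost and cardiac-monitoring cost are incurred and a
fraction `p_cardiac` suffers a symptomatic cardiac event (utility ×0.60 for
0.25 years [1/12–0.5], plus an event cost). Five-year trial survival splits
the cohort into distant-disease-free / metastatic / dead; metastasis onset
and death are placed at 2.5 years [0.5–4.5], decedents spending half the
pre-event period DDF and half metastatic. DDF patients attend a
breast-cancer clinic for 3 years or until metastasis. The five-year splits
are the arm-level event ratios: pooled controls 75.95/10.70/13.35%, the
9-week arm 92.59/1.85/5.56%, the pooled 12-month arms 81.43/8.93/9.63%
(matching the published 81.4/8.9/9.6 sensitivity-analysis values).

Years 5–48 (entry age 52, horizon to age 100): three-state Markov model
with quarterly cycles. DDF→metastatic at a per-cycle probability that
declines linearly from its year-5 value to exactly zero at year 20 (the
stated "gradual decrease" has no published functional form; linear is the
simplest, a step variant is configurable). Death competes: per-cycle
all-cause mortality from an age-indexed life table applies to both alive
states, and metastatic patients face an additional disease-specific
per-cycle death probability combined as `1 − (1−q_ac)(1−q_dis)` to avoid
double counting. No recovery from metastasis. Utilities are age-banded in
5-year tunnels up to year 25 and frozen thereafter, while mortality always
follows actual age — the tunnels exist only for utility/banding purposes.
Rewards (utilities, state costs) apply to occupancy at each cycle start; no
half-cycle correction, by design.

**Cycle length.** The model is quarterly by default; per-cycle
probabilities and costs are declared on a quarterly reference grid and are
rescaled (probabilities by compounding, costs linearly) if the model is run
monthly. Discounting converts the 3.5% [0–7%] annual rate by
`(1+annual)^cycle_length − 1`.

**Costs.** Only arm-differential costs enter: the trastuzumab schedule,
cardiac monitoring and events, clinic follow-up, and metastatic-state care.
Costs common to all arms (the chemotherapy backbone) are excluded, and the
config loader rejects keys that would reintroduce them. Price year is GBP
2013–14; an inflation hook exists but is identity by default.

**Reconstructed inputs.** The utilities, Markov transition probabilities
and unit costs of the original analysis live in supplementary material that
is not available here. They were re-derived as follows, and are tagged
`reconstructed` in every fixture: plausible ranges were fixed from the
clinical literature (DDF utility 0.60–0.84, metastatic utility 0.30–0.60,
metastatic survival roughly 2.5–4.5 years, annual DDF→metastatic risk of a
few percent at year 5), and within those ranges a single calibration chose
the base-case values so that the deterministic model reproduces the
published per-arm totals (costs £20,552 / £23,662 / £46,859; QALYs ≈ 8.6 /
10.0 / 9.2) and pairwise results. The calibrated values are: DDF utility
0.72, metastatic utility 0.45, age-decline factors 1.00/0.96/0.91/0.85/0.78
per 5-year band, quarterly DDF→metastatic probability 0.010 at year 5,
quarterly metastatic→dead probability 0.0636, metastatic care £4,110 per
quarter, clinic £440/year, cardiac event £3,000, cardiac monitoring £400
(9 weeks) and £800 (12 months), and trastuzumab schedule costs £9,807
(9 weeks) and £27,094 (12 months). The schedule costs are calibration
residuals, not bottom-up costings — they absorb whatever small
arm-differential costs the original supplementary table itemised — so they
should be read as "all remaining arm-specific cost", and single-parameter
interpretations of them are unsafe. This is the honest limit of
reconstruction: the *outputs* are faithfully reproduced; the decomposition
into inputs is one consistent solution, not the original one.

**Life table.** Synthetic Gompertz hazard `q(a) = min(1, 6.56e-6·e^{0.11a})`
(≈0.002 at 52, ≈0.13 at 90), standing in for a national female life table.
The model only needs a smooth increasing background hazard; absolute life
expectancy enters the calibration above, so the reconstructed utilities are
conditional on this table.

## Probabilistic sensitivity analysis

All proportions, rates and utilities get beta priors; all costs gamma
priors. Where alpha/beta exist in the source tradition (transition
probabilities; branch probabilities from trial counts, e.g.
dead ~ Beta(events, n − events)) they are supplied directly in the config;
everything else is method-of-moments from the base case and its bounds,
read as a central 95% interval (the 2×1.959964 divisor is configurable).
Bounded non-proportions (event time on [0, 5] years, cardiac duration on
[0, 1] years) use a beta prior rescaled to a declared support. The discount
rate is fixed in the PSA and explored by one-way analysis instead.
Parameters are sampled independently (no correlation structure is
published); each parameter owns a child stream spawned from the master
seed, so extending the parameter set never perturbs existing draws, and a
fixed seed makes summaries bit-identical. The default 5,000 simulations run
as one vectorised model evaluation per strategy (seconds, not minutes).

## Economics

NMB per draw, then summaries (so mean NMB obeys the linear identity
exactly). Pairwise ICERs are only quoted when the increments' signs permit;
cheaper-and-better is reported as dominance. The CEAC splits exact per-draw
NMB ties equally, making the per-WTP probabilities sum to one identically.
The CEAF is defined on *expected* NMB (not the CEAC argmax); on the £2,500
WTP grid the frontier switches from zero to 9 weeks at £2,500/QALY, the
first grid point above the 9-weeks-vs-zero ICER (~£2,300; an exact tie at a
grid point leaves the incumbent on the frontier). The budget cascade
rounds half-up at each stage (46,085 → 7,097 → 5,678), reporting unrounded
values alongside.

## Synthetic trial generator

`simulate_trial` draws exponential event times per patient at a true rate,
censors administratively at follow-up, and aggregates to events and
person-years — exactly the statistical structure the `1/d` variance
approximation assumes, which is what makes it the right recovery test for
the NMA (95% CI coverage at nominal rate over 200 replicates). It does not
emulate non-constant hazards, informative censoring, or correlated
outcomes, so passing tests demonstrate correctness of the synthesis
machinery, not robustness of the published trials' proportional-hazards
assumptions.

## Numerical choices and problem sizes

GLS solves use dense inverses (networks have ≤ 5 nodes); the SUCRA
covariance is resampled via SVD for robustness at semi-definite corners,
with a hard error if an eigenvalue is materially negative. Rank ties are
broken by stable sort order within a draw (ties have probability zero under
the continuous sampling distribution). Tests use 20,000–100,000 ranking
draws, 200–5,000 PSA simulations and 200 coverage replicates; the
acceptance script uses 200,000 ranking draws. The full suite runs in a few
seconds on one CPU.

## Known limitations

* Three disease states only: locoregional recurrence is implicitly
  assigned DDF costs and utilities (a stated limitation of the original
  structure).
* The 4-node cardiac ranking *probabilities* of the original analysis are
  unreproducible from printed data (see above); orderings are reproduced.
* Reconstructed inputs are one consistent solution to an under-determined
  inversion; distributional PSA spreads (not the means) inherit the chosen
  prior widths and are somewhat narrower for QALYs than the published
  intervals.
* No evidence for correlation between parameters; independence is assumed.
* No EVPI, no multi-year budget horizons with uptake, no subgroup analyses.
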