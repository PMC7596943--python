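# Methods

## Model

A two-arm Kaplan-Meier plot determines, at each digitized timepoint t_j, the
survival probabilities S_1(t_j), S_2(t_j).  Within each arm the life table
is generated by two recursions: the risk set n_j = n_{j-1} − (c_{j-1} +
e_{j-1}) and the inverted product-limit step e_j = n_j (1 − S(t_j)/S(t_{j-1})).
Given the starting numbers at risk N_1,0 and N_2,0, the only free quantities
are the censor counts c_ij.  Expected events are allocated under the null of
equal hazards, E_ij = (e_1j + e_2j) n_ij / (n_1j + n_2j), giving per-arm
totals O_i, E_i, the hazard ratio (O_1/E_1)/(O_2/E_2), the
observed-vs-expected chi-square Σ (O_i − E_i)²/E_i, and var ln(HR) =
1/E_1 + 1/E_2.

All counts are real-valued, never rounded: the censor vector must form a
smooth decision space for the optimiser, and nothing downstream requires
integers.

The published P value is converted to a 1-df chi-square via the inverse
survival function (0.05 ↔ 3.841, 0.95 ↔ 3.9e-3).  An exact P yields a point
anchor; "P < α" bounds the statistic below by the α-quantile; "ns" brackets
it between the 0.95- and 0.05-quantiles.  A printed chi-square statistic can
be supplied directly (`chisq:` prefix).

## Optimisation

Decision vector x: the 2m censor counts at the m post-baseline timepoints
(baseline censoring is fixed at zero for user input; the life-table
arithmetic itself accepts a baseline censor mass, which exact ground-truth
tables need when subjects leave before the first event time).  Constraints:

- equality (both arms): Σ_j c_ij + Σ_j e_ij(x) = N_i,0, scaled by N_i,0;
- inequality: n_ij(x) ≥ 0 at every step (scaled), so censoring can never
  remove more people than remain — implicit in the table construction but
  enforced explicitly so the solver is told about the boundary;
- bounds: x ≥ 0, unbounded above.

Exact mode minimises ((X²(x) − target)/max(1, target))² under those
constraints.  Non-exact modes add the chi-square bracket as inequalities and
minimise a mild smoothness regulariser (sum of squared successive censor
differences, scaled), selecting the least erratic censoring pattern among
the feasible set, which the anchor alone leaves unidentified.  The solver is
SLSQP (scipy), with numerical gradients.

Multistart: (1) uniform censoring — the cohort mass not consumed by events
under zero censoring, spread evenly over timepoints (the classical
constant-censoring assumption); (2) all of that mass at the final timepoint
(pure administrative censoring); (3+) random non-negative allocations from
a seeded generator.  The first start satisfying all constraints wins.

Defaults: constraint tolerance 1e-6 (scaled), chi-square acceptance 1e-3
(relative to max(1, target)), SLSQP ftol 1e-10, 1000 iterations, 5 starts.
All configurable via `SolverConfig` or a key = value file.

### Convergence, feasibility, and anchor-short solutions

`converged` requires feasibility (count equalities, non-negative risk sets)
*and* the chi-square anchor met.  On a coarse grid the events between
sampled timepoints aggregate, which attenuates the achievable statistic:
the published chi-square, computed from the full data, can exceed the
maximum any censoring pattern can produce on that grid.  The solver then
returns the closest feasible table, flagged `feasible=True, anchor_met=False`
— never a silent answer, never an exception.  Monte Carlo experiments
exclude only infeasible replicates from aggregates and count anchor-short
ones separately; this mirrors how an SQP solver behaves when anchored on a
full-data statistic, and is what produces the characteristic bias at very
low point counts.

Degenerate inputs: a survival value of exactly 0 is absorbing (events
consume the whole risk set; trailing zero plateaus are legal, which sampled
grids produce whenever one arm's curve ends before the other's); a zero
observed-event total in an arm yields a signalled infinite ln(HR) rather
than an error; time ties are rejected at validation, survival ties (flat
segments) are meaningful censoring-only intervals.

## Synthetic cohorts

`generate_ipd` draws exponential event times (arm 2 hazard λ, arm 1 λ·HR —
proportional hazards by construction; a Weibull shape parameter is exposed
for stress tests), independent exponential censoring, and administrative
censoring at a study horizon.  Defaults emulate a five-year oncology trial
read in months: λ = 0.05/month (median control survival ≈ 14 months),
censoring rate 0.02/month, horizon 60 months, together censoring roughly a
third of subjects.  Ground truth (per-arm KM step functions, interval censor
counts, log-rank O/E totals) is computed by direct counting on the records,
independently of the life-table reconstruction path, so the two routes
cross-validate each other; tests additionally check the KM curves against
lifelines and the O/E totals against values frozen from R's
`survival::survdiff`.

What the generator does not emulate: digitization error (points are read
exactly off the true step function), non-proportional hazards (unless the
Weibull shape is varied per arm, which the API deliberately does not
expose), covariate structure, and competing risks.  Passing tests therefore
demonstrate the reconstruction arithmetic and optimisation, not robustness
to plot-reading noise.

## Simulation experiments and problem sizes

Point subsets are drawn from the union of both arms' event times (reading
either arm's survival as the right-continuous step value at the drawn time,
exactly what a vertical line on a plot yields); the baseline and the common
final timepoint are always included, and a request beyond the available
distinct times is capped with a warning.  Sector-weighted draws split the
study window into equal-width time sectors with fixed per-sector counts.
The recommended placement emits a point whenever either arm has dropped
≥ 2% in survival since the last point; on curves whose follow-up ends with
roughly 40–50% still alive this yields the conventional 20–50 points, while
deeper follow-up (the generator's default horizon) correctly needs more
(~60), since the rule's point count scales with the curves' total descent.

Degrading an exact P to its non-exact published form uses the conventional
scale ladder 0.05, 0.01, 0.005, 0.001, …: the bound is the smallest scale
above the exact value; anything above 0.05 becomes the non-significant
bracket.

Sizes used by the test suite and acceptance script (chosen to keep a full
run at a few minutes on one CPU while leaving the conclusions stable):
recovery over 24 cohorts (HR ∈ {0.5, 1, 2} × 50/200 per arm × 4 seeds) with
2%-drop placement; dispersion trends at 5–30 points × 25 Monte Carlo
repetitions; sector weighting (30 points, schemes 10/10/10, 20/5/5, 5/20/5,
5/5/20) × 15 repetitions on an early-event cohort (λ = 0.05, horizon 150
months, light random censoring, HR 0.6 — events concentrate in the first
third of the window).  The orderings asserted by the property tests
(dispersion maximal at 5 points; non-exact dispersion ≥ exact at 30 points;
late-sector weighting least accurate) hold at those frozen conditions;
individual orderings can flip between random cohorts at these repetition
counts, which the acceptance script's reported values make visible rather
than hide.

## Known limitations

- The method needs a published P value (or statistic); without one the
  anchor does not exist.
- Non-exact anchors identify only a feasible set; accuracy degrades with
  the distance between the quoted bound and the true P value, and more
  points do not compensate.
- The censoring pattern itself is not uniquely identified (only summaries
  anchored by the constraints are); per-patient records cannot be
  reconstructed from the output.
- Strong proportional-hazards violations undermine both the anchoring
  statistic and the HR's interpretability; no PH diagnostic is implemented.
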