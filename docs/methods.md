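# Methods

## Pipeline

Each data group is processed independently through a fixed stage order:

1. **Outlier screen** (optional) — Grubbs' test per replicate set, on the
   raw observed values, before any transform. The test statistic is
   standardised and therefore invariant under the affine transforms that
   follow, so screening first changes no decision but guarantees the
   transform reference means are computed from cleaned data.
2. **Baseline subtraction** — subtract the mean of the unmasked replicates
   of a designated baseline test value.
3. **Normalisation** — divide by the mean of the unmasked replicates of a
   designated normalisation test value (computed after baseline
   subtraction).
4. **Scaling** — multiply all values by a constant (e.g. 100 for percent
   of control).
5. **Aggregation** — per test value: mean, variation, replicate count.
6. **Model fit** — 4PL or linear, by Levenberg–Marquardt on the
   aggregated means.

After the full chain the baseline test's replicate mean is 0 and the
normalisation test's mean equals the scale factor; this identity is
asserted in the tests. Configuring the same test value as both baseline
and normalisation reference is rejected: its post-baseline mean is zero
and normalisation would be degenerate.

Reference means are computed **per group**, not pooled across groups:
groups are independent datasets (different compounds, enzymes, …) that
merely share a layout, and pooling would let one group's systematic
offset contaminate another's transform.

## Replicate binding and missing data

The layout matrix assigns a numeric test value to each used well; wells
sharing a value are replicates. Matching is exact numeric equality after
parsing — labels are data, not display strings. A blank data cell at a
labelled well is a *missing* observation: allowed, excluded from all
statistics, and distinct from an *outlier-masked* value in reports.
Groups stacked in one workbook sheet are delimited by a single name cell
above each block with at least one blank row between blocks; this is the
headless substitute for colour-coded group highlighting in interactive
tools, since cell colours do not survive CSV or scripted round-trips.

## Outlier screening

Two-sided Grubbs test at α = 0.05 by default (the conventional level; the
α is a config knob). The critical value uses the standard two-sided form
with the upper α/(2n) t-quantile on n−2 degrees of freedom. Screening is
**non-iterative**: at most one value is flagged per replicate set per
run. Plate replicate sets are small (typically n = 2–4); iterating Grubbs
on such sets degenerates quickly (after removing one of three values the
test is inapplicable), and a single gross error per set is the realistic
failure mode the screen targets. An opt-in iterative mode is possible
future work. Sets with fewer than three usable values, or zero variance,
are skipped and noted in the report. Ties in the farthermost deviation go
to the earliest well in row-major order, for determinism.

The test assumes approximately normal replicate noise. Its type-I error
is controlled at ≤ α by construction of the critical value; the test
suite verifies this by null simulation (10,000 sets of n = 4).

## Aggregation and variation

Sample standard deviation (n−1 denominator); SEM = SD/√n; the 95 %
confidence half-width uses Student t with n−1 degrees of freedom rather
than 1.96·SEM, because replicate counts of 2–4 dominate plate work and
the normal approximation is badly anticonservative there. A point needs
at least two usable replicates to get a variation, at least one to get a
mean; a fully-masked point is excluded from fitting but still reported.

## Fitting

The 4PL form `bottom + (top−bottom)/(1+(x/ec50)^hill)` makes x = ec50 the
midpoint of the sigmoid, which is the quantity reported as IC50/EC50.
Internally ec50 is fitted as log ec50, keeping it positive without
constrained optimisation; the reported standard error is mapped back by
the delta method (se(ec50) = ec50·se(log ec50)). x = 0 wells (vehicle
controls) evaluate to the appropriate asymptote limit; they are included
in linear fits, and included in 4PL fits unless that test value served as
the baseline or normalisation reference (in which case its transformed
mean is pinned by construction and carries no information about the
curve).

The fit minimises the **unweighted** SSR over the replicate **means**
(not the raw replicates) — the aggregated series is the fit input, so
groups with unequal per-point replicate counts are fitted on equal
per-point footing.

Levenberg–Marquardt with analytic Jacobians: damping λ starts at 1e−3,
×10 on a rejected step, ÷10 on an accepted one; Marquardt diagonal
scaling; convergence when the relative SSR decrease or the gradient norm
falls below 1e−10, capped at 1000 iterations. A final undamped
Gauss–Newton step is taken if it does not worsen the SSR: for the linear
model this lands exactly on the closed-form least-squares solution
(verified to machine precision against `lstsq`), and near a 4PL optimum
it is a free refinement. Start values come from a shape heuristic
(asymptotes from the extreme-x responses, ec50 from the point nearest the
midpoint response, hill sign from the response direction) or from
user-supplied parameters for re-fitting. Non-finite residuals during
iteration end the fit with `converged=False` and the best parameters
found.

Goodness of fit: SSR, R² = 1 − SSR/TSS (TSS about the mean response;
negative values are reported as-is), RMSE = √(SSR/dof) when dof ≥ 1.
Parameter standard errors come from the residual-variance-scaled inverse
Gauss–Newton normal matrix when dof ≥ 1 and the matrix is well
conditioned (condition number ≤ 1e12); otherwise they are omitted.

## Synthetic data generator

`simulate_plate` fills a plate row-major with each dose repeated
n_replicates times, draws responses as model(x) + Gaussian(0, noise_sd),
and displaces a seeded fraction of wells by ±magnitude·range (range =
|top−bottom| for 4PL, |slope|·dose-span for linear) with random sign, to
exercise the two-sided screen. Defaults emulate a typical small-molecule
screen: 8 half-log doses × 4 replicates, noise 2 % of the response range,
gross outliers at 6 range-units. It deliberately omits real plate
artefacts — spatial drift, edge effects, serial-dilution pipetting error,
heteroscedastic noise — so passing tests demonstrate correctness of the
pipeline's statistics and optimisation under the model's own assumptions,
not robustness to those artefacts.

Study sizes used by the tests and the acceptance script: 10,000 null sets
for type-I control, 200 simulated plates for recovery and screening
metrics, 100 random problems for the linear/OLS comparison; these give
Monte-Carlo standard errors well below the margins being checked while
keeping a full run to a few seconds.

## Numerical and I/O choices

- Workbook export writes floats with their shortest exact decimal
  representation (`repr`) instead of the default 16-significant-digit
  formatting, so write-then-read round-trips are bit-exact; the
  tab-separated mirrors do the same and are byte-stable across reruns of
  identical inputs (the timestamped log is the only non-deterministic
  artifact).
- CSV dialect: comma separator, `.` decimal point, empty field = blank
  well, UTF-8.
- All simulation randomness flows from a single integer seed through
  `numpy.random.default_rng`; the analysis pipeline itself contains no
  randomness.

## Known limitations

- No weighted fitting, five-parameter logistic, confidence bands, or
  global shared-parameter fits across groups.
- No spatial (edge-effect) correction; any rectangular layout is accepted
  but geometry is not interpreted.
- The outlier screen handles at most one gross error per replicate set
  per run; two opposing gross errors in one small set can mask each
  other (an inherent limit of single-pass Grubbs on small n).
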