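# Methods

## Model

Recognition confidence for a similar lure is modelled as a three-component
mixture.  On each lure trial exactly one process governs the response:

| process | probability | response rule |
|---|---|---|
| false recollection | `R_f` | highest rating (K) |
| recollection rejection | `R_r` | lowest rating (1) |
| familiarity only | `1 − R_f − R_r` | Gaussian strength binned by criteria |

Familiarity strengths are Gaussian on a common axis: new items
`N(−d′/2, 1)`, lures `N(+d′/2, s²)` with `s = variance_ratio = 1` by
default.  New items are always familiarity-driven.  Acceptance at
criterion `c` is therefore

    P("old"|lure) = R_f + (1 − R_f − R_r)·Φ((d′/2 − c)/s)
    P("old"|new)  = Φ(−d′/2 − c)

and the continuous ROC, after eliminating `c`, is
`y(x) = R_f + (1 − R_f − R_r)·Φ((d′ + Φ⁻¹(x))/s)`.

Assumptions worth stating explicitly:

- **High-confidence recollection.**  All false-recollection mass lands in
  the single top rating bin and all rejection mass in the single bottom
  bin.  Graded recollection strength (recollection spilling into adjacent
  bins) is not modelled; it is the natural extension point if data show
  recollection at intermediate confidence.
- **Equal variance by default.**  The lure/new familiarity model is
  equal-variance; `variance_ratio` exists so the unequal-variance SDT
  special case can be fit (pin `r_false = r_reject = 0`, free the ratio),
  but it is pinned at 1 unless explicitly freed.
- **Homogeneous parameters.**  Group-level simulation and fitting assume a
  single parameter vector; between-subject parameter dispersion has no
  agreed form here and is not simulated.

## Data conventions

Ratings live on a K-point scale (K ≥ 3; default 6) with K = "sure old".
Reversed input scales are flipped at parse time.  Cumulation runs from the
top rating downward and drops the uninformative P(rating ≥ 1) = 1 point,
so a K-point scale yields K−1 fROC points.  Zero-count bins are legal and
receive no smoothing — the SSE objective needs none, and the likelihood
path floors predicted bin probabilities at 1e−12 before logging.  Group
analyses pool raw counts across subjects (the default), not averaged
proportions; per-subject fits warn below 60 lure or 60 new trials, the
conventional minimum for a stable individual ROC.

## Estimation

**SSE fit (primary).**  The objective is
`Σ_j (x_obs_j − x_pred_j)² + (y_obs_j − y_pred_j)²`, minimised jointly
over (R_f, R_r, d′) and all K−1 criteria — x- and y-errors enter
unweighted and symmetrically.  Internals:

- *Parameterisation.*  The simplex constraint `R_f + R_r ≤ 1` is enforced
  by `R_r = (1 − R_f)·b` with `b ∈ [0, 1]`; criterion ordering by a free
  first threshold plus positive increments.  Everything is then a box
  constraint, handled natively by SciPy's trust-region-reflective least
  squares.  Boxes (rather than sigmoid/softplus transforms) were chosen so
  boundary solutions — d′ = 0, R_f = 0 — are exactly attainable instead of
  asymptotic.  Bounds: d′ ∈ [0, 6] and first threshold in [−5, 5] (beyond
  which the normal CDF saturates and parameters are unidentifiable);
  increments in [1e−4, 10], so later thresholds may exceed 5 — only the
  anchor is clamped, keeping the box structure.
- *Multi-start.*  Default 20 starts: the first at a method-of-moments
  guess (R_f from a two-point extrapolation of the fROC to x = 0, R_r from
  the right end, d′ from the central point's z-difference, criteria from
  the new-item proportions), the rest drawn uniformly inside the bounds
  from a generator seeded by `FitConfig.seed`.  Fits are therefore
  bit-reproducible.  Ties within 1e−10 of the best objective break to the
  lexicographically smallest (R_f, R_r, d′).
- *Convergence tolerance* defaults to 1e−12 (ftol/xtol/gtol), cheap at
  this problem size and needed for the 1e−3-level round-trip accuracy the
  validation demands.

**MLE fit.**  Independent multinomials for lure and new counts with cell
probabilities from the binned model; L-BFGS-B on the same parameterisation,
same multi-start protocol; reports AIC/BIC with the free-parameter count
`3 + (K−1)` (fewer when pinned).

**Nested variants** pin parameters via `FitConfig.fixed`: `{r_reject: 0}`
(dual-process style), `{r_false: 0, r_reject: 0}` (equal-variance SDT; add
`free_variance_ratio` for UVSD), `{d_prime: 0}` (linear two-threshold
case, where the ROC is exactly `y = R_f + (1 − R_f − R_r)x`).  A pinned
fit can never achieve a lower objective than the full fit on the same
data.

**Grid oracle.**  `grid_search_sse` is a deliberately simple correctness
check on the optimiser: an exhaustive 20³ lattice over (R_f, R_r, d′) with
the criteria profiled out — each threshold touches only its own fROC
point, so a dense 1-D scan (plus a bounded scalar polish) gives the
minimal SSE at each lattice point.  The continuous fit must always match
or beat it.

**Degenerate inputs.**  All-identical observed points leave the parameters
unidentified; the fit returns its best boundary solution flagged
`converged = False`.  Observed proportions of exactly 0 or 1 are retained
as-is in the SSE path.

## Simulation

One master seed feeds fixed substreams (process draw, lure familiarity,
new familiarity, and one per recovery replicate), so enlarging a
simulation never perturbs earlier draws and regression values stay stable.
Default fixture criteria are `[−1.5, −0.75, 0, 0.75, 1.5]`: symmetric,
spanning the informative CDF range, yielding well-spread fROC points.

The **recovery harness** simulates, refits, and reports per-parameter mean
estimate, bias and RMSE; fit exceptions are counted, never dropped
silently.  The **dissociation scenarios** encode the three qualitative
signatures the model should detect, with magnitudes chosen once as
plausible for the respective manipulations:

- recollect-to-reject instructions: R_r 0.15 → 0.40, R_f and d′ fixed;
- weak → strong lure similarity: R_f 0.05 → 0.25 with d′ 0.4 → 1.2, R_r fixed;
- young → older adults: R_f 0.10 → 0.30 against R_r 0.35 → 0.10, d′ fixed.

The two conditions of a scenario share one random substream (common random
numbers) — the simulated analogue of a within-subject design — so the
fitted condition difference reflects the parameter manipulation rather
than independent sampling noise.  Scenario size is 10,000 trials per item
class per condition.

What the simulator does *not* emulate: between-subject heterogeneity,
lure-similarity gradations within a condition, old/similar/new three-way
responding, response times, and criterion drift over the test.  Passing
recovery and dissociation checks therefore shows the estimator is accurate
*under the model's own assumptions* at realistic trial counts — not that
real data satisfy those assumptions.

## Validation problem sizes

The validation suite works at sizes chosen to make Monte-Carlo error
negligible relative to the checked tolerances while staying desk-scale:
36-point noiseless parameter grid for round-trip identifiability; 10
random datasets of 1,000 trials per class for oracle dominance; 50
replicates of 5,000 + 5,000 trials for recovery bias; 10,000 trials per
class per condition for the dissociation signatures; 20,000 per class for
the group-fit demonstration.

## Known limitations

- Old-item (target) ROCs are handled only through constrained fits; true
  recollection of studied items is not part of the lure model.
- No standard errors or bootstrap intervals on parameter estimates.
- The SSE objective weights x- and y-errors equally and ignores trial
  counts; with very unequal n_lure/n_new a weighted or likelihood fit is
  preferable (use `method="mle"`).
- With K−1 points and 3 + (K−1) free quantities the fROC fit is exactly
  saturated in the x-dimension; identification of the process parameters
  comes from the y-dimension's shape.  Sparse scales (K < 5) leave the
  parameters weakly constrained, and the fit warns accordingly.
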