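# Methods

## Problem and models

High-throughput screening (HTS) programs test each chemical in each assay
at a handful of concentrations, normalize the plate signal to a response
scale, fit a small family of concentration-response models, and reduce the
winning fit to a potency (AC50), an efficacy (top asymptote) and a binary
activity call. `curveboot` implements that point-estimate pipeline and, on
top of it, a smooth nonparametric bootstrap that turns each of those point
outputs into a distribution: parameter confidence intervals, model-selection
frequencies, a hit-call probability, and — across an assay panel — a
confidence interval on an aggregate activity score.

Three mean models are fit to each series, all in the "up" direction with
the bottom asymptote pinned at zero (x is log10 concentration in µM):

- constant (`cnst`): μ(x) = 0
- Hill (`hill`): μ(x) = tp / (1 + 10^((ga − x)·gw))
- gain-loss (`gnls`): μ(x) = tp / [(1 + 10^((ga − x)·gw)) (1 + 10^((x − la)·lw))]

Errors are Student-t with 4 degrees of freedom and scale exp(er); the
heavy tails keep single wild wells from steering the fit. The log scale
`er` is a free parameter of every model, so the models carry k = 1, 4 and
6 parameters and the winner is the minimum of AIC = 2k − 2·loglik, with
exact ties broken toward fewer parameters (parsimony; ties are
measure-zero outside degenerate fixtures).

A curve is a hit (`hitc = 1`) iff the winner is nonconstant, its top
asymptote exceeds the activity cutoff, and the median replicate response
at some concentration exceeds the cutoff. Cutoffs are commonly 3, 6 or
10 × bmad.

### Constraint boxes

Fits are box-constrained, per series (never assay-wide):
0 ≤ tp ≤ 1.2·max(resp); hill ga ∈ [min(conc)−2, max(conc)+0.5];
gnls ga ∈ [min(conc)−2, max(conc)]; gw ∈ [0.3, 8];
la ∈ [min(conc)−2, max(conc)+2]; lw ∈ [0.3, 18]; la − ga > 0.25.
The asymmetric ga boxes deliberately let the AC50 fall below the tested
range (very potent chemicals can saturate at the lowest tested
concentration) while limiting extrapolation above it. The slope bounds cap
the 0/∞ maximum-likelihood degeneracies of flat and single-point-elevated
data. We read the loss-coefficient bound as lw ∈ [0.3, 18]: the
corresponding printed constraint sits between the la box and the la − ga
gap and a second, conflicting ga box would be contradictory, so it is
interpreted as the lw box.

### bmad and the 3·bmad gate

The assay noise scale is the baseline median absolute deviation: pool the
responses at each chemical's two lowest tested concentrations and take
1.4826 × median(|X_i − median(X)|). Median statistics keep the handful of
chemicals already active at baseline from inflating the estimate; the
`baseline_noise_diagnostic` (KS distance of the median-centered pool
against Normal(0, bmad), plus the ecdf table) shows where that robustness
matters — deviations concentrate in the upper tail, where potent
responders live. Series whose median response never exceeds 3·bmad are fit
to `cnst` only.

## Optimization

Each model is maximized with the Nelder-Mead simplex inside its box. The
objective returns the negative log-likelihood inside the box and a large
penalty (1e10 plus the distance to the feasible set) outside, so estimates
are free to land exactly on a boundary — boundary values (gw = 8, lw = 18,
ga at min(conc)−2) are meaningful outputs here, which rules out smooth
reparameterizations.

Because the bootstrap suites refit on the order of 10^5 resampled curves,
the simplex loop and the t(4) objective are numba-compiled
(`curveboot/_nm.py`). It is the textbook algorithm (reflection 1,
expansion 2, contraction 0.5, shrink 0.5; scipy-style 5% initial steps);
scipy's own Nelder-Mead is kept as an independent cross-check in the test
suite, and a dense factorial scan of the constraint box lower-bounds every
point fit in the acceptance tests (optimizer log-likelihood ≥ grid best −
1e-6; hill grid 20 points per dimension including an er grid at ±2 around
the fit, gnls grid 12 per dimension at the fitted er — the full 6-D box at
20 points per dimension is beyond desk scale).

Numerical choices:

- **Starting values.** tp₀ = max median (clipped to its box); ga₀ = first
  concentration whose median exceeds tp₀/2, else mid-range; gw₀ = 1.2;
  la₀ = ga₀ + 1; lw₀ = 5; er₀ = log(max(bmad, scaled MAD of resp, 1e-3)).
  One restart from ga₀ + 1 if the first run fails to converge.
- **Grid-restarted polish.** Point fits follow the simplex run with a
  coarse factorial scan of the box (hill 8³ × 5 er values; gnls 12⁵ at the
  current fitted er), re-polishing from the grid winner until the scan
  stops improving (≤ 3 rounds). The gnls surface is multimodal — the loss
  term can chase local dips — and a single local search from one start is
  not reliable there. Bootstrap refits skip the scan and instead
  warm-start from the point-estimate parameters, with the original
  starting rule as fallback; they also use a slightly looser simplex
  tolerance (xatol 1e-4 vs 1e-6), parameter error that is negligible
  against the bootstrap spread itself.
- **er guard.** er is optimized on the log scale and statistically
  unbounded, but numerically guarded to [−18.4, 30] (scale between ~1e-8
  and ~1e13): on noiseless fixtures the likelihood diverges as er → −∞ and
  the guard keeps the objective finite. Real (noisy) data never touch it.
- **Convergence.** A model whose simplex does not collapse within its
  budget (8000 evaluations for point fits, 4000 warm-started) is marked
  unconverged and excluded from winner selection; `cnst` (a 1-D search)
  always converges, so a winner always exists.
- **Flat-elevated degeneracy.** When every concentration's median exceeds
  3·bmad and the fitted ga falls below the lowest tested concentration,
  the series shows only the saturated top of its curve: the transition
  happened below the tested range and the ML slope tends to 0, which the
  box cannot represent. The reported gw is then set to 0.3 (the fit is
  otherwise left untouched and flagged `degenerate_gw`), matching the
  pipeline convention this package reproduces. Detection is from the data
  and the fitted ga rather than a gw profile-likelihood scan: with ga
  clamped at min(conc)−2 by its box, the gw profile is never numerically
  flat even when the data carry no slope information.
- **Minimum design.** Nonconstant models need ≥ 4 distinct concentrations
  (the Hill model has 4 parameters); below that only `cnst` is fit.
- **Medians.** Replicates are rows with exactly equal log10 concentration;
  no binning is applied.

## Smooth bootstrap

For one series with j(i) replicates at the i-th concentration, one
resample draws, independently at each concentration, j(i) responses with
replacement from that concentration's observed responses, then adds
i.i.d. Normal(0, bmad) noise to every drawn value (baseline
concentrations included — the algorithm draws a noise term for each
value). Concentrations are never altered. The resample is refit to all
three models, yielding a winner, parameters and a hit call; the default is
B = 1000 repetitions.

The smoothing scale matters: with no noise the procedure degenerates to
case resampling, which on single-replicate designs returns the original
curve every time (the `case_resample` variant therefore refuses
single-replicate designs), and with too much noise the uncertainty is
inflated. bmad is exactly the pipeline's estimate of baseline noise, so it
is the natural choice, and the baseline diagnostic checks it against the
data.

Summaries over the B refits:

- hit probability = (# resamples with hitc = 1)/B;
- model-selection frequencies for cnst/hill/gnls, with the hit/non-hit
  split per winner;
- winner-pooled parameter quantiles (0.025, 0.5, 0.975; linear
  interpolation between order statistics, numpy's default "type 7" rule,
  recorded in the output metadata). tp/ga/gw pool resamples won by hill
  or gnls; la/lw pool gnls winners only; cnst winners define no curve
  parameters and are excluded, and the count of contributing resamples is
  always reported so conditioning is visible. A parameter with no
  contributing resamples reports undefined quantiles, not zeros.

RNG discipline: one master seed per curve; resample b uses the child
stream `SeedSequence(seed, spawn_key=(b,))`, so runs are bit-for-bit
reproducible and enlarging B extends a run without reshuffling earlier
resamples. A resample whose refit raises falls back to a cnst-only record
and is counted, keeping B fixed and the hit probability well defined.

## Propagation to an aggregate score

A chemical screened across a panel gets per-assay bootstrap ensembles with
a common B. Sample i of the aggregate score combines sample i of every
assay — pairing by resample index, never re-randomizing across assays —
so whatever dependence the refits induce within an index is preserved. The
point score combines the point-estimate fits; the 95% CI is the 0.025 and
0.975 quantiles of the B computed scores.

The aggregator is deliberately simple and pluggable: each assay
contributes its winning-model response on a shared 50-point log10
concentration grid spanning the panel's union of tested ranges (non-hits
contribute zero; gnls winners contribute only their gain component,
evaluated as a Hill curve), assays are averaged with equal weight, the
trapezoid area under the mean curve is divided by the grid span, and the
result is scaled so a designated reference agonist's point score is 1 (no
reference → unscaled scores, flagged in the output). The full
receptor-pathway deconvolution used in the estrogen-receptor application
(agonist/antagonist/pseudoreceptor modes across 26 receptor hypotheses) is
intentionally out of scope; any aggregator consuming per-sample winner
parameters can be substituted without touching the pairing, quantile or
ranking machinery.

Decision bands on the scaled score: ≥ 0.1 positive; (0.001, 0.1)
inconclusive; otherwise negative; a CI straddling 0.1 raises
`ci_crosses_cutoff`, the flag for chemicals whose activity call is itself
uncertain. `rank_uncertainty_drivers` automates "which assay is driving
the score uncertainty": for each assay it recomputes the score samples
with that assay frozen at its point-estimate response and reports the drop
in score-sample variance, sorted, together with each assay's own hit
probability.

## Synthetic data

The generator emulates the three assay designs the method is used on —
9 concentrations × 1 replicate (ATG-like), 4 × 3 (OT-like), 15 × 3
(TOX21-like) — with evenly log-spaced concentrations. Defaults span
[−1.7, 2] log10 µM for the first two and [−3.7, 2] for TOX21-like,
honouring that the quantitative HTS panel was tested more than 100-fold
lower. Truths are null, hill or gnls means plus i.i.d. noise, either
normal (the baseline model bmad assumes) or t(4) rescaled to the same
standard deviation (heavier-tailed, for robustness checks). Everything is
reproducible from a seed.

What the generator does *not* emulate — plate effects, row/column
artifacts, cytotoxicity bursts, non-i.i.d. replicate structure — bounds
what passing tests show: they validate the estimator and its uncertainty
machinery under the method's own assumptions, not the normalization
pipeline upstream of it.

Study conditions used by the heavier test suites (the package's own
choices, fixed once): recovery/coverage uses 200 TOX21-like hill curves
with tp = 50 = 10·bmad, noise sd = bmad = 5, gw = 1.2, ga uniform on
[−2.7, 1] (inside the tested range), B = 500; null-curve calibration uses
50 null series at cutoff 6·bmad with B = 200; the oracle suite uses 60
ATG-like series (50+ passing the nonconstant gate) with mixed truths.

## Known limitations

- AIC with k = 6 is generous to gnls on short series (9-point designs
  carry 6 parameters); this mirrors the pipeline being reproduced rather
  than a recommendation.
- Percentile intervals are plain quantiles — no BCa or studentization —
  and with smoothing noise added on top of resampling they run
  conservative when the smoothing sd equals the data noise sd: resample
  residual variance is inflated by about 5/3 for triplicate designs, so
  nominal 95% intervals behave closer to 99%. Two independent 200-curve
  replicates of the coverage suite at B = 500 measured ga coverage of
  0.995 and 0.985 (pooled 0.990) at nominal 0.95.
- The hit-call rule is a hard threshold, so hit probabilities near the
  cutoff are sensitive to bmad estimation error; bmad is treated as known
  within a bootstrap run (it is not re-estimated per resample).
- Winner-pooled intervals mix hill and gnls parameter meanings where both
  win resamples; the reported per-model frequencies and contributing
  counts are there to judge that mixing.
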