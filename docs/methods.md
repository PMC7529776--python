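# Methods

## Data model

A cohort is a tidy long table of measurements — one row per (individual,
sample, protein) — plus per-individual metadata (case/control status, cancer
type, sex, baseline age). Abundances are on a log-like relative scale, as
produced by proximity-extension assay panels (NPX units). `draw_day` is an
integer day relative to the individual's reference event: negative days
precede a case's diagnosis; control draws are anchored to enrollment at day 0
(the anchoring convention for controls is a package choice — only ordering
and differences of draw days enter any computation, so the anchor is
immaterial to results). Samples within an individual are ordered by
`draw_day`, with lexicographic `sample_id` as a deterministic tie-break so
that adjacency (and hence spike calling) is reproducible. Missing abundance
cells are legal and treated as absent observations throughout; a non-empty,
non-numeric cell is dropped at read time and counted in the log.

## Robust scaling

Each protein's reference is its median and MAD computed from **all**
non-missing observations of that protein, pooling every individual and draw
(cases and controls alike). Two considerations drive the pooled reference:
an individual contributes only 3–6 draws, far too few for a stable MAD of
its own, and the outlier cutoffs are cohort-level quantities by
construction. The robust score is `(x − median)/MAD` with **no** 1.4826
consistency constant — trajectory values are reported in raw MAD units, and
applying the constant would change the meaning of every quoted "k MAD"
level. Consequently, for Gaussian data the score distribution has standard
deviation 1/0.6745 ≈ 1.483, not 1.

A protein is *degenerate* when its MAD is zero (e.g. values at an assay
floor) or it has fewer than `min_obs` observations (default 20, chosen for
percentile stability on a ~350-observation-per-protein cohort). Degenerate
proteins are flagged, logged, excluded from scoring and from every
downstream pool, and reported in the exclusion log; this is also the rule
that determines the "proteins analyzed" denominator of the resampling null.

## Cutoffs

The lower/upper outlier cutoffs are percentiles (defaults 1 and 99) of the
pooled robust-score distribution over every scored observation of every
non-degenerate protein. Pooling scores — rather than taking percentiles of
the per-protein MAD statistics — is the reading under which a *negative*
lower cutoff exists at all, and it is the one implemented. The delta cutoff
is the 99th percentile of |Δscore| over all adjacent same-individual,
same-protein observation pairs. "Adjacent" means consecutive in draw order
*among observed values*: a missing middle draw pairs its neighbours by
default, because deltas are defined on whatever was measured; a
`strict_adjacency` switch restricts pairs to consecutive schedule positions
instead. Percentiles interpolate linearly between order statistics (the
numpy default), pinned for reproducibility. All cutoff comparisons are
strict (`>` upper, `<` lower, `>` delta).

Asymmetric cutoffs (|lower| ≠ upper) are expected on real panels; on the
synthetic Gaussian cohorts they converge to ±z₀.₉₉/0.6745 ≈ ±3.45. A
`controls_only` flag refits the pools on controls alone as a sensitivity
analysis; the default pools both groups.

## Event calling

*Persistent outlier*: an (individual, protein) pair with at least `min_obs`
(default 3) longitudinal outlier observations. The three observations need
**not** be consecutive by default — persistence is read as "three
longitudinal values", and a `consecutive` switch provides the stricter
run-based reading. High and low outliers are counted together; records
mixing directions are flagged `mixed_direction` so they can be reviewed,
since biologically coherent persistence is usually one-sided.

*Spike*: an adjacent-pair |Δscore| strictly above the delta cutoff, with the
signed delta preserved (a rapid collapse is as reportable as a rapid rise).

*Configuration*: per protein, the pair (total outlier observations, distinct
contributing individuals) across the cohort — the summary whose rarity the
resampling null addresses.

## Resampling null

Each repetition samples `n_individuals_sampled` (default 3) individuals
without replacement from those with at least `n_obs_per_individual` (default
3) draws, then samples that many draws without replacement within each;
every non-degenerate protein is evaluated on the same 9 pooled observations.
The exceedance count is the number of (repetition, protein) pairs with at
least `min_outlier_obs` (default 7) outliers, and the empirical p-value is
exceedance/total with total = repetitions × proteins analyzed. A zero count
reports the conservative bound 1/total with a `zero_count` flag rather than
p = 0. Missing observations count as non-outliers. Sampling uses one seeded
numpy `default_rng`; identical inputs give identical results.

Calibration: with exchangeable scores and per-observation outlier rate *r*,
the 9-observation outlier count is exactly Binomial(9, r), because a
selection made independently of the values keeps i.i.d. observations i.i.d.
The test suite verifies the resampler against this closed form at r = 0.10
and against the ~5e-11 tail of the 7-of-9 event at the 2% rate implied by
1st/99th-percentile cutoffs.

## Schedule summaries

Per individual: draw count, earliest and latest draw day, and mean interval
(max − min)/(n − 1), displayed to one decimal. Group-level mean intervals
are computed under two conventions — pooling all consecutive intervals
across the group, and averaging per-individual means — because they differ
on unbalanced cohorts and the appropriate one depends on the question; the
report emits both, with pooling as the default.

## Synthetic cohort generator

The generator emulates the study design: `n_cases` (10) + `n_controls` (69)
individuals, `n_proteins` (1196), 3–6 draws each, consecutive intervals
uniform on 120–240 days. Case schedules place draw *j* at
−(sum of intervals *j*..end), the last sampled interval being the gap
between final draw and diagnosis, so all case days are negative; controls
run forward from enrollment day 0.

Abundance = protein baseline + individual offset + observation noise, all
Gaussian: baselines N(0, `protein_location_spread`=2), offsets per
(individual, protein) N(0, `between_subject_sd`=0.5), noise N(0,
`within_subject_sd`=1). These variance defaults are documented generator
choices on the log-like scale — plausible for panel data where within-person
longitudinal noise dominates a smaller stable personal offset — not
estimates from any dataset. Injections are specified in robust-score units:
the added abundance shift is magnitude × 0.6745·√(within² + between²), the
MAD-equivalent scale of the pooled null, so recovery tests are
threshold-aware by construction. The three archetypes are: `persistent`
(constant shift), `monotone_rise` (linear ramp 0 → magnitude inclusive),
`spike` (flat 0, one jump to magnitude on the final affected draw).
Missingness (default rate 0) is applied last and never removes an injected
observation. Determinism: one `default_rng(seed)` drives subjects,
schedules, offsets, noise and missingness in a fixed order, so identical
configs give byte-identical cohorts.

What the generator does **not** emulate: assay batch effects,
limit-of-detection censoring, heavy-tailed or skewed protein distributions,
correlated protein modules, and panel bridging. Passing recovery tests on
these cohorts therefore demonstrates the pipeline's arithmetic and
operating characteristics under a clean variance model, not its clinical
sensitivity on real plasma panels — where heavier tails push the fitted
cutoffs outward (published cutoffs from one real cohort, −3.755/4.431 with
delta 5.224, sit well outside the Gaussian ±3.45/4.84).

## Benchmark scenarios and problem sizes

`madtrack.benchmarks` packages the reference studies used by the test suite
and `scripts/acceptance.py`:

- `null_threshold_study`: 200 controls × 140 proteins (~126k pooled scores),
  enough for the fitted 99th percentile to sit within ±0.05 of the 3.45
  closed form; more individuals than the emulated study are used so each
  protein's MAD rests on ~900 observations and scale-estimation noise does
  not inflate the pooled percentile.
- `injection_recovery_study`: the study-sized 79-individual cohort at 300
  proteins with 200 persistent injections and 10 spike injections.
  Persistent injections span an individual's full draw series (the pattern
  of a marker already elevated at enrollment) at magnitude 9.5 — about twice
  the upper cutoff as fitted on the contaminated cohort, since ~0.8% of
  observations carrying injected signal themselves push the fitted 99th
  percentile from 3.45 to ≈ 4.4. Spikes jump 9.4 score-units between the
  final two draws. Full-span persistence also leaves the delta pool
  uncontaminated (a constant shift changes no within-series delta), keeping
  the spike cutoff at its null value.
- `null_resampling_study`: a signal-free cohort run through the full
  resampling (5000 repetitions); at the ~2% outlier rate of 1st/99th
  cutoffs the 7-of-9 tail is ~5e-11, so the expected exceedance count is
  effectively zero.
- `iid_score_cohort`: i.i.d. standard-normal scores with analytic
  thresholds, isolating the resampling machinery for exact binomial
  calibration.

## Numerical and degenerate-input choices

- Medians/percentiles: numpy (`median`, `percentile` with linear
  interpolation); exact-oracle tests pin the conventions.
- Empty or non-finite input to `compute_mad` is a hard error; an empty
  cohort writes header-only files; fewer than two adjacent pairs makes the
  delta cutoff a hard error rather than a guess.
- CSV round-trips are exact: abundances are parsed with correctly-rounded
  `float()` (the default pandas float parser is not exactly rounded).
- Displays: one decimal for intervals, two significant figures for
  empirical p-values; underlying values are never rounded.

## Known limitations

- Cutoffs are fitted on the same data that is then scanned for events; with
  heavy signal contamination the percentile cutoffs shift outward
  (quantified above). The `controls_only` flag mitigates but does not
  remove this.
- The empirical p-value is marginal per configuration; no multiplicity
  correction across proteins or configurations is applied.
- Persistence is count-based; it does not model time spacing between the
  outlier draws.
- Per-protein references assume exchangeability across individuals; strong
  population stratification would widen MADs and mute person-specific
  signal.
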