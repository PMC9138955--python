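# Methods

## The measurement and its summary parameters

Tensiomyography (TMG) records the radial displacement of a muscle belly
during an isometric twitch evoked by a single supramaximal electrical
stimulus.  A twitch waveform is summarised by three parameters:

* **Td** (delay time, ms): time from the stimulus to the first upward
  crossing of 10 % of the maximal displacement;
* **Tc** (contraction time, ms): time from the 10 % crossing to the first
  upward crossing of 90 % of the maximal displacement;
* **Dm** (maximal displacement, mm): the peak radial displacement.

Because the thresholds are fractions of the peak they rarely coincide with
sample points; `extract_twitch_params` locates each crossing by linear
interpolation between the two bracketing samples.  On waveforms that are
monotone over the rise this agrees with dense-grid brute-force search to
well under 0.5 % (property-tested).  Extraction is invariant to amplitude
scaling (Td, Tc unchanged, Dm scales) and equivariant to time scaling.

Numerical conventions and degenerate inputs:

* the analysis window defaults to 0–1000 ms after the stimulus and Dm is
  the global maximum inside it;
* a peak below `min_peak` (default 0.1 mm) raises a "no contraction"
  error; a waveform already above the 10 % threshold at t = 0 raises an
  extraction error (the onset cannot be located);
* no smoothing is applied by default — the device signal is smooth; a
  centred odd-width moving average is available for noisy inputs;
* the record is taken to start at the stimulus (t = 0).  Baseline
  correction subtracts the mean of the first `pre_window` ms (only the
  mean: a drift slope is deliberately not removed).  The delay period
  before the 10 % crossing serves as the quiet window.
* supramaximal selection from a stimulation ramp takes the first step
  whose Dm gain over the previous step is below 2 % (relative); if no such
  plateau occurs the last entry is returned and flagged.  The 2 %
  tolerance is a stand-in — commercial devices do not document theirs.

## Synthetic waveforms

`make_twitch_waveform` inverts the parameter definitions: it emits
y(t) = Dm·g((t − t0)/s) with the fixed unimodal template
g(u) = u^p·exp(p(1 − u)) (peak 1 at u = 1, default p = 2).  The 10 % and
90 % rise points of g are found by bisection, after which t0 and s follow
in closed form from the prescribed Td and Tc.  At zero noise, extraction
recovers prescribed targets to well within 1 % at the default 1 kHz
sampling (the residual is the linear-interpolation error, about 0.01 ms at
1 ms sampling).  Gaussian amplitude noise of configurable SD can be added.
The template has a single smooth rise and a slow decay; it does not model
the undershoot or secondary oscillations of real records, so tests passing
on synthetic waveforms do not certify extraction on pathological
multi-peaked signals.

## Synthetic cohorts

No raw per-subject data for the target population (athletes with acute
biceps femoris injury vs matched controls) are publicly available, so
`sample_cohort` draws whole bilateral cohorts.  The default design is
53 injured and 53 non-injured subjects, 22 female + 31 male in each group.
Each subject's leg pair for each parameter is drawn from a bivariate
normal truncated at zero (by rejection; with these means the acceptance
rate is ≈ 1 and the truncation bias is far below 1 %):

* non-injured subjects draw (left, right) pairs with healthy means/SDs
  (Td 22.8 ± 2.4 / 22.8 ± 2.1 ms, Tc 24.5 ± 4.7 / 24.5 ± 4.5 ms; Dm is
  sex-specific: 4.1 ± 1.3 / 4.2 ± 1.2 mm in females, 5.0 ± 2.0 /
  5.1 ± 1.9 mm in males — the one healthy sex difference that is
  consistently reported);
* injured subjects draw (injured leg, contralateral leg) pairs:
  injured leg Td 25.0 ± 3.6 ms, Tc 32.9 ± 8.5 ms, Dm 5.0 ± 1.9 mm;
  contralateral leg Td 23.1 ± 2.3 ms, Tc 24.6 ± 5.1 ms, Dm 4.9 ± 1.8 mm.
  The injured side is Bernoulli(½) by default.

**Interlimb correlation.**  Published tables report only marginal
means/SDs per leg; the interlimb correlation ρ — which controls bilateral
symmetry and therefore everything downstream (the spread of the healthy
asymmetry scores, the classifier's specificity, the AUC) — is never
reported directly.  It is, however, pinned by the reported *mean healthy
asymmetry*: for a bivariate-normal pair with equal means, |L − R| is
half-normal with E|L − R| = σ_d·√(2/π), σ_d² = σ_L² + σ_R² − 2ρσ_Lσ_R,
and the mean percentage asymmetry is ≈ 100·E|L − R|/μ.  Matching the
reported healthy asymmetries (Td 3.93 %, Tc 5.05 %, Dm 10.27 %) gives the
defaults ρ = {td: 0.884, tc: 0.944, dm: 0.942}.  A scalar or per-parameter
override is accepted; lower values (e.g. 0.8) roughly double the healthy
Tc asymmetry and visibly depress the AUC, which is why the parameter is
exposed.

The injured-group mean asymmetry is *not* matched: with the reported
marginal means (32.9 vs 24.6 ms) any bivariate-normal model implies a mean
per-subject Tc asymmetry near 29 %, whereas ≈ 22 % is reported — the mean
of per-subject ratios is not the ratio of means, and the joint
distribution that produced the reported value is unrecoverable from
marginals.  The generator therefore reproduces the healthy side (which
sets the cut-off scale) exactly and the injured side only through its
marginals.  Consequences observable in the pipeline output: the combined
Tc AUC concentrates near 0.97 (reported: 0.981) and the Youden cut-off
near 12–13 % (reported band: 9.88–14.22 %), while the injured-group mean
asymmetry overshoots.  The generator also models no time-since-injury
dynamics and no subject-level covariates (age, training load).

## The asymmetry statistic

For a bilateral pair (a, b) of one parameter,

    diff% = ( |a − b|/b + |a − b|/a ) · 100 / 2,

i.e. the average of the two one-sided absolute percentage differences.
It is symmetric in (a, b), zero iff a = b, scale-invariant, and bracketed
by the two one-sided percentages.  Injured subjects pair (injured leg,
contralateral leg); non-injured subjects pair (left, right).  Group
contrasts of the per-subject statistics use the Kruskal–Wallis test
(mid-ranks, tie-corrected; H is asymptotically χ² with df = groups − 1),
since asymmetry scores are markedly right-skewed.

## Diagnostic evaluation

Each subject contributes one score (their diff%); injured subjects are the
positives.  The threshold criterion is fixed as "score > c ⇒ positive";
no automatic direction detection is performed.

* **ROC/AUC** — empirical curve over all observed thresholds plus −∞;
  AUC in rank (Mann–Whitney) form, ties half-credit, identical to the
  trapezoidal area.  Standard errors: DeLong placement-value variance
  (default — it conditions on the observed scores) and the Hanley–McNeil
  closed form (Q1 = A/(2−A), Q2 = 2A²/(1+A)); every report tags the
  method.  The p-value tests AUC = 0.5 by a normal approximation.
* **Youden cut-off** — maximises J = sens + spec − 1; ties (within 1e-12,
  absorbing float rounding) break toward the smallest threshold, i.e. the
  most sensitive operating point.
* **Confidence intervals** — stratified (within-class) percentile
  bootstrap for AUC, J and the cut-off; stratification guarantees both
  classes in every resample.  `bootstrap_ci` defaults to B = 10,000; the
  pipeline uses B = 1,000 per block so that a full nine-block report runs
  in seconds (any block can be recomputed at higher B).
* **Independent-ROC comparison** — z = ΔAUC/√(SE₁² + SE₂²) for the
  female-vs-male contrast (independent subgroups; no paired comparison is
  implemented because the subgroups share no subjects).
* **Precision–recall** — AUPRC by the step-function (average-precision)
  rule Σ ΔR·P; trapezoidal PR interpolation is available behind a flag.
  The F1-maximising threshold is reported as the association criterion
  with its PPV and TPR.  If a weak classifier attains F1max only at the
  all-positive end, the criterion is −∞ (serialised as the string
  "-inf").
* **Association test** — the continuous score is dichotomised at the
  Youden cut-off and cross-tabulated against injury status; χ² (no
  continuity correction), V = √(χ²/n), and a Monte-Carlo p-value from
  permutations of the predictions with the (r + 1)/(B + 1) correction
  (default B = 1,000).  The dichotomisation rule is reported alongside
  the result because other constructions are possible.  Note the
  selection effect: the cut-off is estimated on the same data, so under
  the null this test rejects more often than its nominal level (≈ 14 %
  at n = 106 in simulation); it is reported as descriptive, not
  confirmatory.
* **Power** — two-sided two-sample t-test power via the noncentral t
  (df = 2n − 2, δ = d√(n/2)); at d = 0 it returns α exactly.
* **Normality** — Lilliefors-corrected Kolmogorov–Smirnov (parameters
  estimated from the data), matching common statistical-package practice.

## Calibration experiments and their sizes

The test suite checks frequentist calibration at sizes chosen to keep the
full run within minutes while leaving sampling error well inside the
asserted bands:

* bootstrap CI coverage: 200 replications of binormal scores with true
  AUC 0.8 at n = 200/200, B = 500 per replication;
* permutation-test level: 1,000 null 2×2 tables with B = 1,000
  permutations each.  Table size n = 2,000 — at small n the exact
  permutation distribution of a 2×2 statistic is coarsely discrete and
  the test is strongly conservative (at n = 106 with balanced margins the
  exact attainable level is ≈ 0.028, computable from the hypergeometric
  distribution), so near-nominal behaviour is only a meaningful check
  where the atoms near the 5 % tail are fine; at n = 2,000 the exact
  level is ≈ 0.047.

## Pipeline determinism

`run_full_analysis` spawns independent sub-seeds from the configured seed
(`numpy.random.SeedSequence`) for cohort sampling, each bootstrap block
and the permutation test, so a config + seed pair fixes every number in
the report; the JSON serialisation is canonical (sorted keys) and
byte-identical across runs.  Reports carry provenance: package version,
seed, config hash, resample counts and SE-method tags.

## Known limitations

* The synthetic cohort is a parametric emulation; passing tests show the
  pipeline recovers the structure built into the generator, not that the
  reported discrimination holds in new clinical data.
* Per-sex cut-offs are estimated independently and the combined cut-off
  is also evaluated within each sex stratum (both are reported); with 22
  female subjects per group the female-stratum CIs are wide.
* The PR dialect (step vs trapezoid) and the CI method (percentile
  bootstrap) are stated choices; other software uses other dialects, so
  small numeric differences against other tools are expected.
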