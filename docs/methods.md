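# Methods

## Model and rationale

The package treats the baseline values of a meta-analysis' primary
outcome as a natural experiment on randomization quality.  If allocation
in trial *i* is sound, the true standardized between-arm baseline
difference is δᵢ = 0 and the observed coded SMD `yᵢ` is pure sampling
noise with variance `vᵢ`.  The working model behind every diagnostic is
therefore the fixed-effect null

```
yᵢ ~ N(0, vᵢ),   i = 1..k,
```

and each stage probes a different violation:

* the pooled z-test of `b̂ = Σwᵢyᵢ/Σwᵢ` (weights `wᵢ = 1/vᵢ`) probes a
  *systematic* shift common to the trials;
* Cochran's Q / I² probe *heterogeneous* randomization quality
  (trial-specific nonzero δᵢ);
* the sign-proportion z-test probes directional imbalance that a few
  large trials could mask in the pooled estimate;
* the rank-ordered forest diagnostic probes the *shape* of the whole
  set: the k-th smallest SMD is an empirical `k/(n+1)` quantile, so
  under the null the points should track `Φ(x/√var(b̂))`, the cumulative
  normal with the pooled estimate's fixed-effect variance.  One-sided
  departures with a displaced median are the signature of selective
  non-reporting; symmetric displacement suggests a systematic
  allocation problem; CIs that fail to reach the curve indicate
  overdispersion.

Effect sizes are Hedges-type SMDs.  Direction coding (flip the sign for
higher-is-better outcomes) makes "negative = intervention arm better at
baseline" a corpus-wide convention, which is what makes the sign test
and the skew direction interpretable.

### Reporting triage

A trial contributes an effect only if its baseline summaries can be read
as describing the randomized sample: either reported for all randomized
patients, or reported for analyzed patients with overall dropout
`(N_rand − N_anal)/N_rand` strictly below `dropout_threshold`
(default 0.10).  Median/IQR-only trials are classified
`reported_median_excluded` and never converted to mean/SD — distribution
assumptions strong enough to justify the conversion are exactly what is
in doubt when baseline reporting is selective.  Precedence of the
categories is `not_reported` > `reported_median_excluded` > the dropout
rules.  A `baseline_population` of `unknown` is treated like
`randomized`; extraction sheets usually omit the flag when there was
nothing to flag, and the choice is recorded in the classifier's
output rather than silently applied.

## Parameters that matter

| parameter | default | units / scale | why |
|---|---|---|---|
| `method` | `hedges_g` | — | small-sample bias correction `J = 1 − 3/(4df−1)`; `cohens_d` selectable |
| `dropout_threshold` | 0.10 | fraction | strict `<`; the conventional cut for treating analyzed-only baselines as randomized |
| `alpha_median` | 0.10 | probability | exact binomial sign test of median(SMD)=0; screening-level alpha |
| `excess_min` | 0.30 | signed fraction | minimum one-sided excess of points beyond their guideline abscissae to call skew rather than shift |
| `coverage_min` | 0.80 | fraction | per-trial 95% CIs enclosing their guideline abscissa; below this the set is called overdispersed |
| `alpha_trend` | 0.10 | probability | significance level for the SMD-vs-SE trend |
| `n_source` | `randomized` | — | heads used in `s_pooled` and `vᵢ`; `analyzed` available for dropout-admitted trials |

The shape rule, in order: *skewed* (right/left by the sign of the
excess) when the median test rejects at `alpha_median` **and**
|excess| ≥ `excess_min`; else *shifted* when the median test rejects;
else *overdispersed* when coverage < `coverage_min`; else *aligned*.
The underlying visual criterion — median location plus one-directional
deviation from the guideline — has no canonical quantitative form, so
the three thresholds are configuration, not constants, and the
classifier returns a `criteria_trace` with every ingredient so a user
can re-derive the label.  Each trial is compared to the guideline *at
its own plotting position*: the CI of the trial at percentile `p` is
checked against `x = sd_guide·Φ⁻¹(p)`, because that is the point of the
curve it sits next to on the plot.

With a pure location shift of a few pooled-SEs the per-trial excess is
small (each trial's own SE is √k times the pooled SE), so large shifted
corpora are correctly read as *shifted*, not *skewed*; in small corpora
the two patterns genuinely blur, and the trace is the honest output.

The funnel stage defaults to a plain OLS regression of `yᵢ` on `seᵢ`
with a two-sided t-test on the slope, because a linear SMD-in-SE trend
is the pattern one-sided value-dependent non-reporting induces.  The
classical precision-form asymmetry regression (`yᵢ/seᵢ` on `1/seᵢ`,
testing the intercept) is available as `method="egger"`; its intercept
is the same quantity as the OLS slope under the null and shares its
`direction` semantics.

## Simulator

`simulate_corpus` draws, per trial: δᵢ = `true_delta` + `tau`·Zᵢ; arm
sizes from a log-uniform rule on [10, 200] by default (the spread of
arm sizes typical of trials feeding systematic reviews); sample means
from `N(μ, σ²/n)`; sample SDs from the exact scaled-χ law
`σ·√(χ²_{n−1}/(n−1))`.  Means are generated so that the *coded* SMD
targets δᵢ whatever the configured outcome orientation.  The default
configuration (`true_delta = 0, tau = 0`, full reporting, k = 20) is the
well-performed-randomization reference condition.

`apply_missingness` hides whole trials' baseline summaries while keeping
their headcounts (they stay in the corpus as `not_reported`, exercising
the reporting-rate path end to end):

* `mcar`: hide with probability `p_base`;
* `mnar_magnitude`: hide with probability
  `logistic(logit(p_base) + steepness·s·yᵢ)`, `s = ±1` selecting which
  sign is hidden — the mechanism that produces a skewed observed set
  with an SMD-vs-SE trend;
* `mnar_se`: the same logistic link on the standardized SE;
* `subversion_masking`: hide trials on the side opposite an injected
  shift with probability `p_base`, leaving the observed set displaced
  from zero — a stylization of systematic allocation failure whose
  unreported values would *not* pull the mean back to zero.

The logistic link was chosen for its single interpretable steepness
parameter; `subversion_masking` is deliberately one-sided and sharp
because its point is the direction of displacement, not a realistic
response curve.

What the simulator does **not** emulate: correlated reporting across
trials of the same review, multi-arm trials, non-normal outcomes,
rounding/transcription error in extracted summaries, and
median/IQR-style partial reporting (hidden trials lose their summaries
entirely).  Passing validation therefore shows the pipeline detects the
modelled mechanisms at the simulated scales — not that real corpora are
free of other distortions, nor that the thresholds are optimal for any
particular review.

## Validation scales and observed behaviour

The Monte-Carlo validation uses: 2000 replicates of the k = 20 null for
type-I calibration and aligned-rate; 500 replicates of k = 100 for
recovery of `true_delta = −0.2`; 300 replicates per point of the tau
grid {0, 0.1, 0.2, 0.3} at k = 30; 500 replicates of the strong
selective-reporting scenario (k = 60, `p_base = 0.5`, `steepness = 10`,
hide-negative) against a k = 60 null; 300 replicates of subversion
masking (k = 40, shift −0.2, hide-positive at 0.8).  These sizes give
Monte-Carlo SEs of about one percentage point on the reported rates.

The pooled z-test runs slightly conservative (empirical type-I ≈ 0.044
at nominal 0.05) because the large-sample variance formula overstates
`vᵢ` for arms as small as 10; this is a property of the standard
formula, not of the pooling.

## Numerical choices

* Critical value 1.96 (normal) everywhere a 95% interval appears; the
  pooled test uses z, not t.
* Exact SMD zeros count on neither side of the sign test and are drawn
  as open squares in the forest plot.
* Rank ties are broken by ascending SE, then trial id, the more precise
  trial taking the higher plotting position; percentiles are exactly
  `k/(n+1)` and strictly inside (0, 1).
* `I²` is clipped at 0, reported as 0 (with a log note) for k = 1, and
  mapped to a single band by the non-overlapping cuts [0,30), [30,50),
  [50,75), [75,100] — the conventional overlapping ranges are also
  reported as a membership list.
* Degenerate trend fits (zero residual variance) report p = 0 for a
  nonzero slope and p = 1 for a zero slope; a corpus with identical SEs
  refuses the OLS trend rather than fabricating one.
* Dropout rates are computed as integer-difference ratios so that a
  corpus with exactly 10% dropout compares against the threshold
  without float drift.
* Both arms' SDs zero is a degenerate-scale error; fewer than 3 effects
  yields an `aligned` label flagged low-information rather than a
  classification.

## Known limitations

* Two arms per trial; multi-arm trials must be collapsed upstream.
* No imputation of SDs from CIs/SEs/p-values and no median/IQR
  conversion — such trials are counted, logged, and excluded.
* The shape classifier operationalizes a visual judgement; its
  thresholds are screening conventions, and the label should be read
  together with its `criteria_trace`.
* Detection, not correction: the package flags patterns consistent with
  selective non-reporting or subverted allocation but does not adjust
  pooled estimates for them.
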