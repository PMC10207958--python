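# Methods

## The task and the data model

One session of the modelled experiment is a 2-AFC orientation
discrimination: a Gabor tilted θ ∈ {−18°, −15°, …, 0°, …, +15°, +18°} (13
levels, 32 repeats, 416 trials, uniformly randomized order), a left/right
choice, then a 1–4 confidence rating. The trial table (one row per trial,
CSV) is the interchange format for every stage; `correct` is undefined at
θ = 0°, where neither response is veridical.

## Generative observer (synthetic_data)

The synthetic observer is an equal-variance Gaussian SDT observer with two
history mechanisms layered on top:

* **Type-1.** dv = k·θ + ε, ε ~ N(0, σ²); response "right" iff dv ≥ c_t,
  with the effective criterion c_t = c0 − w_resp·r_{t−1}, r ∈ {−1, +1}.
  Positive w_resp attracts the criterion toward the previous response and
  so produces choice repetition. With probability `lapse_rate` the response
  is replaced by a fair coin flip (a stimulus-independent lapse, matching
  the fixed-lapse PF interpretation).
* **Type-2.** The rating compares |dv + ε₂ − c_t| (ε₂ ~ N(0, conf_noise²),
  type-2 noise only) against three criterion distances per response side,
  shifted by −w_conf·(conf_{t−1} − 2.5), floored at 0 and re-sorted.
  Positive w_conf makes high confidence easier after high confidence.

Defaults: k = 0.09 deg⁻¹ (d′ ≈ 0.5 at 3° rising to ≈ 3.2 at 18°, a
realistic psychophysical range), σ = 1 (the model's unit), c0 = 0,
criterion distances (0.5, 1.0, 1.8) (uses all four ratings with a broad
middle), lapse 0.02 (matching the PF's fixed lapse), conf_noise 0.5
(meta-d′ visibly below d′, i.e. imperfect metacognition), history weights 0
(a null observer unless a bias is injected). Conventions fixed for
determinism: ties dv = c_t go to "right"; the previous rating is centered
at 2.5 (the scale midpoint) so a null observer's marginal rating
distribution is unaffected; trial 1 uses c0 and unshifted criteria.

What the generator does *not* emulate: evidence-accumulation dynamics and
RT distributions (the emitted RT is a monotone inversion of predicted
confidence plus noise, for qualitative checks only), slow criterion drifts,
inter-trial stimulus dependencies, and session/block structure. Passing
tests therefore certify the estimators against a memoryless-criterion +
one-trial-history world, not against every mechanism that could produce
serial dependence in real data.

The ideal-confidence variant derives ratings deterministically from the
same dv as the choice (no lapses, no type-2 noise): by construction its
fitted meta-d′ equals d′ up to sampling error, which anchors the meta-d′
machinery.

## Psychometric functions (psychometric)

P(right | x) = γ + (1 − γ − λ)·logistic(slope·(x − threshold)), λ = γ =
0.02 fixed. The two free parameters are named by their verbal definitions —
threshold = 50% point in degrees, slope = logistic steepness in deg⁻¹ —
which resolves a symbol ambiguity in the usual display of the equation
(where the threshold/slope letters can read as swapped in the exponent).
Fitting maximizes the binomial log-likelihood on per-level counts with
L-BFGS-B from a 7 × 5 start grid (thresholds −18…18, slopes 0.05…3),
bounds threshold ∈ [−40, 40], slope ∈ (10⁻⁴, 10]; the `converged` flag is
false for single-response-type data or bound-stuck solutions. 0° trials are
included (they carry response information). History conditioning at lag L
uses the response exactly L trials back, ignoring intervening responses,
and drops the first L trials. Exclusion: a participant is removed if the
overall threshold *or* slope is more than 3 MADs from the group median;
when the MAD is exactly 0, any value off the median is flagged.

## Two-stage confidence regression (confidence_regression)

Stage 1 regresses the *per-|orientation| mean* confidence on |orientation|
within each previous-rating bin and keeps the intercept (a per-trial mode is
available behind a flag; means match the descriptive "mean confidence per
orientation" framing and weight each orientation equally). Stage-1
regressions are unweighted despite unequal bin sizes. A bin with a single
distinct |orientation| contributes its mean confidence, flagged as
degraded; absent rating bins are skipped, and fewer than two usable bins is
an error. Stage 2 regresses the intercepts on the previous rating; that
slope is the bias statistic (positive = repetition). Group inference is a
one-sample t test of the slopes against zero; the default lag range is
1–25.

## Mutual information (mutual_information)

Plug-in MI in bits over observed discrete values, with 0·log 0 ≡ 0.
Orientation is collapsed to 7 bins ({−18,−15} {−12,−9} {−6,−3} {0} {3,6}
{9,12} {15,18}); confidence cardinality is the number of rating values the
participant actually used (3 or 4), which enters the Miller–Madow term
(|X|−1)(|Y|−1)/(2N ln 2). The corrected MI is *not* clipped at zero —
inference runs through the permutation null, not the sign. History
quantities pair elements 1…T−lag with lag+1…T and never cross participant
boundaries.

Permutation inference shuffles the present series (1000 shuffles by
default), applies the identical correction inside the null loop (the bias
term depends only on marginals and cancels), and uses the add-one p-value
(1 + #{null ≥ obs})/(1 + n_perm). The significance threshold is the null's
95th percentile computed as an order statistic (`numpy` method "higher"):
under exchangeability this makes the false-positive rate exactly
⌊0.05·(n_perm+1)⌋/(n_perm+1) ≤ 0.05, whereas interpolated percentiles
inflate it measurably. The calibration test in the suite measures ≈ 4.9% at
n_perm = 200.

## Population prevalence (prevalence)

γ̂ = clip((k/n − α)/(1 − α), 0, 1): the MLE of the fraction of the
population carrying a within-participant-detectable effect, assuming the
test has false-positive rate α and power ≈ 1 for carriers. The 95% CI is a
percentile bootstrap over the binary indicator vector (default 10,000
resamples), clipping each replicate before taking quantiles. Because the
bootstrap distribution is discrete (the resampled k* is binomial), the
interval uses inverse-empirical-CDF quantiles ("lower" for the lower bound,
"higher" for the upper) — the classical empirical-quantile definition,
which avoids interpolating between binomial atoms. BCa was not needed:
simple resampling reproduces the reference intervals. Note one inherent
instability: when a binomial CDF value falls almost exactly on the 0.025
cutoff, the lower bound can alternate between adjacent atoms across
bootstrap seeds; this is a property of the estimand, not of the
implementation.

## Meta-d′ (metad)

Counts are tabulated per absolute-orientation level (3°–18°; 0° is
rejected) into the standard 2 × 2K response-conditional layout and padded
with 1/(2K) per cell — the usual remedy for empty cells at 32–64
trials/level/bin — before both fits. Type-1: d′ = z(HR) − z(FAR),
c = −½[z(HR) + z(FAR)]. Type-2: maximum likelihood over meta-d′ and the
2(K−1) type-2 criteria of the response-conditional rating multinomials,
with the *relative* type-1 criterion c′ = c/d′ held at its observed value
(so the meta-level criterion sits at c′·meta-d′ — the convention matters
for meta-c placement and is used consistently in the reported |meta-c − c|
distances, which are averaged over the K−1 criteria per response side).
Criteria are parameterized as positive increments from the type-1
criterion, guaranteeing order; optimization is multi-start L-BFGS-B
(meta-d′ ∈ [−5, 5]). Estimation is maximum likelihood rather than Bayesian
single-subject fitting: same model, different estimator, validated by
generate-and-refit recovery; a Bayesian backend could be slotted behind the
same interface. Degenerate single-rating data are flagged unidentifiable.
Binned analyses (previous response / previous confidence / repetition, all
at lag 1) drop any bin × level with fewer than 10 trials in either stimulus
class. The high/low confidence split is chosen per participant across *all*
trials — the cut ∈ {1, 2, 3} minimizing the post-low/post-high trial-count
difference, ties toward the larger low bin — before any per-level analysis.

## Normative confidence model (sdt_model)

Confidence is the probability-correct read-out f(|dv − c|),
f(x) = ½[1 + erf(x/(σ√2))], applied to dv ~ N(+d′/2, σ²) (one stimulus
class suffices by symmetry; c = 0 by default). Default evidence levels
d′ ∈ {0.1, 1.58, 3.17} (none/weak/strong); σ = 1 internally, with any
display-axis scaling treated as cosmetic. The default simulation size is
10⁵ trials per level — cell means are stable to ~10⁻² at that size, and the
scale-robustness test confirms agreement with smaller runs; larger n_sim is
a config field, not a different code path. The high/low confidence split
for the accuracy curves is a pooled-median split of predicted confidence
across levels. The RT proxy is 1 − confidence, exactly mirroring the
confidence curves.

## Pipeline and group statistics (pipeline)

Stage order: MAD exclusion → PF history bias (lags 1–3) → confidence
regression (lags 1–25) → MI suite + prevalence (perceptual = I(Resp₋₁;
Resp), metacognitive = I(Conf₋₁; Conf)) → binned meta-d′ (three binners ×
six levels) → group tests. Lag constructions never cross participants. All
stage randomness derives from one config seed, so reruns are
byte-identical. Group tests are frequentist only: paired t tests and 2 × J
fully-within-subject ANOVAs (statsmodels `AnovaRM`; validated in the tests
against a textbook sums-of-squares partition). Follow-up per-level t tests
are reported uncorrected, matching the descriptive convention of the
analyses the pipeline mirrors. Degenerate ANOVAs (zero error variance)
are flagged rather than reported. The 2×6 ANOVAs use only participants with
complete bin × level grids; incomplete rows stay in the per-participant
table with a `dropped` flag.

## Known limitations

* The generative history parameterization is one reasonable choice; real
  mechanisms (drift-rate bias, slow criterion drift) are not distinguished.
* Prevalence assumes within-participant power ≈ 1; it is a lower-bound-style
  estimate of "detectable with this design", not of the latent trait rate.
* meta-d′ at very low d′ is noisy (c′ = c/d′ amplifies criterion noise);
  per-level fits at 32 trials/class rely on the 1/(2K) padding.
* No hierarchical/group-level meta-d′, unequal-variance SDT, ordinal
  mixed-effects confidence models, or Bayes factors.
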