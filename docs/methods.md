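# Methods

## The problem

When two people interact — here a mother and her school-age child
playing a cooperative labyrinth game — their autonomic nervous systems
can covary in time ("physiological synchrony"). `dyadsync` implements a
complete analysis pipeline for this question from R-peak event times:
per-second interbeat-interval (IBI) series, second-by-second
respiratory sinus arrhythmia (RSA), pre-whitened lagged
cross-correlation between partners, shuffled-pair surrogate nulls,
lagged affect regression-out, and cohort-level inference. Because no
public dataset accompanies this protocol, the package ships a
synthetic coupled-dyad generator with full ground truth; every
downstream claim in the test suite is checked against what the
generator injected.

## Signal extraction

**IBI epoch means.** The IBI series is a step function of time
(constant between consecutive R-peaks). It is sampled at 10 Hz on a
fixed grid shared by both partners — a sample at time *t* takes the
value of the interval *containing* *t*, with intervals right-closed
`(t_i, t_{i+1}]` — and the 10 samples of each 1-s epoch are averaged.
Epochs are half-open `[j, j+1)` s from recording start; an epoch
containing any invalid sample (before the first peak, after the last,
or in a masked span) is invalid as a whole. The shared grid is what
makes integer-second lags meaningful across partners.

**Second-by-second RSA.** The irregular IBI sequence is interpolated
at 4 Hz with a natural cubic spline. Each interval is anchored at its
*starting* peak, where the instantaneous heart period it realises is
in effect; anchoring at the ending peak would delay the series by one
beat (irrelevant to band power, but it misaligns the series against a
known generator). A 32-s window (128 samples) slides in 1-s steps
(31-s overlap). Each windowed segment is demeaned, multiplied by a
bank of K = 3 orthonormal Slepian (DPSS) tapers with time–bandwidth
product 2.5, Fourier transformed, and the squared magnitudes averaged
over tapers; one-sided power is summed over the bins inside the
respiration band, 0.12–0.40 Hz (used for adult and child alike). The
per-second RSA value is the natural log of that band power (plus an
ε = 1e−12 ms² guard against a perfectly metronomic degenerate input).

Taper count: the conventional bound admits K ≤ 2·NW − 1 = 4 tapers,
but the last admissible Slepian taper is poorly concentrated; with
K = 4 a 0.05 Hz line leaks ≈ 5.5 % of its reference in-band power into
the respiration band, with K = 3 only ≈ 0.9 %. The default is
therefore K = 2·NW − 2 = 3; both K and NW are configurable and echoed
into output metadata.

Window placement: a 32-s window cannot be centred exactly on an
integer second; the two feasible integer starts are off-centre by
±0.5 s. The estimate for second *s* uses start `min(s − 15, n − 32)` —
the later (more centred) start, falling back to the last feasible
window at the recording tail. Seconds within 15 s of either edge get
no estimate, so a 300-s recording yields exactly 270 valid per-second
values.

## The synchrony statistic

Within-person autocorrelation inflates cross-correlations between
independent smooth series, so each partner's per-second series is
pre-whitened before correlating:

1. order-2 polynomial detrend (removes linear/quadratic task drift);
2. ARIMA(1,1,1) fitted by maximum likelihood without constant
   (the series is already detrended and differenced, so an intercept
   is not identifiable); the one-step-ahead innovations are the
   whitened series. One sample is lost to differencing. On
   non-convergence the fallback is Yule–Walker AR(1) on first
   differences, flagged in the report; a series constant after
   differencing returns all-zero residuals flagged degenerate.

Synchrony is the Pearson correlation of the two innovation series at
integer lags k ∈ [−3, +3] s,

    r(k) = corr( mother[t], child[t+k] ),

so positive k means the mother's signal precedes the child's and
negative k means the child leads. Each lag is computed on its own
overlap with per-lag re-centering (no padding); swapping partners maps
r(k) → r(−k), which the tests assert. Only the largest contiguous
common valid span of the two partners enters the pipeline; unequal
spans are truncated to the shorter length from each span's start.

The test suite demonstrates why pre-whitening matters: on independent
AR(1) pairs with coefficient 0.95, the raw lag-0 correlation exceeds
its nominal 5 % false-positive rate several-fold while the whitened
correlation stays at nominal.

## Surrogates and affect cleaning

**Shuffled pairs.** For each dyad and condition, the child is paired
with every other dyad's mother and the mother with every other dyad's
child; the per-lag correlations of all pairings are averaged
(arithmetic mean of r; a Fisher-z option exists but is off by default,
matching the plain averaging of synchrony values). The set is
exhaustive — no sampling, hence no seed — and never includes the own
partner. Residual series are pre-whitened once per participant and
reused across pairings.

**Affect regression-out.** Positive affect is a binary per-second
series (an annotation interval marks a second iff it covers ≥ 0.5 s of
it). Cleaning regresses a participant's raw per-second ANS series on
21 lagged copies of an affect series (shifts −10…+10 s, all jointly,
plus intercept; out-of-range shifts zero-padded, since absence of
affect is a meaningful value of a binary predictor and padding
preserves series length). The residuals re-enter the unchanged
pipeline. The *individual* variant uses the participant's own affect
only (a config switch adds the partner's series as joint predictors);
the *shared* variant uses the dyad's AND-series for both partners.
The shuffled-affect control substitutes, exhaustively, each other
same-role participant's affect series and averages the cleaned
profiles. Least-squares projection makes cleaning idempotent and
variance non-increasing, both asserted in tests.

## Cohort statistics

* Dependent-sample t-tests (actual vs surrogate, cleaned vs uncleaned,
  mirrored lags r(−k) vs r(+k)), two-sided, with listwise deletion.
  The paired effect size defaults to d_z = mean(diff)/sd(diff); d_av
  (mean difference over the average of the two SDs) is available by
  config, and the choice is recorded in output.
* Linear mixed models of synchrony at one lag on condition with a
  per-dyad random intercept, fitted by REML (statsmodels MixedLM).
  The omnibus F uses Satterthwaite denominator degrees of freedom:
  the restricted likelihood of the random-intercept model is evaluated
  in closed form, the variance-parameter covariance taken as the
  inverse observed information (finite differences), and per-contrast
  df pooled over the eigencontrasts of the hypothesis. On balanced
  two-condition data the F equals the paired t² with df = n − 1
  exactly, which the suite asserts, and the type-I error of the F test
  is calibrated by simulation (≤ 7 % at α = 0.05 over replicate null
  cohorts). Marginal R² follows the fixed/(fixed + random + residual)
  variance decomposition. Pairwise condition contrasts use the same
  machinery with FDR across the six comparisons.
* FDR correction is Benjamini–Hochberg step-up, organised in families:
  across lags per condition and measure for the t-tests, across lags
  per measure for the mixed models, across contrasts per model.
* Across-dyad association: pairwise-complete Pearson correlations
  between lag-0 synchrony values and affect time fractions.

## The synthetic cohort generator

Per dyad and condition the generator produces mother and child R-peak
series and affect series from an instantaneous heart-period function

    m(t) = mean_rr
         + g · L(t − d_role)
         + A · (1 + γ_a · affect(t)) · sin(2π f_r t + φ)
         + β_a · affect(t)
         + ε(t),

with: a shared latent Ornstein–Uhlenbeck process L (unit variance,
timescale 10 s, exact 1-Hz discretisation, linearly interpolated),
whose role-specific delay d places the lead on the configured partner
(negative coupling lag = child leads); a respiration-band oscillation
with per-participant random phase φ and ±0.02 Hz frequency jitter
around the role's nominal rate (adult 0.25, child 0.30 Hz); binary
affect from a stationary two-state Markov chain at 1 Hz
(P(on) = affect rate, mean episode length = mean bout); and white
noise at 1 Hz, linearly interpolated. Beats follow the forward
recursion t_{i+1} = t_i + m(t_i)/1000 from t = 0 — exact and
sufficient at these modulation depths — and stop at the recording
duration. Coupling and affect imitation are active only in the
interactive conditions (La1, La2); Rest and Single are uncoupled and
carry no coded affect. Every stream derives from one seed via
SeedSequence spawn keys, so cohorts are reproducible and dyads
independent.

Default parameters and why:

| parameter | default | rationale |
|---|---|---|
| duration | 300 s | one task block |
| mean RR adult / child | 850 / 700 ms | typical adult and school-age resting heart periods |
| respiration adult / child | 0.25 / 0.30 Hz | inside the analysis band, child faster |
| RSA modulation depth | 25 ms | realistic respiration-band RR amplitude |
| OU timescale | 10 s | slow autonomic drift; deliberately exercises the ARIMA stage |
| coupling gain | 40 ms per unit L | see calibration below |
| coupling lag | −2 s | child leads, the asymmetry of interest |
| affect rate / bout | 0.10 / 6 s | sparse positive-affect episodes, 4–14 % of task time |
| noise SD | 12 ms | beat-to-beat variability not otherwise modelled |

The reference coupling gain was calibrated once, before the acceptance
thresholds were frozen: at gain 40 the per-dyad synchrony at the
injected lag is r ≈ 0.20 ± 0.04 and the injected lag is the profile
argmax in ~99 % of dyads, while lag-0 synchrony stays near the small
values typical of real mother–child cohorts. A weaker gain (peak
r ≈ 0.1, the level empirical studies report at lag 0) leaves the
injected lag recoverable from a single 300-s dyad only ~60 % of the
time — single-dyad lag recovery simply needs more coupling than
group-level detection does.

The `affect_driven_config` preset switches the coupling channel:
latent gain off, full affect imitation at lag 0, and a 40-ms
heart-period effect of affect, so that all synchrony is attributable
to the affect series — the regime the regression-out is designed to
detect and remove.

What the generator does **not** emulate: ectopic/missed beats and
movement artifacts (validity masks exist but manual beat correction is
out of scope), respiration-rate drift within a recording,
sympathetic/PEP dynamics, nonstationary affect base rates, and any
feedback from physiology to behavior. Passing tests therefore show
that the pipeline recovers the structure this generative model
injects — not that real mother–child data contain such structure.

## Numerical choices and degenerate inputs

* Polynomial detrend uses a scaled time index for conditioning.
* ARIMA innovations drop the first (undefined) value; the fallback and
  degenerate paths are flagged in the residual report, never silent.
* Correlation at a lag with zero-variance overlap is NaN ("undefined"),
  excluded from averages via nanmeans.
* `ln(0)` is guarded by ε = 1e−12 ms²; a mixed model with a
  zero-variance response gets a floored residual variance and reports
  F ≈ 0, R² = 0.
* Sub-0.5-s annotation slivers binarize to 0 — the coverage threshold
  is exactly 0.5 s, closed above.
* All tie-breaks (argmax over lags, window placement at the recording
  tail) are deterministic.

## Problem sizes

Simulation-based checks run at: 200 uncoupled dyads (null mean), 50
replicate 6-dyad cohorts (surrogate calibration), 100 coupled dyads
(lag recovery), 100 affect-driven dyads (cleaning prevalence), 30-dyad
cohorts (paired contrasts, shuffled-affect control), 300 replicate
12-dyad value-level cohorts (mixed-model type-I calibration). These
sizes give the proportions being tested standard errors of a few
percent while a full run of the suite stays in the minutes range.

## Known limitations

* The ARIMA(1,1,1)-with-differencing pre-whitener is part of the
  protocol being implemented; it over-differences the stationary
  OU-plus-noise series the generator produces, leaving some residual
  autocorrelation that smears cross-correlation across neighbouring
  lags. This is faithful to the protocol, not a defect of the
  implementation, and it is why single-dyad lag recovery needs a
  clearly supra-threshold coupling gain.
* The Peak-Matched Multiple Window taper family of the original RSA
  tooling is approximated by a Slepian bank behind the same contract;
  the taper family is recorded in output metadata and swappable.
* Surrogate and shuffled-affect sets are exhaustive, so their cost
  grows quadratically with cohort size; residual caching keeps the
  constant small.
* Regressing 21 lagged predictors plus intercept out of an n ≈ 268
  sample series attenuates any true cross-correlation by about the
  dof ratio k/n ≈ 8 %, even when the predictors carry no signal —
  projections applied independently to the two partners each remove a
  random slice of the shared component. A small positive
  cleaned-vs-uncleaned delta under physiologically inert affect is
  therefore expected, not evidence that affect drove synchrony; the
  attenuation-matched control is the shuffled-affect set, which shares
  the same dof loss, and specificity claims in the test suite compare
  own-affect against shuffled-affect deltas.
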