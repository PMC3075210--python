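# Methods

`txcycle` analyses stochastic transcription cycles in single cells from
dual-reporter protein time-series.  This note records the models, the
numerical choices, and what the synthetic benchmark does and does not
establish.

## The reporter model

Each reporter (luciferase, destabilized GFP) follows linear kinetics driven
by a time-dependent transcription rate τ(t):

    dM/dt = τ(t) − δ_M · M        (reporter mRNA)
    dP/dt = α · M − δ_P · P       (reporter protein)

with degradation rates δ_M, δ_P (per hour) and synthesis rate α.  Only the
products α·M and α·τ are identifiable from protein data, so α is fixed to 1
throughout and all transcription quantities are reported in units of
α·transcripts/h.  A constant maturation delay d shifts the observable
signal: the intensity reported at time t reflects protein state at t − d.
Only the between-reporter difference in d matters for the correlation
analyses; the default difference is 0.5 h.

On any interval where τ is constant the system is linear with constant
coefficients; `txcycle._ode` propagates trajectories segment by segment
with the exact closed form (including the confluent t·e^(−δt) branch when
δ_M = δ_P), so the simulator carries no integration error.  Unit tests
verify agreement with an independent adaptive ODE solver to a relative
error below 1e−6.

## The switch process

Transcription is modelled as binary: rate β_on in the active state, β_off
(default 0) in the inactive state.  Active residence times are
Exponential(mean_on); inactive times are a hard refractory minimum plus an
exponential excess.  The calibrated operating point used as ground truth
everywhere is

    mean_on = 4.0 h, refractory = 3.0 h, mean_excess_off = 3.5 h
    (mean off-phase 6.5 h, mean on-to-on period 10.5 h), β_off = 0.

Setting refractory = 0 with mean_excess_off = 6.5 h gives the matched
memoryless telegraph control.  The initial state of an unstimulated cell is
drawn from the stationary occupancy mean_on/(mean_on + mean_off); initial
mRNA/protein amounts default to the mean-field steady state so records
start mid-expression rather than from zero, as in live imaging of
long-expressing cells.

## The synthetic-data generator

`synthdata` emulates the imaging data the analysis is designed for:
hourly (or half-hourly) sampling over 21–30 h, the two reporters sampled on
staggered grids (default 0.5 h offset, mirroring alternating
luminescence/fluorescence acquisition), and heteroscedastic measurement
noise

    observed = P · (1 + ε_m) + ε_a,
    ε_m ~ N(0, cv²),  ε_a ~ N(0, sd²),

with defaults cv = 0.05 and sd = 1% of the population-mean signal.
Reporter kinetics defaults are destabilized-reporter-plausible values:
luciferase δ_M = 0.7/h, δ_P = 0.35/h, d = 0; GFP δ_M = 0.5/h, δ_P = 0.35/h,
d = 0.5 h.  These are this package's operating point, chosen once as
typical short-lived-reporter rates (mRNA half-life ~1–1.4 h, protein
half-life ~2 h).

Scenario presets: `paper-calibrated` (independent switch processes per
reporter, 30 h hourly), `telegraph-no-refractory` (matched-mean memoryless
control) and `shared-stimulus` (one switch path drives both reporters; the
gene is off until a shared activation drawn uniformly within 0.5 h after a
stimulus at 2 h, modelling stimulus-synchronized recruitment).

What the generator does **not** emulate: intrinsic (copy-number) noise in
mRNA/protein dynamics — the trajectories between switches are
deterministic, and all stochasticity beyond switching is folded into the
observation noise; cell division and growth; photophysics (bleaching,
background drift); and population bimodality.  Recovery results on this
benchmark therefore demonstrate correctness of the inference machinery
under the stated model, not robustness to every artefact of real imaging
data.

## Degradation-rate estimation

δ_P is fitted to translation-block (cycloheximide) decay data as a single
exponential; δ_M to transcription-block (actinomycin D) data as the
double-exponential protein solution with δ_P held fixed, multi-started
over δ_M to avoid local minima.  Both use nonlinear least squares with
asymptotic standard errors; downstream stages consume only the point rates.
When the fitted exponent comes within 0.1% of δ_P the two rates are not
separately identifiable and the confluent (a + b·t)·e^(−δt) model is
refitted and flagged.  Averaging traces across cells before fitting is the
default; per-cell fitting is available.

## Transcription reconstruction

The observed protein path is smoothed with a penalized cubic smoothing
spline; the penalty is chosen by generalized cross-validation
(`scipy.interpolate.make_smoothing_spline`).  The mRNA profile follows from
α·M = dP/dt + δ_P·P evaluated on a fine uniform grid (0.1 h), and the
transcription rate from the forward-Euler inversion
τ_i = (M_{i+1} − M_i)/Δt + δ_M·M_i (last grid point dropped).  Negative τ
values are retained — clipping would create ties that distort rank
correlations.  The first and last hour of each profile are flagged
low-confidence (spline boundary behaviour) and excluded from correlation
windows.  A smoothing spline cannot represent the jump discontinuities of a
binary τ: round-trip accuracy is therefore quantified away from ±1 h
neighbourhoods of the true switch times, where noiseless reconstructions
achieve relative L2 error below 10% (typically 1–3% at 0.5-h sampling).

## Autocorrelation period estimation

Per-cell dominant periods are the lag of the first qualifying local maximum
of the biased sample ACF of the mean-removed series.  For observed and
reconstructed single-cell series the peak must occur after the first zero
crossing and rise above the ±1.96/√n white-noise band; sub-band wiggles in
the trough are skipped rather than terminating the scan (stopping at the
first bump rejects almost every weakly coherent cell).  Reconstructed τ
(0.1-h grid) is thinned to 0.5 h first so spline smoothness does not
inflate short-lag correlation.  Population summaries report mean ± SD and
the median of detected peaks plus the fraction of peakless
(white-noise-like) cells.

## Windowed rank correlation

C(T) is the Spearman correlation between the two reporters' reconstructed
τ over [origin, origin + T], T = 1.5–8 h in 0.5-h steps; the staggered
reporter is linearly interpolated onto the other's grid.  The origin is the
stimulus time for stimulated scenarios and 2 h into the record otherwise
(avoiding initial bias).  Cells whose τ range is below 20% of the
population-median range are discarded first (no rank information).
Population summaries give per-T quantiles (0.025, 0.25, 0.5, 0.75, 0.975)
and a percentile-bootstrap 95% CI for the median, resampling cells with
B = 4000; "significant" means the CI excludes 0.  Kendall's τ is available
by flag.  A maturation-shift scan recomputes C(T) with one profile shifted
by candidate d ∈ {0, 0.5, 1} h.

## Binary switch-model inference

The switch path (number of switches k, ordered times, initial state) and
levels (β_off < β_on) are inferred per cell by reversible-jump MCMC.  The
likelihood evaluates the deterministic piecewise-ODE protein solution along
the candidate path (exact per segment, so no discretization error) under
heteroscedastic Gaussian observation noise, sd_i² = σ² + (cv·P_i)²,
matching the generator's noise structure; σ and cv are both sampled.  A
purely additive-noise likelihood was found to over-fit the high-signal
portions of traces with spurious switch pairs.

Priors: number of switch pairs ⌈k/2⌉ ~ Poisson(4) truncated at
max_switches = 20; switch times uniform order statistics on the record;
levels half-normal with scale 5× the trace-implied transcription scale;
σ half-Cauchy; cv half-normal(0.2); initial mRNA/protein half-normal with
trace-derived scales.  Moves per sweep: one structural move (birth/death of
a switch pair within an interval, birth/death of a single switch — these
mix the parity of k — or a Gaussian shift of one time), an initial-state
flip, random-walk level updates (with occasional 10× steps), log-walks on
σ and cv, and an update of the initial conditions.  The chain is
initialized from the spline/Euler reconstruction (thresholded at the
midpoint of the 20th/80th τ percentiles); a cold start mixes too slowly at
the default 10⁴–5×10⁴ iterations.  Fixed seeds give bit-identical chains.

Post-processing removes weak switches: (i) switch pairs whose implied
mRNA excursion fraction 1 − e^(−δ_M·Δ) is below the 0.2 threshold
(sub-≈0.5-h blips), and (ii) switches with posterior inclusion below 0.5,
operationalized as fewer than half the samples placing a switch within
±0.5 h (this collapses the prior-driven diffuse switches that appear when
the two levels coincide and switching is unidentifiable, e.g. on a steady
trace).  Durations are computed from the per-switch marginal posterior
means conditional on the modal (k, initial state) — a MAP variant is
available — with boundary-censored intervals excluded; the on-to-on period
is the difference of successive on-onsets.

## Off-time memory and cyclicity

Exponentiality of duration samples is tested by one-sample
Kolmogorov–Smirnov with the mean estimated from the data and critical
values from a parametric bootstrap (the classical null would be
conservative).  The memory function is the empirical conditional survival
P(D > s + t | D > s) on a 0.5-h grid of additional waits t, with the
memoryless reference e^(−t/mean); s values with fewer than 20 surviving
durations are dropped.  Refractory shifts can be removed (subtract 3 h,
requiring all durations ≥ 3 h) or enforced (add).

Cyclicity of a duration-distribution pair is measured by simulating cells
with alternating sampled durations, integrating the mRNA equation exactly
along each path (0.5-h sampling over 50 h), and taking the variance across
cells of the ACF first-peak time.  Here the *raw* first local maximum is
used, with no zero-crossing or band requirement and a 24-h lag window: an
incoherent process must register as a wildly placed peak rather than as a
missing value, because its ensemble ACF may never cross zero and censoring
would preferentially drop exactly the irregular cells the statistic is
meant to penalize.  With this rule the refractory scenario shows a reliably
lower first-peak-time variance than the matched telegraph control
(ordering correct in ≥95% of paired 1000-cell replicates).

## Statistical fragility of the off-time histogram mode

The mode of the 0.5-h-binned pooled off-duration histogram sits at the
refractory bin [3, 3.5) in expectation, but a 35-cell record (~70–80
complete off-phases) identifies it unreliably: for draws from
3 + Exp(3.5) the maximal bin equals [3, 3.5) in only about half of
populations of that size, and hourly sampling further merges off-phases
separated by sub-resolution on-blips, shifting inferred mass upward.  The
statistic is reported as computed; its run-to-run variability at this
population size is expected behaviour, not an inference defect.

## Problem sizes

Default analysis sizes are chosen to match the study design the generator
emulates: 35 cells for the switch-model duration analysis (10⁴ MCMC
iterations per cell in the benchmark runs; 5×10⁴ by default in the
library), 20 dual-reporter cells for the ACF period analysis, 80 cells for
the independence analysis, 40 for the stimulated-synchronization analysis,
and 1000 simulated cells per arm for the cyclicity comparison.

## Known limitations

* The likelihood treats trajectories between switches as deterministic;
  intrinsic molecular noise is absorbed into the observation-noise term.
* Switch events shorter than roughly half the sampling interval are not
  recoverable; the resulting merging of adjacent off-phases biases pooled
  off-duration histograms upward at hourly sampling.
* The spline reconstruction smears rate discontinuities over ~1 h, so
  short-window rank correlations on noisy data are dominated by smoothing
  error in cells without a strong feature inside the window.
* Between-reporter maturation delay is modelled as a constant shift only.
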