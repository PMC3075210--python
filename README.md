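# txcycle

Dynamic analysis of stochastic transcription cycles in single cells.

Genes like prolactin are transcribed in pulses: the promoter switches
between an active and an inactive state on a timescale of hours, and cycles
at two identical promoters in the *same* cell are uncoordinated — the
timing is an intrinsic property of each locus, not of the cell.  Crucially,
the inactive phase carries a **refractory period**: a hard minimum off-time
that makes the off-duration distribution non-exponential, gives the system
memory, and makes the cycles more regular than a memoryless telegraph
process would be.

`txcycle` is a library for researchers analysing dual-reporter
(luciferase / destabilized-GFP) live-cell imaging of such dynamics.  It
implements the full analysis chain:

1. **Synthetic data** (`txcycle.synthdata`) — dual-reporter populations
   with exponential on-times, refractory + exponential off-times, exact
   linear mRNA→protein kinetics, maturation delay, staggered sampling and
   heteroscedastic noise; ground truth is carried along so every stage is
   testable as a recovery experiment.
2. **Degradation rates** (`txcycle.degradation`) — δ_P from
   translation-block decay (single exponential), δ_M from
   transcription-block decay (double exponential), by nonlinear least
   squares.
3. **Reconstruction** (`txcycle.reconstruct`) — a GCV smoothing spline for
   the protein path, then the inversion
   `α·M(t) = dP/dt + δ_P·P(t)` and the forward-Euler step
   `τ_i = (M_{i+1} − M_i)/Δt + δ_M·M_i` on a 0.1-h grid.
4. **Period** (`txcycle.period`) — sample ACF and first-significant-peak
   dominant-period estimation per cell.
5. **Correlation** (`txcycle.correlate`) — Spearman C(T) between the two
   reporters' transcription profiles over growing windows (1.5–8 h), with
   percentile-bootstrap (B = 4000) confidence intervals for the population
   median, between-cell variants and maturation-shift scans.
6. **Switch model** (`txcycle.switchmodel`) — reversible-jump MCMC over
   binary switch paths (number of switches, times, levels, noise) with the
   exact piecewise-ODE protein solution as the likelihood mean; weak-switch
   removal and on/off/period duration extraction.
7. **Refractory analysis** (`txcycle.refractory`) — exponential-fit
   overlays, parametric-bootstrap KS tests, the off-time memory function
   P(D > s+t | D > s), refractory removal/enforcement, and the cyclicity
   simulation (variance of ACF first-peak times across simulated cells).

`txcycle.workflows` bundles these into complete in-silico studies, and
`examples/` contains one short narrative script per capability.  A thin
CLI (`txcycle simulate|degrade|reconstruct|period|correlate|refractory|
cyclicity|run-all`) wraps the library for shell pipelines, with a
manifest-writing orchestrator (`txcycle.pipeline`).

## Worked example

Infer binary switch dynamics for one synthetic cell
(`examples/03_switch_inference.py`):

```text
true switch times (h): [ 7.15 10.23 14.09 15.93 22.38 24.6  31.78] starting off
posterior modal k = 6, initial state off
switch time posterior means (h): [ 7.13 10.33 13.9  15.75 22.33 24.67]
switch time posterior SDs  (h): [0.07 0.19 0.13 0.11 0.08 0.14]
beta_on = 9.85 (truth 10), beta_off = 0.07 (truth 0)
complete on-durations (h): [3.2  1.84 2.34]
complete off-durations (h): [3.57 6.58]
```

From hourly protein observations alone, the sampler recovers every true
switch inside the 30-h record to within ~0.2 h, the transcription levels to
a few percent, and off-durations that respect the 3-h refractory floor.

Contrast the two dual-reporter scenarios
(`examples/04_dual_reporter_correlation.py`):

```text
independent median:  [ 0.27  0.27  0.19  0.13  0.05 -0.01  0.    0.   -0.08 ...]
  CI excludes 0?     [False False False False False False False False False ...]
shared-path median:  [0.9  0.81 0.79 0.72 0.74 0.72 0.74 0.74 0.77 ...]
  CI excludes 0?     [ True  True  True  True  True  True  True  True  True ...]
```

With independent promoters the median rank correlation is indistinguishable
from zero at every window length; after a synchronizing stimulus drives
both promoters from one switch path, the short-window median is close to 1.

And the refractory signature (`examples/05_refractory_and_cyclicity.py`):

```text
off-times vs exponential: KS = 0.366, p = 0.002
excess (refractory removed): KS = 0.025, p = 0.353
P(wait > 2 h more | waited 0 h) = 1.00  (memoryless reference 0.74)
P(wait > 2 h more | waited 2 h) = 0.77
first-peak variance, with refractory:    19.6 h^2
first-peak variance, without refractory: 21.9 h^2
ordered (without > with) in 10/10 replicates
```

Off-times fail the exponentiality test until the 3-h refractory shift is
removed; the time already waited changes the remaining wait (memory); and
enforcing the refractory period makes the simulated population cycle more
regularly.

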