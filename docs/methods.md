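# Methods

This note documents the models implemented in `oculochain`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish.

## Task model and clocks

A trial has two clocks. The *WS clock* starts at warning-stimulus offset
(the start of the foreperiod); the *IS clock* starts at imperative-stimulus
onset. For any recorded saccade `lat_ws_ms = lat_is_ms + fp_ms` exactly, and
a negative IS-clock latency means the movement began during the foreperiod.
Foreperiods take the four values {400, 900, 1400, 1900} ms with equal
probability. In explicit-condition trials the cue duration equals the
foreperiod; in implicit trials the cue column is empty and the foreperiod
itself is the only temporal variable (anticipation in the implicit
condition is driven by the passage of time alone — the "base rate").

Trial tables are TSV with a fixed column order and empty fields for missing
values; the medication level "NA" (controls) is written as `NONE` so an
empty field unambiguously means missing. Invalid rows fail the whole load
by default (`skip_bad` downgrades them to dropped-with-diagnostics),
because silently losing rows would corrupt the sequence analyses.

## Synthetic-data generator

The generator is the package's stand-in for subject recordings, which are
not publicly available. Per group × medication × condition it simulates a
latent first-order Markov chain over `{first, second, v, f}`, started from
its stationary distribution, and draws latencies conditional on the state:

* `first` (premature): WS-clock Gaussian, mean `250 + 0.05·d` ms
  (`d` = foreperiod/cue duration), SD 60 ms by default. The near-zero slope
  encodes that premature saccades depend only weakly on temporal
  information.
* `second` (anticipatory): WS-clock Gaussian, mean `200 + 0.75·d` ms,
  SD 80 ms, so the movement lands near the imperative stimulus and scales
  with duration at the regime observed for anticipatory responses.
* `v` (visual): IS-clock Gaussian; means use the per-condition values
  319/317 ms (controls, implicit/explicit) and 376/364 ms (patients), SD
  50 ms (the dispersion is not printed anywhere; 50 ms is a typical
  visually-guided latency SD).
* `f`: no latency.

**Default transition matrices.** Only a few cells are printed in the source
text: the controls-implicit merged early row (e→e = 0.17, e→v = 0.64, hence
e→f = 0.19), the patients-OFF explicit merged e→e = 0.315, and the explicit
4-state diagonals first→first = 0.12/0.20/0.30 and second→second =
0.53/0.26/0.10 for controls / patients-ON / patients-OFF. All remaining
cells are fill-ins: each row is proportional to the cell's marginal
response rates (failed/visual/early percentages from the summary table,
early split into first/second by the duration-averaged mixing proportions),
with the printed cells overriding and the remainder redistributed
proportionally. For patients-OFF explicit, the first↔second cross terms are
chosen so the merged early diagonal equals the printed 0.315 (the merge
weights use the marginal first-share; merging with stationary weights
instead gives 0.33 — the fill-in is approximate by construction). Because
the diagonal overrides perturb the stationary distribution, the realized
early percentage in explicit cells is somewhat above the marginal target
(e.g. ~26% rather than 18% for controls); the printed transition values,
which the recovery tests target, are exact.

**Truncation / separation.** Latency draws are rejection-sampled so that
realized labels match latent states by construction: early-mode draws
satisfy `0 < lat_ws` and `lat_is ≤ 170`; visual draws satisfy
`170 < lat_is ≤ 1000`. This truncates the Gaussians slightly (most visibly
the anticipatory mode at the 400 ms duration, where the upper bound sits
~0.9 SD above the mean at the default SD). Tests that need clean
premature/anticipatory separation use SDs of 25/40 ms, which puts the two
modes more than four pooled SDs apart at every duration.

**Other knobs.** The "850 ± 100 ms" fixation period is modeled as uniform
on [750, 950] ms (the generating distribution is not named anywhere; it
matters only for trace synthesis, which the package does not do per trial).
`second_mode_pressure` (default 0) optionally converts premature draws to
anticipatory ones with probability proportional to `(d − 400)/1500`,
emulating the duration-increasing anticipatory share seen in explicit-
condition controls; it is off by default because it breaks the exact
correspondence between the latent chain and the realized labels.
Per-subject streams in `generate_cohort` are spawned from the master seed
via `numpy.random.SeedSequence`, so adding subjects does not perturb
existing ones. The generator writes ground-truth `state3`/`state4` labels;
the classification stage recomputes labels from latencies alone, and tests
compare the two.

Passing tests on this generator demonstrate that the *pipeline* recovers
known generating structure. Real recordings differ in ways the generator
does not emulate: latency distributions are skewed rather than Gaussian,
transition structure may drift within a session (fatigue, learning), blocks
are shorter, and per-subject heterogeneity is larger. The tests therefore
validate the estimators, not any clinical claim.

## Classification

The early/visual cut-off on the IS clock defaults to the fixed 170 ms
value; latencies exactly at the cut-off count as early. Saccades later than
1000 ms on the IS clock are relabeled failed — an unbounded "visual"
category is implausible and the failed category is otherwise the complement
of the other two. Data-driven detection fits
`y = a + b₁x + b₂·max(0, x − c)` to the cumulative count curve on a
latency grid, scanning `c` exhaustively (ties to the smaller breakpoint).
The fitted knee sits at the foot of the visually-guided rise — just below
where the visual latency density becomes appreciable — and the detector
falls back to the fixed value when the sample is small (< 50) or the
right/left slope ratio is below 2 (a unimodal, visual-only sample has no
meaningful breakpoint). Saccade detection in gaze traces uses a 5-sample
moving-average smooth, central-difference velocity, and a 30 deg/s
threshold with one onset per supra-threshold episode.

Response-type percentages are computed subject-first: each subject's
percentages within a group × medication × condition cell, then the
across-subject mean and standard error (n−1 sample SD / √n).

## Mixture model

The two-component Gaussian mixture is fitted by EM with: means initialized
at the 25th/75th sample percentiles (restarts add uniform jitter up to
±10% of the IQR — additive so that fits are exactly shift-equivariant),
SDs at the sample SD, weights ½/½; convergence at relative log-likelihood
change < 1e-8 or 1000 iterations; a 1 ms floor on component SDs prevents
likelihood blow-up on duplicated latencies; the best restart by final
log-likelihood wins and components are returned ordered by mean. Restarts
that collapse (a component losing essentially all weight with its SD at
the floor) are discarded; if all collapse the fit errors out.

The premature/anticipatory cut solves
`λ₁φ(x; μ₁, σ₁) = λ₂φ(x; μ₂, σ₂)` — after logs a quadratic
`(1/σ₂² − 1/σ₁²)x² + 2(μ₁/σ₁² − μ₂/σ₂²)x + (μ₂²/σ₂² − μ₁²/σ₁² +
2·ln(λ₁σ₂/λ₂σ₁)) = 0` — and returns the root in `(μ₁, μ₂)` where dominance
flips from the first to the second component moving rightward; equal-SD
cases reduce to a linear equation, and a dominated component raises an
explicit no-crossing error (callers may fall back to assignment impossible
/ pooled handling). A latency exactly at the cut goes to the first mode.

Fits are per duration within group × condition, with medication pooled
(whether the printed mixing-proportion table pools ON/OFF is not stated;
pooling is the default and a flag splits). Cells with fewer than 30 early
saccades fall back to a single pooled fit across durations, flagged in the
output; cells whose pooled fit is also impossible keep their early trials'
modes unassigned rather than inventing labels.

## Markov analysis

Sequences are built per subject × condition × block in trial order;
transitions never span subjects or blocks. The first-order property test
is a triplet chi-square: for each middle state `s`, the contingency table
of (state at n−1) × (state at n+1) over positions with state `s` at `n` is
tested for independence (rows/columns with zero margins dropped), the
Pearson statistics and degrees of freedom summed over middle states. This
is a documented stand-in for the property test in the R `markovchain`
package, whose exact internal statistic at the version used is not
described; simulation shows type-I control (≈0.05 at α = 0.05 for
first-order chains of length 2000) and essentially full power against a
strong second-order alternative. Subjects rejecting the property at
α = 0.05 (the screen's conventional level, distinct from the study-wide
0.01) are excluded from pooled fits.

Pooled transition matrices sum per-sequence adjacent-pair counts;
`p̂ᵢⱼ = nᵢⱼ/nᵢ` with per-cell Wald intervals `p̂ ± z·√(p̂(1−p̂)/nᵢ)` clipped
to [0, 1] (the CI construction is not named in the source; Wilson is
available behind a flag). Unvisited rows propagate as NaN, never zero.
Row uniformity uses the Pearson chi-square with df = k−1. Differences
between two transition probabilities are tested by the (1 − α/m) CI of
`p₁ − p₂` with `se = √(p₁(1−p₁)/n₁ + p₂(1−p₂)/n₂)` — significant iff the
interval excludes zero — with m the Bonferroni correction count (m = 3 for
the three pairwise group comparisons). The 4-state analysis runs only on
explicit-condition data by default, where early-saccade samples are large
enough to split by mode.

## Distributions

Kernel densities are means of Gaussian kernels with fixed SD 40 ms — the
"width" of the kernel is read as its standard deviation, not FWHM; this is
an interpretation and is configurable. The grid spans the data ± 6
bandwidths at 1 ms steps so the trapezoid integral is 1 to within 1e-6
(sub-millisecond resolution is meaningless at 1 kHz tracking). Density
differences are computed on the union grid by linear interpolation and
require matching bandwidths. The KS test reports
`D = sup|ECDF₁ − ECDF₂|`, `Z = D·√(n₁n₂/(n₁+n₂))`, and the p-value from
the asymptotic Kolmogorov distribution (the classic "KS Z test"
parameterization); an exact small-sample p-value is available behind a
flag. Latencies are pooled across subjects per cell for these tests.
OLS slope summaries report the raw slope, the standardized slope
`β = b·sd(x)/sd(y)` (the correlation, for simple regression), `t`, `F = t²`
and `r²`; note that with artificially small residual SDs even a weak raw
slope standardizes to a large β, so generator-contrast tests compare raw
slopes.

## Pipeline

`run_full_analysis` chains generate/load → classify → mixture → markov →
distributions, writing every artifact plus a manifest (config snapshot,
seed, per-file SHA-256, version, timestamp). All stage randomness derives
from the single configured seed, and re-running a manifest reproduces each
file byte-for-byte. A missing explicit condition skips the 4-state stage
with a logged reason rather than failing.

## Problem sizes used in the checks

The automated checks use: 20 replicates of n = 1000 for mixture recovery;
100 random parameter sets against a 0.01 ms grid for the crossing cut;
1000 fuzzed sequence sets for the MLE oracle; 1000 first-order chains of
length 2000 (plus 200 second-order chains) for property-test calibration;
one 20 000-trial session for 4-state pipeline recovery and 100 × 2000-trial
replicates for CI coverage; 1000 null replicates at n = 200 per sample for
KS calibration (the asymptotic p-value needs samples of this order to
attain its nominal level); and 20 000-trial cohorts for the density-
difference sign pattern, where the lobe contrast at the premature mode is
a few standard errors at realistic early-saccade counts.

## Known limitations

* The default matrices are anchored to a handful of printed probabilities;
  everything else is a constructed fill-in, and stationary response rates
  deviate from the marginal targets where printed diagonals override them.
* Gaussian latency components are a modeling convenience; real latency
  distributions are right-skewed.
* The breakpoint detector's knee is a property of the two-segment fit, not
  of any physiological event; with a long shallow early ramp it lands at
  the foot of the visual rise (about 50 ms below the visual mean at
  realistic dispersions), and the fixed 170 ms default remains the
  reference cut-off.
* The Markov-property triplet test is one reasonable operationalization of
  the first-order hypothesis; other statistics (e.g. likelihood-ratio
  against a second-order fit) would differ in detail.
* Mixed-model inference on latencies (the repeated-measures analyses of
  the original study) is out of scope.
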