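# Methods

This note documents the models, conventions and design choices behind
`vocseq`, in the spirit of a statistical-software methods appendix. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Input model

The unit of observation is one vocalization with four spectrogram
measurements: maximum frequency (Hz; frequency of highest amplitude, a
pitch proxy), duration (s), average peak-frequency-contour slope
(reported in Hz, carried verbatim — no conversion to Hz/s is attempted
since measurement software reports it this way), and average acoustic
entropy (bits; spectral disorder of a single call, not to be confused
with the sequence-level Shannon entropy below). Calls are ordered
1-based within a (subject, session) pair. Missing values are rejected
rather than imputed: every analysis is sequence-positional, and an
imputed call would fabricate a transition that was never observed.

## Acoustic-space geometry

Two fixed planes: activation (duration × maxfreq) and modulation
(freqslope × entropy). For consecutive calls, percent change per axis is
`100·(next − current)/|current|` — the absolute-value denominator keeps
the sign meaningful when the current value is negative (slopes). A zero
current value makes percent change undefined; such vectors are flagged,
logged and excluded from slice summaries rather than silently dropped.

Grids default to 10×10 bins over the observed min–max per parameter,
half-open except the last bin (closed). The resolution is a display/
aggregation choice, not a modelled quantity; rectangular cells are used
and any hexagonal rendering is treated as cosmetic. Outgoing movement
from a cell is categorized into 8 compass sectors of 45° centred on 0°,
45°, …, 315°, plus a `self` category for exactly zero displacement.
Every consecutive pair contributes exactly one arrow (from the earlier
call's cell), so arrow counts sum to n − 1 per n-call session.

Slice summaries partition vectors by angle into equal sectors from 0°
and report count, median distance and the 2.5%/97.5% distance
percentiles. All quantiles use linear interpolation between order
statistics (numpy's default), pinned so tests are bit-stable.

Pooling is a parameter (`all` / `subject` / `session`), mirroring the
three comparison levels of a two-subject study: across subjects,
between subjects, between sessions. Vectors never span a sequence
boundary.

## Call typing

Features are one plane's parameter pair, standardized (pooled mean/sd)
and rotated to principal components; standardization before PCA is used
because the two axes have incommensurate units. Gaussian mixtures with
full covariance are fitted for each k in 2..20 with 10 random restarts
(best by likelihood kept; `reg_covar` acts as a variance floor,
escalated once on numerical failure). k is chosen by the mean silhouette
of the hard assignments, ties to the smaller k; the AIC curve is emitted
as a diagnostic only. Calls are labelled by maximum posterior, with
posterior ties resolved to the lower component index.

Transition tables count consecutive (from, to) type pairs; pooling m
sessions of total length n yields n − m transitions because boundaries
are never crossed. Row normalization leaves unvisited rows all-zero.

### Table similarity

The similarity between two tables is `1 − MI(T;E)/H(T)` where T is a
uniform binary variable naming the table and E is the (from, to) cell
variable with each table's count-normalized cell distribution as its
conditional law. This equals 1 minus the Jensen–Shannon divergence (in
bits) between the two cell distributions. It was adopted because it is
symmetric, bounded in [0, 1], equals 1 exactly for identical tables and
0 for disjoint supports, and decreases as tables diverge — the direction
the permutation test needs. It is exposed behind a single function so an
alternative NMI definition can be swapped in; a within-table from/to NMI
(how predictive the current type is of the next) is provided as a
separate diagnostic. Conventions: 0·log 0 = 0; two empty tables (and the
one-empty edge case) are defined as similarity 1 and logged.

### Permutation test

Exactly two groups are compared. The observed statistic is the
similarity between the groups' transition tables. Null draws rearrange
the group labels over the pooled, chronologically ordered call list
(group sizes preserved) and recount per-group transitions between
consecutive same-label calls within a session. The p-value is one-sided
toward dissimilarity with ties counted as extreme and the standard +1
correction: `p = (#{null ≤ observed} + 1)/(n_perm + 1)`; ties must count
for the test to remain exact with a discrete statistic (e.g., when the
observed similarity is the maximal 1.0, p is 1 by construction).

**Permutation unit.** Call-type sequences are serially dependent, and a
permutation test is exact only if the shuffled units are exchangeable
under the null. Shuffling individual calls breaks the Markov dependence:
the two permuted groups become interleaved subsequences of the *same*
realization, whose tables are mutually correlated and systematically
more similar than tables from two independent sequences — an
anti-conservative null (empirically, type-I error ≈ 0.18 at α = 0.05 for
a moderately persistent 3-state chain; shuffling transitions instead of
calls suffers the same defect, ≈ 0.16). The default therefore shuffles
*contiguous blocks of 10 calls*, which preserves local serial dependence
inside each null draw while still mixing group labels. Ten calls is
comfortably above the mixing scale of realistic call-type chains and
one sixth of a typical 60-call session; block sizes 6–12 behave
equivalently. Monte-Carlo calibration (500 null replicates, the
acceptance suite) puts the block scheme's type-I error at the nominal
5% level. `unit="call"` and `unit="transition"` remain available for
sensitivity analysis. Whole-session label swaps would be the classically
exact alternative, but with 2 subjects × 2 sessions only 3 distinct
non-identity rearrangements exist — far too few to resolve small
p-values.

## Moving entropic emergence (ESC)

For a univariate parameter series, values are discretized into l global
states (default equal-width bins over the observed range; equal-
frequency quantile bins optional). Global binning is essential: with
per-window bins on continuous data every window would have all-distinct
states and emergence would be identically 1. A constant series maps to a
single state (valid, logged).

Per window of length l ending at t, with state frequencies p_i:
`E = −K Σ pᵢ log₂ pᵢ`, `S = 1 − E`, `C = 4·E·S`. The normalization is
`K = 1/log₂ l`, which is the unique constant making E the entropy
normalized by its window maximum so that 0 ≤ E ≤ 1 with E = 1 at the
uniform (all-distinct) window — the stated interpretation of the scale.
A base-10 constant (`K = 1/log₁₀ l`, entropy still in bits) appears in
some descriptions of these metrics; it is available behind the `k_base`
switch for sensitivity checks but does not bound E by 1, so it is not
the default.

The scan yields n − l values: of the n − l + 1 full windows the first is
dropped. Only the output length is contractual (a 39-value series with
l = 8 gives exactly 31 values; the worked bookkeeping the forecasting
stage depends on); whether one indexes from the first or second full
window is a convention.

Window length: l is simultaneously the state count and the window size.
Lengths 4 and 6 react noisily on short call series; 8 is the default,
and `window_length_report` exposes the variance/roughness comparison
across {4, 6, 8} so the choice can be inspected per dataset.

## Forecasting

### ARFIMA

No Python ARFIMA implementation was available in the supported
dependency set, so the model is implemented here. The series is
demeaned; candidate memory parameters d ∈ (−0.49, 0.49) are profiled on
a coarse grid (step 0.1) against the analytic white-noise Gaussian
likelihood of the fractionally differenced series (truncated binomial
expansion `(1−B)^d`, truncation at the series length); the ARMA(p, q)
order (p, q ≤ 2) is then chosen by AIC at the coarse optimum via exact
ML (statsmodels), and d is refined by bounded scalar optimisation
(tolerance 1e−3, span ±0.15) with the selected order's profile
likelihood. With d fixed at 0 the procedure reduces exactly to a plain
ARMA fit (tested to 1e−6 in log-likelihood). Constant or very short
(< 20) series raise a degenerate-input error.

Forecasting inverts the model to its AR(∞) representation
`π(B) = Φ(B)(1−B)^d/Θ(B)` (power-series division, truncated at history
length + horizon), iterates point forecasts, and builds 95% interval
paths from the cumulative MA(∞) variance. Forecast increments of a
stationary fit damp monotonically toward the process mean.

### Model comparison

Five families: ARIMA (AIC search p, q ≤ 2, d ∈ {0, 1}); ARFIMA (above;
inside cross-validation the order search is lightened to p, q ≤ 1);
ETS restricted to additive error/trend variants, since emergence lives
in [0, 1] where multiplicative forms are unstable near 0; TBATS in its
non-seasonal reduction — Box-Cox transform (MLE λ, with shift when the
series touches 0), linear trend, ARMA(≤1, ≤1) errors — because the
emergence series are short and aseasonal, making the trigonometric
seasonal machinery of full TBATS inapplicable; and TSLM, a linear trend
regression (exactly recovers linear series, a useful bookkeeping
control).

Rolling-origin cross-validation trains on expanding prefixes from
`min_train` (default max(8, l), so the first fold has seen at least one
discretization window's worth of values) and scores the error at
exactly step h — not the average over 1..h — for h up to half the series
length. Fold count per horizon is L − min_train − h + 1. A model failing
a fold has the fold recorded missing; failing more than 25% of folds
disqualifies it from winner selection. The winner minimizes mean RMSE
across horizons, with MAE tabulated alongside (the aggregation is a
choice; both tables are emitted).

### Depletion check

The final ARFIMA forecast runs to half the series length (default rule).
The depletion report extends the point-forecast path to
`ceil(0.5 × length)` steps and reports whether it ever reaches ≤ 0 —
i.e., whether the flow of new variants would have stopped had the
session continued 50% longer — plus the mean and minimum forecast.
Forecasts are reported unclipped with a flag when outside [0, 1].

## Synthetic data

The generator emulates the target study design: 2 subjects × 2 sessions
× 39 calls (a length at which the l = 8 scan gives 31 emergence values),
5 true call types, subject-specific sticky Markov chains (0.45 self,
0.35 to a subject-dependent successor, rest uniform), and Gaussian
emissions whose type means span > 1000 Hz in maxfreq, > 1.5 s in
duration, ~12 Hz in slope and > 2 bits in entropy — ranges comparable to
published captive great-ape voiced-call data; the exact values are
configuration, not claims. Positivity of duration/maxfreq and
nonnegativity of entropy are enforced by clipping (truncation chosen
over rejection sampling for reproducibility). Fixed seeds give
byte-identical outputs.

Calibration/power scenarios use a 3-state base chain
`[[.6,.3,.1],[.1,.6,.3],[.3,.1,.6]]` — deliberately persistent so serial
dependence genuinely stresses the permutation test — and construct the
second subject's matrix at an exact row-wise total-variation distance
(0.3 moderate, 0.8 large) by moving that much mass from each row's
largest entries onto its smallest entry. With 10 calls per subject the
moderate scenario has low power; that is a documented small-sample
caveat, not an asserted property.

What the generator does *not* emulate: articulatory acoustics, session-
level nonstationarity (drift in emission means within a session),
observer measurement error models, and cross-parameter emission
correlation beyond the diagonal covariance default. Tests passing on
synthetic data therefore validate the statistical machinery and its
calibration under the assumed Markov-emission structure, not the
biological claims one would make on real recordings.

## Numerical conventions

- 0·log 0 = 0 throughout; entropies in bits (log₂).
- Quantiles/percentiles: linear interpolation (numpy default).
- Ties: smaller k at equal silhouette; lower component index at equal
  posterior; p-value ties count as extreme.
- All stochastic operations take an explicit integer seed
  (`numpy.random.default_rng`); pipeline outputs embed the seed and a
  SHA-256 per artifact in `manifest.json`.
- Degenerate inputs: length-1 label sequences give empty (not invalid)
  transition tables; empty tables compare as similarity 1 (logged);
  constant series are a hard error for ARFIMA but valid (all state 1)
  for discretization.

## Problem sizes in the distributed checks

The test suite exercises the statistical claims at desk scale: 500
replicates × 200 permutations for type-I calibration, 200 replicates for
power, n = 500 for ARFIMA parameter recovery, exhaustive window-oracle
enumeration for binary series to length 7 and quaternary to length 5
plus seeded random coverage to length 30. These sizes make the full
suite run in well under a minute while leaving Monte-Carlo standard
errors small relative to the asserted margins.

## Known limitations

- The block-permutation null is approximate (block length must exceed
  the chain's mixing scale); it is calibrated empirically, not exact.
- ARFIMA's two-stage d/order search can bias d̂ when strong short-memory
  AR structure coexists with long memory; the local refinement span
  (±0.15) bounds how far the second stage can correct the first.
- The non-seasonal TBATS reduction is not the full trigonometric
  multi-seasonal model and should not be read as one.
- Percent-change vectors are undefined at zero current values; studies
  whose slope measurements cross zero frequently will see many excluded
  vectors in modulation-plane percent summaries (counts are reported).
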