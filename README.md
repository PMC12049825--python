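# vocseq

Quantitative analysis of real-time vocal plasticity in animal call
sequences — written for bioacousticians and behavioural ecologists who
have per-call acoustic measurements (e.g., from Raven selection tables)
and want to ask: *how freely does a subject move through acoustic space,
do individuals differ in how they sequence call variants, and is the
supply of new variants running out?*

## What it computes

Given per-call tables with four parameters — maximum frequency (Hz),
duration (s), peak-frequency-contour average slope (Hz) and average
acoustic entropy (bits) — the toolkit runs four analysis stages:

1. **Acoustic-space change geometry.** Consecutive calls are points in
   two planes (voice *activation*: duration × maxfreq; voice
   *modulation*: freqslope × entropy). Displacement vectors (absolute or
   percent), per-cell compass direction/distance maps on a grid, and
   angular "pizza-slice" summaries (median and 2.5/97.5-percentile
   distance from origin per sector).
2. **Call typing and transition structure.** Gaussian-mixture clustering
   on the two principal components of each standardized parameter pair,
   with k chosen by mean silhouette over k = 2..20 (10 restarts per k,
   AIC as diagnostic). Sessions become call-type sequences, summarized
   by k×k transition tables. Two subjects' tables are compared with a
   bounded NMI similarity,

   `NMI(A, B) = 1 − MI(T; E) / H(T) = 1 − JSD₂(P_A, P_B)`,

   where T is a uniform binary table-identity variable, E the (from, to)
   cell variable, and JSD₂ the Jensen–Shannon divergence in bits between
   the count-normalized cell distributions (1 = identical tables, 0 =
   disjoint support). Significance comes from a label permutation test
   on the pooled call list (blocks of calls shuffled to respect serial
   dependence; p one-sided toward dissimilarity).
3. **Moving entropic emergence.** Each parameter series is discretized
   into l = 8 global states and scanned with a length-l window; per
   window `E = −K Σ pᵢ log₂ pᵢ` with `K = 1/log₂ l`, `S = 1 − E`,
   `C = 4·E·S`. E = 0 means a fully repetitive window, E = 1 a window of
   all-distinct states. A length-n series yields length n − l outputs
   (39 calls → 31 values).
4. **Emergence forecasting.** ARIMA, ARFIMA, ETS, non-seasonal TBATS and
   a linear trend model are compared by rolling-origin cross-validation
   (expanding training windows, error scored at exactly step h, h up to
   half the series length; MAE and RMSE per model and horizon). The
   ARFIMA model (fractional differencing order d estimated by profile
   likelihood) produces the final forecast, plus a *depletion report*:
   would emergence have hit zero had the session run 50% longer?

A synthetic-data module generates call sequences with known type
structure (subject-specific Markov chains with Gaussian emissions), so
the entire pipeline runs and is tested without any field recordings.

## Worked example

```python
import vocseq

# two subjects x two sessions of synthetic calls (39 per session)
seqs, true_types = vocseq.simulate_markov_calls(vocseq.GeneratorSpec(seed=7))

# moving emergence of the acoustic-entropy parameter, first session
esc = vocseq.moving_esc(seqs[0].param("entropy_bits"),
                        vocseq.DiscretizationSpec(l=8))
print(f"emergence series: length {len(esc)}, mean {esc.mE.mean():.3f}")

# ARFIMA forecast and depletion check
fit = vocseq.fit_arfima(esc.mE, vocseq.ArfimaConfig(max_pq=1))
path, report = vocseq.forecast_emergence(fit, esc.mE)
print(f"ARFIMA d = {fit.d:.3f}, horizon {len(path)}, "
      f"mean forecast {report.mean_forecast:.3f}, depleted: {report.depleted}")

# between-subject transition-structure test on the pooled call types
frames = vocseq.sequences_to_frame(seqs)
res = vocseq.permutation_test(true_types, frames["subject"].to_numpy(),
                              frames["subject"] + "/" + frames["session"],
                              n_perm=10_000, seed=7)
print(f"NMI similarity = {res.observed_nmi:.3f}, p = {res.p_value:.4f}")
```

prints

```
emergence series: length 31, mean 0.625
ARFIMA d = 0.487, horizon 15, mean forecast 0.683, depleted: False
NMI similarity = 0.681, p = 0.0012
```

A 39-call session gives 31 emergence values; their mean of 0.63 says new
entropy states kept appearing throughout the session, and the forecast
staying near 0.68 (never approaching 0) says the variant supply shows no
sign of depletion. The two simulated subjects use different transition
matrices, and the permutation test detects it (similarity 0.68 of a
maximum 1, p ≈ 0.001).

The same analysis runs end to end from the shell, writing every stage's
tables plus a hash manifest:

```bash
vocseq run-all --simulate --outdir out --seed 7
vocseq esc --config analysis.yaml       # re-run one stage from intermediates
```

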