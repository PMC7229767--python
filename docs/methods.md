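# Methods

## The problem

Nonparametric species-richness estimators (Chao2, ICE, the jackknives) infer the number
of species present but never detected from the rare tail of an inventory: the counts
`Q_1` (species seen in exactly one sampling unit) and `Q_2` (seen in two). In very large
presence/absence datasets two things happen at once: genuine species accumulate so many
detections that `Q_1` and `Q_2` drain to zero, and any rare erroneous records
(misidentifications, bad coordinates, escapes) surface precisely in those now-empty
classes. The estimators then amplify noise instead of signal, biasing richness upward.
`richsim` reproduces this mechanism in silico, where the true richness is known by
construction.

## Sampling model

A virtual community has `S` species with per-day mean abundances `λ_i` drawn once per
community from a cross-species distribution — log-normal on the natural-log scale
(default `µ = 1.5`, `σ = 2.0`) or gamma (`α` shape, `β` scale). Daily detection follows
a Poisson mixed model: the day-`j` abundance of species `i` is `Poisson(λ_i)` and the
incidence cell is `m_ij = 1` iff that abundance is ≥ 1. Cells are independent, so
`m_ij ~ Bernoulli(p_i)` with `p_i = 1 − e^{−λ_i}`; the default simulation path draws the
Bernoulli indicator directly, and a literal Poisson-threshold path (`method="poisson"`)
is kept and tested to be distributionally indistinguishable. Never-detected species stay
in the matrix as all-zero rows (the truth is known), but are dropped before any
frequency count or estimator sees the data.

Error species emulate rare spurious records: `n_error` extra species (default 10), each
with the same mean abundance `error_factor × E[λ]` where `E[λ]` is the theoretical mean
of the real-species distribution (`e^{µ+σ²/2}` or `αβ`) and `error_factor = 1e−6`. With
the defaults this is `λ ≈ 3.31e−5`: invisible for hundreds of days, then appearing as
singletons in very large samples. Using the theoretical rather than the realized mean
keeps the error intensity identical across replicates; a `reference="realized"` option
uses the replicate's sample mean instead. All error species share one λ — the simplest
reading of "a fixed number of orders of magnitude rarer"; per-species heterogeneity adds
nothing to the mechanism under study.

## Estimators

With `T` units, `S_obs` observed species and frequency counts `Q_k`:

* **Chao2** — `S_obs + [(T−1)/T] Q1²/(2Q2)` when `Q2 > 0`, otherwise the always-defined
  bias-corrected form `S_obs + [(T−1)/T] Q1(Q1−1)/(2(Q2+1))`; the branch taken is
  reported via `fallback_used`.
* **Jackknife1 / Jackknife2** — `S_obs + Q1 (T−1)/T` (needs `T ≥ 2`) and
  `S_obs + Q1 (2T−3)/T − Q2 (T−2)²/(T(T−1))` (needs `T ≥ 3`; the `Q2` term can push it
  below `S_obs`).
* **ICE** — species are partitioned at 10 incidences (the conventional cut, exposed as
  `infrequent_threshold`). With `S_infreq` infrequent species carrying `N_infreq`
  incidences over `T_infreq` units, coverage `C = 1 − Q1/N_infreq` and
  `γ² = max{(S_infreq/C)(T_infreq/(T_infreq−1)) Σk(k−1)Q_k / N_infreq² − 1, 0}`
  (sums over infrequent classes only; `N²` denominator — published variants differ here
  and this is the convention adopted), the estimate is
  `S_freq + S_infreq/C + (Q1/C) γ²`. When every infrequent species is a unique, `C = 0`
  and no coverage correction exists; the implementation falls back to Chao2 and flags it,
  rather than returning an unusable infinity.
* **Singleton-corrected Chao2 (`chiu_chao`)** — treats the observed `Q1` as potentially
  inflated by spurious species and replaces it by a Good–Turing prediction from the
  higher classes, which errors almost never reach:

      Q̂1 = 2 Q2 (Q2 + Q3) / (3 Q3 + 4 Q4)

  i.e. `Q̂1 = 2 Q2 / λ̂` with the pooled Good–Turing rate estimate
  `λ̂ = (3 Q3 + 4 Q4)/(Q2 + Q3)`. The predictor is exact when all species share one
  detection rate (`Q_k ∝ λ^k/k!` makes both ratios collapse to λ) and is defined
  whenever `Q3 > 0` or `Q4 > 0`. The corrected estimate removes the presumed-spurious
  uniques from the observed count and re-runs the Chao2 correction with `Q̂1`:

      Ŝ = (S_obs − Q1 + Q̂1) + [(T−1)/T] Q̂1² / (2 Q2)

  (bias-corrected denominator when `Q2 = 0`). When `Q3 = Q4 = 0` there is no information
  about the rare-species rate; the estimator returns the plain Chao2 value with
  `fallback_used=True` instead of extrapolating. Because heterogeneous communities put
  more mass in `Q1` than the homogeneous prediction allows, `Q̂1 < Q1` in clean samples
  and the estimator deliberately biases low there — the price of robustness to
  singleton inflation.

## Experiment design

`ExperimentDesign` defaults are the study conditions: 100 real species, LN(1.5, 2.0),
100 replicates, effort grid (5, 7, 10, 15, 20, 25, 50, 75, 100, 125, 150, 175, 200, 300,
…, 1000) days, 10 error species at `1e−6` in the with-errors scenario. A fresh community
is drawn per replicate (default), so replicate scatter includes community-assembly
variance; `community_mode="shared"` freezes one community across all cells for
conditional-on-community behaviour. RNG streams are spawned per
(scenario, effort level, replicate) from the master seed via `numpy.random.SeedSequence`
spawn keys: no sample is recycled between effort levels and every cell is independently
reproducible. Estimator domain errors (jackknives at tiny `T`) are recorded as missing
values; summaries report per-cell medians (the headline statistic), means (reported,
never asserted), median `Q1`/`Q2`, the count of valid replicates, and the fraction of
replicates in which at least one error species was detected.

## Numerical choices and degenerate inputs

Everything is computed in double precision with no rounding in the data path (display
rounding only in the acceptance report). `1 − e^{−λ}` uses `expm1` to keep precision at
tiny λ. Degenerate cases are explicit, not silent: empty matrices give `S_obs = 0`
(ICE returns 0), `Q1 ∈ {0, 1}` makes the corrected Chao2 branch return exactly `S_obs`,
the ICE `C = 0` and chiu-chao `Q3 = Q4 = 0` fallbacks are flagged, and every other
undefined intermediate raises a typed error rather than producing NaN.

## What the generator does and does not emulate

The generator reproduces the statistical skeleton of a massively-sampled inventory:
finite biota, heavy-tailed detectability, independent daily sampling, and vanishingly
rare contaminant records. It deliberately omits spatial structure, day-to-day
autocorrelation (weather, seasonality, observer pooling), taxonomically structured error
(a misidentification is *correlated* with a similar common species), and
abundance-format data. Passing tests therefore demonstrate the estimators' sampling
behaviour under the idealized model — convergence on truth without errors, singleton-driven
upward bias with them — not their performance on any particular real dataset, where
non-independence typically slows convergence and vagrants blur the line between error
and genuine rarity.

Under these defaults detection saturates quickly: the expected number of undetected
species falls below ~0.5 by T = 50, so per-cell medians sit at exactly 100 from roughly
50 days on, and the clean-sample downward bias of the singleton-corrected estimator is
visible in the medians at T ≤ 25 (e.g. ≈ 96.5 at T = 10) rather than at intermediate
effort. The replicate scatter, not the median, carries the convergence signal between
50 and 150 days.

## Problem sizes

Tests and the acceptance script run the full 100 replicates per cell but only the effort
levels each question needs (e.g. {50, 100, 400, 1000} for the error-intrusion contrast;
the 13 grid levels ≥ 100 for the `Q1`/`Q2` saturation check). One full single-level cell
(100 replicates × 110 species × 1000 days) simulates and estimates in well under a
second, so the complete 21-level × 2-scenario study is also practical
(`richsim experiment`).
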