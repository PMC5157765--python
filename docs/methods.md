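# Methods

`aelead` compares adverse-event (AE) reporting between two spontaneous
report streams — patient reviews on a social-media site and reports in a
FAERS-like regulatory database — and asks whether the social-media series
*leads* the regulatory series in time. This note documents the models,
the synthetic-data generator, the numerical choices, and the limits of
what the tests demonstrate.

## The lead-lag model

Monthly report counts are modelled jointly as a bivariate vector
autoregression. With `y_t` the regulatory count and `x_t` the
social-media count in month `t`:

    y_t = c_y + Σ_{i=1..p} α_i y_{t−i} + Σ_{i=1..p} β_i x_{t−i} + u_t
    x_t = c_x + Σ_{i=1..p} γ_i x_{t−i} + Σ_{i=1..p} δ_i y_{t−i} + v_t

Each equation is estimated by ordinary least squares, which coincides
with the Gaussian maximum-likelihood estimator because both equations
share the same regressors. The residual covariance Σ is the MLE
(divisor `n_obs = T − p`); the per-equation coefficient covariance uses
the finite-sample divisor `n_obs − (2p + 1)`, the OLS convention, so the
Wald test below matches what standard VAR software reports.

**Granger causality.** `x` Granger-causes `y` when the joint restriction
β₁ = … = β_p = 0 is rejected. The primary statistic is the Wald
chi-square `W = β̂′ V̂_β⁻¹ β̂` with `p` degrees of freedom. A
likelihood-ratio variant — refitting the `y` equation without any `x`
lags on the same sample and forming `n·ln(RSS_r/RSS_u)` — is always
computed as a cross-check; the two agree asymptotically and the decision
(at the two-sided 0.05 level) is taken on the Wald p-value.

**Lag selection.** All candidate orders `1..max_lag` (default 12 months)
are fitted on the common sample implied by `max_lag`, so the fits are
nested and likelihood-ratio tests between adjacent orders are valid.
Stepping down from `max_lag`, `LR_m = n_obs(ln|Σ_{m−1}| − ln|Σ_m|)` is
referred to χ² with 4 df (one extra lag of two variables in two
equations); the chosen order is the largest `m` significant at 5%, else
1. No multiplicity correction is applied, which is the common
econometric convention; the consequence is that under a true white-noise
null the search picks an order above 1 in a substantial minority of
samples (roughly `1 − 0.95^(max_lag−1)` if the tests were independent).
Lag 1 remains the clear modal choice under the null, and on strongly
coupled data the search recovers the generative order as the mode; both
properties are what the test suite asserts. `aic`/`bic` minimisation
over the same common-sample fits is available as an alternative.

**Modelling scale.** Raw counts are modelled directly (the default). An
optional `log1p` transform is provided because counts are
heteroskedastic; it changes none of the interfaces.

**Degenerate inputs.** A constant series, `x ≡ 0`, or `x` identical to
`y` makes the design matrix rank-deficient and raises
`CollinearityError` rather than returning numbers from a pseudo-inverse.
Series shorter than `2p + 4` (or `2·max_lag + 4` for selection) are
refused with the minimum stated.

## Monthly series and PRR

Counts are aggregated to zero-filled calendar-month series; the day of
the month is never used after ingest. The monthly proportional reporting
ratio for a target AE uses a within-drug, month-versus-rest 2×2 table:
for month `t`, `a`/`b` are target/non-target reports in `t` and `c`/`d`
the same in all other months, with `PRR_t = (a/(a+b)) / (c/(c+d))`.
This comparator choice is deliberate and worth flagging: the classic PRR
contrasts one drug against all other drugs, which is impossible with a
single-drug extract, so the calendar complement plays the role of the
comparator stratum. Months with `a + b = 0` or `c = 0` are flagged
undefined, not dropped; an optional Haldane-style correction adds 0.5 to
all four cells when exactly one cell is zero (off by default).

## Ingest and classification

Free-text reviews are classified by a deterministic, case-insensitive
phrase lexicon (a plain CSV, drug-scoped because reviewer category
labels overlap textually between drugs). This replaces the manual
curation a human reviewer would perform; it does no negation handling or
spelling correction. Seriousness on the review side is triggered by
FDA-style serious-outcome phrases (death, hospitalization, disability,
permanent damage, intervention to prevent permanent impairment).
Regulatory reports are classified through a bundled synthetic PT → HLT →
HLGT → SOC hierarchy (~60 PTs); real regulatory dictionaries are
licensed and not shipped. Categories default to HLT level, with HLGT
aggregation as a sensitivity switch.

Exclusion rules: reviews that are hearsay (second-hand phrasing), carry
no classifiable side-effect information, or exactly duplicate an earlier
review on (text, age, gender, month) are excluded, each with a logged
reason; a review with unknown age or gender is never treated as an
"obvious" duplicate, since the key cannot be confirmed. Regulatory
reports are kept only when the study drug is the primary suspect and the
source is a consumer or health professional; trial/literature reports
can be retained as a sensitivity analysis. Filters are idempotent and
partition the input exactly into survivors plus the exclusion log.

Two-sample comparisons use the pooled-variance Student t-test for means
(Welch available) and the pooled two-proportion z-test for proportions
(the equivalent 1-df chi-square is reported alongside). No multiplicity
adjustment is applied. Top-K tables rank categories by the share of
reports mentioning them (multi-label, so shares can sum past 100%);
concentration is the fraction of unique reports mentioning at least one
top-K category, each report counted once; ranking ties break
alphabetically. Cross-stream overlap is counted through an explicit
hand-matched concept map, not string similarity.

## The synthetic-data generator

No public extract of either stream exists, so the generator is a
first-class module that emulates the study conditions with known ground
truth.

**Counts.** The paired monthly counts follow a log-linear Poisson
autoregression:

    log μ_t = log r + Σ_i a_i (log1p(y_{t−i}) − log1p(r))
                     + b (log1p(x_{t−L}) − log1p(r_x)),   y_t ~ Poisson(μ_t)

The centering around `log1p(r)` makes the base rate `r` the stationary
scale of the series, keeps counts non-negative integers, and leaves a
linear, Granger-detectable signal in the log domain; `b = 0` gives
conditional independence, and a zero base rate gives an identically-zero
stream. A 24-month burn-in is discarded.

**Records.** Each month's count is disaggregated into records: ages are
draw-and-reject truncated normals on [18, 100]; gender is Bernoulli; one
primary AE category is drawn from the stream's mixture with extra
categories added with probability 0.3 (reports are multi-label);
seriousness is Bernoulli with a per-category probability, taking the
maximum over the record's categories; review ratings are a rounded,
clipped latent normal depressed by fixed shifts for specific-AE and
serious reporters. Junk records — hearsay, uninformative, duplicate
reviews; non-primary-suspect and trial/literature regulatory reports —
are injected *on top of* the target counts and flagged in hidden
`truth_*` columns, so the post-filter monthly counts reproduce the
ground-truth series exactly and filter accuracy can be scored with zero
tolerance.

**Presets.** Two archetypes encode the study conditions: a statin-like
drug (older reporters, mean age 53.9 vs 64.0 years across streams,
balanced gender, musculoskeletal-dominated mixture, ~6 reviews and ~120
regulatory reports per month, no coupling — the null archetype) and an
anorectic-like drug (younger, predominantly female reporters, 36.8 vs
43.8 years, cardiometabolic mixture, ~2 reviews and ~38 regulatory
reports per month, coupling 0.8 at lag 4 — the coupled archetype).
Category mixtures are the observed top-20 relative frequencies of each
stream; per-category seriousness probabilities are set so the serious
fraction among specific-AE reports matches the observed gap (≈2.5% vs
38% for the statin pain filter, ≈8% vs 63% for the anorectic
cardiovascular filter).

**What the generator does not emulate.** Media shocks, litigation waves
and market-withdrawal discontinuities; reporting backlogs; secular trends
in internet use; free text beyond lexicon templates (so classification
accuracy on synthetic data is exact by construction and says nothing
about recall on real prose); and the full breadth of a real AE
dictionary — the regulatory stream spreads over ~30 HLTs here versus
hundreds in reality, so the concentration gap between streams is
reproduced in direction but not in magnitude. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not performance on real-world text or real reporting
dynamics.

## Problem sizes and calibration checks

The Monte-Carlo calibration of the Granger test uses 1000 null pairs of
150 months at lag 3 for size, 200 coupled pairs of 180 months for power,
and 60 pairs of 300 months for lag recovery; these sizes give
Monte-Carlo standard errors of ~0.7% (size) and ~2% (power) while
keeping the full suite under a minute. The reference-implementation
cross-check compares coefficients, residual covariance, log-likelihood,
and the Wald statistic to an established VAR implementation at 1e-6 on
50 random datasets; that implementation serves only as a test oracle and
is never used in the analysis path.

## Known limitations

- Phrase matching is substring-based; negated mentions ("no muscle
  pain") count as mentions.
- The sequential LR lag search inherits the multiplicity behaviour noted
  above.
- The VAR treats counts as homoskedastic Gaussian; for very sparse
  specific-AE series (a few reports per month) the Wald test can be
  under-powered, and the `log1p` switch is advisable.
- PRR is within-drug by construction; it is not comparable to
  drug-versus-database disproportionality values.
- No confounder adjustment, cointegration testing, or impulse-response
  analysis is attempted.
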