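# Methods

This note documents the statistical procedures, the numerical choices, and
the places where the design was genuinely open. It states no result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data

The packaged table (`specmeta/data/table1.csv`) transcribes the printed
study table of the source meta-analysis: 105 independent samples, each with a
Pearson correlation between an intelligence measure and a religiosity
measure, the sample size, the reported (possibly bounded) two-sided p, and
moderator codes. Two caveats:

- The intelligence-assessment coding (iq / gpa / mixed) is derived from the
  free-text measure column (pure GPA-type proxies → `gpa`, test + GPA
  composites → `mixed`, otherwise `iq`); it reproduces the reported marginal
  counts (93/8/4) exactly.
- The printed table is not byte-identical to the authors' deposited analysis
  file: its participant total (201,181) and some religiosity/sample-type
  codings differ slightly from the marginal counts quoted in the source's
  text, and Cochran's *Q* — which depends on the data alone — differs by
  ~5% from the printed value. The package ships the printed table verbatim
  rather than guessing row-level corrections. Re-derived quantities are
  therefore close to, but not always equal at printed precision to, the
  published values; the acceptance tests keep the strict comparisons and let
  the affected ones fail visibly.

Reported p-values are stored as exact values or upper bounds ("< .01"); any
method that needs an exact p (significance filters, the conditional-p
estimators) recomputes it from (r, n) via the two-sided z-test on the Fisher
scale. Percentages of men are proportions in [0, 1] internally.

## Pooling and heterogeneity

Effects are analyzed on the Fisher-z scale, v = 1/(n − 3), unless a
specification requests the raw-r scale (v = (1 − r²)²/(n − 1)) or raw r with
unit variance (see *Multiverse*). Estimators:

- **FE**: inverse-variance weights 1/vᵢ.
- **DL**: τ² = max(0, (Q − df)/C), C = Σw − Σw²/Σw, then weights 1/(vᵢ + τ²).
- **REML**: τ² maximizes the restricted log-likelihood by bounded scalar
  optimization on [0, max(10·var(z), 10·max v)] with absolute tolerance
  1e-10 and an explicit boundary check at τ² = 0. Verified against both a
  200,001-point grid search of the restricted likelihood and r-metafor.
- **UNWEIGHTED**: arithmetic mean, SE = sd/√k; τ² reported as the
  variance-decomposition moment max(0, var(z) − mean v).

Q is always computed under FE weights. I² = 100·τ²/(τ² + s²) with s² the
Higgins–Thompson typical within-study variance under FE weights; with the DL
τ² this is algebraically identical to max(0, (Q − df)/Q)·100, and with REML
it matches the convention of the standard R implementation (which the source
analysis used — its printed I² values are not reproducible from the
(Q − df)/Q formula). Confidence intervals are Wald on the analysis scale,
back-transformed; no Knapp–Hartung adjustment, matching the published
intervals. A k = 1 input yields a result with undefined Q/I².

**Estimator defaults.** Library calls take an explicit `method`; the
pipeline's headline analyses default to REML because the published intervals,
I² and between-group statistics follow REML arithmetic (the original software
default), while the acceptance script uses DL where the quantity is defined
as a DL estimate. The multiverse treats the estimator as an explicit factor,
so nothing there depends on a default.

## Subgroups and meta-regression

Subgroup comparisons are mixed-effects: each level pooled by a random-effects
model with its own τ², then Q_between = Σ w_g(θ̂_g − θ̄)², w_g = 1/se_g²,
referred to χ²(#groups − 1). Records of levels not under comparison (e.g. the
four mixed-type samples) simply drop out of the comparison while remaining in
overall pooling.

Meta-regression is weighted least squares on the z scale with weights
1/(vᵢ + τ²). The residual τ² is REML by default; a DL-type moment estimator
on the FE-WLS residuals is available (`tau2_method="DL"`), but on the
packaged data the moment estimate exceeds the intercept-only τ², driving the
pseudo-R² = max(0, 1 − τ²_res/τ²_null) to zero, so REML is also the better
default here. Coefficient covariance is (XᵀWX)⁻¹ (known-variance Wald
inference, not the WLS mean-square scaling). Rows missing a moderator are
dropped with a logged count — 29 of the 105 samples lack a sex breakdown,
leaving the k = 76 regression of effects on the proportion of men.

## Dissemination bias

All methods default to the published subset (88 samples) and internally flip
effects so the summary is positive, reporting estimates flipped back.
Study significance is always recomputed from (r, n), two-sided, α = .05
(on this table the recomputed and the reported p's select the same 55
published significant negative samples).

- **Begg–Mazumdar**: Kendall τ between variance-stabilized deviates
  (zᵢ − ẑ_FE)/√(vᵢ − 1/Σw) and vᵢ; tie-corrected normal approximation
  (identical to r-metafor's `ranktest` on the packaged data). The
  conventional decision level for this low-powered test is α = .10.
- **Egger**: OLS of zᵢ/seᵢ on 1/seᵢ; the intercept's z and two-sided p.
- **Trim-and-fill**: iterated L0 (or R0) rank estimator of the number of
  suppressed studies on a chosen funnel side (default: the side opposite the
  observed effect), mirror-imputation about the trimmed FE summary, DL
  re-pooling; at most 50 iterations with a convergence flag. k0 equals
  r-metafor's on shared test data. The rank estimators can only detect
  suppression when precise studies pin the funnel's center — an
  equal-variance symmetric set minus its extremes is symmetric about its own
  mean again, which the test constructions respect.
- **Excess significance**: per-study power of the two-sided z-test against
  the pooled effect, counting the hypothesis-conforming tail only,
  P(Z > z_{α/2} − |θ̂|√(nᵢ − 3)); expected count E = Σ power; χ² comparison
  of observed conforming-significant count O vs E, each Pearson term guarded
  against a degenerate margin. Because O is Poisson-binomial, the χ² test is
  conservative when power varies across studies (empirical size ≈ .001 under
  the calibration simulation); it is reported for both the published subset
  and all samples, since the published 63% → 66 arithmetic corresponds to
  the all-samples count.
- **p-curve**: Stouffer right-skew and 33%-power flatness tests on
  conditional p-values (pp-values, normal approximation on the z scale);
  the effect estimate minimizes the Kolmogorov–Smirnov distance between the
  pp's and Uniform(0, 1) (bounded search, tolerance 1e-6).
- **p-uniform**: the default "P" moment condition Σ ppᵢ(θ) = k/2 (mean of
  the Irwin–Hall distribution), solved by bracketed root-finding on the z
  scale (bracket (−2, 2), doubled up to 4 times); CI by inverting the
  statistic at its normal-approximation 2.5/97.5% quantiles, clipped into
  the attainable range (0, k). A Fisher-type "LNP" condition
  Σ −ln ppᵢ = k against Gamma(k, 1) is exposed as an option; on heterogeneous
  data it lands much further from zero than the P method, and only the P
  method reproduces the published estimate. The publication-bias test
  compares the pp distribution at the fixed-effect estimate of the full
  input set against uniformity (one-sided toward left-skew); as a plug-in
  test it is conservative (empirical size ≈ .014 in calibration).
  A study with p exactly at α has pp ≡ 1 for every candidate effect; the
  root search then fails by design and signals the degenerate case.
- **p-uniform\***: joint conditional ML of (θ, τ²) over all published
  studies, each study's normal density truncated to its own two-sided
  significance stratum; Nelder–Mead from four starts on (θ, √τ²), τ² ≥ 0 by
  squaring.

## Multiverse and specification curve

Which factors: religiosity type {beliefs, behavior, mixed, all} × sample type
{precollege, college, noncollege, all} × publication status {published,
unpublished, all}; "all" imposes no filter (so mixed-sample-type records
appear only under sample = "all"). How factors: metric {r, z, r_unit} ×
estimator {FE, DL, REML, UNWEIGHTED}, i.e. 48 × 12 = 576 specifications.
The third metric level, `r_unit` (raw correlations with unit sampling
variance, i.e. unweighted-synthesis variances), fills the three-level
effect-size choice of the original design, whose third level is not stated;
a strict two-metric grid (`SpecificationGrid.strict_two_metric()`) and fully
custom grids (YAML) are provided. Admissibility is k ≥ 2; on the packaged
table 40 of 48 Which cells qualify, giving 480 admissible specifications —
the source reports 192, a count not derivable from its printed table under
any k-threshold, so the discrepancy is surfaced rather than patched.

Curves are sorted by estimate with a lexicographic specification tie-break.
The bootstrap test holds study features fixed, redraws each study's z from
N(0, 1/(nᵢ − 3)), re-runs the full multiverse B times (default 999), and
takes pointwise type-7 (linear-interpolation) 2.5/97.5% quantiles over the
B + 1 curves including the observed one. The decision is "non-nill" when the
observed curve escapes the envelope. Calibration: under a true zero effect
the observed curve falls inside the envelope at ~95% of ranks (meta-
simulation at k = 25, B = 199, 200 replicates — sizes chosen to exercise the
machinery densely at small cost).

## GOSH

Subset sizes uniform on [2, K], membership uniform given size, duplicates
rejected by bitmask hashing; when the feasible count 2^K − 1 − K is below the
request, enumeration is exhaustive instead. Stratified oversampling (on by
default) forces every second draw to contain one of the two most extreme
observed effects. Pooling is vectorized DL over mask batches. The two
leverage studies flagged in the output are identified by leave-one-out
influence (largest |Δ estimate|), not hard-coded.

## Mediation

Stage 1 pools each of the three correlations (intelligence–religiosity,
intelligence–mediator, mediator–religiosity) independently by DL on Fisher z
over the studies reporting that cell; the pooled matrix is eigenvalue-clipped
to PSD (threshold 1e-6, unit diagonal restored) with a flag when projection
was needed. Stage 2 is exact standardized path algebra — a = r_xm,
b = (r_my − r_xm·r_xy)/(1 − r_xm²), c′ = (r_xy − r_xm·r_my)/(1 − r_xm²) —
so total = c′ + a·b holds to machine precision. Indirect-effect CIs come from
10,000 seeded Monte-Carlo draws of the stage-1 cells on the z scale from
their asymptotic normals. This cellwise-univariate two-stage approach (not a
full TSSEM with joint asymptotic covariance) reproduces pooled, partial and
path quantities from the same inputs and is the documented simplification.
The per-study correlation matrices for the published education and
cognitive-style models live in external supplementary files and are treated
as optional inputs; the pipeline validates the machinery on synthetic
matrices with known population structure instead.

## Synthetic data

`SimConfig` defaults mirror the packaged table's conditions: k = 105,
ρ = −0.14, τ² = 0.018 (z² units), sample sizes log-uniform on [20, 40000],
moderator composition matching the observed margins. Publication selection
acts on each study's own significance and sign (probability
`select_prob_sig` for significant, direction-conforming studies,
`select_prob_nonsig` otherwise; under a zero true effect the positive
direction counts as conforming), never on effect magnitude. One seed
sequence is split into per-study substreams, so growing k leaves earlier
studies unchanged. The generator emulates study-level sampling only: it does
not model correlated multiple outcomes within studies, rounded reporting,
or non-normal effect distributions, so passing recovery tests demonstrate
correctness of the estimators under the model's own assumptions, not
robustness to those real-data features.

## Known limitations

- The printed-table/analysis-file mismatch documented above bounds how
  closely the published values can be reproduced (most deviations are
  ≤ 0.01 on the r scale; the multiverse admissibility count differs
  qualitatively).
- p-curve/p-uniform use the normal approximation on the z scale throughout;
  no exact t machinery (inputs are correlations with n only; a noncentral-t
  variant of p-curve was checked and changes the estimate by < 0.001 here).
- Between-subgroup tests use separate within-group τ² (no pooled-τ² option).
- GOSH supports the DL estimator only in the vectorized path.
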