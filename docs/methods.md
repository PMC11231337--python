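# Methods

## The EMT score

Each sample is scored independently.  The expression values (log2 scale) of
the matched epithelial genes and matched mesenchymal genes form two empirical
distributions; the score is the signed two-sample Kolmogorov–Smirnov
statistic between them.

Conventions, fixed so the statistic is exactly reproducible:

- ECDFs are right-continuous, F(x) = #{v ≤ x}/n; ties count with ≤.
- The ECDF difference is evaluated on the pooled unique values of both arms
  (the maxima of a two-sample ECDF difference are attained there).
- D+ = max(F_E − F_M) and D− = max(F_M − F_E), both clamped at 0 (the
  difference is 0 at the pooled maximum, so both are non-negative).
- Sign: +D+ if D+ > D−, −D− if D− > D+.  A higher-expressed mesenchymal arm
  drags F_M below F_E, so positive = mesenchymal-shifted.
- Tie (D+ = D−, e.g. symmetric interleavings): the sign is taken from the
  comparison of mean ranks of the two arms in the pooled ranking (average
  ranks for ties), zero if those tie as well.  This tie-break is a package
  convention — the statistic's definition does not determine it — chosen to
  be deterministic and antisymmetric under arm exchange.
- Coverage guard: a sample is scored only if both arms match at least
  `min_genes` genes in the matrix (default 10 per arm).  Degenerate ECDFs
  from a handful of genes are flagged (`valid = False`, score NaN) rather
  than reported.  Non-finite values are dropped per sample before scoring.

Consequences used as test invariants: the score lies in [−1, 1] and reaches
±1 iff the two arms are completely separated; it is antisymmetric under arm
exchange whenever D+ ≠ D−; it is invariant under strictly increasing
per-sample transforms (it sees only ranks); and adding a positive shift to
all mesenchymal values can never decrease it.

## Signature scores

A signature score is the mean over the signature's matched genes of the
gene-wise z-scored log2 fold-change.  Two conventions are deliberate:

- The fold-change reference (per-gene cohort mean or median of log2 values)
  is an additive per-gene shift, which z-scoring removes.  The scores are
  therefore identical — to floating-point — for any reference choice; the
  default is `cohort_mean` and the invariance is asserted to 1e-12 in tests.
  This matters because a cohort-external reference is often unavailable.
- z-scores use the sample standard deviation (n−1).  Zero-variance genes are
  excluded (warning) rather than propagating division by zero; signatures
  matching fewer than `min_genes` (default 3) usable genes are flagged
  invalid.

By construction each score column has cohort mean 0 when all samples are
scored; scores are invariant to per-gene affine maps a·x + b (a > 0).

## Stratification and group statistics

- Median split: high ⟺ value > median, so ties at the median go low and the
  high group is never the larger one.  Missing values stay unassigned.
- TPS split: PD-L1-high ⟺ tumor proportion score ≥ cutoff, default 1
  (inclusive boundary).
- Response comparisons: two-sided Welch t-test by default (no equal-variance
  assumption); Mann–Whitney U available.  p-values are reported raw — the
  analysis design reports per-contrast significance at 0.05 without
  multiplicity correction, and readers should treat the secondary contrasts
  accordingly.
- Correlations: tie-corrected Spearman rho with the two-sided t
  approximation on n−2 df; pairwise-complete; constant inputs yield a
  flagged NaN rather than an arbitrary value.

## ROC-Euclidean cutpoints

Candidate thresholds are the midpoints between consecutive sorted unique
marker values plus one sentinel below the minimum and one above the maximum;
a sample is called positive iff marker ≥ threshold.  The selected cutpoint
minimizes the Euclidean distance √((1−sens)² + (1−spec)²) to the perfect
classifier; exact ties are resolved by larger Youden index, then smaller
threshold, so the result is deterministic.  For markers where *low* values
predict the event (E-cadherin H-score), the marker is negated before the
search and the returned rule is marker ≤ threshold.  The default outcome the
cutpoint discriminates is progression (PD vs non-PD); this is a declared
package default, configurable per analysis.

## Survival analysis

Kaplan–Meier uses the product-limit estimator with the events-before-
censoring convention at tied times (subjects censored at t remain at risk at
t).  With no censoring the curve equals the empirical survivor function
exactly.  The log-rank test is the two-group Mantel–Haenszel form: over the
pooled event times, U = Σ(O_A − E_A) with the hypergeometric variance V per
time, and U²/V is referred to chi-square with 1 df.  Both are implemented
directly — the report contract includes the observed/expected tables, and the
calibration study needs many cheap calls — and both are cross-checked in the
test suite against lifelines (agreement to 1e-9) on random censored data;
the implementation also agrees with `scipy.stats.logrank` to 1e-8.

Measured calibration: under the null (exponential times, n = 100 with
complete follow-up, random balanced labels) the rejection rate at α = 0.05
is ≈ 5.5% — the usual mild anti-conservativeness of the chi-square reference
at this sample size, shared by the reference implementations.  The
calibration test estimates this rate with enough replicates (10,000) that
the Monte Carlo standard error (≈ 0.2%) is small against the accepted band
[4%, 6%].

## The synthetic cohort generator

The generator exists to make the stratum-restricted biomarker hypothesis a
*ground truth* that the analysis chain must recover.  Per patient i:

- latent EMT axis e_i ~ N(0, 1);
- latent PD-L1 p_i = ρ_p·e_i + √(1−ρ_p²)·N(0, 1), ρ_p = 0.2; PD-L1-high ⟺
  p_i above the cohort median; the expression matrix carries
  CD274 = 5 + p_i;
- epithelial genes: x = μ_g − β·e_i + ε; mesenchymal genes:
  x = μ_g + β·e_i + ε, with β = 1 (log2 units), ε ~ N(0, 1), and gene
  baselines μ_g ~ N(5, 1) — realistic log2 magnitudes, irrelevant to the
  rank-based score;
- immune signature genes load ∓κ·e_i (CTL −κ; Treg and M2 +κ; M1 uncoupled)
  **only for PD-L1-high patients**, κ = 0.8; 2000 background genes are pure
  noise;
- response: PD with probability logistic(α + γ_r·e_i·1[PD-L1-high]), else
  PR, with α = 0 (balanced baseline) and γ_r = 1;
- PFS: exponential with rate (1/s)·exp(γ_h·e_i·1[PD-L1-high]), s = 6 months,
  γ_h = 0.8; OS identical with s = 18 months; independent exponential
  censoring scaled so ≈ 30% of baseline patients are censored.

Cohort sizes default to 234 (RNA-seq) and 90 (IHC).  The IHC generator draws
integer H-scores in [0, 300] as clip(round(150 + 55·sign·e_i + N(0, 45)))
with sign −1 for E-cadherin and +1 for Slug/Twist1/vimentin, a PD-L1 H-score
driven by p_i, and a zero-inflated TPS (lowest 35% of latent PD-L1 stain
negative).  The effect sizes (β, κ, γ_r, γ_h) were chosen once for clear
detectability at the default cohort sizes — the real cohort's effect sizes
are unknowable from published figures — and are not tuned thereafter.

What the generator does **not** emulate: count-level RNA-seq noise (negative
binomial overdispersion), batch effects, tumor purity, correlated gene-gene
structure beyond the single latent axis, SD/CR response categories, and
non-exponential hazards.  Passing recovery tests therefore demonstrates that
the analysis chain is correct and powerful under its own assumptions, not
that those effect sizes or significance rates transfer to real cohorts.

All draws flow from one `numpy` generator seeded from the config (separate
substreams for the RNA-seq and IHC cohorts), so a fixed config reproduces
byte-identical outputs.

## Problem sizes in the validation suite

The recovery study runs 100 independent cohorts at the default n = 234; the
signed-KS oracle comparison uses 1000 random arm pairs (sizes 1–50, with
ties); the cutpoint oracle comparison uses 500 random instances (n ≤ 50);
the log-rank calibration uses 10,000 null replicates at n = 100.  The
acceptance script uses 50 cohort seeds for the rejection-rate summaries and
2000 replicates for the calibration figure.

## Known limitations

- Gene matching is exact-symbol; no alias/ortholog resolution.
- The bundled signature GMTs are synthetic placeholders with the published
  arm sizes; analyses of real data should substitute the real gene lists
  (same GMT layout, `<name>_EPI` / `<name>_MES` entries).
- Two-group log-rank only; no Cox models or hazard-ratio intervals.
- The KS score treats the two arms as exchangeable samples of values; genes
  are not weighted by reliability or expression level.
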