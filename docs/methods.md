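# Methods

## Setting and model

Two-sample summary-data Mendelian randomization. For variant *j* the data
are the estimated exposure association β̂_Xj with SE σ_Xj (SD units of the
exposure) and the estimated outcome association β̂_Yj with SE σ_Yj (ln-OR
units for a binary outcome, SD units for a continuous one), from
non-overlapping samples. Under the instrumental-variable assumptions
(relevance, independence, exclusion restriction) each valid variant
satisfies β_Yj = θ·β_Xj, and θ is the causal effect per 1 SD of exposure.
Violations are modelled as per-variant pleiotropic intercepts α_j:
β_Yj = θ·β_Xj + α_j.

## Harmonization

Outcome associations are re-expressed with respect to the exposure's effect
allele: direct match; allele swap (negate β, reflect EAF); strand flip
(reverse-complement, non-palindromic only); palindromic A/T and C/G
variants resolved by comparing effect-allele frequencies — same side of 0.5
keeps the orientation, opposite sides flips it, and either frequency within
a half-width of 0.08 of 0.5 (window 0.42–0.58, configurable) drops the
variant as ambiguous. The window is a conventional conservative default; no
universally agreed value exists, so marginal variants may differ between
implementations. Instruments missing from the outcome can be replaced from
a user-supplied proxy map, which is trusted as given (no reference-panel LD
validation). Variants are matched by identifier only, and only biallelic
SNPs are accepted. Harmonization is idempotent, conserves the instrument
count across action categories, and is invariant to swapping outcome
alleles with negated betas.

## Instrument selection and strength

Selection keeps variants with p < 5×10⁻⁸ (strict), minor allele frequency
> 0.1% (strict) and, when available, imputation info > 0.5. Independence
pruning is *not* recomputed: inputs are assumed to be published,
pre-pruned (r² < 0.05) instrument lists. Per-variant strength is the
t-statistic approximation of the F statistic, (β/σ)², with F > 10 the
conventional strong-instrument threshold.

Effects known only as (p, sign, EAF, N) are reconstructed on the SD scale
via the signed normal quantile z = sign·Φ⁻¹(1−p/2):

    β_std = z / sqrt(2p(1−p)(n+z²)),   se_std = 1 / sqrt(2p(1−p)(n+z²)).

Natural-log-scale effects are standardized the same way from z = β_ln/σ_ln
(the log-scale magnitude is discarded; the result is invariant to common
rescaling of β and SE). Per-variant variance explained is

    r² = 2β²p(1−p) / (2β²p(1−p) + 2σ²·n·p(1−p)) = β²/(β² + nσ²),

evaluated in the simplified right-hand form — the 2p(1−p) heterozygosity
factors cancel exactly, so for reconstructed effects r² = z²/(n+z²) holds to
machine precision. Totals over pre-pruned instruments are additive; a total
≥ 0.5 triggers a warning since it indicates correlated instruments.
p-values of exactly 0 (or below 1e-300) are a fatal error: the caller must
choose an explicit minimum-p convention rather than rely on silent capping.

## Estimators

All estimators consume the harmonized table. Ratio weights are first-order:
w_j = β̂²_Xj/σ²_Yj (the delta-method inverse variance of the Wald ratio;
the second-order correction is a documented extension point, not used).

* **IVW** — weighted mean of ratios; equivalently weighted zero-intercept
  regression of β̂_Y on β̂_X with weights 1/σ²_Y. Fixed-effect SE
  (Σw)^(−1/2); the default multiplicative random-effects mode inflates it by
  max(1, √(Q/(J−1))). The floor at 1 makes the interval conservative when
  data are homogeneous; calibration checks of nominal coverage therefore use
  the fixed-effect interval under a homogeneous generating model. Normal
  inference.
* **MR-Egger** — weighted least squares of β̂_Y on β̂_X *with* intercept,
  after re-orienting rows so every β̂_X > 0; the intercept estimates the
  mean directional pleiotropic effect (valid under InSIDE: instrument
  strength independent of direct effects). Inference is t with J−2 df and a
  multiplicative residual dispersion floored at 1.
* **Weighted median** — sort ratios, form cumulative-midpoint weight
  positions p_j = (cum(w)_j − w_j/2)/Σw, linearly interpolate to 0.5.
  Consistent when ≥ 50% of weight comes from valid instruments. SE by a
  seeded parametric bootstrap (default 1000 draws of β̂_X, β̂_Y from
  independent normals at their observed values/SEs).
* **Weighted mode** — argmax of a Gaussian-kernel weighted density over the
  ratios with bandwidth h = φ·0.9·min(sd, MAD/0.6745)·J^(−1/5) (φ = 1 by
  default), located on a 512-point grid spanning the ratio range ±3h and
  refined by bounded scalar maximization; bootstrap SE as for the median.
  Because h depends on J, exact duplication of the row set moves the argmax
  only marginally (not exactly zero).
* **MR-Lasso** — β̂_Yj = θ·β̂_Xj + α_j with weights 1/σ²_Yj and penalty
  λΣ|α_j|; for fixed λ the α-update is an exact per-variant soft threshold
  (so invalid variants get exactly non-zero α) alternated with a weighted
  slope update. λ walks a 60-point geometric grid downward from the
  all-retained limit and stops at the first (largest) λ whose retained
  (α_j = 0) set has Cochran Q below the 0.95 null chi-square quantile;
  the reported estimate is fixed-effect IVW on that retained set.
* **MR-RAPS** — profile likelihood of the errors-in-variables model
  β̂_Yj ~ N(θγ_j, σ²_Yj + τ²), β̂_Xj ~ N(γ_j, σ²_Xj); profiling γ_j leaves
  β̂_Yj − θβ̂_Xj ~ N(0, V_j), V_j = σ²_Yj + τ² + θ²σ²_Xj. θ and the
  overdispersion τ² ≥ 0 solve the two score equations, iterated from the
  IVW start to 1e-8 with bracketed root-finding (error after 200
  iterations, with a trace). SE is the sandwich variance of the θ-score.
  As σ_X → 0 with τ² = 0 the score reduces to the IVW normal equations.
* **MR-PRESSO** — leave-one-out IVW estimates θ̂_{−j} give the observed
  global statistic RSS = Σ w_j(β̂_Yj − θ̂_{−j}β̂_Xj)². Parametric
  simulations (β̂*_X ~ N(β̂_X, σ_X), β̂*_Y ~ N(θ̂_{−j}β̂_X, σ_Y), fully
  seeded, default 1000) give the global p (rank), per-variant residual p
  values (Bonferroni-corrected over J; outlier if below α = 0.05) and a
  distortion p for the with/without-outlier estimate difference. The
  returned estimate is outlier-corrected IVW when outliers exist.
  Note the corrected per-variant p has a floor of J/(n_sims+1): with J = 50
  at α = 0.05 at least 1000 simulations are required for the outlier test
  to be able to reject at all.

A battery runner executes any subset with deterministic per-method seed
substreams (derived from one master seed, so repeated methods are
bit-identical and method order is irrelevant); individual method failures
are captured per-method without aborting the run.

All estimators are equivariant under rescaling of the outcome (β, SE) by
c > 0 and invariant under re-orienting any subset of variants (flipping
both β̂_X and β̂_Y signs).

## Diagnostics and filters

Cochran's Q uses ratio weights about the fixed-effect IVW estimate;
I² = max(0, (Q−df)/Q). Steiger filtering keeps a variant only when its
exposure variance explained z²_X/(n_exp+z²_X) strictly exceeds its outcome
variance explained, computed for binary outcomes with the effective sample
size 4/(1/cases + 1/controls) (a naive total-N alternative is available);
ties drop, and a per-variant p comes from the two-sample Fisher-z test on
the implied correlations. The confounder filter excludes any instrument
with a supplied confounder-GWAS association below α/n_tests (e.g.
0.05/732 ≈ 6.83×10⁻⁵ when correcting over 732 unique exposure variants —
n_tests is an explicit parameter because the union of instrument sets is
analysis-specific); variants absent from the confounder table are kept and
logged. Funnel (ratio vs |β̂_X|/σ_Y) and scatter plot data are exported as
tables with one fitted line per estimator (intercept 0 except Egger).

## Correlated cis instruments

Cis variants (near the gene encoding the measured protein) are analysed
per-variant by Wald ratios and jointly by generalized least squares with
outcome-error covariance Ω_ij = σ_Yi·σ_Yj·ρ_ij, where ρ is the signed LD
correlation (r, not r²):

    θ̂ = (bᵀΩ⁻¹b)⁻¹ bᵀΩ⁻¹y,   SE = √((bᵀΩ⁻¹b)⁻¹).

With ρ = I this equals fixed-effect IVW to numerical precision (asserted at
1e-10). LD matrices are validated for symmetry, unit diagonal and positive
semi-definiteness (tiny negative eigenvalues are clipped with a warning);
|ρ| = 1 pairs and condition numbers above 1e8 are errors rather than being
ridge-regularized, to keep estimates reproducible. Signs in ρ refer to the
originally reported alleles; rows flipped during harmonization re-sign the
corresponding rows/columns. The named three-variant cis set for the SHBG
protein (rs6761, rs1799941, rs858519; HapMap proxies rs12150660 and
rs727428) ships as identifiers only.

## Meta-analysis, cohorts and power

Per-variant outcome associations from several case–control cohorts are
combined by fixed-effect inverse-variance meta-analysis after harmonizing
alleles to a reference cohort; single-cohort variants are carried through
flagged, and sample/case counts are summed. A packaged cohort table (cases,
controls, totals, median fracture age for the four contributing biobanks)
supports offline bookkeeping: the three-cohort two-sample outcome set
totals 111,351 women with 8,823 cases; all four cohorts total 348,923 with
20,387 cases.

Binary-outcome power uses the mRnd risk-difference approximation: with case
fraction K and causal OR,

    b = K(OR/(1 + K(OR−1)) − 1),  v = (K(1−K) − b²)/(N·R²),  NCP = b²/v,

and power is the upper tail of a non-central χ²(1, NCP) beyond the central
(1−α) quantile; OR = 1 returns exactly α. A log-OR variant
(NCP = (ln OR)²·N·R²·K(1−K)) is provided because published detectable ORs
do not uniquely identify which variant produced them; bound-style checks
hold under both. The detectable-OR solver bisects on ln OR within
[−5, 5] (pulling the bracket end inside the domain where K(1−K) − b² > 0)
to |power − target| < 1e-8 and is the functional inverse of the power
formula on each monotone branch.

## Synthetic data generator

The generator emulates the summary statistics of a selected instrument set
against a biobank-scale binary outcome, directly on the summary level (no
genotypes): EAF ~ U(0.05, 0.95); instrument effects γ_j = sign·(0.5+|N(0,1)|)
rescaled so Σ2p_j(1−p_j)γ_j² equals the target total R² exactly. Magnitudes
are bounded away from zero deliberately: published instrument lists contain
only genome-wide-significant variants (each with F > 10), and near-null
instruments would introduce sign-misorientation artifacts (e.g. Egger
intercept attenuation) that are properties of an unrealistic design rather
than of the estimators. True outcome effects are θγ_j + α_j with α_j by
regime — balanced N(0, τ²); directional N(μ, τ²); InSIDE-violating with a
configured correlation to |γ| — defined in the exposure-increasing allele
orientation, since "directional" pleiotropy means the exposure-raising
allele also raises the outcome directly. Observed estimates add normal
noise with the analytic GWAS standard errors 1/√(2p(1−p)n_exp) and
1/√(2p(1−p)·n_out·K(1−K)) (the large-sample ln-OR approximation; exact
logistic simulation is out of scope). Reverse-causal variants get a direct
outcome effect with a weak induced exposure effect so their outcome r²
dominates. A master seed spawns independent substreams per component, so
later stages never perturb earlier draws, and runs are bit-reproducible.

Default design points mirror the study sizes the pipeline targets: 359
instruments / R² 0.176 / n_exp 189,473 (SHBG), 180 / 0.070 / 188,507
(bioavailable testosterone), 254 / 0.093 / 230,454 (total testosterone),
outcome N 111,351 with K ≈ 0.0792; cohort simulation defaults to the
73,617 / 36,028 / 1,706 three-cohort split. Cis blocks draw signed pairwise
correlations with r² uniform in [0.35, 0.53] and generate estimate noise
through the matrix's Cholesky factor.

What the generator does *not* model: LD among trans-instruments, winner's
curse from instrument discovery, sample overlap, covariate-adjustment
effects, population stratification, or correlated multi-exposure
structure. Passing recovery tests therefore demonstrate estimator
correctness under the stated model, not robustness to those features of
real data.

## Test conditions and numerical choices

Simulation-based checks are scaled to run on one CPU in seconds to a few
minutes: parameter recovery uses 200 replicates at the largest design point
(mean-recovery within 3 Monte-Carlo SEs of the mean; CI coverage over 500
replicates, where the binomial noise of a 200-replicate proportion would be
comparable to the width of the 93–97% acceptance band around the measured
~94.9% true coverage). At this design point the simulated exposure
estimates carry sampling error, so IVW shows the standard weak-instrument
dilution of ≈1.1% (bias ≈ −0.005 on θ = ln 1.61) — visible but within the
recovery tolerance. The sensitivity battery uses: directional regime
μ = 0.02, τ² = 1e-4, 30% invalid instruments (IVW bias ~4 of its SEs, the
weighted median within 3 of its Monte-Carlo-estimated SEs — note the
weighted median retains a finite-sample quantile-offset bias of order half
its sampling SD under one-sided contamination, which is the correct
behavior of the estimator, not an implementation artifact); balanced regime
τ² = 2e-4, comparable to the median per-variant outcome sampling variance;
Egger calibration at J = 100, R² = 0.05 over 500 replicates; PRESSO and
Steiger demonstrations at J = 50, R² = 0.05, with the injected outlier
placed in the largest-weight instrument (a weighted residual test carries
no information about a variant with near-zero weight).

Other numerical conventions: 95% intervals use the exact normal quantile
1.959964 (t for Egger); bootstrap and PRESSO p-values use the (1+k)/(n+1)
rank convention; RAPS root-brackets widen geometrically before failing;
the mode's zero-spread degeneracy returns the common ratio; TSV output is
written at 17 significant digits and read back with round-trip float
parsing so pipelines reproduce byte-identically.

## Limitations

Additive random-effects IVW, multivariable MR, contamination-mixture and
one-sample 2SLS estimators are out of scope. The confounder filter consumes
a pre-extracted association table (no live GWAS-database queries). Proxy
instruments are not LD-validated. The binary Steiger effective-sample-size
choice is an approximation the field has not standardized; both it and the
naive alternative are exposed. Power formulas assume the instrument R² is
known without error.
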