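# Methods

## Setting

`tsmr` performs two-sample Mendelian randomization: the exposure GWAS and
the outcome GWAS come from different cohorts, and only per-variant summary
associations are used.  The package was designed around a screen of
brain-imaging exposures (DTI white-matter measures at n ≈ 17,700; regional
volumes at n ≈ 19,600) against a biobank glaucoma outcome (8,591 cases,
210,201 controls), and its defaults and synthetic scenarios reflect that
geometry: standardized quantitative exposure effects, log-odds outcome
effects, and a heavily case-imbalanced binary outcome.

## Instrument selection

Filters run in a fixed order, and every variant that leaves the analysis is
logged with a stage and reason (`SelectionReport`); stage counts are
non-increasing by construction.

1. **Relevance:** p < 5×10⁻⁸, strict inequality.
2. **Independence:** greedy LD clumping at r² < 0.001.  Candidates are
   ranked by (p ascending, variant id) — the id tie-break makes results
   independent of input order — and each kept index variant eliminates all
   remaining candidates with r² at or above the threshold.  Clumping runs
   against a user-supplied r² matrix (e.g. precomputed from 1000 Genomes)
   rather than a live reference panel, keeping the pipeline hermetic.  No
   distance window is applied beyond the matrix's scope; variants absent
   from the matrix are dropped with a warning by default (configurable to
   keep-as-uncorrelated or error).
3. **Strand safety:** palindromic (A/T, C/G) variants are removed
   unconditionally.  No frequency-based rescue is attempted, which is why
   effect-allele frequency may be missing throughout.
4. **Harmonization:** outcome records are expressed on the exposure's
   effect allele: identical alleles are kept, swapped alleles negate the
   outcome beta, opposite-strand alleles are base-complemented first (a
   complement-plus-swap also negates; it is reported under the
   `strand_complemented` action).  Irreconcilable pairs are dropped with a
   reason.  Harmonizing an already-aligned pair is the identity.
5. **Directionality (Steiger):** variance explained is computed from the t
   statistic, r² = t²/(t² + n − 2), for both studies; a variant with
   r²_outcome > r²_exposure (strict) is removed as a probable
   reverse-direction variant, exact ties are kept with a flag, and each
   diagnostic carries the z-test p-value from comparing Fisher-transformed
   |correlations|.  The t-form is an approximation for a binary outcome; an
   allele-frequency-based r² (2·f·(1−f)·β²) is available via
   `r2_method="eaf"`.  The same drop rule is applied regardless, because
   binary-outcome t statistics are computed on the log-odds scale where the
   comparison remains monotone in association strength.

## Estimators

All estimators treat the outcome SEs as known (the standard summary-data
assumption, NO Measurement Error in the exposure not assumed — exposure
noise simply attenuates, and the synthetic studies quantify by how much).

* **IVW, multiplicative random effects (primary).**  WLS through the origin
  with weights 1/σ_Yj²; SE = √(1/Σw_jβ̂_Xj²) · max(1, √(Q/(J−1))).  The
  floor at 1 means overdispersion widens intervals but under-dispersion is
  never converted into spurious precision.  p-values use the standard
  normal; CIs are θ̂ ± 1.959964·SE.  Algebraically this equals the
  inverse-variance-weighted mean of Wald ratios with first-order weights
  β̂_Xj²/σ_Yj² (tested to 1e-10).
* **MR-Egger.**  Instruments are oriented so every β̂_Xj ≥ 0 (negating both
  betas, which leaves IVW invariant), then WLS with intercept.  SEs carry
  the same multiplicative floor with J−2 df; p-values use the t
  distribution with J−2 df.  This matches the convention of the widely used
  R implementation.  The combination of the floor and the t reference makes
  the intercept test conservative at small J: its true type-I rate at J = 20
  is ≈ 0.029 rather than 0.05 (by direct Monte-Carlo integration of the
  statistic's null distribution), which is visible in the calibration study.
  With the intercept constrained to zero the slope reproduces IVW exactly
  (a test-mode identity).
* **Weighted median.**  Ratios sorted ascending with normalized weights
  w_j = β̂_Xj²/σ_Yj²; breakpoints p_j = s_j − w_j/2; the estimate
  interpolates linearly to cumulative weight 1/2 (clamped at the extreme
  ratios).  The SE is a parametric bootstrap: both betas of every variant
  are redrawn from normals at their observed values and SEs, the median is
  recomputed, and the SE is the standard deviation over replicates
  (default 1000; the seed is mandatory).
* **Wald ratio** for single-instrument pairs: θ̂ = β̂_Y/β̂_X,
  SE = σ_Y/|β̂_X| (first-order).

Odds ratios are exp-transforms of estimate and CI; tables round OR/CI to 2
decimals and p to 3 significant figures while full precision is kept
internally.

## Sensitivity analysis

* **Cochran's Q** with first-order ratio weights; df = J−1 (IVW form) or
  J−2 (Egger form); upper-tail chi-square p.
* **MR-PRESSO.**  Observed residual sum RSS = Σ_j w_j(β̂_Yj − θ̂₋j·β̂_Xj)²
  with leave-one-out IVW predictions; the null distribution is simulated by
  redrawing both betas (outcome centered at the leave-one-out prediction);
  global and per-variant p-values use add-one smoothing
  (1+#exceed)/(1+n_sim), per-variant p-values are Bonferroni-corrected by J
  and flagged below 0.05.  The outlier-corrected estimate is IVW on the
  unflagged set (identical to the raw estimate when nothing is flagged);
  the distortion p compares the raw-vs-corrected difference against
  differences from removing random subsets of the outlier count — a
  bootstrap-flavored approximation chosen for simplicity.  Below 4
  instruments the method returns a structured `performed = False` with
  reason `insufficient_snps` instead of raising, so a 3-SNP exposure still
  yields a complete report.  Defaults: n_sim = 1000, mandatory seed.
* **Leave-one-out:** multiplicative random-effects IVW on every (J−1)
  subset plus the full set; the robustness flag records whether the reduced
  sets agree with the full set about excluding zero.

## Pipeline

`run_pair` chains the stages and degrades by instrument count (1: Wald
only; 2: +IVW; ≥3: +Egger, weighted median, leave-one-out; ≥4: +PRESSO);
each of the seven analysis components is either present or carries a skip
reason.  The decision rule is exactly *IVW p < α* (default 0.05); the
additional estimators corroborate but never change the decision, and pairs
without an IVW estimate (fewer than 2 instruments) are not significant by
definition.  `run_matrix` screens many exposures with no multiple-testing
adjustment by default — the screen-at-nominal-α design — with Bonferroni
and Benjamini–Hochberg available.  Runs are deterministic: sub-seeds for
the bootstrap and PRESSO are derived from the config seed and recorded in
the run metadata together with input checksums, and re-rendering is
byte-identical.

## Synthetic data

The generator plants J instruments with true effects γ_j ~ N(0.15, 0.02²)
on a standardized exposure scale, MAF ~ U(0.2, 0.5), and sampling SEs
1/√(2·maf·(1−maf)·n), with binary-outcome SEs further inflated by
1/√(v(1−v)) for case fraction v (default ≈ 0.039, the FinnGen-like
imbalance).  These defaults were chosen so that relevance is actually
plantable: at n = 20,000 a planted instrument reaches p < 5×10⁻⁸ in over
99% of draws (weaker defaults, e.g. γ ≈ 0.05, would sit at z ≈ 4–5 and
routinely fail genome-wide significance, making selection tests
meaningless).  Invalid instruments (count = invalid_fraction·J, rounded
half-up) receive pleiotropic effects α_j — balanced (mean 0) or directional
(mean 0.1) — and the InSIDE assumption can be violated by correlating α_j
with γ_j (ρ = 0.8 by default when on).  Null background variants (γ = 0)
pad the tables; the LD matrix is block-diagonal with planted instruments as
singleton blocks and nulls grouped (default blocks of five at r² = 0.8).
Configured fractions of variants are palindromic, strand-flipped (outcome
labels complemented; never for palindromes, which are unresolvable), or
allele-swapped (labels exchanged, beta negated), exercising every
harmonization branch.

What the generator does *not* emulate: realistic chromosome-scale LD,
winner's-curse selection of instruments, sample overlap between the two
GWAS, population stratification, and non-normal effect-size distributions.
Passing calibration on synthetic data therefore demonstrates correctness of
the estimators and pipeline under the stated generative model, not
robustness to those real-data pathologies.

### Study sizes

The calibration studies use: parameter recovery 200 replicates (θ = 0.5,
J = 50, n = 20,000 both sides); type-I error 1000 replicates (θ = 0,
J = 20); weighted-median breakdown 200 replicates per arm; PRESSO null 500
replicates at n_sim = 1000; outlier recovery 100 replicates.  The breakdown
arms use a quantitative outcome at n = 100,000 with γ ~ N(0.15, 0.02²) and
directional pleiotropy of mean 0.1: that places the per-ratio noise at
≈ 0.035, small enough that the median's bias below the 50% breakdown point
stays under 0.05 while the 60%-invalid arm is displaced by
≈ α/γ ≈ 0.65 — a design chosen by power analysis before any measurement.

## Known limitations

* Steiger filtering on a binary outcome uses the t-statistic r² as an
  approximation; liability-scale variance explained is not computed.
* No proxy-variant lookup for instruments missing from the outcome study,
  no multivariable MR, no mode-based or contamination-mixture estimators.
* The Egger intercept test inherits the conservatism described above at
  small J.
* MR-PRESSO's distortion test follows the bootstrap-style reassignment
  described here; published implementations differ in detail and the
  original algorithm's distortion flavor is not uniquely specified.
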